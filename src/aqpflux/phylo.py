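"""Trees, substitution models, pruning likelihood and ancestral states.

Trees are dendropy objects throughout; leaf taxon labels must match
alignment record ids.  Substitution models cover JC69, K2P and TN93 with
uniform rates across sites; likelihoods are computed by Felsenstein's
pruning algorithm and ancestral sequences by marginal posterior
reconstruction at a (re)rooted node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .seqio import Alignment

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def read_tree(source: str | Path) -> dendropy.Tree:
    """Read a Newick tree from a path or a literal Newick string."""
    text = str(source)
    if "(" not in text:
        text = Path(source).read_text()
    return dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)


def write_tree(tree: dendropy.Tree, dest: str | Path | None = None) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    if dest is not None:
        Path(dest).write_text(s)
    return s


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Substitution models


@dataclass
class SubstModel:
    """A reversible nucleotide model (JC69, K2P or TN93), uniform rates.

    ``kappa1``/``kappa2`` are the purine (A<->G) and pyrimidine (C<->T)
    transition rates relative to a transversion rate of 1; K2P uses
    kappa1 = kappa2 = kappa.  The generator is scaled to one expected
    substitution per site per unit branch length.
    """

    name: str = "JC69"
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    kappa1: float = 1.0
    kappa2: float = 1.0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.name not in ("JC69", "K2P", "TN93"):
            raise ValueError(f"unknown model {self.name}")
        if self.name in ("JC69", "K2P"):
            self.freqs = np.full(4, 0.25)
        if abs(self.freqs.sum() - 1.0) > 1e-8 or (self.freqs < 0).any():
            raise ValueError("base frequencies must be nonnegative and sum to 1")
        if self.kappa1 <= 0 or self.kappa2 <= 0:
            raise ValueError("rates must be positive")
        if self.name == "JC69" and (self.kappa1 != 1.0 or self.kappa2 != 1.0):
            raise ValueError("JC69 has no free rate parameters")
        if self.name == "K2P" and self.kappa1 != self.kappa2:
            raise ValueError("K2P uses a single transition/transversion ratio")

    def rate_matrix(self) -> np.ndarray:
        """Scaled generator Q (order ACGT), mean rate 1."""
        pi = self.freqs
        q = np.zeros((4, 4))
        transitions = {(0, 2): self.kappa1, (2, 0): self.kappa1,
                       (1, 3): self.kappa2, (3, 1): self.kappa2}
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                q[i, j] = transitions.get((i, j), 1.0) * pi[j]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu

    def transition_probs(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be >= 0")
        return expm(self.rate_matrix() * t)


def jc69_pair_loglik(a: str, b: str, t: float) -> float:
    """Closed-form JC69 log-likelihood of two sequences at distance t."""
    same = 0.25 * (0.25 + 0.75 * math.exp(-4.0 * t / 3.0))
    diff = 0.25 * (0.25 - 0.25 * math.exp(-4.0 * t / 3.0))
    ll = 0.0
    for x, y in zip(a, b):
        ll += math.log(same if x == y else diff)
    return ll


# ---------------------------------------------------------------------------
# Pruning likelihood


def _leaf_partial(residue: str) -> np.ndarray:
    v = np.zeros(4)
    if residue in _BASE_INDEX:
        v[_BASE_INDEX[residue]] = 1.0
    else:  # N, gap: no information
        v[:] = 1.0
    return v


def _partials(tree: dendropy.Tree, aln: Alignment, model: SubstModel):
    """Postorder partial likelihoods; returns (partials dict, log-scale)."""
    seqs = {r.id: r.residues for r in aln.records}
    labels = set(leaf_labels(tree))
    if labels != set(seqs):
        raise ValueError(
            f"tree leaves and alignment ids differ: {sorted(labels ^ set(seqs))}"
        )
    n_sites = aln.n_columns
    partials: dict[int, np.ndarray] = {}
    log_scale = np.zeros(n_sites)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = seqs[node.taxon.label]
            partials[id(node)] = np.stack([_leaf_partial(c) for c in s])
        else:
            p = np.ones((n_sites, 4))
            for child in node.child_nodes():
                t = child.edge.length
                if t is None:
                    t = 0.0
                if t < 0:
                    raise ValueError("negative branch length")
                P = model.transition_probs(t)
                p *= partials[id(child)] @ P.T
            mx = p.max(axis=1)
            mx[mx == 0.0] = 1.0
            log_scale += np.log(mx)
            partials[id(node)] = p / mx[:, None]
    return partials, log_scale


def tree_loglik(tree: dendropy.Tree, aln: Alignment, model: SubstModel) -> float:
    """Felsenstein pruning log-likelihood, additive over sites."""
    partials, log_scale = _partials(tree, aln, model)
    root = tree.seed_node
    site_lik = partials[id(root)] @ model.freqs
    return float(np.sum(np.log(site_lik)) + log_scale.sum())


def fit_tn93(tree: dendropy.Tree, aln: Alignment, tol: float = 1e-8) -> SubstModel:
    """TN93 with empirical base frequencies and ML transition rates.

    The two transition/transversion rates are optimized on the fixed
    topology and branch lengths; frequencies are empirical counts over
    the alignment.
    """
    counts = np.zeros(4)
    for r in aln.records:
        for c in r.residues:
            if c in _BASE_INDEX:
                counts[_BASE_INDEX[c]] += 1
    freqs = counts / counts.sum()

    def neg_ll(x: np.ndarray) -> float:
        m = SubstModel("TN93", freqs, math.exp(x[0]), math.exp(x[1]))
        return -tree_loglik(tree, aln, m)

    res = minimize(neg_ll, x0=[math.log(2.0), math.log(2.0)], method="Nelder-Mead",
                   options={"xatol": tol, "fatol": tol, "maxiter": 2000})
    return SubstModel("TN93", freqs, math.exp(res.x[0]), math.exp(res.x[1]))


# ---------------------------------------------------------------------------
# Marginal ancestral states


@dataclass(frozen=True)
class AncestralResult:
    """Per-site marginal posteriors and the most-probable sequence."""

    posterior: np.ndarray          # (n_sites, 4), rows sum to 1, order ACGT
    sequence: str                  # argmax per site, ties -> A < C < G < T
    ties: np.ndarray               # boolean per site: posterior tie at max


def _node_by_leafset(tree: dendropy.Tree, labels: set[str]):
    node = tree.mrca(taxon_labels=sorted(labels))
    if node is None:
        raise ValueError("no node with that leaf set")
    return node


def ancestral_states(
    tree: dendropy.Tree,
    aln: Alignment,
    model: SubstModel,
    node_leaves: set[str] | None = None,
) -> AncestralResult:
    """Marginal ML reconstruction at a node of a rooted tree.

    ``node_leaves`` identifies the target node by the set of leaf labels
    below it (default: the root).  For non-root nodes the tree is cloned
    and rerooted there, which is exact for reversible models.
    """
    work = tree
    if node_leaves is not None:
        target = _node_by_leafset(tree, set(node_leaves))
        if target is not tree.seed_node:
            if target.is_leaf():
                raise ValueError("ancestral state target must be internal")
            work = tree.clone(depth=1)
            t2 = _node_by_leafset(work, set(node_leaves))
            work.reroot_at_node(t2, update_bipartitions=False)
    partials, _ = _partials(work, aln, model)
    p = partials[id(work.seed_node)] * model.freqs
    posterior = p / p.sum(axis=1, keepdims=True)
    best = posterior.argmax(axis=1)
    mx = posterior.max(axis=1)
    ties = (np.abs(posterior - mx[:, None]) < 1e-12).sum(axis=1) > 1
    seq = "".join(BASES[i] for i in best)
    return AncestralResult(posterior, seq, ties)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dist: np.ndarray, ids: list[str]) -> dendropy.Tree:
    """Classic neighbor joining on a symmetric zero-diagonal matrix.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch, preserving the joined pair's path length.  The
    final two clusters are connected through a root node splitting the
    remaining distance equally (the placement of this root carries no
    information; treat the result as unrooted).
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(ids):
        raise ValueError("matrix/ids size mismatch")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have zero diagonal")
    if n < 2:
        raise ValueError("need at least two taxa")

    # each active cluster is a newick fragment
    nodes = [f"{_quote(l)}" for l in ids]
    d = d.copy()
    active = list(range(n))

    def _join(i: int, j: int, li: float, lj: float) -> str:
        return f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_label = _join(i, j, li, lj)
        # distances from the new node to the remaining clusters
        new_d = {}
        for ak in active:
            if ak in (i, j):
                continue
            new_d[ak] = 0.5 * (d[i, ak] + d[j, ak] - dij)
        nodes[i] = new_label
        for ak, val in new_d.items():
            d[i, ak] = d[ak, i] = max(val, 0.0)
        active.remove(j)

    i, j = active
    half = max(d[i, j], 0.0) / 2.0
    newick = f"({nodes[i]}:{half:.10g},{nodes[j]}:{half:.10g});"
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def _quote(label: str) -> str:
    if any(c in label for c in "(),:;[] '\t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def tree_path_lengths(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths, keyed by sorted label pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for a in range(len(taxa)):
        for b in range(a + 1, len(taxa)):
            key = tuple(sorted((taxa[a].label, taxa[b].label)))
            out[key] = pdm.patristic_distance(taxa[a], taxa[b])
    return out
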