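"""NJ construction, pruning likelihood, model fits and ancestral states."""

import itertools
import math

import dendropy
import numpy as np
import pytest

from aqpflux.molevo import jc_matrix
from aqpflux.phylo import (
    SubstModel,
    ancestral_states,
    fit_tn93,
    jc69_pair_loglik,
    nj_tree,
    read_tree,
    tree_loglik,
    tree_path_lengths,
    write_tree,
)
from aqpflux.seqio import Alignment, SeqRecord


class TestSubstModel:
    def test_rate_matrix_rows_sum_to_zero(self):
        for m in (SubstModel("JC69"),
                  SubstModel("K2P", kappa1=2.0, kappa2=2.0),
                  SubstModel("TN93", np.array([0.3, 0.2, 0.3, 0.2]), 3.0, 5.0)):
            q = m.rate_matrix()
            assert np.allclose(q.sum(axis=1), 0.0)
            assert -(m.freqs * np.diag(q)).sum() == pytest.approx(1.0)

    def test_transition_probs_rows_sum_to_one(self):
        P = SubstModel("TN93", np.array([0.4, 0.1, 0.2, 0.3]), 2.0, 4.0).transition_probs(0.3)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert (P >= 0).all()

    def test_stationarity(self):
        m = SubstModel("TN93", np.array([0.4, 0.1, 0.2, 0.3]), 2.0, 4.0)
        assert np.allclose(m.freqs @ m.transition_probs(5.0), m.freqs)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SubstModel("HKY")
        with pytest.raises(ValueError):
            SubstModel("TN93", np.array([0.5, 0.5, 0.5, 0.5]))


class TestNeighborJoining:
    def test_two_taxa_split_evenly(self):
        t = nj_tree(np.array([[0.0, 0.4], [0.4, 0.0]]), ["a", "b"])
        lengths = {l.taxon.label: l.edge.length for l in t.leaf_node_iter()}
        assert lengths == {"a": pytest.approx(0.2), "b": pytest.approx(0.2)}

    def test_additive_four_taxon_recovery(self):
        # generating tree: ((A:1,B:2):3,(C:4,D:5)) -> additive distances
        d = np.array([[0, 3, 8, 9],
                      [3, 0, 9, 10],
                      [8, 9, 0, 9],
                      [9, 10, 9, 0]], dtype=float)
        t = nj_tree(d, list("ABCD"))
        paths = tree_path_lengths(t)
        for (i, a) in enumerate("ABCD"):
            for (j, b) in enumerate("ABCD"):
                if i < j:
                    assert paths[(a, b)] == pytest.approx(d[i, j])

    def test_matches_skbio_topology(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        n = 7
        ids = [f"x{i}" for i in range(n)]
        # random additive-ish matrix from random points
        pts = rng.random((n, 5))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, 0.0)
        ours = nj_tree(d, ids)
        theirs = skbio_nj(DistanceMatrix(d, ids))
        ours_dp = dendropy.Tree.get(data=write_tree(ours), schema="newick",
                                    preserve_underscores=True)
        theirs_dp = dendropy.Tree.get(data=str(theirs),
                                      schema="newick", preserve_underscores=True,
                                      taxon_namespace=ours_dp.taxon_namespace)
        ours_dp.encode_bipartitions()
        theirs_dp.encode_bipartitions()
        ours_bips = {b.split_as_bitstring() for b in ours_dp.bipartition_encoding}
        theirs_bips = {b.split_as_bitstring() for b in theirs_dp.bipartition_encoding}
        assert ours_bips == theirs_bips

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(d, ["a", "b"])


def exhaustive_site_likelihood(tree_newick, seqs, model):
    """Oracle: sum over all internal-state assignments, per site."""
    tree = read_tree(tree_newick)
    tree.is_rooted = True
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    n_sites = len(next(iter(seqs.values())))
    idx = {b: i for i, b in enumerate("ACGT")}
    total = 0.0
    for site in range(n_sites):
        lik = 0.0
        for states in itertools.product(range(4), repeat=len(internal)):
            assign = {id(n): s for n, s in zip(internal, states)}
            for n in nodes:
                if n.is_leaf():
                    assign[id(n)] = idx[seqs[n.taxon.label][site]]
            p = model.freqs[assign[id(tree.seed_node)]]
            for n in nodes:
                if n is tree.seed_node:
                    continue
                P = model.transition_probs(n.edge.length or 0.0)
                p *= P[assign[id(n.parent_node)], assign[id(n)]]
            lik += p
        total += math.log(lik)
    return total


class TestPruningLikelihood:
    def test_single_leaf_closed_form(self):
        tree = read_tree("(x:0.0);")
        aln = Alignment([SeqRecord("x", "ACG")])
        ll = tree_loglik(tree, aln, SubstModel("JC69"))
        assert ll == pytest.approx(3 * math.log(0.25))

    def test_two_leaf_jc_closed_form(self):
        a, b = "ACGTACGTACGTAC", "ACGTACTTACGGAC"
        tree = read_tree("(x:0.07,y:0.05);")
        aln = Alignment([SeqRecord("x", a), SeqRecord("y", b)])
        ll = tree_loglik(tree, aln, SubstModel("JC69"))
        assert ll == pytest.approx(jc69_pair_loglik(a, b, 0.12), abs=1e-9)

    def test_matches_exhaustive_enumeration(self):
        newick = "((a:0.1,b:0.2):0.05,(c:0.3,d:0.15):0.1);"
        seqs = {"a": "ACG", "b": "ACT", "c": "GCG", "d": "ACG"}
        model = SubstModel("TN93", np.array([0.35, 0.15, 0.25, 0.25]), 2.0, 3.0)
        aln = Alignment([SeqRecord(k, v) for k, v in seqs.items()])
        tree = read_tree(newick)
        assert tree_loglik(tree, aln, model) == pytest.approx(
            exhaustive_site_likelihood(newick, seqs, model), abs=1e-9)

    def test_rerooting_invariance(self):
        seqs = {"a": "ACGTAC", "b": "ACTTAC", "c": "GCGTAA", "d": "ACGGAC"}
        aln = Alignment([SeqRecord(k, v) for k, v in seqs.items()])
        model = SubstModel("K2P", kappa1=2.0, kappa2=2.0)
        t1 = read_tree("((a:0.1,b:0.2):0.05,(c:0.3,d:0.15):0.1);")
        # same unrooted tree, rooted at the 'a' leaf edge instead
        t2b = read_tree("((b:0.2,(c:0.3,d:0.15):0.15):0.1,a:0.0);")
        ll1 = tree_loglik(t1, aln, model)
        ll2 = tree_loglik(t2b, aln, model)
        assert ll1 == pytest.approx(ll2, abs=1e-9)

    def test_negative_branch_rejected(self):
        tree = read_tree("(a:-0.1,b:0.1);")
        aln = Alignment([SeqRecord("a", "A"), SeqRecord("b", "A")])
        with pytest.raises(ValueError, match="negative"):
            tree_loglik(tree, aln, SubstModel("JC69"))


class TestAncestralStates:
    def test_uniform_site_reconstructs_shared_state(self):
        tree = read_tree("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);")
        tree.is_rooted = True
        aln = Alignment([SeqRecord(x, "CCC") for x in "abcd"])
        res = ancestral_states(tree, aln, SubstModel("JC69"))
        assert res.sequence == "CCC"
        assert (res.posterior[:, 1] > 0.9).all()

    def test_symmetric_two_leaf_tie(self):
        tree = read_tree("(a:0.1,b:0.1);")
        tree.is_rooted = True
        aln = Alignment([SeqRecord("a", "A"), SeqRecord("b", "C")])
        res = ancestral_states(tree, aln, SubstModel("JC69"))
        assert res.posterior[0, 0] == pytest.approx(res.posterior[0, 1])
        assert res.ties[0]
        assert res.sequence == "A"    # tie broken by fixed base order

    def test_non_root_node_by_leafset(self):
        tree = read_tree("((a:0.05,b:0.05):0.3,(c:0.05,d:0.05):0.3);")
        tree.is_rooted = True
        aln = Alignment([SeqRecord("a", "A"), SeqRecord("b", "A"),
                         SeqRecord("c", "T"), SeqRecord("d", "T")])
        res = ancestral_states(tree, aln, SubstModel("JC69"), node_leaves={"a", "b"})
        assert res.sequence == "A"
        res2 = ancestral_states(tree, aln, SubstModel("JC69"), node_leaves={"c", "d"})
        assert res2.sequence == "T"


class TestTN93Fit:
    def test_recovers_transition_bias_direction(self, rng):
        # simulate on a pair with strong purine-transition bias; the
        # fitted kappa1 should exceed kappa2's neighborhood of 1
        true = SubstModel("TN93", np.array([0.3, 0.2, 0.3, 0.2]), 8.0, 1.0)
        P = true.transition_probs(0.2)
        base_idx = rng.choice(4, size=4000, p=true.freqs)
        child_idx = np.array([rng.choice(4, p=P[i]) for i in base_idx])
        a = "".join("ACGT"[i] for i in base_idx)
        b = "".join("ACGT"[i] for i in child_idx)
        aln = Alignment([SeqRecord("x", a), SeqRecord("y", b)])
        tree = read_tree("(x:0.1,y:0.1);")
        fitted = fit_tn93(tree, aln)
        assert fitted.kappa1 > 2.0
        assert fitted.kappa1 > fitted.kappa2
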