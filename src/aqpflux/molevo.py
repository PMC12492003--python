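"""Codon-level molecular evolution: gap-codon removal, Jukes-Cantor
distances, and Nei-Gojobori (NG86) dN/dS with between-group means and
codon-bootstrap standard errors.

The NG86 scheme counts, for every sense codon, the fraction of
single-nucleotide changes at each position that are synonymous (changes
creating stop codons are excluded from the denominator), giving fractional
synonymous (S) and nonsynonymous (N) site counts with S + N = 3 per codon.
Observed differences between two codons are averaged over all mutational
pathways that avoid stop-codon intermediates.  Proportions pS = Sd/S and
pN = Nd/N are Jukes-Cantor corrected to per-site distances dS and dN.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .seqio import Alignment, SeqRecord

BASES = "ACGT"

#: Standard genetic code, codon -> one-letter amino acid ("*" = stop).
from Bio.Data import CodonTable as _CodonTable

_STD_TABLE = _CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_STD_TABLE.forward_table)
GENETIC_CODE.update({c: "*" for c in _STD_TABLE.stop_codons})

STOP_CODONS = frozenset(c for c, a in GENETIC_CODE.items() if a == "*")
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))


def translate(nt: str) -> str:
    """Translate an ungapped in-frame nucleotide string."""
    if len(nt) % 3:
        raise ValueError("length not divisible by 3")
    return "".join(GENETIC_CODE.get(nt[i:i + 3], "X") for i in range(0, len(nt), 3))


class SaturationError(ValueError):
    """A proportion of differences >= 0.75 cannot be Jukes-Cantor corrected."""


def jc_distance(p: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3) for 0 <= p < 0.75."""
    if p < 0:
        raise ValueError("proportion of differences must be >= 0")
    if p >= 0.75:
        raise SaturationError(f"p = {p:.4f} >= 0.75: saturated, JC correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class CodonAlignment:
    """A gap-free, in-frame nucleotide alignment."""

    alignment: Alignment

    def __post_init__(self) -> None:
        if self.alignment.n_columns % 3:
            raise ValueError("codon alignment length not divisible by 3")
        for r in self.alignment.records:
            if "-" in r.residues:
                raise ValueError(f"gap remaining in codon alignment record {r.id}")

    @property
    def n_codons(self) -> int:
        return self.alignment.n_columns // 3

    @property
    def ids(self) -> list[str]:
        return self.alignment.ids

    def codons(self, seq_id: str) -> list[str]:
        s = self.alignment[seq_id].residues
        return [s[i:i + 3] for i in range(0, len(s), 3)]


def remove_gap_codons(aln: Alignment) -> CodonAlignment:
    """Delete whole codon column-triplets containing any gap in any sequence.

    This is the frame-preserving analogue of complete gap deletion: a
    triplet (3k, 3k+1, 3k+2) is dropped for all sequences iff any sequence
    has a gap in any of its three columns, so the reading frame never
    shifts.
    """
    if aln.n_columns % 3:
        raise ValueError("alignment length not divisible by 3")
    keep: list[int] = []
    for k in range(aln.n_columns // 3):
        cols = range(3 * k, 3 * k + 3)
        if not any("-" in aln.column(j) for j in cols):
            keep.extend(cols)
    records = [
        SeqRecord(r.id, "".join(r.residues[j] for j in keep), r.alphabet)
        for r in aln.records
    ]
    return CodonAlignment(Alignment(records))


# ---------------------------------------------------------------------------
# NG86 counting


@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """Fractional synonymous site count S(codon) under NG86.

    At each codon position the three single-nucleotide changes are
    examined; changes creating stop codons are excluded from the
    denominator.  The nonsynonymous count is 3 - S.
    """
    if codon in STOP_CODONS or len(codon) != 3:
        raise ValueError(f"not a sense codon: {codon}")
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if GENETIC_CODE[alt] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s


@lru_cache(maxsize=None)
def pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, pathway-averaged.

    All orders of applying the differing positions are enumerated;
    pathways passing through stop-codon intermediates are discarded.  In
    the rare case that every pathway is blocked, all pathways are used
    (steps into/out of stops counted by the amino-acid change they imply).
    """
    for c in (c1, c2):
        if c in STOP_CODONS or len(c) != 3:
            raise ValueError(f"not a sense codon: {c}")
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        cur = c1
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and not allow_stops and nxt != c2:
                return None
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [r for o in itertools.permutations(diff) if (r := walk(o, False))]
    if not results:
        results = [walk(o, True) for o in itertools.permutations(diff)]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


@dataclass(frozen=True)
class NG86Result:
    """Pairwise NG86 counts; JC-corrected distances computed on access.

    ``dS``/``dN`` raise :class:`SaturationError` when the corresponding
    proportion reaches 0.75 (the counts themselves are always valid).
    """

    S: float
    N: float
    Sd: float
    Nd: float
    n_codons: int          # codons compared (stop-containing codons excluded)

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S > 0 else 0.0

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N > 0 else 0.0

    @property
    def dS(self) -> float:
        return jc_distance(self.pS)

    @property
    def dN(self) -> float:
        return jc_distance(self.pN)

    @property
    def ratio(self) -> float:
        dS = self.dS
        if dS <= 0:
            raise ZeroDivisionError("dN/dS undefined: dS = 0")
        return self.dN / dS


def _codon_arrays(codons_a: list[str], codons_b: list[str]) -> tuple[np.ndarray, ...]:
    """Per-codon (s, n, sd, nd, valid) arrays for one sequence pair."""
    m = len(codons_a)
    s = np.zeros(m)
    n = np.zeros(m)
    sd = np.zeros(m)
    nd = np.zeros(m)
    valid = np.zeros(m, dtype=bool)
    for k, (ca, cb) in enumerate(zip(codons_a, codons_b)):
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        valid[k] = True
        s[k] = 0.5 * (synonymous_sites(ca) + synonymous_sites(cb))
        n[k] = 3.0 - s[k]
        sd[k], nd[k] = pathway_differences(ca, cb)
    return s, n, sd, nd, valid


def _distances_from_sums(S: float, N: float, Sd: float, Nd: float) -> tuple[float, float, float, float]:
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    return pS, pN, jc_distance(pS), jc_distance(pN)


def ng86_pair(a: str | SeqRecord, b: str | SeqRecord) -> NG86Result:
    """NG86 synonymous/nonsynonymous sites, differences and distances.

    Both sequences must be gap-free, in frame and of equal length; codons
    containing a stop in either sequence are excluded entirely.
    """
    sa = a.residues if isinstance(a, SeqRecord) else a.upper()
    sb = b.residues if isinstance(b, SeqRecord) else b.upper()
    if len(sa) != len(sb):
        raise ValueError("sequences must be equal length")
    if len(sa) % 3:
        raise ValueError("length not divisible by 3")
    if "-" in sa or "-" in sb:
        raise ValueError("gaps present; run remove_gap_codons first")
    ca = [sa[i:i + 3] for i in range(0, len(sa), 3)]
    cb = [sb[i:i + 3] for i in range(0, len(sb), 3)]
    s, n, sd, nd, valid = _codon_arrays(ca, cb)
    return NG86Result(float(s.sum()), float(n.sum()), float(sd.sum()),
                      float(nd.sum()), int(valid.sum()))


# ---------------------------------------------------------------------------
# Between-group means with codon bootstrap


@dataclass
class GroupAssignment:
    """seq_id -> group label (e.g. Gp1 / Gp2 / N20 / other)."""

    labels: dict[str, str]

    def members(self, group: str) -> list[str]:
        return [i for i, g in self.labels.items() if g == group]


@dataclass(frozen=True)
class GroupDistanceResult:
    """Mean between-group dN/dS with bootstrap standard errors."""

    dN: float
    dS: float
    dN_se: float
    dS_se: float
    n_boot: int

    @property
    def ratio(self) -> float:
        if self.dS <= 0:
            raise ZeroDivisionError("dN/dS undefined: dS = 0")
        return self.dN / self.dS


def group_mean_dn_ds(
    caln: CodonAlignment,
    groups: GroupAssignment,
    group_a: str,
    group_b: str,
    n_boot: int = 500,
    seed: int | None = None,
) -> GroupDistanceResult:
    """Mean NG86 dN and dS over all cross-group sequence pairs.

    The statistic is the arithmetic mean of the per-pair JC-corrected
    distances (within-group diversity is not netted off, matching the
    plain between-group mean).  Standard errors come from resampling codon
    sites with replacement, the same sites for every pair, ``n_boot``
    times; ``seed`` is required when ``n_boot`` > 0.
    """
    ids_a = groups.members(group_a)
    ids_b = groups.members(group_b)
    if not ids_a or not ids_b:
        raise ValueError("both groups must be nonempty")
    pairs = [(i, j) for i in ids_a for j in ids_b]
    arrays = []
    for i, j in pairs:
        try:
            arrays.append(_codon_arrays(caln.codons(i), caln.codons(j)))
        except SaturationError as exc:  # pragma: no cover - re-raise with names
            raise SaturationError(f"pair ({i}, {j}): {exc}") from exc

    def mean_stat(idx: np.ndarray | slice) -> tuple[float, float]:
        dns, dss = [], []
        for (i, j), (s, n, sd, nd, _v) in zip(pairs, arrays):
            try:
                _, _, dS, dN = _distances_from_sums(
                    s[idx].sum(), n[idx].sum(), sd[idx].sum(), nd[idx].sum()
                )
            except SaturationError as exc:
                raise SaturationError(f"pair ({i}, {j}): {exc}") from exc
            dns.append(dN)
            dss.append(dS)
        return float(np.mean(dns)), float(np.mean(dss))

    dN, dS = mean_stat(slice(None))
    dN_se = dS_se = 0.0
    if n_boot > 0:
        if seed is None:
            raise ValueError("seed required for bootstrap")
        rng = np.random.default_rng(seed)
        m = caln.n_codons
        reps = np.empty((n_boot, 2))
        for r in range(n_boot):
            idx = rng.integers(0, m, size=m)
            reps[r] = mean_stat(idx)
        dN_se = float(np.std(reps[:, 0], ddof=1))
        dS_se = float(np.std(reps[:, 1], ddof=1))
    return GroupDistanceResult(dN, dS, dN_se, dS_se, n_boot)


def p_distance(a: str | SeqRecord, b: str | SeqRecord, ignore_gaps: bool = True) -> float:
    """Proportion of differing sites between two equal-length sequences."""
    sa = a.residues if isinstance(a, SeqRecord) else a.upper()
    sb = b.residues if isinstance(b, SeqRecord) else b.upper()
    if len(sa) != len(sb):
        raise ValueError("sequences must be equal length")
    diff = comp = 0
    for x, y in zip(sa, sb):
        if ignore_gaps and "-" in (x, y):
            continue
        comp += 1
        diff += x != y
    if comp == 0:
        raise ValueError("no comparable sites")
    return diff / comp


def jc_matrix(aln: Alignment) -> tuple[np.ndarray, list[str]]:
    """Pairwise Jukes-Cantor distance matrix over an alignment."""
    ids = aln.ids
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jc_distance(
                p_distance(aln.records[i], aln.records[j])
            )
    return d, ids
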