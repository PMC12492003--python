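"""Aromatic/arginine (ar/R) selectivity-filter extraction and classification.

Aquaporin pores constrict at four residues, the ar/R selectivity filter.
For Aqp10s, bulky aromatic residues at filter positions 1 and 3 narrow the
pore and restrict permeation to water and glycerol; replacing the position-3
aromatic with a small residue (e.g. the Y->G substitution in eel Aqp10.2b2/b3)
widens the pore and admits urea and boric acid as well.

Filter positions are supplied as 1-based indices into an ungapped reference
sequence and mapped through the alignment, so every aligned sequence's filter
residues can be read off the same four columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .seqio import Alignment

logger = logging.getLogger(__name__)

#: Residues counted as aromatic for the selectivity rule.  Histidine is
#: excluded: the Aqp10 filters contrast F/Y against small residues (A/G/S)
#: and never use H.
AROMATIC = frozenset("FYW")

#: Default anchor: European eel Aqp10.2b1, whose filter position 3 is
#: residue 205 (the Y mutated to G in the broad-selectivity paralogs).
#: Positions 1, 2 and 4 are fixture conventions recorded here, not
#: published coordinates.
DEFAULT_REFERENCE_ID = "AanAqp10.2b1"
DEFAULT_REFERENCE_POSITIONS = (85, 201, 205, 219)


@dataclass(frozen=True)
class FilterSpec:
    """Where the four filter residues sit in an ungapped reference."""

    reference_id: str = DEFAULT_REFERENCE_ID
    reference_positions: tuple[int, int, int, int] = DEFAULT_REFERENCE_POSITIONS

    def __post_init__(self) -> None:
        p = self.reference_positions
        if len(p) != 4:
            raise ValueError("exactly four filter positions required")
        if any(x < 1 for x in p) or list(p) != sorted(set(p)):
            raise ValueError("filter positions must be strictly increasing and >= 1")


@dataclass(frozen=True)
class ArRFilter:
    """One sequence's four filter residues plus its selectivity call."""

    seq_id: str
    residues: tuple[str, str, str, str]
    columns: tuple[int, int, int, int]
    selectivity_call: str  # "broad" | "narrow" | "unclassifiable"


def map_filter_columns(aln: Alignment, spec: FilterSpec) -> tuple[int, int, int, int]:
    """Map ungapped reference positions to 0-based alignment columns."""
    ref = aln[spec.reference_id]
    cols = []
    ungapped = 0
    wanted = {p: None for p in spec.reference_positions}
    for j, ch in enumerate(ref.residues):
        if ch != "-":
            ungapped += 1
            if ungapped in wanted:
                wanted[ungapped] = j
    for p in spec.reference_positions:
        if wanted[p] is None:
            raise ValueError(
                f"filter position {p} beyond ungapped length {ungapped} of {spec.reference_id}"
            )
        cols.append(wanted[p])
    return tuple(cols)  # type: ignore[return-value]


def classify_selectivity(residues: tuple[str, str, str, str]) -> str:
    """narrow iff both filter positions 1 and 3 are aromatic (F/Y/W).

    Gaps at position 1 or 3 make the call undefined.
    """
    p1, _, p3, _ = residues
    if "-" in (p1, p3):
        return "unclassifiable"
    return "narrow" if (p1 in AROMATIC and p3 in AROMATIC) else "broad"


def extract_filters(aln: Alignment, spec: FilterSpec = FilterSpec()) -> list[ArRFilter]:
    """One ArRFilter per aligned sequence, classified broad/narrow."""
    cols = map_filter_columns(aln, spec)
    out = []
    for rec in aln.records:
        residues = tuple(rec.residues[c] for c in cols)
        if "-" in residues:
            logger.warning("gap in filter columns of %s: %s", rec.id, residues)
        out.append(ArRFilter(rec.id, residues, cols, classify_selectivity(residues)))
    return out
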