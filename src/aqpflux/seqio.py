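"""Sequence I/O and low-level sequence procedures.

Readers/writers for (gapped) FASTA plus the small comparative-genomics
utilities the Aqp10 analyses need: percent identity, dot plots, in-silico
PCR with an exact-match primer model, and restriction digestion with
IUPAC recognition patterns.

Coordinates are 0-based half-open internally; 1-based only in
human-readable reports.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np

logger = logging.getLogger(__name__)

NUCLEOTIDE_ALPHABET = set("ACGTN-")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*-")

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


class FastaFormatError(ValueError):
    """Raised when a FASTA stream violates the format; names the line."""


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence over a declared alphabet (stored uppercase)."""

    id: str
    residues: str
    alphabet: str = "nucleotide"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record must have a non-empty id")
        if self.alphabet not in ("nucleotide", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        object.__setattr__(self, "residues", self.residues.upper())
        allowed = NUCLEOTIDE_ALPHABET if self.alphabet == "nucleotide" else PROTEIN_ALPHABET
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: residues {sorted(bad)} outside {self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass
class Alignment:
    """An ordered set of equal-length records."""

    records: list[SeqRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment needs at least one record")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal record lengths in alignment: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, seq_id: str) -> SeqRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)


def parse_fasta(source: str | Path | TextIO, alphabet: str = "nucleotide") -> list[SeqRecord]:
    """Parse FASTA text into records.

    Ids are taken from the header up to the first whitespace; wrapped
    sequence lines are concatenated and uppercased.  Raises
    :class:`FastaFormatError` naming the line number for empty ids or
    residues outside the declared alphabet.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        with open(source) as fh:
            lines = fh.read().splitlines()
    elif isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = source.read().splitlines()

    allowed = NUCLEOTIDE_ALPHABET if alphabet == "nucleotide" else PROTEIN_ALPHABET
    records: list[SeqRecord] = []
    cur_id: str | None = None
    cur_parts: list[str] = []

    def _flush() -> None:
        if cur_id is not None:
            records.append(SeqRecord(cur_id, "".join(cur_parts), alphabet))

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            _flush()
            cur_id = line[1:].split()[0] if line[1:].split() else ""
            if not cur_id:
                raise FastaFormatError(f"line {lineno}: FASTA header with empty id")
            cur_parts = []
        else:
            if cur_id is None:
                raise FastaFormatError(f"line {lineno}: sequence data before any header")
            chunk = line.upper()
            bad = set(chunk) - allowed
            if bad:
                raise FastaFormatError(
                    f"line {lineno}: residues {sorted(bad)} outside {alphabet} alphabet"
                )
            cur_parts.append(chunk)
    _flush()
    return records


def read_alignment(source: str | Path | TextIO, alphabet: str = "nucleotide") -> Alignment:
    return Alignment(parse_fasta(source, alphabet))


def write_fasta(records: Iterable[SeqRecord] | Alignment, dest: str | Path | TextIO,
                width: int = 70) -> None:
    if isinstance(records, Alignment):
        records = records.records
    out_lines = []
    for r in records:
        out_lines.append(f">{r.id}")
        for i in range(0, max(len(r.residues), 1), width):
            out_lines.append(r.residues[i:i + width])
    text = "\n".join(out_lines) + "\n"
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def pairwise_identity(a: SeqRecord, b: SeqRecord, ignore_gap_columns: bool = True) -> float:
    """Percent identity between two equal-length (aligned) sequences.

    Columns where either sequence has a gap are skipped when
    ``ignore_gap_columns`` is set.  Full precision is returned; round for
    reporting.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {a.id} ({len(a)}) vs {b.id} ({len(b)})")
    matches = 0
    compared = 0
    for x, y in zip(a.residues, b.residues):
        if ignore_gap_columns and ("-" in (x, y)):
            continue
        compared += 1
        if x == y:
            matches += 1
    if compared == 0:
        raise ValueError("no comparable columns")
    return 100.0 * matches / compared


@dataclass(frozen=True)
class DotplotConfig:
    """Sliding-window dot plot parameters (EMBOSS dotmatcher semantics).

    Defaults reproduce the window 20 / threshold 70 run with the EDNAFULL
    diagonal (+5 match, -4 mismatch).
    """

    window: int = 20
    threshold: float = 70.0
    match_score: float = 5.0
    mismatch_score: float = -4.0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")


def dotplot(a: SeqRecord, b: SeqRecord, cfg: DotplotConfig = DotplotConfig()) -> set[tuple[int, int]]:
    """All window anchors (i, j) whose ungapped window score >= threshold.

    The window a[i:i+w] is compared with b[j:j+w]; score is the sum of
    match/mismatch scores.  Runs one vectorized rolling sum per diagonal.
    """
    w = cfg.window
    if w > len(a) or w > len(b):
        raise ValueError("window exceeds a sequence length")
    sa = np.frombuffer(a.residues.encode(), dtype=np.uint8)
    sb = np.frombuffer(b.residues.encode(), dtype=np.uint8)
    n, m = len(sa), len(sb)
    hits: set[tuple[int, int]] = set()
    kernel = np.ones(w)
    for d in range(-(n - w), m - w + 1):
        if d >= 0:
            xa = sa[: min(n, m - d)]
            xb = sb[d: d + len(xa)]
            i0 = 0
        else:
            xb = sb[: min(m, n + d)]
            xa = sa[-d: -d + len(xb)]
            i0 = -d
        if len(xa) < w:
            continue
        scores = np.where(xa == xb, cfg.match_score, cfg.mismatch_score)
        window_scores = np.convolve(scores, kernel, mode="valid")
        for k in np.nonzero(window_scores >= cfg.threshold - 1e-9)[0]:
            hits.add((i0 + int(k), i0 + d + int(k)))
    return hits


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse PCR primers, both written 5'->3'."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not p:
                raise ValueError(f"{name} primer is empty")
            if set(p.upper()) - set("ACGT"):
                raise ValueError(f"{name} primer contains non-ACGT characters")
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product: a half-open slice of the template."""

    template_id: str
    start: int
    end: int
    sequence: str

    def __len__(self) -> int:
        return self.end - self.start


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def in_silico_pcr(template: SeqRecord, primers: PrimerPair) -> list[Amplicon]:
    """Predict PCR products under an exact-match primer model.

    The forward primer must match the template; the reverse-complement of
    the reverse primer must match downstream (binding sites may not
    overlap).  Products span from forward-primer start through the end of
    the reverse-primer binding site.  Returns all products sorted by
    start; logs a warning when more than one is found.
    """
    tpl = template.residues
    fwd_starts = _find_all(tpl, primers.forward)
    rc = reverse_complement(primers.reverse)
    rev_starts = _find_all(tpl, rc)
    products = []
    for f in fwd_starts:
        for r in rev_starts:
            if r >= f + len(primers.forward):
                end = r + len(rc)
                products.append(Amplicon(template.id, f, end, tpl[f:end]))
    products.sort(key=lambda p: (p.start, p.end))
    if len(products) > 1:
        logger.warning("in_silico_pcr: %d products on template %s", len(products), template.id)
    return products


@dataclass(frozen=True)
class Enzyme:
    """Restriction enzyme: IUPAC recognition pattern + top-strand cut offset.

    ``cut_offset`` is the 0-based position within the pattern after which
    the top strand is cut.  Bottom-strand cuts are ignored: fragment sizes
    at gel resolution depend only on the top-strand position.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        pat = self.recognition.upper()
        bad = set(pat) - set(IUPAC_DNA)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC characters {sorted(bad)} in pattern")
        if not 0 <= self.cut_offset <= len(pat):
            raise ValueError(f"{self.name}: cut_offset outside pattern")
        object.__setattr__(self, "recognition", pat)

    def regex(self) -> re.Pattern[str]:
        expanded = "".join(
            c if len(IUPAC_DNA[c]) == 1 else "[" + IUPAC_DNA[c] + "]" for c in self.recognition
        )
        # lookahead so overlapping sites are all found
        return re.compile(f"(?=({expanded}))")


#: NcoI cuts C^CATGG; BglI cuts GCCNNNN^NGGC.  These are the two enzymes
#: that discriminate eel aqp10.2b1 (NcoI site) from aqp10.2b2 (BglI site)
#: amplicons on a gel.
NCOI = Enzyme("NcoI", "CCATGG", 1)
BGLI = Enzyme("BglI", "GCCNNNNNGGC", 7)

BUILTIN_ENZYMES = {e.name: e for e in (NCOI, BGLI)}


def digest(seq: SeqRecord | str, enzyme: Enzyme) -> list[int]:
    """Ordered fragment lengths from a complete linear digest.

    Every top-strand match of the recognition pattern is cut (overlapping
    sites included); no sites yields a single full-length fragment.
    """
    s = seq.residues if isinstance(seq, SeqRecord) else seq.upper()
    cuts = sorted({m.start() + enzyme.cut_offset for m in enzyme.regex().finditer(s)})
    cuts = [c for c in cuts if 0 < c < len(s)]
    bounds = [0] + cuts + [len(s)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def digest_fragments(seq: SeqRecord | str, enzyme: Enzyme) -> list[str]:
    """The fragment sequences themselves, in template order."""
    s = seq.residues if isinstance(seq, SeqRecord) else seq.upper()
    out, pos = [], 0
    for length in digest(s, enzyme):
        out.append(s[pos:pos + length])
        pos += length
    return out
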