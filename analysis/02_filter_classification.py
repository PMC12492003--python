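#!/usr/bin/env python
"""Classify the ar/R selectivity filters of the fixture Aqp10 sequences.

The rule — narrow solute selectivity iff both filter positions 1 and 3
are aromatic — reproduces the published broad/narrow pattern: Aqp10.1a
(F,S,A,R) and the eel Aqp10.2b2/b3 paralogs (F,G,G,R) are broad, every
Aqp10.2b/2b1 ortholog (F,G,Y,R) is narrow.
"""

from pathlib import Path

from aqpflux.workflows import filter_classification

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    df = filter_classification()
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "filter_calls.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    n_ok = int(df.match.sum())
    print(f"\n{n_ok}/{len(df)} calls match the expected broad/narrow pattern")


if __name__ == "__main__":
    main()
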