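#!/usr/bin/env python
"""Two-group dN/dS contrast mirroring the Gp1/Gp2 split of eel aqp10.2b.

Simulates 100 codon alignments on a two-clade tree (omega 0.06 in the
ancestral-function clade, 0.51 in the broad-selectivity clade), then
estimates each group's NG86 dN/dS against the true ancestral sequence and
checks ordering and calibration.
"""

from pathlib import Path

from aqpflux.workflows import dnds_contrast

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    df = dnds_contrast(n_replicates=100, seed=1)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "dnds_contrast.tsv", sep="\t", index=False)
    ordering = (df.ratio_gp1 < df.ratio_gp2).mean()
    print(f"replicates: {len(df)}")
    print(f"dN/dS ordering correct (Gp1 < Gp2): {ordering:.0%}")
    print(f"mean dN/dS Gp1: {df.ratio_gp1.mean():.4f} (generating omega 0.06)")
    print(f"mean dN/dS Gp2: {df.ratio_gp2.mean():.4f} (generating omega 0.51)")
    print(f"mean dN ancestor->Gp2: {df.dN_gp2.mean():.4f}, "
          f"mean dS: {df.dS_gp2.mean():.4f}")


if __name__ == "__main__":
    main()
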