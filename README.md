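# aqpflux

Analyses for the evolution and function of eel **Aqp10** aquaglyceroporin
paralogs: what a tandem gene duplication plus a single selectivity-filter
substitution did to solute transport, and how to quantify it — from oocyte
swelling kinetics to dN/dS and divergence dates.

The package is written for molecular physiologists and molecular-evolution
researchers who want a tested, scriptable version of this analysis chain:

- **ar/R selectivity filters.** The aromatic/arginine constriction of an
  aquaporin pore is formed by four residues. With bulky aromatics (F/Y/W) at
  filter positions 1 *and* 3, an Aqp10 passes only water and glycerol
  ("narrow"); if either position holds a small residue, urea and boric acid
  pass too ("broad"). `aqpflux.arr` maps filter positions through a protein
  alignment and classifies every sequence.
- **Oocyte swelling assays.** Permeabilities are estimated from the initial
  rate of relative volume change of *Xenopus* oocytes,

  $$P_{water} = \frac{V_o \, d(V/V_o)/dt}{S \, V_w \, (osm_{in} - osm_{out})},\qquad
    P_{solute} = \frac{osm_{total} \, V_o \, d(V/V_o)/dt}{S \, (sol_{out} - sol_{in})}$$

  with $V_w = 18\ \mathrm{cm^3/mol}$, followed by one-way ANOVA with
  Holm–Šidák, Tukey or Dunnett post-hoc comparisons (`aqpflux.permeability`).
- **Molecular evolution.** Frame-preserving gap-codon removal, Nei–Gojobori
  (NG86) dN/dS with between-group means and codon-bootstrap standard errors,
  Jukes–Cantor distances, neighbor joining, Felsenstein pruning likelihoods
  (JC69/K2P/TN93, uniform rates), and marginal ML ancestral sequences
  (`aqpflux.molevo`, `aqpflux.phylo`).
- **Divergence dating.** Mean-path ultrametricization of a phylogram plus a
  single calibration (e.g. 175 Mya for the Elopiformes–Anguilliformes split)
  gives node ages in Mya (`aqpflux.timetree`).
- **Synthetic data.** Every input can be generated with known ground truth:
  an ODE forward model of swelling assays, a stop-rejecting codon simulator
  with per-clade dN/dS, strict-clock trees, and a packaged filter-residue
  fixture (`aqpflux.synthetic`).

## Worked example

Simulate the two-clade contrast behind the rapid-evolution result — one
clade keeps the ancestral narrow-selectivity protein (purifying selection,
ω = 0.06), the other carries the filter substitution (relaxed/positive
selection, ω = 0.51) — and estimate each group's dN/dS against the true
ancestral sequence:

```sh
python analysis/04_dnds_contrast.py
```

```
replicates: 100
dN/dS ordering correct (Gp1 < Gp2): 100%
mean dN/dS Gp1: 0.0611 (generating omega 0.06)
mean dN/dS Gp2: 0.5124 (generating omega 0.51)
mean dN ancestor->Gp2: 0.0292, mean dS: 0.0583
```

The estimated ratios bracket the generating ω values, and nonsynonymous
divergence concentrates in the broad-selectivity clade while synonymous
divergence is the same in both — the signature separating functional change
from elapsed time. Classifying the packaged filter fixture:

```sh
python analysis/02_filter_classification.py
```

prints one row per sequence, e.g. `AanAqp10.2b1 FGYR narrow` and
`AanAqp10.2b3 FGGR broad`, with `10/10 calls match the expected
broad/narrow pattern`.

The remaining drivers (`analysis/01…05`) generate the fixture bundle,
validate the permeability estimators (worst noiseless error 2.1%, worst
noisy 10-oocyte group-mean error 7.9%), and score clock dating (median
node-age error 3.9% over 10 replicates). The same stages run from a single
config via the CLI:

```sh
aqpflux run config.yaml        # stages: [synth, arr, permeability, dnds, clock]
aqpflux seq digest amplicon.fa --enzyme NcoI
```

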