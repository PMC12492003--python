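# Methods

This note documents the models, estimators and numerical choices behind
`aqpflux`, what the synthetic-data generators do and do not emulate, and
the design decisions taken where the design was genuinely open.

## Swelling-assay permeability estimation

**Model.** An oocyte is treated as a well-mixed compartment of volume
$V$ (initial $V_o$) with fixed surface area $S$; with spherical geometry
from diameter $d$, $V_o = \pi d^3/6$ and $S = \pi d^2$ (so $V_o/S = d/6$).
Transmembrane water flux follows the osmotic gradient,
$dV/dt = P_{water}\,S\,V_w\,(n_{osm}/V - osm_{out})$ with
$V_w = 18\ \mathrm{cm^3/mol}$, where $n_{osm}$ is the mole content of
internal osmolytes. In a solute assay the permeant solute enters down its
gradient, $dn_{sol}/dt = P_{solute}\,S\,(sol_{out} - n_{sol}/V)$, and the
absorbed solute counts toward $n_{osm}$, dragging water behind it.

**Estimators.** $P_{water}$ and $P_{solute}$ are read off the initial
slope $d(V/V_o)/dt$ via the two standard formulas (README). The slope is
an OLS fit of $V/V_o$ against time over an early window; the default
window is min(60 s, 20 % of the trace), configurable everywhere. The
initial-rate window matters: as the cell swells, the internal osmolyte
pool dilutes and the driving force decays, so long windows bias the slope
low (about −8 % at $P_{water} = 2\times10^{-2}$ cm/s with a 48 s window;
under 1 % at $10^{-3}$ cm/s). $S$ is held at its initial value during
estimation, matching the formulas' definition; the simulator optionally
grows $S \propto V^{2/3}$ to quantify that model mismatch.

**Units.** Canonical internal units are cm, s, mol/cm³. Osmolalities in
mOsmol/kg and concentrations in mM both convert by $10^{-6}$ to mol/cm³
under the dilute-solution assumption (1 kg solvent ≈ 1 L solution), which
is what lets osmolality and molarity share one formula.

**Solute-mode water limit.** The coupled ODEs are integrated exactly as
written for finite $P_{water}$. The initial-rate $P_{solute}$ formula,
however, presupposes that water equilibration is fast relative to solute
entry; with realistic finite $P_{water}$ the osmotic relaxation time
$V_o/(P_{water} S V_w\,osm_{total})$ is hundreds of seconds and the early
observed slope lags the quasi-steady slope by far more than the
estimator's tolerance. Solute-mode generation therefore defaults to the
quasi-static limit ($P_{water} = \infty$, $V = n_{osm}/osm_{out}$) — the
regime the estimator is valid in — while the finite-$P_{water}$ mode
remains available to study the lag bias itself.

**Statistics.** Construct-vs-control comparisons use one-way ANOVA
followed by Holm–Šidák-adjusted pairwise t tests (default), Tukey HSD
over all pairs, or Dunnett many-to-one tests; significance tiers are the
conventional 0.05/0.01/0.001/0.0001 cuts. Constant data (zero variance
everywhere) is reported as an exact tie rather than a spurious p-value.

**Simulated assay design.** Fixtures use a 1.2 mm oocyte (a conventional
value; the true diameters behind any given experiment are not knowable
from published volumes), hypoosmotic shock 200 → 100 mOsmol/kg for water
assays and iso-osmotic 180 mM solute at 200 mOsmol/kg total for solute
assays, with additive Gaussian measurement noise (sd 0.005 on $V/V_o$,
reflecting error in the projected-area volume estimate). Recordings are
60 s for noiseless validation runs and 240–300 s for noisy group
experiments: a power analysis of the OLS slope (se
$= \sigma/\sqrt{\sum(t-\bar t)^2}$) shows the slowest solute condition
($P = 10^{-6}$ cm/s, slope ≈ 4.5×10⁻⁵ s⁻¹) needs a long dense window —
video-rate capture at 25 frames/s over 60 s — to hold the standard error
of a 10-oocyte group mean near 5 %, while the window must stay early
enough to keep the dilution bias small. Fixture CSVs are written at
10 frames/s to keep them manageable.

**Numerics.** Fixed-step 4th-order Runge–Kutta with dt = 0.05 s
(halving dt changes the final $V/V_o$ by < 10⁻⁶); integration aborts if
$V \le 0$. Noise streams are `numpy.random.default_rng(seed)`, so every
trace is reproducible cross-platform.

## ar/R selectivity filters

Filter positions are specified as four 1-based indices into an ungapped
reference sequence and mapped through the alignment, so gapped references
are handled exactly. The shipped default anchors position 3 at reference
residue 205 of the European eel Aqp10.2b1 (the Y→G site); positions 1, 2
and 4 (85, 201, 219) are fixture conventions recorded in the config, not
published coordinates — real analyses should pass their own `FilterSpec`.
Classification: narrow iff positions 1 and 3 are both aromatic, with
aromatic = {F, Y, W}. Histidine is deliberately excluded: the Aqp10
filters contrast F/Y against A/G/S and never use H, and H's smaller ring
does not constrict the pore the way F/Y do. A gap at position 1 or 3
makes the call "unclassifiable" rather than guessing.

## NG86 dN/dS

For each sense codon the synonymous site count is
$S = \sum_{i=1}^{3} s_i$, where $s_i$ is the fraction of the single-
nucleotide changes at position $i$ that are synonymous, excluding changes
to stop codons from the denominator; thus $S + N = 3$ per codon by
construction. Pairwise differences are averaged over all orderings of the
differing positions, discarding pathways through stop intermediates (if
every pathway is blocked — possible only for a handful of codon pairs —
all pathways are used as a fallback). Codons containing a stop in either
sequence are excluded entirely. $p_S = S_d/S$ and $p_N = N_d/N$ are
Jukes–Cantor corrected, $d = -\tfrac34\ln(1 - \tfrac43 p)$, with
$p \ge 0.75$ raising a saturation error rather than returning NaN.

Between-group values are plain means of the per-pair distances over all
cross-group pairs (within-group diversity is *not* netted off — this
matches the common "mean between-group distance" convention). Standard
errors resample codon columns with replacement (same columns for all
pairs), 500 replicates by default, explicit seed required.

The counting scheme is verified in two independent ways: a brute-force
enumeration oracle over all 61 × 61 ordered sense-codon pairs (exact
agreement on sites and pathway-averaged differences), and simulation
calibration — on two-clade alignments generated with ω ∈ {0.06, 0.51}
(500 codons), estimated group ratios order correctly in 100/100
replicates and their means land within a few percent of the generating ω.

## Trees, likelihoods and ancestral sequences

Distance trees use classic neighbor joining; a negative branch length is
clamped to zero with the deficit moved to its sister so the joined pair's
path length is preserved. The topology agrees with an independent NJ
implementation on random matrices, and additive matrices are recovered
exactly. Likelihoods use Felsenstein pruning with per-node scaling;
models are JC69, K2P and TN93 (generator scaled to one expected
substitution per site per unit branch length, uniform rates across
sites). TN93 fitting takes empirical base frequencies and optimizes the
two transition rates by Nelder–Mead on the fixed topology (tolerance
1e-8). Ancestral sequences are marginal ML reconstructions: posterior ∝
prior × product of child messages at a (re)rooted node, which is exact
for reversible models; per-site ties are broken by the fixed base order
A < C < G < T and flagged. The reconstruction target node is named by its
leaf set, so "the root of the ingroup" is expressible without node ids.

## Divergence dating

A phylogram is ultrametricized by mean-path smoothing — each node's
relative depth is the mean path length to its descendant leaves,
reconciled upward so a parent is never shallower than a child — and all
depths are scaled linearly so one calibrated node takes its known age.
This is a deliberate simplification of relative-rate dating: no rate
model, no confidence intervals, single calibration only. On strict-clock
simulations (8 ingroup taxa, outgroup rooting, 1000 codons, JC + NJ) the
median absolute node-age error is ≈ 4 %, with the spread driven almost
entirely by substitution-sampling noise in the branch-length estimates.
Scaling is exactly linear (doubling the calibration age doubles every
node age), and age monotonicity along root-to-leaf paths is guaranteed by
the reconciliation step.

## Codon simulator

Sequences evolve by Gillespie-style proposal/rejection along each branch:
per-site proposal rate 1 per unit branch length (so branch lengths are
expected neutral substitutions per nucleotide site), transition proposals
weighted by κ, proposals creating stops rejected, nonsynonymous proposals
accepted with probability ω (per-clade ω via leaf-set lookup). True
synonymous/nonsynonymous event counts are recorded per branch. Defaults:
κ = 1 — matching the equal-rate assumption of the NG86 counting scheme so
that estimator-validation experiments test the estimator, not the
κ-misspecification bias (which is a known property of NG86 and can be
probed by raising κ); uniform root codon frequencies over the 61 sense
codons.

## What the generators do not emulate

Synthetic swelling traces have homoscedastic Gaussian noise, identical
geometry across oocytes, and no batch (frog-to-frog) effects, membrane
stretch response, or channel gating; passing recovery tests therefore
demonstrates estimator correctness under the stated model, not robustness
to those real-data features. The codon simulator has no rate
heterogeneity across sites, no codon-usage bias, and no indels (gap
handling is tested separately on constructed alignments). The filter
fixture alignment is synthetic scaffold sequence carrying the published
filter-residue patterns — it validates the mapping and classification
machinery, not homology detection. Real-sequence workflows (accession
download, MSA construction) are consumed as pre-aligned FASTA and are out
of scope.

## Problem sizes

Validation experiments use 500-codon alignments × 100 replicates for the
dN/dS contrast, 1000 codons × 10 replicates for dating, and 10-oocyte
groups per permeability condition; these sizes give Monte-Carlo errors
comfortably inside every stated tolerance while keeping a full validation
run in seconds.
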