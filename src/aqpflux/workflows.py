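"""End-to-end study workflows over synthetic data with known truth.

Each function runs one of the validation experiments the analysis scripts
and the acceptance checks report: permeability-estimator recovery, the
two-group dN/dS contrast, strict-clock dating recovery, and filter
classification on the packaged fixture alignment.  All of them exercise
the same library code a user would run on real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .arr import FilterSpec, extract_filters
from .molevo import group_mean_dn_ds, jc_matrix
from .permeability import estimate_permeability, sphere_geometry
from .phylo import nj_tree, write_tree
from .synthetic import (
    FILTER_CALLS,
    FILTER_TABLE,
    FIXTURE_DIAMETER_CM,
    CodonSimConfig,
    SwellingSimConfig,
    hypoosmotic_design,
    make_filter_alignment,
    simulate_clock_tree,
    simulate_codon_alignment,
    simulate_swelling,
    simulate_swelling_group,
    simulate_two_group_codons,
    solute_design,
)
from .timetree import Calibration, date_tree


# ---------------------------------------------------------------------------
# Permeability-estimator recovery


#: recording lengths (s): short noiseless validation runs; longer noisy
#: group recordings so small slopes beat the measurement noise.
NOISELESS_WATER_DURATION = 60.0
NOISY_WATER_DURATION = 240.0
SOLUTE_DURATION = 300.0

#: frame interval (s) for noisy group recordings: video-rate capture
#: (25 frames/s) so that the slowest solute slope (P = 1e-6 cm/s,
#: d(V/V0)/dt ~ 4.5e-5 /s) is resolved against 0.005 relative-volume
#: noise with a <5% standard error on a 10-oocyte group mean.
NOISY_OBS_DT = 0.04


def permeability_recovery(seed: int, n_oocytes: int = 10,
                          noise_sd: float = 0.005) -> pd.DataFrame:
    """Recovery of known P_water / P_solute from simulated traces.

    Noiseless single traces over the water grid {1e-3, 5e-3, 2e-2} cm/s
    and the solute grid {1e-6, 1e-5} cm/s, plus noisy n-oocyte groups at
    the same truths.  Returns one row per condition with the relative
    error of the estimate (noiseless) or of the group mean (noisy).
    """
    geometry = sphere_geometry(FIXTURE_DIAMETER_CM)
    rng = np.random.default_rng(seed)
    rows = []
    for true_p in (1e-3, 5e-3, 2e-2):
        cfg = SwellingSimConfig(geometry, hypoosmotic_design(), true_P_water=true_p,
                                duration=NOISELESS_WATER_DURATION)
        est = estimate_permeability(simulate_swelling(cfg), cfg.design)
        rows.append(("water", true_p, "noiseless", 1, est.value,
                     (est.value - true_p) / true_p))
        cfg_n = SwellingSimConfig(geometry, hypoosmotic_design(), true_P_water=true_p,
                                  duration=NOISY_WATER_DURATION, obs_dt=NOISY_OBS_DT,
                                  noise_sd=noise_sd, seed=int(rng.integers(2**31)))
        vals = [estimate_permeability(t, cfg_n.design).value
                for t in simulate_swelling_group(cfg_n, n_oocytes)]
        mean = float(np.mean(vals))
        rows.append(("water", true_p, "noisy_group", n_oocytes, mean,
                     (mean - true_p) / true_p))
    for true_p in (1e-6, 1e-5):
        cfg = SwellingSimConfig(geometry, solute_design("urea"),
                                true_P_water=float("inf"), true_P_solute=true_p,
                                duration=SOLUTE_DURATION)
        est = estimate_permeability(simulate_swelling(cfg), cfg.design)
        rows.append(("urea", true_p, "noiseless", 1, est.value,
                     (est.value - true_p) / true_p))
        cfg_n = SwellingSimConfig(geometry, solute_design("urea"),
                                  true_P_water=float("inf"), true_P_solute=true_p,
                                  duration=SOLUTE_DURATION, obs_dt=NOISY_OBS_DT,
                                  noise_sd=noise_sd, seed=int(rng.integers(2**31)))
        vals = [estimate_permeability(t, cfg_n.design).value
                for t in simulate_swelling_group(cfg_n, n_oocytes)]
        mean = float(np.mean(vals))
        rows.append(("urea", true_p, "noisy_group", n_oocytes, mean,
                     (mean - true_p) / true_p))
    return pd.DataFrame(rows, columns=["assay", "true_P", "condition", "n",
                                       "estimate", "rel_error"])


# ---------------------------------------------------------------------------
# dN/dS simulation contrast


def dnds_contrast(n_replicates: int = 100, seed: int = 0, n_codons: int = 500,
                  omega_gp1: float = 0.06, omega_gp2: float = 0.51) -> pd.DataFrame:
    """Ancestor-vs-group NG86 dN/dS on two-clade simulations.

    One replicate = one simulated alignment on the Gp1/Gp2 tree with the
    true root sequence standing in for the inferred ancestor; reports the
    estimated ratio of each group per replicate.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        sim, groups = simulate_two_group_codons(int(rng.integers(2**31)),
                                                n_codons=n_codons,
                                                omega_gp1=omega_gp1,
                                                omega_gp2=omega_gp2)
        r1 = group_mean_dn_ds(sim.alignment, groups, "N20", "Gp1", n_boot=0)
        r2 = group_mean_dn_ds(sim.alignment, groups, "N20", "Gp2", n_boot=0)
        rows.append((rep, r1.ratio, r2.ratio, r1.dN, r1.dS, r2.dN, r2.dS))
    return pd.DataFrame(rows, columns=["replicate", "ratio_gp1", "ratio_gp2",
                                       "dN_gp1", "dS_gp1", "dN_gp2", "dS_gp2"])


# ---------------------------------------------------------------------------
# Strict-clock dating recovery


@dataclass
class ClockRecovery:
    """Per-node age errors from one dating replicate."""

    median_abs_rel_error: float
    n_matched: int
    n_clades: int
    table: pd.DataFrame


def clock_recovery(seed: int, n_taxa: int = 8, n_codons: int = 1000,
                   root_age: float = 100.0, rate: float = 1.5e-3) -> ClockRecovery:
    """Date a strict-clock simulation end to end and score node ages.

    An ingroup clock tree plus an outgroup (diverging at twice the root
    age) is simulated at neutrality; the estimated tree comes from JC
    distances + NJ, is rooted on the outgroup, ultrametricized and
    calibrated with the true ingroup-root age; matched clades are scored
    by relative age error.
    """
    ingroup, true_ages = simulate_clock_tree(n_taxa, seed=seed,
                                             root_age=root_age, rate=rate)
    ing_newick = write_tree(ingroup).strip().rstrip(";")
    nwk = f"({ing_newick}:{root_age * rate:.10g},out:{2 * root_age * rate:.10g});"
    tree = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
    sim = simulate_codon_alignment(
        CodonSimConfig(tree=tree, n_codons=n_codons, omega=1.0, seed=seed + 1)
    )
    d, ids = jc_matrix(sim.alignment.alignment)
    est = nj_tree(d, ids)
    est.is_rooted = True
    out_leaf = next(l for l in est.leaf_node_iter() if l.taxon.label == "out")
    est.reroot_at_edge(out_leaf.edge, update_bipartitions=False)

    # calibration pair spanning the ingroup root: one leaf per root child
    ingroup.is_rooted = True
    children = ingroup.seed_node.child_nodes()
    pair = tuple(next(l.taxon.label for l in c.leaf_iter()) for c in children[:2])
    tt = date_tree(est, Calibration(pair[0], pair[1], root_age))

    rows = []
    for leafset, age in true_ages.items():
        if age <= 0:
            continue
        node = est.mrca(taxon_labels=sorted(leafset))
        got = frozenset(l.taxon.label for l in node.leaf_iter())
        if got == leafset:
            rows.append((",".join(sorted(leafset)), age, tt.ages[id(node)],
                         abs(tt.ages[id(node)] - age) / age))
    table = pd.DataFrame(rows, columns=["clade", "true_age", "estimated_age",
                                        "abs_rel_error"])
    med = float(table["abs_rel_error"].median()) if len(table) else float("nan")
    return ClockRecovery(med, len(table), sum(a > 0 for a in true_ages.values()), table)


# ---------------------------------------------------------------------------
# Filter classification on the packaged fixture


def filter_classification(seed: int = 7) -> pd.DataFrame:
    """Extract and classify the ar/R filters of the fixture alignment.

    Returns one row per sequence with the extracted residues, the call
    made by the classifier and the expected call from the fixture table.
    """
    aln = make_filter_alignment(seed=seed)
    filters = extract_filters(aln, FilterSpec())
    rows = []
    for f in filters:
        rows.append((f.seq_id, "".join(f.residues), f.selectivity_call,
                     FILTER_CALLS[f.seq_id],
                     "".join(FILTER_TABLE[f.seq_id]),
                     f.selectivity_call == FILTER_CALLS[f.seq_id]))
    return pd.DataFrame(rows, columns=["seq_id", "residues", "call",
                                       "expected_call", "expected_residues", "match"])
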