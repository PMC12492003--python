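"""Synthetic-data generators with known ground truth.

Everything the pipeline consumes can be generated here: oocyte swelling
traces from a forward ODE model of the assay physics, codon alignments
evolved along trees with controlled dN/dS, strict-clock trees for dating
recovery, and a protein-alignment fixture carrying the published ar/R
filter residue patterns.  All generators are deterministic given a seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .molevo import CodonAlignment, GENETIC_CODE, STOP_CODONS, SENSE_CODONS, GroupAssignment
from .permeability import (
    AssayDesign,
    OocyteGeometry,
    VolumeTrace,
    hypoosmotic_design,
    solute_design,
    sphere_geometry,
)
from .phylo import write_tree
from .seqio import Alignment, SeqRecord, write_fasta

#: molar volume of water, cm^3/mol
V_W = 18.0

#: conventional oocyte diameter used by fixtures (1.2 mm); the real
#: diameter is not printed anywhere, this is a fixture choice.
FIXTURE_DIAMETER_CM = 0.12


# ---------------------------------------------------------------------------
# Oocyte swelling forward model


@dataclass
class SwellingSimConfig:
    """Forward model of one swelling assay.

    ``true_P_water = inf`` selects the quasi-static water limit in solute
    mode (water equilibrates instantly, V = n_osm/osm_out), the regime the
    initial-rate estimator presupposes.  ``surface_mode`` "fixed" holds S
    at its initial value (matching the estimator); "spherical" grows S
    with V^(2/3) to probe model-mismatch bias.
    """

    geometry: OocyteGeometry
    design: AssayDesign
    true_P_water: float = 0.0
    true_P_solute: float = 0.0
    dt: float = 0.05
    obs_dt: float = 0.1
    duration: float = 60.0
    noise_sd: float = 0.0
    surface_mode: str = "fixed"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration < self.dt:
            raise ValueError("need dt > 0 and duration >= dt")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.surface_mode not in ("fixed", "spherical"):
            raise ValueError("surface_mode must be 'fixed' or 'spherical'")
        if self.noise_sd > 0 and self.seed is None:
            raise ValueError("seed required when noise_sd > 0")


class IntegrationError(RuntimeError):
    """The fixed-step integration produced a non-physical state."""


def _rk4(f, y: np.ndarray, t: float, dt: float) -> np.ndarray:
    k1 = f(t, y)
    k2 = f(t + dt / 2, y + dt / 2 * k1)
    k3 = f(t + dt / 2, y + dt / 2 * k2)
    k4 = f(t + dt, y + dt * k3)
    return y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)


def simulate_swelling_path(cfg: SwellingSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless (times, V/V_o) of the forward model at obs_dt resolution.

    Water mode integrates dV/dt = P_water * S * V_w * (n_osm/V - osm_out)
    with fixed internal osmoles; solute mode adds
    dn_sol/dt = P_solute * S * (sol_out - n_sol/V) and counts absorbed
    solute in the internal osmoles.  4th-order fixed-step integration.
    """
    g, d = cfg.geometry, cfg.design
    V0, S0 = g.V_o, g.S
    substeps = max(1, round(cfg.obs_dt / cfg.dt))
    dt = cfg.obs_dt / substeps
    n_obs = int(round(cfg.duration / cfg.obs_dt))
    times = np.arange(n_obs + 1) * cfg.obs_dt

    def surf(V: float) -> float:
        if cfg.surface_mode == "fixed":
            return S0
        return S0 * (V / V0) ** (2.0 / 3.0)

    if d.mode == "water":
        osm_out = d.osm_out
        n_osm0 = d.osm_in * V0

        def f(_t: float, y: np.ndarray) -> np.ndarray:
            V = y[0]
            return np.array([cfg.true_P_water * surf(V) * V_W * (n_osm0 / V - osm_out)])

        y = np.array([V0])
        vols = [V0]
        for _ in range(n_obs):
            for _ in range(substeps):
                y = _rk4(f, y, 0.0, dt)
                if y[0] <= 0:
                    raise IntegrationError("volume became non-positive")
            vols.append(y[0])
        return times, np.array(vols) / V0

    # solute mode
    osm_out = d.osm_total
    n_osm0 = d.osm_total * V0          # iso-osmotic inside at t = 0
    quasi_static = math.isinf(cfg.true_P_water)

    if quasi_static:
        def volume(n_sol: float) -> float:
            return (n_osm0 + n_sol) / osm_out

        def f(_t: float, y: np.ndarray) -> np.ndarray:
            V = volume(y[0])
            return np.array([cfg.true_P_solute * surf(V) * (d.sol_out - y[0] / V)])

        y = np.array([0.0])
        vols = [V0]
        for _ in range(n_obs):
            for _ in range(substeps):
                y = _rk4(f, y, 0.0, dt)
            vols.append(volume(y[0]))
        return times, np.array(vols) / V0

    def f(_t: float, y: np.ndarray) -> np.ndarray:
        V, n_sol = y
        S = surf(V)
        dV = cfg.true_P_water * S * V_W * ((n_osm0 + n_sol) / V - osm_out)
        dn = cfg.true_P_solute * S * (d.sol_out - n_sol / V)
        return np.array([dV, dn])

    y = np.array([V0, 0.0])
    vols = [V0]
    for _ in range(n_obs):
        for _ in range(substeps):
            y = _rk4(f, y, 0.0, dt)
            if y[0] <= 0:
                raise IntegrationError("volume became non-positive")
        vols.append(y[0])
    return times, np.array(vols) / V0


def simulate_swelling(cfg: SwellingSimConfig, oocyte_id: str = "sim",
                      construct_id: str = "sim") -> VolumeTrace:
    """One observed trace: the forward model plus optional Gaussian noise."""
    times, rel = simulate_swelling_path(cfg)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        rel = rel + rng.normal(0.0, cfg.noise_sd, size=rel.shape)
    return VolumeTrace(times, rel, cfg.geometry, oocyte_id, construct_id)


def simulate_swelling_group(cfg: SwellingSimConfig, n_oocytes: int,
                            construct_id: str = "sim") -> list[VolumeTrace]:
    """n oocytes sharing one deterministic path, independent noise each.

    The deterministic ODE is solved once; per-oocyte measurement noise is
    drawn from a single seeded stream.
    """
    times, rel = simulate_swelling_path(cfg)
    rng = np.random.default_rng(cfg.seed)
    traces = []
    for k in range(n_oocytes):
        obs = rel + rng.normal(0.0, cfg.noise_sd, size=rel.shape) if cfg.noise_sd > 0 else rel
        traces.append(VolumeTrace(times, obs, cfg.geometry, f"{construct_id}_{k:02d}", construct_id))
    return traces


# ---------------------------------------------------------------------------
# Codon evolution along a tree


@dataclass
class CodonSimConfig:
    """Codon alignment evolved on a tree with per-clade dN/dS.

    Branch lengths are in expected neutral substitutions per nucleotide
    site; nonsynonymous proposals are accepted with probability omega and
    proposals creating stop codons are rejected.  ``clade_omegas`` maps a
    frozenset of leaf labels to the omega applied on every branch inside
    (and on the stem of) that clade; other branches use ``omega``.
    ``kappa`` is the transition/transversion proposal ratio; the default
    1.0 matches the equal-rate assumption of the NG86 counting scheme.
    """

    tree: dendropy.Tree
    n_codons: int
    omega: float = 1.0
    clade_omegas: dict[frozenset, float] | None = None
    kappa: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.omega < 0 or self.kappa <= 0:
            raise ValueError("omega must be >= 0 and kappa > 0")


@dataclass
class CodonSimResult:
    """Leaf alignment plus the true substitution history."""

    alignment: CodonAlignment
    root_sequence: str
    branch_events: dict[frozenset, tuple[int, int]]   # leafset below edge -> (syn, nonsyn)

    @property
    def total_events(self) -> tuple[int, int]:
        s = sum(v[0] for v in self.branch_events.values())
        n = sum(v[1] for v in self.branch_events.values())
        return s, n


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _evolve_branch(seq: list[str], t: float, omega: float, kappa: float,
                   rng: np.random.Generator) -> tuple[list[str], int, int]:
    """Gillespie-style substitution over one branch; returns (seq, syn, nonsyn)."""
    L = len(seq)
    n_attempts = rng.poisson(L * t)
    p_ts = kappa / (kappa + 2.0)
    syn = nonsyn = 0
    seq = list(seq)
    for _ in range(n_attempts):
        site = int(rng.integers(L))
        base = seq[site]
        if rng.random() < p_ts:
            alt = _TRANSITION[base]
        else:
            alt = _TRANSVERSIONS[base][int(rng.integers(2))]
        c0 = site - site % 3
        old_codon = "".join(seq[c0:c0 + 3])
        new_codon = old_codon[:site - c0] + alt + old_codon[site - c0 + 1:]
        if new_codon in STOP_CODONS:
            continue
        if GENETIC_CODE[new_codon] == GENETIC_CODE[old_codon]:
            seq[site] = alt
            syn += 1
        elif rng.random() < omega:
            seq[site] = alt
            nonsyn += 1
    return seq, syn, nonsyn


def simulate_codon_alignment(cfg: CodonSimConfig) -> CodonSimResult:
    """Evolve a root codon sequence down the tree, recording true events."""
    rng = np.random.default_rng(cfg.seed)
    root_codons = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=cfg.n_codons)]
    root_seq = list("".join(root_codons))

    clade_omegas = cfg.clade_omegas or {}

    def edge_omega(leafset: frozenset) -> float:
        best = None
        for clade, om in clade_omegas.items():
            if leafset <= clade and (best is None or len(clade) < len(best[0])):
                best = (clade, om)
        return best[1] if best else cfg.omega

    tree = cfg.tree
    seqs: dict[int, list[str]] = {id(tree.seed_node): root_seq}
    events: dict[frozenset, tuple[int, int]] = {}
    leaf_records: list[SeqRecord] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        leafset = frozenset(
            lf.taxon.label for lf in node.leaf_iter()
        )
        om = edge_omega(leafset)
        seq, syn, nonsyn = _evolve_branch(seqs[id(node.parent_node)], t, om, cfg.kappa, rng)
        seqs[id(node)] = seq
        events[leafset] = (syn, nonsyn)
        if node.is_leaf():
            leaf_records.append(SeqRecord(node.taxon.label, "".join(seq)))
    aln = CodonAlignment(Alignment(leaf_records))
    return CodonSimResult(aln, "".join(root_seq), events)


# ---------------------------------------------------------------------------
# Strict-clock trees


def simulate_clock_tree(n_taxa: int, seed: int, root_age: float = 1.0,
                        rate: float = 0.05, prefix: str = "t") -> tuple[dendropy.Tree, dict[frozenset, float]]:
    """Random rooted ultrametric tree with a strict clock.

    Topology and internal node times come from successive random joins
    (coalescent-style), rescaled so the root sits exactly at ``root_age``
    time units; branch lengths are time x ``rate`` (substitutions/site).
    Returns the phylogram and the true node ages keyed by clade leafset.
    """
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    rng = np.random.default_rng(seed)
    labels = [f"{prefix}{i}" for i in range(n_taxa)]
    # random join times, strictly increasing
    increments = rng.exponential(1.0, size=n_taxa - 1)
    join_times = np.cumsum(increments)
    join_times *= root_age / join_times[-1]

    items: list[tuple[str, float, frozenset]] = [
        (lab, 0.0, frozenset([lab])) for lab in labels
    ]
    true_ages: dict[frozenset, float] = {}
    for age in join_times:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        (na, ta, sa) = items[i]
        (nb, tb, sb) = items[j]
        la = (age - ta) * rate
        lb = (age - tb) * rate
        merged = f"({na}:{la:.10g},{nb}:{lb:.10g})"
        leafset = sa | sb
        true_ages[leafset] = float(age)
        items = [items[k] for k in range(len(items)) if k not in (i, j)]
        items.append((merged, float(age), leafset))
    newick = items[0][0] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return tree, true_ages


# ---------------------------------------------------------------------------
# ar/R filter fixture (synthetic sequences, published residue patterns)


#: seq_id -> four filter residues (positions 1-4), mirroring the residue
#: table for tarpon/bonefish Aqp10.1a, the Aqp10.2b orthologs and the
#: three European eel paralogs.
FILTER_TABLE: dict[str, tuple[str, str, str, str]] = {
    "McyAqp10.1a": ("F", "S", "A", "R"),
    "McyAqp10.2b": ("F", "G", "Y", "R"),
    "AglAqp10.1a": ("F", "S", "A", "R"),
    "AglAqp10.2b": ("F", "G", "Y", "R"),
    "SkaAqp10.2b": ("F", "G", "Y", "R"),
    "GjaAqp10.2b": ("F", "G", "Y", "R"),
    "CcoAqp10.2b": ("F", "G", "Y", "R"),
    "AanAqp10.2b1": ("F", "G", "Y", "R"),
    "AanAqp10.2b2": ("F", "G", "G", "R"),
    "AanAqp10.2b3": ("F", "G", "G", "R"),
}

#: expected broad/narrow calls for the fixture (narrow = aromatic at both
#: filter positions 1 and 3)
FILTER_CALLS: dict[str, str] = {
    sid: ("narrow" if (res[0] in "FYW" and res[2] in "FYW") else "broad")
    for sid, res in FILTER_TABLE.items()
}

_FILTER_REF_POSITIONS = (85, 201, 205, 219)
_SCAFFOLD_LENGTH = 260
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def make_filter_alignment(seed: int = 7, divergence: float = 0.08) -> Alignment:
    """Synthetic 10-sequence protein alignment carrying the filter table.

    Sequences share a random scaffold with sparse substitutions outside
    the filter columns; the two Aqp10.1a sequences carry a 2-residue
    insertion so the reference (AanAqp10.2b1) mapping must skip gap
    columns.  Filter position 3 of the reference falls at ungapped
    residue 205.
    """
    rng = np.random.default_rng(seed)
    scaffold = [ _AA20[i] for i in rng.integers(20, size=_SCAFFOLD_LENGTH) ]
    insert_at = 120          # alignment column of the Aqp10.1a-only insertion
    records = []
    for sid, filt in FILTER_TABLE.items():
        seq = list(scaffold)
        mask = rng.random(_SCAFFOLD_LENGTH) < divergence
        for j in np.nonzero(mask)[0]:
            seq[j] = _AA20[int(rng.integers(20))]
        for pos, res in zip(_FILTER_REF_POSITIONS, filt):
            seq[pos - 1] = res
        if sid.endswith("10.1a"):
            ins = "".join(_AA20[int(rng.integers(20))] for _ in range(2))
            aligned = "".join(seq[:insert_at]) + ins + "".join(seq[insert_at:])
        else:
            aligned = "".join(seq[:insert_at]) + "--" + "".join(seq[insert_at:])
        records.append(SeqRecord(sid, aligned, "protein"))
    return Alignment(records)


# ---------------------------------------------------------------------------
# Two-group dN/dS tree mirroring the Gp1/Gp2 contrast


GP1_TIPS = ("Ama_aqp10.2b1", "Aja_aqp10.2b1", "Aro_aqp10.2b1", "Aan_aqp10.2b1")
GP2_TIPS = ("Ama_aqp10.2b2", "Aja_aqp10.2b2", "Aro_aqp10.2b2",
            "Aan_aqp10.2b2", "Aan_aqp10.2b3")


def two_group_tree(stem: float = 0.02, tip: float = 0.04) -> dendropy.Tree:
    """Rooted tree: root -> (Gp1 clade, Gp2 clade), equal branch lengths."""
    gp1 = ",".join(f"{t}:{tip:.6g}" for t in GP1_TIPS)
    gp2 = ",".join(f"{t}:{tip:.6g}" for t in GP2_TIPS)
    newick = f"(({gp1}):{stem:.6g},({gp2}):{stem:.6g});"
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def simulate_two_group_codons(seed: int, n_codons: int = 500,
                              omega_gp1: float = 0.06, omega_gp2: float = 0.51,
                              kappa: float = 1.0) -> tuple[CodonSimResult, GroupAssignment]:
    """Codon alignment with the ancestral sequence included as 'N20'.

    The true root sequence plays the role of the inferred ancestor, so
    NG86 distances between N20 and each group estimate the generating
    omegas directly.
    """
    cfg = CodonSimConfig(
        tree=two_group_tree(),
        n_codons=n_codons,
        clade_omegas={frozenset(GP1_TIPS): omega_gp1, frozenset(GP2_TIPS): omega_gp2},
        kappa=kappa,
        seed=seed,
    )
    sim = simulate_codon_alignment(cfg)
    records = [SeqRecord("N20", sim.root_sequence)] + sim.alignment.alignment.records
    aln = CodonAlignment(Alignment(records))
    labels = {"N20": "N20"}
    labels.update({t: "Gp1" for t in GP1_TIPS})
    labels.update({t: "Gp2" for t in GP2_TIPS})
    sim2 = CodonSimResult(aln, sim.root_sequence, sim.branch_events)
    return sim2, GroupAssignment(labels)


# ---------------------------------------------------------------------------
# Fixture suite


#: true permeabilities (cm/s) used by the swelling fixtures; broad-selectivity
#: constructs transport urea and boric acid, narrow ones barely do.
CONSTRUCT_TRUTH: dict[str, dict[str, float]] = {
    "control": {"water": 1.0e-3, "glycerol": 1.0e-7, "urea": 1.0e-7, "boric_acid": 1.0e-7},
    "AanAqp10.2b1": {"water": 1.0e-2, "glycerol": 1.0e-5, "urea": 5.0e-7, "boric_acid": 5.0e-7},
    "AanAqp10.2b2": {"water": 1.2e-2, "glycerol": 1.2e-5, "urea": 1.0e-5, "boric_acid": 8.0e-6},
    "AanAqp10.2b3": {"water": 1.1e-2, "glycerol": 1.1e-5, "urea": 9.0e-6, "boric_acid": 7.0e-6},
    "SkaAqp10.2b": {"water": 9.0e-3, "glycerol": 9.0e-6, "urea": 5.0e-7, "boric_acid": 5.0e-7},
    "CcoAqp10.2b": {"water": 1.0e-2, "glycerol": 1.0e-5, "urea": 6.0e-7, "boric_acid": 6.0e-7},
    "McyAqp10.2b": {"water": 1.1e-2, "glycerol": 1.0e-5, "urea": 6.0e-7, "boric_acid": 6.0e-7},
}

#: assay recording lengths (s): hypoosmotic runs are short; solute runs are
#: longer because solute-driven swelling is slower.
ASSAY_DURATIONS = {"water": 240.0, "glycerol": 300.0, "urea": 300.0, "boric_acid": 300.0}

FIXTURE_NOISE_SD = 0.005
FIXTURE_N_OOCYTES = 10


def assay_design(assay: str) -> AssayDesign:
    return hypoosmotic_design() if assay == "water" else solute_design(assay)


def _assay_config(assay: str, truth: dict[str, float], geometry: OocyteGeometry,
                  seed: int, noise_sd: float = FIXTURE_NOISE_SD) -> SwellingSimConfig:
    if assay == "water":
        return SwellingSimConfig(
            geometry=geometry, design=hypoosmotic_design(),
            true_P_water=truth["water"], duration=ASSAY_DURATIONS[assay],
            noise_sd=noise_sd, seed=seed,
        )
    return SwellingSimConfig(
        geometry=geometry, design=solute_design(assay),
        true_P_water=float("inf"), true_P_solute=truth[assay],
        duration=ASSAY_DURATIONS[assay], noise_sd=noise_sd, seed=seed,
    )


def make_fixture_suite(seed: int, out_dir: str | Path,
                       n_oocytes: int = FIXTURE_N_OOCYTES) -> dict:
    """Write the full fixture bundle and return its manifest.

    Emits filters.fasta, traces.csv, design.yaml, codons.fasta,
    groups.tsv, tree.nwk and manifest.json; byte-identical for the same
    seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # (i) ar/R filter protein alignment
    filt_aln = make_filter_alignment(seed=int(rng.integers(2**31)))
    write_fasta(filt_aln, out / "filters.fasta")

    # (ii) swelling traces
    geometry = sphere_geometry(FIXTURE_DIAMETER_CM)
    frames = []
    for construct, truth in CONSTRUCT_TRUTH.items():
        for assay in ASSAY_DURATIONS:
            cfg = _assay_config(assay, truth, geometry, seed=int(rng.integers(2**31)))
            for tr in simulate_swelling_group(cfg, n_oocytes, construct):
                frames.append(pd.DataFrame({
                    "oocyte_id": f"{tr.oocyte_id}_{assay}",
                    "construct_id": construct,
                    "assay": assay,
                    "time_s": tr.times,
                    "rel_volume": np.round(tr.rel_volume, 6),
                }))
    pd.concat(frames, ignore_index=True).to_csv(out / "traces.csv", index=False)

    design_doc = {
        "geometry": {"diameter_cm": FIXTURE_DIAMETER_CM},
        "assays": {
            "water": {"mode": "water", "osm_in_mosm": 200.0, "osm_out_mosm": 100.0},
            **{
                s: {"mode": "solute", "solute_name": s, "osm_total_mosm": 200.0,
                    "sol_out_mm": 180.0, "sol_in_mm": 0.0}
                for s in ("glycerol", "urea", "boric_acid")
            },
        },
    }
    (out / "design.yaml").write_text(yaml.safe_dump(design_doc, sort_keys=False))

    # (iii) codon alignment + trees
    dnds_seed = int(rng.integers(2**31))
    sim, groups = simulate_two_group_codons(dnds_seed)
    write_fasta(sim.alignment.alignment, out / "codons.fasta")
    with open(out / "groups.tsv", "w") as fh:
        fh.write("seq_id\tgroup\n")
        for sid, grp in groups.labels.items():
            fh.write(f"{sid}\t{grp}\n")
    clock_seed = int(rng.integers(2**31))
    clock_tree, clock_ages = simulate_clock_tree(8, seed=clock_seed, root_age=175.0, rate=3e-4)
    write_tree(clock_tree, out / "tree.nwk")

    manifest = {
        "seed": seed,
        "n_oocytes": n_oocytes,
        "noise_sd": FIXTURE_NOISE_SD,
        "geometry": {"diameter_cm": FIXTURE_DIAMETER_CM,
                     "V_o_cm3": geometry.V_o, "S_cm2": geometry.S},
        "true_permeability_cm_per_s": CONSTRUCT_TRUTH,
        "filter_calls": FILTER_CALLS,
        "dnds": {"omega_gp1": 0.06, "omega_gp2": 0.51, "n_codons": 500,
                 "seed": dnds_seed},
        "clock": {"root_age_mya": 175.0, "rate": 3e-4, "seed": clock_seed,
                  "true_ages": {",".join(sorted(k)): v for k, v in clock_ages.items()}},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
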