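"""Configuration-driven orchestration of the analysis stages.

A single validated config runs any subset of the stages in dependency
order (synth -> arr / permeability / dnds / clock), writes per-stage
tables under the output directory, and emits a manifest with input
hashes, seeds and versions so identical configs and inputs yield
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .arr import FilterSpec, extract_filters
from .molevo import GroupAssignment, group_mean_dn_ds, remove_gap_codons, CodonAlignment
from .permeability import (
    AssayDesign,
    VolumeTrace,
    compare_groups,
    estimate_permeability,
    hypoosmotic_design,
    solute_design,
    sphere_geometry,
)
from .phylo import read_tree
from .seqio import read_alignment
from .synthetic import make_fixture_suite
from .timetree import Calibration, date_tree

logger = logging.getLogger(__name__)

STAGES = ("synth", "arr", "permeability", "dnds", "clock")


class StageError(RuntimeError):
    """A stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class CalibrationConfig(BaseModel):
    taxon_a: str
    taxon_b: str
    age_mya: float = 175.0


class RunConfig(BaseModel):
    """Validated pipeline configuration (all defaults end up in the manifest)."""

    stages: list[str]
    out_dir: str
    seed: int = 0
    fixtures_dir: str | None = None
    n_oocytes: int = 10
    # stage parameters
    fit_window_s: float | None = None
    posthoc: str = "holm_sidak"
    control_id: str = "control"
    n_boot: int = 500
    reference_id: str = "AanAqp10.2b1"
    filter_positions: tuple[int, int, int, int] = (85, 201, 205, 219)
    group_a: str = "N20"
    groups_b: list[str] = Field(default_factory=lambda: ["Gp1", "Gp2"])
    calibration: CalibrationConfig | None = None

    @field_validator("stages")
    @classmethod
    def _known_stages(cls, v: list[str]) -> list[str]:
        unknown = set(v) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
        if not v:
            raise ValueError("at least one stage required")
        return v

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls.model_validate(doc)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fixture(cfg: RunConfig, name: str) -> Path:
    base = Path(cfg.fixtures_dir) if cfg.fixtures_dir else Path(cfg.out_dir) / "fixtures"
    p = base / name
    if not p.exists():
        raise FileNotFoundError(f"required input missing: fixtures_dir/{name} ({p})")
    return p


def _load_designs(path: Path) -> tuple[Any, dict[str, AssayDesign]]:
    doc = yaml.safe_load(path.read_text())
    geometry = sphere_geometry(doc["geometry"]["diameter_cm"])
    designs = {}
    for name, a in doc["assays"].items():
        if a["mode"] == "water":
            designs[name] = hypoosmotic_design(a["osm_in_mosm"], a["osm_out_mosm"])
        else:
            designs[name] = solute_design(a["solute_name"], a["sol_out_mm"],
                                          a["osm_total_mosm"])
    return geometry, designs


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the machine-readable report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"version": __version__, "seed": cfg.seed, "stages": {}}
    inputs: dict[str, str] = {}

    ordered = [s for s in STAGES if s in cfg.stages]
    for stage in ordered:
        logger.info("running stage %s", stage)
        try:
            report["stages"][stage] = _STAGE_FNS[stage](cfg, out, inputs)
        except Exception as exc:  # noqa: BLE001 - aborts with stage name and cause
            raise StageError(stage, exc) from exc

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": json.loads(cfg.model_dump_json()),
        "input_hashes": inputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _stage_synth(cfg: RunConfig, out: Path, inputs: dict) -> dict:
    fixtures = Path(cfg.fixtures_dir) if cfg.fixtures_dir else out / "fixtures"
    manifest = make_fixture_suite(cfg.seed, fixtures, n_oocytes=cfg.n_oocytes)
    return {"fixtures_dir": str(fixtures), "n_constructs": len(manifest["true_permeability_cm_per_s"])}


def _stage_arr(cfg: RunConfig, out: Path, inputs: dict) -> dict:
    path = _fixture(cfg, "filters.fasta")
    inputs["filters.fasta"] = _sha256(path)
    aln = read_alignment(path, alphabet="protein")
    spec = FilterSpec(cfg.reference_id, tuple(cfg.filter_positions))
    filters = extract_filters(aln, spec)
    df = pd.DataFrame(
        [(f.seq_id, *f.residues, f.selectivity_call) for f in filters],
        columns=["seq_id", "p1", "p2", "p3", "p4", "call"],
    )
    df.to_csv(out / "arr_filters.tsv", sep="\t", index=False)
    return {"table": "arr_filters.tsv",
            "calls": {f.seq_id: f.selectivity_call for f in filters}}


def _stage_permeability(cfg: RunConfig, out: Path, inputs: dict) -> dict:
    traces_path = _fixture(cfg, "traces.csv")
    design_path = _fixture(cfg, "design.yaml")
    inputs["traces.csv"] = _sha256(traces_path)
    inputs["design.yaml"] = _sha256(design_path)
    geometry, designs = _load_designs(design_path)
    df = pd.read_csv(traces_path)
    rows = []
    for (oocyte, construct, assay), grp in df.groupby(["oocyte_id", "construct_id", "assay"]):
        trace = VolumeTrace(grp["time_s"].to_numpy(), grp["rel_volume"].to_numpy(),
                            geometry, oocyte, construct)
        est = estimate_permeability(trace, designs[assay], window=cfg.fit_window_s)
        rows.append((construct, assay, oocyte, est.kind, est.value, est.slope, est.fit_r2))
    res = pd.DataFrame(rows, columns=["construct_id", "assay", "oocyte_id", "kind",
                                      "P_cm_per_s", "slope_per_s", "fit_r2"])
    res.to_csv(out / "permeability.tsv", sep="\t", index=False)

    stats_rows = []
    comparisons = {}
    for assay, sub in res.groupby("assay"):
        values = {c: g["P_cm_per_s"].to_numpy() for c, g in sub.groupby("construct_id")}
        cmp_res = compare_groups(values, cfg.control_id, cfg.posthoc)
        comparisons[assay] = {
            "anova_F": cmp_res.anova_f, "anova_p": cmp_res.anova_p,
            "comparisons": cmp_res.table.to_dict(orient="records"),
        }
        for _, r in cmp_res.table.iterrows():
            stats_rows.append((assay, r["comparison"], r["raw_p"], r["adj_p"], r["stars"]))
    pd.DataFrame(stats_rows, columns=["assay", "comparison", "raw_p", "adj_p", "stars"]) \
        .to_csv(out / "permeability_stats.tsv", sep="\t", index=False)
    means = res.groupby(["construct_id", "assay"])["P_cm_per_s"].mean()
    return {"table": "permeability.tsv", "stats": "permeability_stats.tsv",
            "group_means": {f"{c}:{a}": v for (c, a), v in means.items()},
            "anova": {a: comparisons[a]["anova_p"] for a in comparisons}}


def _stage_dnds(cfg: RunConfig, out: Path, inputs: dict) -> dict:
    aln_path = _fixture(cfg, "codons.fasta")
    groups_path = _fixture(cfg, "groups.tsv")
    inputs["codons.fasta"] = _sha256(aln_path)
    inputs["groups.tsv"] = _sha256(groups_path)
    aln = read_alignment(aln_path)
    caln = remove_gap_codons(aln)
    gdf = pd.read_csv(groups_path, sep="\t")
    groups = GroupAssignment(dict(zip(gdf["seq_id"], gdf["group"])))
    rows = []
    result = {}
    for gb in cfg.groups_b:
        r = group_mean_dn_ds(caln, groups, cfg.group_a, gb,
                             n_boot=cfg.n_boot, seed=cfg.seed)
        rows.append((cfg.group_a, gb, r.dN, r.dN_se, r.dS, r.dS_se, r.ratio, r.n_boot))
        result[f"{cfg.group_a}_vs_{gb}"] = {"dN": r.dN, "dS": r.dS, "dN_se": r.dN_se,
                                            "dS_se": r.dS_se, "ratio": r.ratio}
    pd.DataFrame(rows, columns=["group_a", "group_b", "dN", "dN_se", "dS", "dS_se",
                                "dN_dS", "n_boot"]) \
        .to_csv(out / "dnds.tsv", sep="\t", index=False)
    return {"table": "dnds.tsv", **result}


def _stage_clock(cfg: RunConfig, out: Path, inputs: dict) -> dict:
    tree_path = _fixture(cfg, "tree.nwk")
    inputs["tree.nwk"] = _sha256(tree_path)
    tree = read_tree(tree_path)
    tree.is_rooted = True
    if cfg.calibration is not None:
        cal = Calibration(cfg.calibration.taxon_a, cfg.calibration.taxon_b,
                          cfg.calibration.age_mya)
    else:
        children = tree.seed_node.child_nodes()
        if len(children) < 2:
            raise ValueError("cannot auto-calibrate: root is not bifurcating")
        a = next(l.taxon.label for l in children[0].leaf_iter())
        b = next(l.taxon.label for l in children[1].leaf_iter())
        cal = Calibration(a, b, 175.0)
    tt = date_tree(tree, cal)
    rows = []
    for node in tree.preorder_internal_node_iter():
        leaves = sorted(l.taxon.label for l in node.leaf_iter())
        rows.append((",".join(leaves), tt.ages[id(node)]))
    pd.DataFrame(rows, columns=["clade", "age_mya"]).to_csv(out / "node_ages.tsv",
                                                            sep="\t", index=False)
    return {"table": "node_ages.tsv", "root_age_mya": tt.root_age,
            "calibration": {"taxa": [cal.taxon_a, cal.taxon_b], "age_mya": cal.age}}


_STAGE_FNS = {
    "synth": _stage_synth,
    "arr": _stage_arr,
    "permeability": _stage_permeability,
    "dnds": _stage_dnds,
    "clock": _stage_clock,
}
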