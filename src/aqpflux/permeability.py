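"""Permeability estimation from oocyte swelling kinetics.

Water permeability is estimated from hypoosmotic swelling as

    P_water = [V_o * d(V/V_o)/dt] / [S * V_w * (osm_in - osm_out)]

with V_w = 18 cm^3/mol the molar volume of water, and solute permeability
from iso-osmotic swelling in a solute gradient as

    P_solute = osm_total * [V_o * d(V/V_o)/dt] / [S * (sol_out - sol_in)]

Internal canonical units are cm, s and mol/cm^3; 1 mOsmol/kg and 1 mM both
convert to 1e-6 mol/cm^3 under the dilute-solution assumption (1 kg ~ 1 L).
The initial rate d(V/V_o)/dt is an ordinary least-squares slope over an
early window; S is held at its initial value throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd

#: molar volume of water, cm^3/mol
V_W = 18.0

SIGNIFICANCE_TIERS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def mosm_to_molcm3(mosm_per_kg: float) -> float:
    """mOsmol/kg -> mol/cm^3 (dilute aqueous solution, 1 kg ~ 1 L)."""
    return mosm_per_kg * 1e-6


def mm_to_molcm3(mm: float) -> float:
    """mM -> mol/cm^3."""
    return mm * 1e-6


def stars(p: float) -> str:
    for cut, sym in SIGNIFICANCE_TIERS:
        if p < cut:
            return sym
    return "ns"


@dataclass(frozen=True)
class OocyteGeometry:
    """Initial volume (cm^3) and surface area (cm^2) of one oocyte."""

    V_o: float
    S: float

    def __post_init__(self) -> None:
        if self.V_o <= 0 or self.S <= 0:
            raise ValueError("V_o and S must be positive")


def sphere_geometry(diameter_cm: float) -> OocyteGeometry:
    """Geometry of a spherical oocyte: V_o = pi d^3/6, S = pi d^2."""
    if diameter_cm <= 0:
        raise ValueError("diameter must be positive")
    return OocyteGeometry(
        V_o=math.pi * diameter_cm**3 / 6.0,
        S=math.pi * diameter_cm**2,
    )


@dataclass(frozen=True)
class AssayDesign:
    """Bath/oocyte osmolalities and solute gradients, in mol/cm^3.

    ``mode`` is "water" (hypoosmotic shock) or "solute" (iso-osmotic bath
    with a permeant solute gradient).
    """

    mode: str
    osm_in: float = 0.0
    osm_out: float = 0.0
    osm_total: float = 0.0
    sol_in: float = 0.0
    sol_out: float = 0.0
    solute_name: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("water", "solute"):
            raise ValueError("mode must be 'water' or 'solute'")
        if self.mode == "water" and self.osm_in == self.osm_out:
            raise ValueError("water mode requires an osmotic gradient")
        if self.mode == "solute":
            if self.sol_out == self.sol_in:
                raise ValueError("solute mode requires a solute gradient")
            if self.osm_total <= 0:
                raise ValueError("solute mode requires osm_total > 0")


def hypoosmotic_design(osm_in_mosm: float = 200.0, osm_out_mosm: float = 100.0) -> AssayDesign:
    """Water assay: oocytes at ~200 mOsm moved to 2-fold diluted bath."""
    return AssayDesign(
        "water",
        osm_in=mosm_to_molcm3(osm_in_mosm),
        osm_out=mosm_to_molcm3(osm_out_mosm),
    )


def solute_design(solute_name: str, sol_out_mm: float = 180.0,
                  osm_total_mosm: float = 200.0) -> AssayDesign:
    """Solute assay: iso-osmotic bath with 180 mM glycerol/urea/boric acid."""
    return AssayDesign(
        "solute",
        osm_total=mosm_to_molcm3(osm_total_mosm),
        sol_in=0.0,
        sol_out=mm_to_molcm3(sol_out_mm),
        solute_name=solute_name,
    )


@dataclass
class VolumeTrace:
    """Relative oocyte volume V/V_o versus time for one oocyte."""

    times: np.ndarray
    rel_volume: np.ndarray
    geometry: OocyteGeometry
    oocyte_id: str = ""
    construct_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rel_volume = np.asarray(self.rel_volume, dtype=float)
        if self.times.shape != self.rel_volume.shape:
            raise ValueError("times and rel_volume must have equal length")
        if self.times[0] != 0.0:
            raise ValueError("trace must start at t = 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if abs(self.rel_volume[0] - 1.0) > 0.1:
            raise ValueError("rel_volume[0] should be ~1")

    @property
    def duration(self) -> float:
        return float(self.times[-1])


def default_window(trace: VolumeTrace) -> float:
    """First 60 s or first 20% of the trace, whichever is shorter."""
    return min(60.0, 0.2 * trace.duration)


def fit_initial_slope(trace: VolumeTrace, window: float | None = None) -> tuple[float, float]:
    """OLS slope (s^-1) and r^2 of V/V_o vs t over [0, window]."""
    if window is None:
        window = default_window(trace)
    mask = trace.times <= window + 1e-12
    if mask.sum() < 3:
        raise ValueError(f"fewer than 3 points within window {window} s")
    t = trace.times[mask]
    v = trace.rel_volume[mask]
    res = stats.linregress(t, v)
    return float(res.slope), float(res.rvalue**2)


@dataclass(frozen=True)
class PermeabilityResult:
    """A permeability coefficient (cm/s) and the slope fit behind it."""

    kind: str
    value: float
    slope: float
    fit_window: float
    fit_r2: float


def p_water(slope: float, g: OocyteGeometry, design: AssayDesign,
            fit_window: float = float("nan"), fit_r2: float = float("nan")) -> PermeabilityResult:
    """Osmotic water permeability from an initial swelling slope."""
    if design.mode != "water":
        raise ValueError("p_water requires a water-mode design")
    value = (g.V_o * slope) / (g.S * V_W * (design.osm_in - design.osm_out))
    return PermeabilityResult("P_water", value, slope, fit_window, fit_r2)


def p_solute(slope: float, g: OocyteGeometry, design: AssayDesign,
             fit_window: float = float("nan"), fit_r2: float = float("nan")) -> PermeabilityResult:
    """Solute permeability from an iso-osmotic swelling slope."""
    if design.mode != "solute":
        raise ValueError("p_solute requires a solute-mode design")
    value = design.osm_total * g.V_o * slope / (g.S * (design.sol_out - design.sol_in))
    kind = f"P_{design.solute_name}" if design.solute_name else "P_solute"
    return PermeabilityResult(kind, value, slope, fit_window, fit_r2)


def estimate_permeability(trace: VolumeTrace, design: AssayDesign,
                          window: float | None = None) -> PermeabilityResult:
    """Fit the initial slope of a trace and apply the matching formula."""
    if window is None:
        window = default_window(trace)
    slope, r2 = fit_initial_slope(trace, window)
    fn = p_water if design.mode == "water" else p_solute
    return fn(slope, trace.geometry, design, fit_window=window, fit_r2=r2)


# ---------------------------------------------------------------------------
# Group statistics


@dataclass
class GroupComparison:
    """One-way ANOVA plus adjusted per-comparison p-values."""

    anova_f: float
    anova_p: float
    method: str
    table: pd.DataFrame          # comparison, raw_p, adj_p, stars
    exact_tie: bool = False


def compare_groups(values: Mapping[str, Sequence[float]], control_id: str,
                   method: str = "holm_sidak") -> GroupComparison:
    """Compare constructs against a control (or all pairs for Tukey).

    ``method`` is "holm_sidak" (pairwise t-tests vs control, Holm-Sidak
    step-down adjustment), "tukey" (all-pairs Tukey HSD) or "dunnett"
    (many-to-one comparisons vs control).  Significance tiers follow the
    conventional 0.05 / 0.01 / 0.001 / 0.0001 cuts.
    """
    if method not in ("holm_sidak", "tukey", "dunnett"):
        raise ValueError(f"unknown method {method}")
    if control_id not in values:
        raise KeyError(f"control {control_id!r} not among groups")
    groups = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    for k, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    if len(groups) < 2:
        raise ValueError("need at least two groups")

    all_vals = np.concatenate(list(groups.values()))
    exact_tie = bool(np.ptp(all_vals) == 0.0)
    if exact_tie:
        anova_f, anova_p = 0.0, 1.0
    else:
        anova_f, anova_p = stats.f_oneway(*groups.values())

    others = [k for k in groups if k != control_id]
    rows = []
    if method == "holm_sidak":
        raw = []
        for k in others:
            if exact_tie:
                raw.append(1.0)
            else:
                raw.append(stats.ttest_ind(groups[k], groups[control_id]).pvalue)
        adj = multipletests(raw, method="holm-sidak")[1] if raw else []
        for k, rp, ap in zip(others, raw, adj):
            rows.append((f"{k} vs {control_id}", rp, ap, stars(ap)))
    elif method == "dunnett":
        if exact_tie:
            for k in others:
                rows.append((f"{k} vs {control_id}", 1.0, 1.0, "ns"))
        else:
            res = stats.dunnett(*[groups[k] for k in others], control=groups[control_id])
            for k, p in zip(others, res.pvalue):
                rows.append((f"{k} vs {control_id}", float(p), float(p), stars(p)))
    else:  # tukey
        if exact_tie:
            keys = list(groups)
            for a in range(len(keys)):
                for b in range(a + 1, len(keys)):
                    rows.append((f"{keys[b]} vs {keys[a]}", 1.0, 1.0, "ns"))
        else:
            data = np.concatenate([groups[k] for k in groups])
            labels = np.concatenate([[k] * len(groups[k]) for k in groups])
            tk = pairwise_tukeyhsd(data, labels)
            pairs = list(itertools.combinations(tk.groupsunique, 2))
            for (a, b), p in zip(pairs, tk.pvalues):
                rows.append((f"{b} vs {a}", float(p), float(p), stars(p)))

    table = pd.DataFrame(rows, columns=["comparison", "raw_p", "adj_p", "stars"])
    return GroupComparison(float(anova_f), float(anova_p), method, table, exact_tie)
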