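"""Plan evaluation: DVH curves and metrics, clinical goals, robustness pass
rates, gamma analysis, and paired nonparametric comparison.

Gamma analysis ships in two independent implementations:

* :func:`gamma` — fast search in the style of Wendling et al.: candidate
  offsets on a fine lattice are visited in order of increasing distance and
  a voxel stops searching as soon as the distance term alone exceeds its
  current best gamma^2 (the interpolation uses ``scipy.ndimage``);
* :func:`gamma_dense` — exhaustive scan of the full offset lattice with
  hand-rolled trilinear interpolation and no early termination.

The two must agree to within interpolation tolerance; the dense version is
the reference oracle, the fast one the production route.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import scipy.stats

from .grid_core import DoseGrid, RoiMask, StructureSet

__all__ = [
    "ClinicalGoal",
    "GammaParams",
    "GammaResult",
    "compute_dvh",
    "dvh_metric",
    "evaluate_goals",
    "robustness_pass_rate",
    "gamma",
    "gamma_dense",
    "paired_compare",
    "default_goals",
]

GOAL_METRICS = ("V_pct_rx", "V_abs", "D_mean", "D_hotspot")


@dataclass(frozen=True)
class ClinicalGoal:
    """One dosimetric objective, e.g. ``V95%(Rx) >= 95%`` or
    ``D_0.03cc <= 40 Gy``.

    metric/parameter semantics:
      V_pct_rx:  parameter = percent of Rx; value = % ROI volume at/above
      V_abs:     parameter = absolute Gy;   value = % ROI volume at/above
      D_mean:    parameter unused;          value = mean ROI dose (Gy)
      D_hotspot: parameter = volume in cc;  value = min dose to hottest cc
    """

    roi: str
    metric: str
    parameter: float
    threshold: float
    comparator: str  # '>=' or '<='

    def __post_init__(self) -> None:
        if self.metric not in GOAL_METRICS:
            raise ValueError(f"metric must be one of {GOAL_METRICS}, got {self.metric!r}")
        if self.comparator not in (">=", "<="):
            raise ValueError("comparator must be '>=' or '<='")
        if self.threshold <= 0 or (self.metric != "D_mean" and self.parameter <= 0):
            raise ValueError("goal parameter and threshold must be positive")

    def label(self) -> str:
        if self.metric == "V_pct_rx":
            return f"V{self.parameter:g}%(Rx) {self.comparator} {self.threshold:g}%"
        if self.metric == "V_abs":
            return f"V{self.parameter:g}Gy {self.comparator} {self.threshold:g}%"
        if self.metric == "D_mean":
            return f"DAVG {self.comparator} {self.threshold:g} Gy"
        return f"D{self.parameter:g}cc {self.comparator} {self.threshold:g} Gy"


def default_goals(ipsilateral_lung: str = "lungs", total_lung: str = "lungs") -> list[ClinicalGoal]:
    """The chest-wall goal set used for plan scoring.  Laterality is
    anatomical, so the ipsilateral/total lung ROI names are explicit."""
    return [
        ClinicalGoal("PTV nodes", "V_pct_rx", 95.0, 95.0, ">="),
        ClinicalGoal("PTV chest wall", "V_pct_rx", 95.0, 95.0, ">="),
        ClinicalGoal("esophagus", "D_hotspot", 0.03, 40.0, "<="),
        ClinicalGoal("heart", "D_mean", 1.0, 1.25, "<="),
        ClinicalGoal(ipsilateral_lung, "V_abs", 20.0, 20.0, "<="),
        ClinicalGoal(ipsilateral_lung, "D_mean", 1.0, 10.0, "<="),
        ClinicalGoal(total_lung, "V_abs", 5.0, 25.0, "<="),
    ]


def compute_dvh(
    dose: DoseGrid, mask: RoiMask, bin_width_gy: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative DVH: percent of ROI volume receiving at least each dose
    level.  Returns (dose levels, volume %); V(0) = 100 and the curve is
    monotone non-increasing."""
    if mask.voxel_count == 0:
        raise ValueError(f"ROI {mask.name!r} is empty")
    if bin_width_gy <= 0:
        raise ValueError("bin width must be > 0")
    vals = dose.values[mask.values]
    levels = np.arange(0.0, vals.max() + 2 * bin_width_gy, bin_width_gy)
    volume = 100.0 * (vals[None, :] >= levels[:, None]).mean(axis=1)
    return levels, volume


def _hotspot_dose(vals: np.ndarray, voxel_cc: float, volume_cc: float, roi: str) -> float:
    """Min dose to the hottest ``volume_cc``: linear interpolation on the
    sorted hottest voxels, across the partial voxel."""
    srt = np.sort(vals)[::-1]
    total = srt.size * voxel_cc
    if volume_cc >= total:
        warnings.warn(
            f"ROI {roi!r} ({total:.3f} cc) smaller than hotspot volume "
            f"{volume_cc} cc; whole-ROI minimum reported",
            stacklevel=3,
        )
        return float(srt[-1])
    knots_v = voxel_cc * np.arange(1, srt.size + 1)
    if volume_cc <= knots_v[0]:
        return float(srt[0])
    return float(np.interp(volume_cc, knots_v, srt))


def dvh_metric(
    dose: DoseGrid,
    mask: RoiMask,
    goal: ClinicalGoal,
    rx: float = 50.4,
) -> float:
    """Evaluate one goal's metric value on one ROI."""
    if mask.voxel_count == 0:
        raise ValueError(f"ROI {mask.name!r} is empty")
    vals = dose.values[mask.values]
    if goal.metric == "V_pct_rx":
        level = goal.parameter / 100.0 * rx
        return float(100.0 * (vals >= level).mean())
    if goal.metric == "V_abs":
        return float(100.0 * (vals >= goal.parameter).mean())
    if goal.metric == "D_mean":
        return float(vals.mean())
    return _hotspot_dose(vals, dose.voxel_volume_cc, goal.parameter, mask.name)


def evaluate_goals(
    dose: DoseGrid,
    structures: StructureSet,
    goals: Sequence[ClinicalGoal],
    rx: float = 50.4,
) -> pd.DataFrame:
    """Evaluate every goal; missing ROIs are reported as not-evaluable
    rather than aborting the run."""
    rows = []
    for goal in goals:
        if goal.roi not in structures:
            rows.append(
                {"roi": goal.roi, "goal": goal.label(), "value": np.nan,
                 "threshold": goal.threshold, "passed": pd.NA, "evaluable": False}
            )
            continue
        value = dvh_metric(dose, structures[goal.roi], goal, rx)
        passed = value >= goal.threshold if goal.comparator == ">=" else value <= goal.threshold
        rows.append(
            {"roi": goal.roi, "goal": goal.label(), "value": value,
             "threshold": goal.threshold, "passed": bool(passed), "evaluable": True}
        )
    return pd.DataFrame(rows)


def robustness_pass_rate(
    scenario_doses: Sequence[DoseGrid],
    structures: StructureSet,
    goals: Sequence[ClinicalGoal],
    rx: float = 50.4,
) -> pd.DataFrame:
    """Percent of perturbed scenarios in which each clinical goal is met."""
    if not scenario_doses:
        raise ValueError("need at least one scenario dose")
    tables = [evaluate_goals(d, structures, goals, rx) for d in scenario_doses]
    base = tables[0][["roi", "goal"]].copy()
    passes = np.zeros(len(base))
    evaluable = np.ones(len(base), dtype=bool)
    for t in tables:
        evaluable &= t["evaluable"].to_numpy()
        passes += t["passed"].fillna(False).to_numpy(dtype=float)
    base["pass_rate_pct"] = 100.0 * passes / len(tables)
    base.loc[~evaluable, "pass_rate_pct"] = np.nan
    base["n_scenarios"] = len(tables)
    return base


# ---------------------------------------------------------------------------
# gamma analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaParams:
    """3%(local)/3 mm criteria with a 10% low-dose threshold by default.

    The low-dose threshold is relative to the *reference* grid's maximum.
    The candidate search is capped at ``search_radius_factor * dta_mm`` and
    sampled every ``dta_mm / step_divisor`` millimetres.
    """

    dose_pct: float = 3.0
    dta_mm: float = 3.0
    threshold_pct: float = 10.0
    search_radius_factor: float = 3.0
    step_divisor: int = 10

    def __post_init__(self) -> None:
        if min(self.dose_pct, self.dta_mm, self.threshold_pct) <= 0:
            raise ValueError("gamma criteria must be positive")
        if self.search_radius_factor < 1 or self.step_divisor < 1:
            raise ValueError("search radius factor and step divisor must be >= 1")


@dataclass
class GammaResult:
    """Per-voxel gamma on the reference lattice (NaN below threshold)."""

    values: np.ndarray
    pass_rate_pct: float
    n_evaluated: int

    def histogram(self, bin_width: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
        vals = self.values[np.isfinite(self.values)]
        edges = np.arange(0.0, max(vals.max(), 1.0) + 2 * bin_width, bin_width)
        counts, edges = np.histogram(vals, bins=edges)
        return edges, counts


def _offset_lattice(spacing, shape, params: GammaParams) -> np.ndarray:
    """Candidate offsets (mm) within the search sphere, on the interpolation
    step lattice.  Axes of extent 1 voxel (2D slabs) get zero offsets only."""
    step = params.dta_mm / params.step_divisor
    radius = params.dta_mm * params.search_radius_factor
    nmax = int(np.floor(radius / step))
    axes = []
    for a in range(3):
        if shape[a] == 1:
            axes.append(np.array([0.0]))
        else:
            axes.append(step * np.arange(-nmax, nmax + 1))
    D = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    r2 = (D**2).sum(axis=1)
    return D[r2 <= radius**2 + 1e-12]

def _check_congruent(ref: DoseGrid, ev: DoseGrid) -> None:
    if ref.shape != ev.shape or ref.spacing != ev.spacing:
        raise ValueError(
            f"gamma requires congruent grids: {ref.shape}@{ref.spacing} vs "
            f"{ev.shape}@{ev.spacing}"
        )


def gamma(ref: DoseGrid, ev: DoseGrid, params: GammaParams = GammaParams()) -> GammaResult:
    """Fast local-dose gamma: sorted-offset search with early termination.

    For each reference voxel at or above the low-dose threshold,
    ``gamma^2 = min over offsets d of (dD / (q * D_ref))^2 + (|d| / dta)^2``
    with q the local dose criterion, dD the difference between the
    trilinearly interpolated evaluated dose at the offset position and the
    reference voxel dose.  Offsets are visited nearest first, so a voxel is
    final once the distance term alone exceeds its current gamma^2.
    """
    _check_congruent(ref, ev)
    R = ref.values
    thr = params.threshold_pct / 100.0 * R.max()
    sel = R >= thr
    n_eval = int(sel.sum())
    out = np.full(R.shape, np.nan)
    if n_eval == 0:
        return GammaResult(out, 100.0, 0)

    q = params.dose_pct / 100.0
    dref = R[sel]
    denom = q * dref  # local normalization
    base = np.argwhere(sel).astype(float)  # (n, 3) index coords

    offsets = _offset_lattice(ref.spacing, R.shape, params)
    order = np.argsort((offsets**2).sum(axis=1), kind="stable")
    offsets = offsets[order]
    dist2 = (offsets**2).sum(axis=1) / params.dta_mm**2

    gamma2 = np.full(n_eval, np.inf)
    active = np.arange(n_eval)
    spacing = np.asarray(ref.spacing)
    for off, d2 in zip(offsets, dist2):
        if active.size == 0:
            break
        # retire voxels whose best gamma^2 can no longer improve
        keep = gamma2[active] > d2
        active = active[keep]
        if active.size == 0:
            break
        coords = (base[active] + off / spacing).T
        sampled = ndi.map_coordinates(ev.values, coords, order=1, mode="constant", cval=np.nan)
        valid = np.isfinite(sampled)
        if not valid.any():
            continue
        idx = active[valid]
        cand = ((sampled[valid] - dref[idx]) / denom[idx]) ** 2 + d2
        np.minimum.at(gamma2, idx, cand)
    g = np.sqrt(gamma2)
    out[sel] = g
    pass_rate = 100.0 * float((g <= 1.0 + 1e-9).mean())
    return GammaResult(out, pass_rate, n_eval)


def _trilinear(values: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Hand-rolled trilinear interpolation at fractional index coords
    (n, 3); NaN outside the grid."""
    shape = np.array(values.shape)
    out = np.full(len(pts), np.nan)
    inside = np.all((pts >= 0) & (pts <= shape - 1), axis=1)
    if not inside.any():
        return out
    p = pts[inside]
    i0 = np.minimum(np.floor(p).astype(int), shape - 2)
    i0 = np.maximum(i0, 0)
    f = p - i0
    acc = np.zeros(len(p))
    for dx in (0, 1):
        wx = f[:, 0] if dx else 1.0 - f[:, 0]
        for dy in (0, 1):
            wy = f[:, 1] if dy else 1.0 - f[:, 1]
            for dz in (0, 1):
                wz = f[:, 2] if dz else 1.0 - f[:, 2]
                acc += (
                    wx * wy * wz
                    * values[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
                )
    out[inside] = acc
    return out


def gamma_dense(ref: DoseGrid, ev: DoseGrid, params: GammaParams = GammaParams()) -> GammaResult:
    """Exhaustive brute-force gamma: scan every offset of the search lattice
    for every above-threshold voxel, no shortcuts.  Reference oracle for
    :func:`gamma`."""
    _check_congruent(ref, ev)
    R = ref.values
    thr = params.threshold_pct / 100.0 * R.max()
    sel = R >= thr
    n_eval = int(sel.sum())
    out = np.full(R.shape, np.nan)
    if n_eval == 0:
        return GammaResult(out, 100.0, 0)

    q = params.dose_pct / 100.0
    dref = R[sel]
    base = np.argwhere(sel).astype(float)
    spacing = np.asarray(ref.spacing)
    offsets = _offset_lattice(ref.spacing, R.shape, params)
    gamma2 = np.full(n_eval, np.inf)
    for off in offsets:
        d2 = float((off**2).sum()) / params.dta_mm**2
        sampled = _trilinear(ev.values, base + off / spacing)
        valid = np.isfinite(sampled)
        if not valid.any():
            continue
        cand = ((sampled[valid] - dref[valid]) / (q * dref[valid])) ** 2 + d2
        np.minimum.at(gamma2, np.nonzero(valid)[0], cand)
    g = np.sqrt(gamma2)
    out[sel] = g
    pass_rate = 100.0 * float((g <= 1.0 + 1e-9).mean())
    return GammaResult(out, pass_rate, n_eval)


# ---------------------------------------------------------------------------
# paired statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedResult:
    p_value: float
    n_effective: int  # pairs remaining after dropping zero differences
    degenerate: bool  # all differences were zero


def paired_compare(values_a: Sequence[float], values_b: Sequence[float]) -> PairedResult:
    """Two-sided Wilcoxon signed-rank test on paired per-case metrics.

    Zero-difference pairs are dropped (and reported via ``n_effective``); if
    every pair is tied the comparison is degenerate and p is reported as 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired_compare needs two equal-length 1D sequences")
    diff = a - b
    nz = diff != 0
    if not nz.any():
        return PairedResult(1.0, 0, True)
    stat = scipy.stats.wilcoxon(
        a[nz], b[nz], zero_method="wilcox", alternative="two-sided"
    )
    return PairedResult(float(stat.pvalue), int(nz.sum()), False)
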