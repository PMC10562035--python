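"""Robust voxel-wise dose-mimicking optimization.

Given a reference (predicted, postprocessed) dose ``d_ref`` and a sparse
dose-influence matrix ``A`` per uncertainty scenario, find nonnegative spot
weights ``x`` minimizing the one-sided quadratic objective

    f(x) = sum_i [ w+_i (d_i - d_ref_i)^2  if d_i > d_ref_i
                 + w-_i (d_i - d_ref_i)^2  if d_i < d_ref_i ]

with ``d = A x``.  Overdose and underdose carry separate per-voxel weights;
voxels belonging only to an organ at risk get ``w- = 0`` so dose below the
reference there is never penalized.  For robust ROIs the objective term is
averaged over all perturbation scenarios, with the single predicted dose as
the reference in every scenario; non-robust voxels are scored on the nominal
scenario only.

The objective is continuously differentiable (the two quadratic branches
meet with zero slope at d = d_ref), so projected gradient descent with a
backtracking line search converges reliably; the returned objective trace is
non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .dose_engine import SpotPlan
from .grid_core import DoseGrid, StructureSet

__all__ = [
    "VoxelWeights",
    "MimicConfig",
    "assign_voxel_weights",
    "mimic_objective",
    "robust_objective",
    "optimize",
]


@dataclass
class VoxelWeights:
    """Per-voxel overdose (w+) and underdose (w-) penalty weights."""

    w_plus: np.ndarray
    w_minus: np.ndarray

    def __post_init__(self) -> None:
        self.w_plus = np.asarray(self.w_plus, dtype=float)
        self.w_minus = np.asarray(self.w_minus, dtype=float)
        if self.w_plus.shape != self.w_minus.shape:
            raise ValueError("w_plus / w_minus shape mismatch")
        if self.w_plus.min(initial=0) < 0 or self.w_minus.min(initial=0) < 0:
            raise ValueError("voxel weights must be nonnegative")

    def ravel(self) -> "VoxelWeights":
        return VoxelWeights(self.w_plus.ravel(), self.w_minus.ravel())


@dataclass
class MimicConfig:
    """Configuration of the mimicking optimizer.

    roi_weights maps ROI name -> (w+, w-); default_weights applies to voxels
    inside the external contour covered by no configured ROI.  The iteration
    budget counts outer projected-gradient iterations.
    """

    roi_weights: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "PTV chest wall": (30.0, 100.0),
            "PTV nodes": (30.0, 100.0),
            "lungs": (5.0, 1.0),
            "heart": (5.0, 1.0),
            "esophagus": (5.0, 1.0),
        }
    )
    default_weights: tuple[float, float] = (1.0, 0.1)
    robust_rois: list[str] = field(default_factory=lambda: ["PTV chest wall", "PTV nodes"])
    iterations: int = 200
    tolerance: float = 0.0  # relative objective change for early stop; 0 = run all
    scenario_aggregation: str = "mean"
    min_weight: float = 0.0  # deliverability floor: weights below it snap to 0
    # optional hook scaling (w+, w-) by the predicted dose level; signature
    # f(dose_level_array) -> multiplier array.  Off by default.
    dose_level_multiplier: object = None

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.min_weight < 0:
            raise ValueError("min_weight must be >= 0")
        if self.scenario_aggregation != "mean":
            raise ValueError("only 'mean' scenario aggregation is supported")


def assign_voxel_weights(
    structures: StructureSet,
    cfg: MimicConfig,
    predicted_dose: np.ndarray | None = None,
) -> VoxelWeights:
    """Build per-voxel (w+, w-) maps from per-ROI configuration.

    Each voxel takes the elementwise maximum of the (w+, w-) pairs of every
    configured ROI containing it; voxels inside the external contour but in
    no configured ROI get the default pair.  Voxels inside an OAR with no
    target overlap are forced to ``w- = 0`` regardless of configuration, so
    underdosing an organ at risk is never penalized.

    If ``cfg.dose_level_multiplier`` is set and a predicted dose is given,
    both maps are scaled voxel-wise by the hook's multiplier — the optional
    dependence of the weights on the predicted dose level.
    """
    shape = structures.shape
    w_plus = np.zeros(shape)
    w_minus = np.zeros(shape)
    covered = np.zeros(shape, dtype=bool)
    for mask in structures.masks:
        pair = cfg.roi_weights.get(mask.name)
        if pair is None:
            continue
        wp, wm = float(pair[0]), float(pair[1])
        m = mask.values
        np.maximum(w_plus, np.where(m, wp, 0.0), out=w_plus)
        np.maximum(w_minus, np.where(m, wm, 0.0), out=w_minus)
        covered |= m

    ext = structures.external.values
    fallback = ext & ~covered
    w_plus[fallback] = cfg.default_weights[0]
    w_minus[fallback] = cfg.default_weights[1]

    in_target = np.zeros(shape, dtype=bool)
    for mask in structures.by_role("target"):
        in_target |= mask.values
    in_oar = np.zeros(shape, dtype=bool)
    for mask in structures.by_role("oar"):
        in_oar |= mask.values
    w_minus[in_oar & ~in_target] = 0.0
    if cfg.dose_level_multiplier is not None and predicted_dose is not None:
        mult = np.asarray(cfg.dose_level_multiplier(np.asarray(predicted_dose)))
        w_plus = w_plus * mult
        w_minus = w_minus * mult
    return VoxelWeights(w_plus, w_minus)


def _one_sided_residual(
    d: np.ndarray, d_ref: np.ndarray, w: VoxelWeights
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted residual and per-voxel objective contribution."""
    diff = d - d_ref
    wvox = np.where(diff > 0, w.w_plus, np.where(diff < 0, w.w_minus, 0.0))
    contrib = wvox * diff * diff
    return wvox * diff, contrib


def mimic_objective(d: DoseGrid | np.ndarray, d_ref: DoseGrid | np.ndarray, w: VoxelWeights) -> float:
    """The one-sided quadratic mimicking objective summed over all voxels."""
    dv = d.values if isinstance(d, DoseGrid) else np.asarray(d)
    rv = d_ref.values if isinstance(d_ref, DoseGrid) else np.asarray(d_ref)
    if dv.shape != rv.shape or dv.shape != w.w_plus.shape:
        raise ValueError(
            f"shape mismatch: dose {dv.shape}, reference {rv.shape}, weights {w.w_plus.shape}"
        )
    _, contrib = _one_sided_residual(dv, rv, w)
    return float(contrib.sum())


def _masked_weights(w: VoxelWeights, mask: np.ndarray) -> VoxelWeights:
    return VoxelWeights(np.where(mask, w.w_plus, 0.0), np.where(mask, w.w_minus, 0.0))


def robust_objective(
    weights_x: np.ndarray,
    influences: Sequence[sp.spmatrix],
    d_ref: np.ndarray,
    w: VoxelWeights,
    robust_mask: np.ndarray | None = None,
    nominal_index: int = 0,
) -> float:
    """Scenario-composite objective.

    Mean over scenarios of the objective restricted to robust-ROI voxels
    (computed on each scenario dose ``A_s x`` against the one fixed reference)
    plus the objective restricted to the remaining voxels on the nominal
    scenario dose.  With an empty robust mask this reduces exactly to
    :func:`mimic_objective` on the nominal dose.
    """
    if not influences:
        raise ValueError("at least one (nominal) scenario influence is required")
    if not 0 <= nominal_index < len(influences):
        raise ValueError("nominal scenario index out of range")
    x = np.asarray(weights_x, dtype=float)
    ref = np.asarray(d_ref).ravel()
    wf = w.ravel()
    if robust_mask is None:
        robust_mask = np.zeros(ref.shape, dtype=bool)
    rmask = np.asarray(robust_mask).ravel().astype(bool)

    d_nom = np.asarray(influences[nominal_index] @ x).ravel()
    total = mimic_objective(d_nom, ref, _masked_weights(wf, ~rmask))
    if rmask.any():
        w_rob = _masked_weights(wf, rmask)
        acc = 0.0
        for A in influences:
            d_s = np.asarray(A @ x).ravel()
            acc += mimic_objective(d_s, ref, w_rob)
        total += acc / len(influences)
    return total


def _robust_gradient(
    x: np.ndarray,
    influences: Sequence[sp.spmatrix],
    ref: np.ndarray,
    wf: VoxelWeights,
    rmask: np.ndarray,
    nominal_index: int,
) -> np.ndarray:
    w_nom = _masked_weights(wf, ~rmask)
    d_nom = np.asarray(influences[nominal_index] @ x).ravel()
    res, _ = _one_sided_residual(d_nom, ref, w_nom)
    grad = 2.0 * (influences[nominal_index].T @ res)
    if rmask.any():
        w_rob = _masked_weights(wf, rmask)
        for A in influences:
            d_s = np.asarray(A @ x).ravel()
            res_s, _ = _one_sided_residual(d_s, ref, w_rob)
            grad += (2.0 / len(influences)) * (A.T @ res_s)
    return np.asarray(grad).ravel()


@dataclass
class OptimizeResult:
    plan: SpotPlan
    weights: np.ndarray
    trace: np.ndarray  # objective after iteration 0..n (index 0 = initial)
    n_iterations: int


def optimize(
    plan: SpotPlan,
    influences: Sequence[sp.spmatrix],
    d_ref: np.ndarray | DoseGrid,
    w: VoxelWeights,
    cfg: MimicConfig = MimicConfig(),
    robust_mask: np.ndarray | None = None,
    nominal_index: int = 0,
    x0: np.ndarray | None = None,
) -> OptimizeResult:
    """Projected-gradient dose mimicking with backtracking line search.

    Starts from zero weights (deterministic cold start), projects onto the
    nonnegative orthant after each gradient step, and accepts a step only if
    it satisfies an Armijo decrease, so the objective trace never increases.
    """
    influences = list(influences)
    if not influences:
        raise ValueError("need at least one scenario influence matrix")
    n_spots = influences[0].shape[1]
    if n_spots != len(plan.spots):
        raise ValueError("influence matrix column count does not match plan spots")
    if any(A.shape != influences[0].shape for A in influences):
        raise ValueError("all influence matrices must share one shape")
    col_norms = np.asarray(abs(influences[nominal_index]).sum(axis=0)).ravel()
    if influences[nominal_index].nnz == 0 or col_norms.max() == 0:
        raise ValueError("influence matrix is all-zero: no dose can be delivered")

    ref = (d_ref.values if isinstance(d_ref, DoseGrid) else np.asarray(d_ref)).ravel()
    if not np.all(np.isfinite(ref)):
        raise ValueError("reference dose must be finite")
    wf = w.ravel()
    rmask = (
        np.zeros(ref.shape, dtype=bool)
        if robust_mask is None
        else np.asarray(robust_mask).ravel().astype(bool)
    )

    x = np.zeros(n_spots) if x0 is None else np.asarray(x0, dtype=float).copy()
    if x.min(initial=0) < 0:
        raise ValueError("initial weights must be nonnegative")

    # precompute: the scenario term only involves robust-ROI voxels, so each
    # scenario matrix is sliced to those rows; the nominal term keeps the
    # full matrix with robust voxels masked out of its weights
    w_nom = _masked_weights(wf, ~rmask)
    A_nom = influences[nominal_index]
    rob_rows = np.nonzero(rmask)[0]
    has_robust = rob_rows.size > 0
    if has_robust:
        A_rob = [A.tocsr()[rob_rows] for A in influences]
        ref_rob = ref[rob_rows]
        w_rob = VoxelWeights(wf.w_plus[rob_rows], wf.w_minus[rob_rows])

    def f(v: np.ndarray) -> float:
        total = mimic_objective(np.asarray(A_nom @ v).ravel(), ref, w_nom)
        if has_robust:
            acc = 0.0
            for A in A_rob:
                acc += mimic_objective(np.asarray(A @ v).ravel(), ref_rob, w_rob)
            total += acc / len(A_rob)
        return total

    def grad_f(v: np.ndarray) -> np.ndarray:
        res, _ = _one_sided_residual(np.asarray(A_nom @ v).ravel(), ref, w_nom)
        g = 2.0 * (A_nom.T @ res)
        if has_robust:
            for A in A_rob:
                res_s, _ = _one_sided_residual(np.asarray(A @ v).ravel(), ref_rob, w_rob)
                g += (2.0 / len(A_rob)) * (A.T @ res_s)
        return np.asarray(g).ravel()

    fx = f(x)
    trace = [fx]
    step = None
    for it in range(cfg.iterations):
        g = grad_f(x)
        gnorm2 = float(g @ g)
        if gnorm2 == 0.0:
            trace.append(fx)
            continue
        if step is None:
            # scale-free initial step: unit move along the gradient direction
            step = max(float(np.abs(x).max()), 1.0) / np.sqrt(gnorm2)
        step *= 2.0  # optimistic growth, trimmed by backtracking
        accepted = False
        for _ in range(40):
            x_new = np.maximum(x - step * g, 0.0)
            if cfg.min_weight > 0.0:
                x_new[x_new < cfg.min_weight] = 0.0
            dx = x_new - x
            if not dx.any():
                break
            f_new = f(x_new)
            if f_new <= fx + 1e-4 * float(g @ dx):
                x, fx, accepted = x_new, f_new, True
                break
            step *= 0.5
        trace.append(fx)
        if not accepted:
            continue
        if cfg.tolerance > 0 and len(trace) > 1:
            prev = trace[-2]
            if prev > 0 and (prev - fx) / prev < cfg.tolerance:
                break
    return OptimizeResult(
        plan=plan.with_weights(x),
        weights=x,
        trace=np.asarray(trace),
        n_iterations=len(trace) - 1,
    )
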