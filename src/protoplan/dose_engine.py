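"""Analytic pencil-beam-scanning spot dose engine.

A deliberately simple, fully differentiable-by-linearity dose model: dose is
linear in the spot weights, ``dose = A @ weights`` with a sparse influence
matrix ``A``.  Each spot contributes a separable kernel

* depth factor: entry plateau plus a Gaussian Bragg peak in water-equivalent
  depth (WED), peaking exactly where WED equals the spot's nominal range;
* lateral factor: a 2D Gaussian in beam's-eye-view distance from the spot
  center, with sigma growing linearly with geometric depth.

The beam direction is fixed en-face along +y (array axis 1); WED is the
cumulative density-weighted path length along that axis.  Setup/range
uncertainty scenarios are modeled as integer-voxel isocenter shifts plus a
multiplicative WED (density) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import json
import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp

from .grid_core import DoseGrid, RoiMask

__all__ = [
    "Spot",
    "SpotPlan",
    "BeamModel",
    "Scenario",
    "make_scenarios",
    "wed_grid",
    "spot_dose",
    "influence_matrix",
    "place_spots",
]

BEAM_AXIS = 1  # +y, posterior->anterior; lateral BEV axes are (x, z)


@dataclass(frozen=True)
class Spot:
    """One PBS beamlet: lateral BEV position (u, v) mm, nominal range R in
    mm water-equivalent, and a nonnegative MU-like weight."""

    u: float
    v: float
    range_mm: float
    weight: float = 0.0

    def __post_init__(self) -> None:
        if self.range_mm <= 0:
            raise ValueError(f"spot range must be > 0, got {self.range_mm}")
        if self.weight < 0:
            raise ValueError(f"spot weight must be >= 0, got {self.weight}")


@dataclass
class SpotPlan:
    """A single en-face beam: isocenter (mm, patient coords) plus spots."""

    spots: list[Spot]
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.spots = list(self.spots)
        if not self.spots:
            raise ValueError("a plan needs at least one spot")

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.spots])

    def with_weights(self, weights: np.ndarray) -> "SpotPlan":
        if len(weights) != len(self.spots):
            raise ValueError("weight vector length mismatch")
        spots = [replace(s, weight=float(w)) for s, w in zip(self.spots, weights)]
        return SpotPlan(spots, self.isocenter)

    def to_json(self, path) -> None:
        payload = {
            "isocenter": list(self.isocenter),
            "spots": [
                {"u": s.u, "v": s.v, "range_mm": s.range_mm, "weight": s.weight}
                for s in self.spots
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SpotPlan":
        with open(path) as fh:
            payload = json.load(fh)
        spots = [Spot(d["u"], d["v"], d["range_mm"], d["weight"]) for d in payload["spots"]]
        return cls(spots, tuple(payload["isocenter"]))


@dataclass(frozen=True)
class BeamModel:
    """Kernel parameters of the analytic engine.

    sigma_mm:        lateral Gaussian sigma at patient entry (mm)
    sigma_growth:    sigma increase per mm of geometric depth (dimensionless)
    bragg_sigma_mm:  Gaussian width of the Bragg peak in WED (mm)
    plateau:         entry-plateau-to-peak dose ratio, in (0, 1)
    """

    sigma_mm: float = 6.0
    sigma_growth: float = 0.02
    bragg_sigma_mm: float = 6.0
    plateau: float = 0.35

    def __post_init__(self) -> None:
        if min(self.sigma_mm, self.sigma_growth, self.bragg_sigma_mm) <= 0:
            raise ValueError("beam model lengths/rates must be positive")
        if not 0 < self.plateau < 1:
            raise ValueError(f"plateau ratio must be in (0,1), got {self.plateau}")


@dataclass(frozen=True)
class Scenario:
    """One uncertainty perturbation: rigid setup shift (mm) and a density
    (range) scale factor."""

    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    density_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.9 <= self.density_scale <= 1.1:
            raise ValueError(f"density scale {self.density_scale} outside [0.9, 1.1]")

    @property
    def is_nominal(self) -> bool:
        return self.shift_mm == (0.0, 0.0, 0.0) and self.density_scale == 1.0


def make_scenarios(setup_mm: float, range_pct: float, mode: str) -> list[Scenario]:
    """Enumerate the uncertainty scenario set.

    mode='optimization': {no shift, +-setup on each axis} x {1-r, 1, 1+r}
                         -> 7 x 3 = 21 scenarios (robust optimization set);
    mode='evaluation':   {+-setup on each axis} x {1-r, 1+r}
                         -> 6 x 2 = 12 scenarios (robustness evaluation set);
    mode='nominal':      the identity perturbation only.
    """
    if setup_mm < 0 or range_pct < 0:
        raise ValueError("setup_mm and range_pct must be >= 0")
    s, r = float(setup_mm), float(range_pct) / 100.0
    axis_shifts = []
    for ax in range(3):
        for sign in (+1, -1):
            vec = [0.0, 0.0, 0.0]
            vec[ax] = sign * s
            axis_shifts.append(tuple(vec))
    if mode == "optimization":
        shifts = [(0.0, 0.0, 0.0)] + axis_shifts
        scales = [1.0 - r, 1.0, 1.0 + r]
    elif mode == "evaluation":
        shifts = axis_shifts
        scales = [1.0 - r, 1.0 + r]
    elif mode == "nominal":
        return [Scenario()]
    else:
        raise ValueError(f"unknown scenario mode {mode!r}")
    return [Scenario(shift, scale) for scale in scales for shift in shifts]


def _shift_voxels(shift_mm: Sequence[float], spacing: Sequence[float]) -> tuple[int, int, int]:
    """Nearest-voxel rendering of a rigid shift (mm) on this lattice."""
    return tuple(int(round(d / s)) for d, s in zip(shift_mm, spacing))


def _integer_shift(values: np.ndarray, shift_vox: Sequence[int]) -> np.ndarray:
    """Shift an array by whole voxels with zero fill (no wrap-around)."""
    out = values
    for ax, n in enumerate(shift_vox):
        if n == 0:
            continue
        shifted = np.zeros_like(out)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        if n > 0:
            dst[ax], src[ax] = slice(n, None), slice(0, -n)
        else:
            dst[ax], src[ax] = slice(0, n), slice(-n, None)
        shifted[tuple(dst)] = out[tuple(src)]
        out = shifted
    return out


def wed_grid(density: DoseGrid, scenario: Scenario = Scenario()) -> DoseGrid:
    """Water-equivalent depth along the beam axis for a scenario.

    The patient is shifted (nearest voxel) relative to the beam, the density
    is scaled by the scenario's range factor, and WED at a voxel is the
    cumulative density x path-length integral up to that voxel's center:
    for uniform density 1 and spacing s the k-th voxel gets ``s * (k + 0.5)``.
    Monotone nondecreasing along the axis for nonnegative density.
    """
    shift_vox = _shift_voxels(scenario.shift_mm, density.spacing)
    rho = _integer_shift(density.values, shift_vox)
    step = density.spacing[BEAM_AXIS]
    cum = np.cumsum(rho, axis=BEAM_AXIS)
    wed = (cum - 0.5 * rho) * step * scenario.density_scale
    return density.new_like(wed)


def _depth_factor(wed: np.ndarray, range_mm: float, model: BeamModel) -> np.ndarray:
    """Entry plateau + Bragg-peak Gaussian in (WED - R); maximum ~1 at
    WED = R.  The plateau is proximal only: it is rolled off smoothly just
    past the peak (protons stop), so the distal falloff is carried by the
    peak Gaussian alone.  The roll-off midpoint sits 2 Bragg widths beyond
    the peak, keeping the kernel symmetric in the peak region."""
    from scipy.special import expit

    s = model.bragg_sigma_mm
    gauss = np.exp(-0.5 * ((wed - range_mm) / s) ** 2)
    proximal = expit((range_mm + 2.0 * s - wed) / (0.5 * s))
    return model.plateau * proximal + (1.0 - model.plateau) * gauss


def spot_dose(
    spot: Spot,
    wed: DoseGrid,
    model: BeamModel = BeamModel(),
    scenario: Scenario = Scenario(),
) -> DoseGrid:
    """Dose per unit weight of one spot, on the patient grid.

    ``wed`` must come from :func:`wed_grid` with the *same* scenario: the
    kernel is evaluated in the beam frame (where the WED grid lives after
    the patient shift) and the resulting dose is shifted back onto the
    patient lattice, so the nominal scenario is reproduced bit-identically.
    """
    x = wed.voxel_coords(0)
    z = wed.voxel_coords(2)
    ny = wed.shape[BEAM_AXIS]
    depth_mm = (np.arange(ny) + 0.5) * wed.spacing[BEAM_AXIS]
    sigma = model.sigma_mm + model.sigma_growth * depth_mm  # (ny,)

    du = x - spot.u  # (nx,)
    dv = z - spot.v  # (nz,)
    gx = np.exp(-0.5 * (du[:, None] / sigma[None, :]) ** 2)  # (nx, ny)
    gz = np.exp(-0.5 * (dv[None, :] / sigma[:, None]) ** 2)  # (ny, nz)
    depth = _depth_factor(wed.values, spot.range_mm, model)  # (nx, ny, nz)
    dose = depth * gx[:, :, None] * gz[None, :, :]

    shift_vox = _shift_voxels(scenario.shift_mm, wed.spacing)
    if any(shift_vox):
        dose = _integer_shift(dose, tuple(-n for n in shift_vox))
    return wed.new_like(dose)


@dataclass(frozen=True)
class EngineConfig:
    """Numerical knobs of the influence-matrix builder."""

    beam_model: BeamModel = BeamModel()
    sparsity_cutoff: float = 1e-4  # relative to each column's max
    max_voxels: int = 2_000_000

    def __post_init__(self) -> None:
        if not 0 <= self.sparsity_cutoff < 1:
            raise ValueError("sparsity cutoff must be in [0, 1)")


def influence_matrix(
    plan: SpotPlan,
    density: DoseGrid,
    config: EngineConfig = EngineConfig(),
    scenario: Scenario = Scenario(),
) -> sp.csr_matrix:
    """Sparse dose-influence matrix A (n_voxels x n_spots) under a scenario.

    Column j is the flattened per-unit-weight dose of spot j; entries below
    ``sparsity_cutoff`` times the column max are dropped.  The full scenario
    dose of a weight vector w is ``(A @ w).reshape(grid shape)``.
    """
    n_vox = int(np.prod(density.shape))
    if n_vox > config.max_voxels:
        raise MemoryError(
            f"grid has {n_vox} voxels, above the configured limit of {config.max_voxels}"
        )
    wed = wed_grid(density, scenario)
    cols = []
    for spot in plan.spots:
        dose = spot_dose(spot, wed, config.beam_model, scenario).values.ravel()
        peak = dose.max()
        if peak > 0:
            dose = np.where(dose >= config.sparsity_cutoff * peak, dose, 0.0)
        cols.append(sp.csc_matrix(dose[:, None]))
    A = sp.hstack(cols, format="csr")
    return A


def scenario_dose(A: sp.spmatrix, weights: np.ndarray, shape) -> np.ndarray:
    """Dense dose array from an influence matrix and spot weights."""
    return np.asarray(A @ np.asarray(weights)).reshape(shape)


def place_spots(
    target: RoiMask,
    density: DoseGrid,
    margin_mm: float = 5.0,
    lateral_spacing_mm: float = 7.5,
    layer_spacing_mm: float = 7.5,
) -> SpotPlan:
    """Deterministic spot placement covering a target volume.

    Lateral positions form a regular BEV grid over the target's projection
    along the beam axis, dilated by ``margin_mm``.  Nominal ranges form
    layers spanning the target's WED interval (per lateral column) padded by
    ``margin_mm`` water.
    """
    if target.voxel_count == 0:
        raise ValueError("cannot place spots on an empty target")
    wed = wed_grid(density).values
    proj = target.values.any(axis=BEAM_AXIS)  # (nx, nz)
    x = density.voxel_coords(0)
    z = density.voxel_coords(2)

    # BEV lateral lattice covering bounding box + margin
    ix, iz = np.nonzero(proj)
    x_lo, x_hi = x[ix.min()] - margin_mm, x[ix.max()] + margin_mm
    z_lo, z_hi = z[iz.min()] - margin_mm, z[iz.max()] + margin_mm
    us = np.arange(x_lo, x_hi + 1e-9, lateral_spacing_mm)
    vs = np.arange(z_lo, z_hi + 1e-9, lateral_spacing_mm)

    # distance (mm) from each lattice point to the projected target
    dilate_vox = (
        max(1, int(np.ceil((margin_mm + lateral_spacing_mm) / density.spacing[0]))),
        max(1, int(np.ceil((margin_mm + lateral_spacing_mm) / density.spacing[2]))),
    )
    proj_dil = ndi.binary_dilation(
        proj, structure=np.ones((2 * dilate_vox[0] + 1, 2 * dilate_vox[1] + 1), dtype=bool)
    )

    tgt_wed = np.where(target.values, wed, np.nan)
    wed_lo = np.nanmin(tgt_wed)
    wed_hi = np.nanmax(tgt_wed)
    layers = np.arange(wed_lo - margin_mm, wed_hi + margin_mm + 1e-9, layer_spacing_mm)
    if layers.size == 0:
        layers = np.array([max(wed_lo, 1.0)])
    layers = np.maximum(layers, 0.5 * layer_spacing_mm)

    spots = []
    for u in us:
        i = int(np.clip(round((u - x[0]) / density.spacing[0]), 0, len(x) - 1))
        for v in vs:
            k = int(np.clip(round((v - z[0]) / density.spacing[2]), 0, len(z) - 1))
            if not proj_dil[i, k]:
                continue
            # layers relevant to this column: its own WED span if on target,
            # otherwise the neighborhood span (margin column)
            window = tgt_wed[
                max(0, i - dilate_vox[0]) : i + dilate_vox[0] + 1,
                :,
                max(0, k - dilate_vox[1]) : k + dilate_vox[1] + 1,
            ]
            if np.all(np.isnan(window)):
                continue
            lo = np.nanmin(window) - layer_spacing_mm
            hi = np.nanmax(window) + layer_spacing_mm
            for R in layers:
                if lo <= R <= hi:
                    spots.append(Spot(float(u), float(v), float(R), 0.0))
    if not spots:
        raise ValueError("spot placement produced no spots (degenerate target)")
    return SpotPlan(spots)
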