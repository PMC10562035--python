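"""Seeded synthetic thorax phantoms and training-pair generation.

Stands in for a clinical cohort of post-mastectomy chest-wall patients: a
body ellipsoid, two lungs, a heart, an esophagus tube, a chest-wall shell
target on one side and a nodal target volume, all voxelized on a regular
grid.  Reference doses are produced by the package's own analytic engine and
mimicking optimizer against an idealized prescription (uniform Rx inside the
targets with a Gaussian margin falloff), so the prediction network has a
physics-consistent mapping to learn.

Densities are water-equivalent surrogates: soft tissue 1.0 g/cc, lung
0.26 g/cc, air 0.  Per-case anatomical variation is Gaussian jitter of organ
centers and semi-axes, reproducible from the cohort seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi

from . import dose_engine as de
from . import mimic
from .grid_core import (
    DoseGrid,
    RoiMask,
    StructureSet,
    read_grid,
    read_structure_set,
    write_grid,
    write_structure_set,
)

__all__ = [
    "PhantomConfig",
    "generate_phantom",
    "ideal_target_dose",
    "generate_reference_dose",
    "generate_cohort",
    "split_cohort",
    "write_cohort",
    "read_cohort",
]

LUNG_DENSITY = 0.26
TISSUE_DENSITY = 1.0


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry of the synthetic thorax (all lengths in mm).

    The default grid is the desk-scale lattice 32 x 32 x 48 at 5 mm.  The
    beam enters the low-y face, so the chest-wall target shell sits in the
    low-y (entry-side) half of the body.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 48)
    spacing: tuple[float, float, float] = (5.0, 5.0, 5.0)
    body_semi_axes: tuple[float, float, float] = (70.0, 55.0, 104.0)
    body_center_offset: tuple[float, float, float] = (0.0, -5.0, 0.0)
    lung_semi_axes: tuple[float, float, float] = (28.0, 36.0, 70.0)
    lung_separation: float = 72.0  # center-to-center along x
    lung_center_y: float = 3.0  # offset from body center, toward the deep side
    heart_radius: float = 22.0
    heart_center: tuple[float, float, float] = (8.0, 0.0, -22.0)  # rel. body center
    esophagus_radius: float = 5.0
    esophagus_offset_y: float = 18.0  # posterior of body center
    esophagus_z_extent: tuple[float, float] = (-60.0, 60.0)  # rel. body center
    shell_norm_band: tuple[float, float] = (0.78, 0.96)  # chest-wall shell, body-normalized
    laterality: str = "left"  # side (+x or -x) carrying the targets
    shell_z_extent: tuple[float, float] = (-55.0, 40.0)
    nodes_semi_axes: tuple[float, float, float] = (15.0, 14.0, 25.0)
    nodes_center: tuple[float, float, float] = (28.0, -25.0, 58.0)  # rel. body center
    jitter_center_mm: float = 3.0
    jitter_axes_frac: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.laterality not in ("left", "right"):
            raise ValueError("laterality must be 'left' or 'right'")
        if any(n <= 0 for n in self.grid_shape) or any(s <= 0 for s in self.spacing):
            raise ValueError("grid shape and spacing must be positive")


def _coords(cfg: PhantomConfig):
    axes = [cfg.spacing[a] * np.arange(cfg.grid_shape[a]) for a in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(xyz, center, semi) -> np.ndarray:
    q = sum(((c - cc) / ss) ** 2 for c, cc, ss in zip(xyz, center, semi))
    return q <= 1.0


def generate_phantom(config: PhantomConfig = PhantomConfig()) -> tuple[StructureSet, DoseGrid]:
    """Build one voxelized phantom: masks plus a density grid.

    Deterministic for a fixed config (the config's seed drives the geometry
    jitter).  Raises if the jittered body ellipsoid does not fit the grid.
    """
    rng = np.random.default_rng(config.seed)

    def tnorm(sigma: float) -> float:
        # jitter draws truncated at 2 sigma so default anatomy always fits
        return float(np.clip(rng.normal(0.0, sigma), -2.0 * sigma, 2.0 * sigma)) if sigma > 0 else 0.0

    def jc(center):  # jitter a center triple
        return tuple(c + tnorm(config.jitter_center_mm) for c in center)

    def ja(axes):  # jitter semi-axes multiplicatively
        if np.isscalar(axes):
            return axes * (1.0 + tnorm(config.jitter_axes_frac))
        return tuple(a * (1.0 + tnorm(config.jitter_axes_frac)) for a in axes)

    extent = tuple(s * (n - 1) for n, s in zip(config.grid_shape, config.spacing))
    grid_center = tuple(e / 2.0 for e in extent)
    body_c = jc(tuple(g + o for g, o in zip(grid_center, config.body_center_offset)))
    body_s = ja(config.body_semi_axes)
    for a in range(3):
        if body_c[a] - body_s[a] < -config.spacing[a] or body_c[a] + body_s[a] > extent[a] + config.spacing[a]:
            raise ValueError(
                f"body ellipsoid exceeds the grid on axis {a}: "
                f"center {body_c[a]:.1f}, semi-axis {body_s[a]:.1f}, extent {extent[a]:.1f}"
            )

    xyz = _coords(config)
    body = _ellipsoid(xyz, body_c, body_s)

    side = +1.0 if config.laterality == "left" else -1.0
    lung_s = ja(config.lung_semi_axes)
    lung_dx = ja(config.lung_separation) / 2.0
    lung_cy = body_c[1] + config.lung_center_y
    lung_l = _ellipsoid(xyz, (body_c[0] + lung_dx, lung_cy, body_c[2]), lung_s)
    lung_r = _ellipsoid(xyz, (body_c[0] - lung_dx, lung_cy, body_c[2]), lung_s)
    lungs = (lung_l | lung_r) & body

    heart_c = jc(tuple(b + o for b, o in zip(body_c, config.heart_center)))
    heart_r = ja(config.heart_radius)
    heart = _ellipsoid(xyz, heart_c, (heart_r,) * 3) & body
    lungs &= ~heart  # lungs and heart are disjoint by construction

    eso_c = (body_c[0], body_c[1] + config.esophagus_offset_y)
    eso = (
        ((xyz[0] - eso_c[0]) ** 2 + (xyz[1] - eso_c[1]) ** 2 <= ja(config.esophagus_radius) ** 2)
        & (xyz[2] >= body_c[2] + config.esophagus_z_extent[0])
        & (xyz[2] <= body_c[2] + config.esophagus_z_extent[1])
        & body
    )
    eso &= ~heart

    # chest-wall shell: band of the body-normalized radius, entry-side half,
    # target side only, limited z extent, excluding lung
    q = sum(((c - cc) / ss) ** 2 for c, cc, ss in zip(xyz, body_c, body_s))
    lo, hi = config.shell_norm_band
    shell = (
        (q >= lo**2)
        & (q <= hi**2)
        & (side * (xyz[0] - body_c[0]) > 0)
        & (xyz[1] < body_c[1])
        & (xyz[2] >= body_c[2] + config.shell_z_extent[0])
        & (xyz[2] <= body_c[2] + config.shell_z_extent[1])
        & body
        & ~lungs
    )

    nodes_c = jc(
        (
            body_c[0] + side * config.nodes_center[0],
            body_c[1] + config.nodes_center[1],
            body_c[2] + config.nodes_center[2],
        )
    )
    nodes = _ellipsoid(xyz, nodes_c, ja(config.nodes_semi_axes)) & body & ~lungs

    if not shell.any() or not nodes.any():
        raise ValueError("degenerate phantom: an empty target volume was produced")

    masks = [
        RoiMask("PTV chest wall", shell, role="target", robust=True),
        RoiMask("PTV nodes", nodes, role="target", robust=True),
        RoiMask("lungs", lungs, role="oar"),
        RoiMask("heart", heart, role="oar"),
        RoiMask("esophagus", eso, role="oar"),
        RoiMask("External", body, role="external"),
    ]
    structures = StructureSet(masks, config.spacing, (0.0, 0.0, 0.0))

    density = np.zeros(config.grid_shape)
    density[body] = TISSUE_DENSITY
    density[lungs] = LUNG_DENSITY
    return structures, DoseGrid(density, config.spacing, (0.0, 0.0, 0.0))


def ideal_target_dose(
    structures: StructureSet,
    rx: float = 50.4,
    falloff_mm: float = 10.0,
    margin_mm: float = 5.0,
) -> DoseGrid:
    """Idealized reference: uniform Rx over the targets dilated by
    ``margin_mm`` (the setup-uncertainty margin, so robust optimization is
    rewarded for covering target edges in shifted scenarios), Gaussian
    falloff with distance beyond, zero outside the body."""
    target = np.zeros(structures.shape, dtype=bool)
    for m in structures.by_role("target"):
        target |= m.values
    dist = ndi.distance_transform_edt(~target, sampling=structures.spacing)
    dose = rx * np.exp(-0.5 * (np.maximum(dist - margin_mm, 0.0) / falloff_mm) ** 2)
    dose[~structures.external.values] = 0.0
    return DoseGrid(dose, structures.spacing, structures.origin)


def generate_reference_dose(
    structures: StructureSet,
    density: DoseGrid,
    engine: de.EngineConfig = de.EngineConfig(),
    rx: float = 50.4,
    iterations: int = 150,
    margin_mm: float = 12.0,
    lateral_spacing_mm: float = 7.5,
    layer_spacing_mm: float = 7.5,
    robust: bool = True,
    setup_mm: float = 5.0,
    range_pct: float = 3.0,
    target_dose_scale: float = 1.03,
) -> tuple[DoseGrid, de.SpotPlan]:
    """Physically consistent training dose: place spots over the targets and
    mimic the idealized dose with the package's own optimizer.  By default
    the optimization is robust over the full 21-scenario set for the target
    volumes, mirroring how the treatment plans a prediction model learns
    from are themselves produced; the returned dose is the nominal-scenario
    dose in Gy, plus the optimized plan."""
    target_union = np.zeros(structures.shape, dtype=bool)
    for m in structures.by_role("target"):
        target_union |= m.values
    tgt = RoiMask("targets", target_union, role="target")
    plan = de.place_spots(
        tgt,
        density,
        margin_mm=margin_mm,
        lateral_spacing_mm=lateral_spacing_mm,
        layer_spacing_mm=layer_spacing_mm,
    )
    scenarios = (
        de.make_scenarios(setup_mm, range_pct, "optimization")
        if robust
        else de.make_scenarios(0.0, 0.0, "nominal")
    )
    nominal_index = next(i for i, s in enumerate(scenarios) if s.is_nominal)
    influences = [de.influence_matrix(plan, density, engine, s) / rx for s in scenarios]
    # plans aim slightly above Rx so coverage goals hold under perturbation
    ideal = ideal_target_dose(structures, rx=rx * target_dose_scale, margin_mm=setup_mm)
    cfg = mimic.MimicConfig(iterations=iterations)
    w = mimic.assign_voxel_weights(structures, cfg)
    robust_mask = target_union if robust else None
    # objective on Rx-normalized dose: both sides scaled by 1/rx
    result = mimic.optimize(
        plan, influences, ideal.values / rx, w, cfg,
        robust_mask=robust_mask, nominal_index=nominal_index,
    )
    dose = de.scenario_dose(influences[nominal_index] * rx, result.weights, structures.shape)
    return DoseGrid(dose, structures.spacing, structures.origin), result.plan


@dataclass
class PhantomCase:
    """One cohort member: masks, density, reference dose, provenance seed."""

    structures: StructureSet
    density: DoseGrid
    dose: DoseGrid
    seed: int


def generate_cohort(
    n: int,
    base_config: PhantomConfig = PhantomConfig(),
    seed: int = 0,
    rx: float = 50.4,
    iterations: int = 150,
) -> list[PhantomCase]:
    """Generate ``n`` jittered phantoms with reference doses, reproducible
    from ``seed`` (case i uses sub-seed derived from (seed, i))."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    ss = np.random.SeedSequence(seed)
    case_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
    cases = []
    for cs in case_seeds:
        cfg = replace(base_config, seed=cs)
        structures, density = generate_phantom(cfg)
        dose, _ = generate_reference_dose(structures, density, rx=rx, iterations=iterations)
        cases.append(PhantomCase(structures, density, dose, cs))
    return cases


def split_cohort(
    n: int, counts: tuple[int, ...], seed: int = 0
) -> list[np.ndarray]:
    """Random disjoint index split of ``n`` cases into len(counts) groups
    covering all indices (sum(counts) must equal n)."""
    if sum(counts) != n:
        raise ValueError(f"split counts {counts} do not sum to {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    out, at = [], 0
    for c in counts:
        out.append(np.sort(perm[at : at + c]))
        at += c
    return out


def write_cohort(cases: list[PhantomCase], directory: str | Path, split: dict | None = None) -> None:
    """Write a cohort as per-case NRRD volumes plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"cases": [], "split": split or {}}
    for i, case in enumerate(cases):
        cdir = directory / f"case_{i:03d}"
        write_structure_set(case.structures, cdir / "structures")
        write_grid(case.density, cdir / "density.nrrd")
        write_grid(case.dose, cdir / "dose.nrrd")
        manifest["cases"].append({"dir": cdir.name, "seed": case.seed})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_cohort(directory: str | Path) -> tuple[list[PhantomCase], dict]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    cases = []
    for entry in manifest["cases"]:
        cdir = directory / entry["dir"]
        structures = read_structure_set(cdir / "structures")
        density = read_grid(cdir / "density.nrrd")
        dose = read_grid(cdir / "dose.nrrd")
        cases.append(PhantomCase(structures, density, dose, entry["seed"]))
    return cases, manifest.get("split", {})
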