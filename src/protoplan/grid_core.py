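"""Voxel-grid data model for dose and ROI masks.

Conventions
-----------
Arrays are indexed ``(i, j, k)`` mapping to patient axes
``(x: right->left, y: posterior->anterior, z: inferior->superior)``.
``origin`` is the patient-coordinate position (mm) of the *center* of voxel
``(0, 0, 0)``.  All volumes of one case share a single lattice; resampling
between non-congruent grids is out of scope — only centered crop/pad is
offered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "DoseGrid",
    "RoiMask",
    "StructureSet",
    "crop_pad",
    "normalize_dose",
    "denormalize_dose",
    "build_input_channels",
    "read_grid",
    "write_grid",
    "read_structure_set",
    "write_structure_set",
]

ROLES = ("target", "oar", "external")


@dataclass
class DoseGrid:
    """A scalar field (dose in Gy, Rx-normalized dose, WED in mm, or density
    in g/cc) on a regular 3D voxel lattice."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if self.values.size and self.values.min() < 0:
            raise ValueError("dose/density values must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def new_like(self, values: np.ndarray) -> "DoseGrid":
        return DoseGrid(values, self.spacing, self.origin)

    def voxel_coords(self, axis: int) -> np.ndarray:
        """Patient coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)


@dataclass
class RoiMask:
    """A named binary region of interest on the parent lattice."""

    name: str
    values: np.ndarray
    role: str = "oar"
    robust: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"mask {self.name!r} must be 3D")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"mask {self.name!r} must be binary")
            arr = arr.astype(bool)
        self.values = arr
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())


@dataclass
class StructureSet:
    """Ordered collection of ROI masks sharing one grid geometry.

    Exactly one mask must have ``role='external'`` (the body contour)."""

    masks: list[RoiMask]
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.masks = list(self.masks)
        if not self.masks:
            raise ValueError("structure set needs at least one mask")
        shapes = {m.shape for m in self.masks}
        if len(shapes) != 1:
            raise ValueError(f"all masks must share one shape, got {shapes}")
        externals = [m for m in self.masks if m.role == "external"]
        if len(externals) != 1:
            raise ValueError(f"exactly one external mask required, found {len(externals)}")
        names = [m.name for m in self.masks]
        if len(set(names)) != len(names):
            raise ValueError("duplicate ROI names")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.masks[0].shape

    @property
    def external(self) -> RoiMask:
        return next(m for m in self.masks if m.role == "external")

    def names(self) -> list[str]:
        return [m.name for m in self.masks]

    def __contains__(self, name: str) -> bool:
        return any(m.name == name for m in self.masks)

    def __getitem__(self, name: str) -> RoiMask:
        for m in self.masks:
            if m.name == name:
                return m
        raise KeyError(f"no ROI named {name!r}; have {self.names()}")

    def __iter__(self) -> Iterator[RoiMask]:
        return iter(self.masks)

    def union(self, names: Iterable[str]) -> np.ndarray:
        """Boolean union of the named masks."""
        out = np.zeros(self.shape, dtype=bool)
        for n in names:
            out |= self[n].values
        return out

    def by_role(self, role: str) -> list[RoiMask]:
        return [m for m in self.masks if m.role == role]

    def voxel_volume_cc(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0


def _crop_pad_slices(n: int, t: int) -> tuple[slice, slice]:
    """Source and destination slices for centering an axis of length n into
    length t.  The odd remainder goes to the high-index side (removed when
    cropping, added when padding)."""
    if t >= n:
        lo = (t - n) // 2
        return slice(0, n), slice(lo, lo + n)
    lo = (n - t) // 2
    return slice(lo, lo + t), slice(0, t)


def crop_pad(obj, target_dims: Sequence[int]):
    """Center-crop or zero-pad a :class:`DoseGrid` or :class:`RoiMask` to
    ``target_dims``.  Padding value is 0; the extra voxel of any odd margin
    goes to the high-index side.  The grid origin is adjusted so retained
    voxels keep their patient coordinates."""
    target = tuple(int(d) for d in target_dims)
    if len(target) != 3 or any(d <= 0 for d in target):
        raise ValueError(f"target_dims must be 3 positive integers, got {target_dims}")

    if isinstance(obj, DoseGrid):
        values, shape = obj.values, obj.shape
    elif isinstance(obj, RoiMask):
        values, shape = obj.values, obj.shape
    else:
        raise TypeError(f"crop_pad expects DoseGrid or RoiMask, got {type(obj).__name__}")

    src, dst = zip(*(_crop_pad_slices(n, t) for n, t in zip(shape, target)))
    out = np.zeros(target, dtype=values.dtype)
    out[dst[0], dst[1], dst[2]] = values[src[0], src[1], src[2]]

    if isinstance(obj, RoiMask):
        return replace(obj, values=out)
    # index 0 of output maps to patient coord of (src.start - dst.start)
    new_origin = tuple(
        obj.origin[a] + obj.spacing[a] * (src[a].start - dst[a].start) for a in range(3)
    )
    return DoseGrid(out, obj.spacing, new_origin)


def crop_pad_structures(structures: StructureSet, target_dims: Sequence[int]) -> StructureSet:
    """Apply :func:`crop_pad` to every mask of a structure set."""
    masks = [crop_pad(m, target_dims) for m in structures.masks]
    src, dst = zip(
        *(_crop_pad_slices(n, int(t)) for n, t in zip(structures.shape, target_dims))
    )
    new_origin = tuple(
        structures.origin[a] + structures.spacing[a] * (src[a].start - dst[a].start)
        for a in range(3)
    )
    return StructureSet(masks, structures.spacing, new_origin)


def normalize_dose(dose: DoseGrid, rx: float) -> DoseGrid:
    """Rescale dose so voxels at the prescription ``rx`` (Gy) get value 1."""
    if rx <= 0:
        raise ValueError(f"rx must be > 0, got {rx}")
    return dose.new_like(dose.values / float(rx))


def denormalize_dose(dose: DoseGrid, rx: float) -> DoseGrid:
    """Inverse of :func:`normalize_dose`."""
    if rx <= 0:
        raise ValueError(f"rx must be > 0, got {rx}")
    return dose.new_like(dose.values * float(rx))


DEFAULT_CHANNEL_MAP: dict[str, list[str]] = {
    "targets": ["PTV chest wall", "PTV nodes"],
    "lungs": ["lungs"],
    "heart_esophagus": ["heart", "esophagus"],
    "external": ["External"],
}


def build_input_channels(
    structures: StructureSet,
    channel_map: Mapping[str, Sequence[str]] | None = None,
) -> np.ndarray:
    """Assemble the 4-channel binary model input: (1) union of target
    volumes, (2) lungs, (3) heart & esophagus, (4) external region.

    ``channel_map`` maps channel name -> list of ROI names; the grouping is
    configurable because it is treatment-site specific.
    Returns a float32 array of shape ``(4,) + grid shape``.
    """
    cmap = dict(DEFAULT_CHANNEL_MAP if channel_map is None else channel_map)
    if len(cmap) != 4:
        raise ValueError(f"channel map must define 4 channels, got {len(cmap)}")
    missing = [n for names in cmap.values() for n in names if n not in structures]
    if missing:
        raise KeyError(
            f"channel map references missing ROIs {missing}; available: {structures.names()}"
        )
    channels = np.stack(
        [structures.union(names).astype(np.float32) for names in cmap.values()]
    )
    return channels


# ---------------------------------------------------------------------------
# NRRD I/O (SimpleITK keeps arrays as (z, y, x); we store (x, y, z))
# ---------------------------------------------------------------------------

def _to_sitk(values: np.ndarray, spacing, origin):
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(values.T))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def write_grid(grid: DoseGrid, path: str | Path) -> None:
    """Write a grid as an (uncompressed-header) NRRD volume."""
    import SimpleITK as sitk

    sitk.WriteImage(_to_sitk(grid.values, grid.spacing, grid.origin), str(path))


def read_grid(path: str | Path) -> DoseGrid:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).T
    return DoseGrid(values, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def write_structure_set(structures: StructureSet, directory: str | Path) -> None:
    """Write each mask as NRRD plus an index JSON with roles/flags."""
    import SimpleITK as sitk

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = []
    for m in structures.masks:
        fname = m.name.replace(" ", "_") + ".nrrd"
        img = _to_sitk(m.values.astype(np.uint8), structures.spacing, structures.origin)
        sitk.WriteImage(img, str(directory / fname))
        index.append({"name": m.name, "file": fname, "role": m.role, "robust": m.robust})
    (directory / "structures.json").write_text(json.dumps(index, indent=2))


def write_labeled_masks(structures: StructureSet, path: str | Path) -> None:
    """Export all masks as one labeled NRRD (labels 1..n in mask order;
    overlaps take the later label)."""
    labels = np.zeros(structures.shape, dtype=np.uint8)
    for i, m in enumerate(structures.masks, start=1):
        labels[m.values] = i
    import SimpleITK as sitk

    sitk.WriteImage(_to_sitk(labels, structures.spacing, structures.origin), str(path))


def read_structure_set(directory: str | Path) -> StructureSet:
    import SimpleITK as sitk

    directory = Path(directory)
    index = json.loads((directory / "structures.json").read_text())
    masks, spacing, origin = [], None, None
    for entry in index:
        img = sitk.ReadImage(str(directory / entry["file"]))
        spacing, origin = tuple(img.GetSpacing()), tuple(img.GetOrigin())
        masks.append(
            RoiMask(
                entry["name"],
                sitk.GetArrayFromImage(img).T.astype(bool),
                role=entry["role"],
                robust=entry.get("robust", False),
            )
        )
    return StructureSet(masks, spacing, origin)
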