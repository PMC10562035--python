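"""DVH modification of a predicted dose by rank-preserving histogram matching.

A rule edits the dose-volume histogram of one ROI and the voxel doses inside
that ROI are resampled to fit the edited DVH by a monotone (rank-preserving)
remap; voxels outside all ruled ROIs are left bit-identical.  Two rule kinds
cover the usual clinical edits:

* ``max_dose_clamp`` — compress doses above a level down to the level (the
  minimal monotone change limiting the ROI's max point dose);
* ``min_coverage`` — raise the coldest tail so that a stated volume fraction
  of the ROI receives at least the level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.stats

from .grid_core import DoseGrid, StructureSet

__all__ = ["DvhRule", "apply_dvh_rules", "histogram_match"]

log = logging.getLogger(__name__)

RULE_KINDS = ("max_dose_clamp", "min_coverage")


@dataclass(frozen=True)
class DvhRule:
    """One DVH edit.

    The dose level is either absolute (``dose_gy``) or a fraction of the
    prescription (``dose_rx_fraction``); exactly one must be set.
    ``volume_fraction`` (in (0, 1]) applies to ``min_coverage`` only: the
    fraction of the ROI that must receive at least the level.
    """

    roi: str
    kind: str
    dose_gy: float | None = None
    dose_rx_fraction: float | None = None
    volume_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise ValueError(f"rule kind must be one of {RULE_KINDS}, got {self.kind!r}")
        if (self.dose_gy is None) == (self.dose_rx_fraction is None):
            raise ValueError("set exactly one of dose_gy / dose_rx_fraction")
        level = self.dose_gy if self.dose_gy is not None else self.dose_rx_fraction
        if level <= 0:
            raise ValueError("dose level must be > 0")
        if not 0 < self.volume_fraction <= 1:
            raise ValueError("volume_fraction must be in (0, 1]")

    def level(self, rx: float) -> float:
        return float(self.dose_gy) if self.dose_gy is not None else float(self.dose_rx_fraction) * rx


def histogram_match(values: np.ndarray, target_quantile: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
    """Remap a 1D dose sample onto a target quantile function.

    The value at (average) rank r among n samples becomes
    ``target_quantile(r / (n - 1))``; tied inputs share an average rank and
    therefore map to one output value, so the remap is monotone and
    rank-preserving.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("histogram_match expects a nonempty 1D sample")
    if v.size == 1:
        return np.asarray(target_quantile(np.array([0.5])), dtype=float)
    ranks = scipy.stats.rankdata(v, method="average") - 1.0
    p = ranks / (v.size - 1)
    return np.asarray(target_quantile(p), dtype=float)


def _empirical_quantile(sample: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    srt = np.sort(sample)
    def q(p: np.ndarray) -> np.ndarray:
        return np.quantile(srt, np.clip(p, 0.0, 1.0))
    return q


def apply_dvh_rules(
    dose: DoseGrid,
    structures: StructureSet,
    rules: Sequence[DvhRule],
    rx: float = 50.4,
) -> DoseGrid:
    """Apply DVH rules in list order; voxels outside all ruled ROIs are
    untouched.  Overlapping ruled ROIs take the last applied transform (a
    conflict is logged)."""
    out = dose.values.copy()
    touched = np.zeros(out.shape, dtype=bool)
    for rule in rules:
        if rule.roi not in structures:
            raise KeyError(f"DVH rule references missing ROI {rule.roi!r}")
        mask = structures[rule.roi].values
        if not mask.any():
            continue
        if (touched & mask).any():
            log.warning(
                "DVH rules overlap on ROI %r; the later rule wins on shared voxels",
                rule.roi,
            )
        level = rule.level(rx)
        sample = out[mask]
        base_q = _empirical_quantile(sample)
        if rule.kind == "max_dose_clamp":
            tq = lambda p, q=base_q, L=level: np.minimum(q(p), L)
        else:  # min_coverage: raise the coldest (1 - fraction) tail
            p_cut = 1.0 - rule.volume_fraction
            def tq(p, q=base_q, L=level, pc=p_cut):
                vals = q(p)
                return np.where(np.asarray(p) >= pc, np.maximum(vals, L), vals)
        out[mask] = histogram_match(sample, tq)
        touched |= mask
    return dose.new_like(out)
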