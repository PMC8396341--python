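"""Slide-level immune density: counts per region -> log density L.

L is the natural logarithm of the mean number of cells per square
millimeter over the slide's regions: L = ln((1/n) * sum_i c_i / A_i).
Regions are either all tiles of a slide (pipeline mode) or a handful of
hand-picked fields (reference/pathologist mode); the formula is the same.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SlideDensityEstimate",
    "tile_geometry",
    "slide_density",
    "compare_densities",
]


@dataclass(frozen=True)
class SlideDensityEstimate:
    slide_id: str
    counts: np.ndarray
    areas_mm2: np.ndarray
    L: float  # -inf sentinel when the total count is zero

    @property
    def n_regions(self) -> int:
        return len(self.counts)

    @property
    def total_count(self) -> float:
        return float(self.counts.sum())

    @property
    def is_empty(self) -> bool:
        return not np.isfinite(self.L)


def tile_geometry(side_px: int, resolution_um_per_px: float) -> tuple[float, float]:
    """(side in mm, area in mm^2) of a square tile.

    side_mm = side_px * resolution * 1e-3; area = side_mm ** 2.
    E.g. a 512-px tile at 0.5 um/px is 0.256 mm across (0.065536 mm^2).
    """
    if side_px <= 0 or resolution_um_per_px <= 0:
        raise ValueError("side and resolution must be positive")
    side_mm = side_px * resolution_um_per_px * 1e-3
    return side_mm, side_mm**2


def slide_density(
    counts, areas_mm2, slide_id: str = ""
) -> SlideDensityEstimate:
    """Log mean density over regions; zero total count gives L = -inf."""
    c = np.asarray(counts, dtype=float)
    a = np.asarray(areas_mm2, dtype=float)
    if c.shape != a.shape or c.ndim != 1 or c.size == 0:
        raise ValueError("counts and areas must be equal-length 1-D vectors")
    if (a <= 0).any():
        raise ValueError("all region areas must be positive")
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    mean_density = (c / a).mean()
    L = np.log(mean_density) if mean_density > 0 else -np.inf
    return SlideDensityEstimate(slide_id=slide_id, counts=c, areas_mm2=a, L=float(L))


def compare_densities(predicted, reference):
    """Pearson agreement between predicted and reference per-slide L.

    Returns ``(r, p_value, residuals)`` with residuals = predicted -
    reference (their mean is the systematic offset).  Requires >= 3
    finite pairs and non-constant vectors.
    """
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape:
        raise ValueError("vectors must have equal length")
    finite = np.isfinite(p) & np.isfinite(r)
    p, r = p[finite], r[finite]
    if p.size < 3:
        raise ValueError("need at least 3 finite slide pairs")
    if np.ptp(p) == 0 or np.ptp(r) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(p, r)
    return float(res.statistic), float(res.pvalue), p - r
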