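"""Density map -> cell centers: clip, Otsu, watershed, centers of mass.

The three-step pipeline: (1) negative values are zeroed, (2) the map is
binarized at the Otsu threshold (256 uniform bins over the value range,
foreground strictly above the threshold), (3) dense connected components
are split by watershed on the negated density seeded from local maxima
(minimum seed separation one cell diameter, 8 px by default), and each
labeled component contributes its density-weighted center of mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

__all__ = [
    "LabeledMask",
    "DegenerateHistogramError",
    "clip_negative",
    "otsu_threshold",
    "split_components",
    "centers_of_mass",
    "detect",
]

OTSU_BINS = 256
DEFAULT_SEED_SEPARATION = 8


class DegenerateHistogramError(ValueError):
    """Raised when a map has a constant histogram (no threshold exists)."""


@dataclass(frozen=True)
class LabeledMask:
    """Binary foreground mask plus an integer component labeling.

    Labels run 1..n with 0 as background; ``n_components`` equals the
    number of distinct nonzero labels.
    """

    mask: np.ndarray
    labels: np.ndarray
    n_components: int

    def component_pixels(self, label: int) -> np.ndarray:
        rows, cols = np.nonzero(self.labels == label)
        return np.column_stack([cols, rows])  # (x, y)


def clip_negative(density: np.ndarray) -> np.ndarray:
    """Elementwise max(x, 0).  NaNs are rejected."""
    arr = np.asarray(density, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("density map contains NaN values")
    return np.maximum(arr, 0.0)


def otsu_threshold(density: np.ndarray, bins: int = OTSU_BINS) -> float:
    """Threshold maximizing inter-class variance over ``bins`` uniform bins.

    Candidate thresholds are the interior bin edges over [min, max]; the
    between-class variance of the exact pixel values split at each
    candidate (foreground strictly above) is maximized, first maximum on
    ties.
    """
    v = np.asarray(density, dtype=float).ravel()
    vmin, vmax = v.min(), v.max()
    if vmin == vmax:
        raise DegenerateHistogramError("constant map: threshold undefined")
    edges = np.linspace(vmin, vmax, bins + 1)[1:-1]
    order = np.sort(v)
    csum = np.concatenate([[0.0], np.cumsum(order)])
    n = v.size
    # number of pixels <= edge (background class, '>' thresholding)
    k = np.searchsorted(order, edges, side="right")
    total = csum[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = csum[k] / k
        mu1 = (total - csum[k]) / (n - k)
        w0 = k / n
        var = w0 * (1 - w0) * (mu0 - mu1) ** 2
    var = np.where((k == 0) | (k == n), -np.inf, var)
    return float(edges[int(np.argmax(var))])


def split_components(
    mask: np.ndarray,
    density: np.ndarray,
    min_seed_separation: int = DEFAULT_SEED_SEPARATION,
    min_area: int = 0,
) -> LabeledMask:
    """Watershed split of dense components into per-cell labels.

    Seeds are local maxima of the density inside the mask with the given
    minimum separation; watershed runs on the negated density restricted
    to the mask.  Components that receive no seed (flat plateaus) keep a
    single label, so the output label count is never below the input
    connected-component count.
    """
    mask = np.asarray(mask, dtype=bool)
    density = np.asarray(density, dtype=float)
    if mask.shape != density.shape:
        raise ValueError("mask and density map shapes differ")
    if not mask.any():
        return LabeledMask(mask=mask, labels=np.zeros_like(mask, dtype=int), n_components=0)
    peaks = peak_local_max(
        density,
        min_distance=min_seed_separation,
        labels=mask,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-density, markers=markers, mask=mask)
    # components untouched by any seed keep one label each
    cc, n_cc = ndimage.label(mask)
    next_label = labels.max() + 1
    for comp in range(1, n_cc + 1):
        sel = cc == comp
        if not labels[sel].any():
            labels[sel] = next_label
            next_label += 1
    if min_area > 1:
        for lab in np.unique(labels):
            if lab and (labels == lab).sum() < min_area:
                labels[labels == lab] = 0
    labels = _compact_labels(labels)
    return LabeledMask(mask=labels > 0, labels=labels, n_components=int(labels.max()))


def _compact_labels(labels: np.ndarray) -> np.ndarray:
    vals = np.unique(labels)
    vals = vals[vals > 0]
    out = np.zeros_like(labels)
    for new, old in enumerate(vals, start=1):
        out[labels == old] = new
    return out


def centers_of_mass(labeled: LabeledMask, density: np.ndarray) -> np.ndarray:
    """Density-weighted centroid of each component, as (x, y) rows."""
    if labeled.n_components == 0:
        return np.empty((0, 2))
    density = np.asarray(density, dtype=float)
    idx = range(1, labeled.n_components + 1)
    sums = ndimage.sum_labels(density, labeled.labels, list(idx))
    centers = []
    for lab, s in zip(idx, sums):
        if s > 0:
            r, c = ndimage.center_of_mass(density, labeled.labels, lab)
        else:  # zero-mass component: fall back to the geometric centroid
            r, c = ndimage.center_of_mass(labeled.labels == lab)
        centers.append((c, r))
    return np.asarray(centers)


def detect(
    density: np.ndarray,
    min_seed_separation: int = DEFAULT_SEED_SEPARATION,
    min_area: int = 0,
) -> np.ndarray:
    """Full pipeline: predicted density map -> (n, 2) array of (x, y).

    A constant (e.g. all-zero) map yields an empty prediction set.
    """
    clipped = clip_negative(density)
    try:
        thr = otsu_threshold(clipped)
    except DegenerateHistogramError:
        return np.empty((0, 2))
    mask = clipped > thr
    labeled = split_components(mask, clipped, min_seed_separation, min_area)
    return centers_of_mass(labeled, clipped)
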