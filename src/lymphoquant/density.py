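"""Gaussian density-map regression targets from point annotations.

A point annotation set is turned into a scalar field whose integral
equals (peak value ``d``) × (number of annotations), by placing ``d`` at
each annotated pixel and convolving with a square Gaussian kernel with
zero-padded borders.  With the default unit-mass kernel and ``d = 1``
the map mass is the object count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DensityMap", "gaussian_kernel", "build_density_map", "DEFAULT_SIGMA", "DEFAULT_D"]

#: Default kernel width: lymphocyte radius ~4 px at 0.5 um/pixel.
DEFAULT_SIGMA = 4.0
#: Default peak value assigned to each annotated pixel.
DEFAULT_D = 1.0


def default_side(sigma: float) -> int:
    """Default odd kernel side covering +-3 sigma (l = 6*sigma + 1)."""
    side = int(round(6 * sigma)) + 1
    if side % 2 == 0:
        side += 1
    return max(side, 3)


@dataclass(frozen=True)
class DensityMap:
    """A nonnegative scalar field over tile pixels encoding object count."""

    values: np.ndarray
    d: float
    sigma: float
    side: int

    @property
    def mass(self) -> float:
        return float(self.values.sum())

    @property
    def estimated_count(self) -> float:
        return self.mass / self.d


def gaussian_kernel(sigma: float, side: int | None = None, normalize: bool = True) -> np.ndarray:
    """Square 2-D Gaussian kernel evaluated at integer offsets.

    ``G(x, y) = exp(-(x^2 + y^2) / (2 sigma^2)) / (2 pi sigma^2)``
    centred on the kernel midpoint.  If ``normalize``, entries are scaled
    to sum to exactly 1 (unit mass).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if side is None:
        side = default_side(sigma)
    if side < 3:
        raise ValueError("side must be >= 3")
    if side % 2 == 0:
        raise ValueError(f"kernel side must be odd, got {side}")
    half = side // 2
    ax = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2)) / (2.0 * np.pi * sigma**2)
    if normalize:
        k = k / k.sum()
    return k


def _round_half_away(v: np.ndarray) -> np.ndarray:
    """Round half away from zero (VIA exports fractional coordinates)."""
    return np.sign(v) * np.floor(np.abs(v) + 0.5)


def build_density_map(
    annotations: np.ndarray,
    shape: tuple[int, int],
    d: float = DEFAULT_D,
    sigma: float = DEFAULT_SIGMA,
    side: int | None = None,
    normalize: bool = True,
) -> DensityMap:
    """Build the target density map for a tile.

    Equivalent to convolving the point-mass image (value ``d`` at each
    rounded annotation pixel, masses adding on collision) with the
    Gaussian kernel under zero padding; implemented by additive kernel
    stamping, which is exact for that boundary rule.

    Parameters
    ----------
    annotations : (n, 2) array of (x, y) centers; fractional values are
        rounded half-away-from-zero to the pixel grid.
    shape : (H, W) of the output map.
    """
    h, w = shape
    if side is None:
        side = default_side(sigma)
    kernel = gaussian_kernel(sigma, side, normalize=normalize)
    values = np.zeros((h, w), dtype=float)
    ann = np.asarray(annotations, dtype=float).reshape(-1, 2)
    half = side // 2
    for k, (x, y) in enumerate(ann):
        col = int(_round_half_away(np.array(x)))
        row = int(_round_half_away(np.array(y)))
        if not (0 <= col <= w - 1 and 0 <= row <= h - 1):
            raise ValueError(
                f"annotation {k} at (x={x}, y={y}) lies outside the {h}x{w} image"
            )
        r0, r1 = row - half, row + half + 1
        c0, c1 = col - half, col + half + 1
        kr0, kc0 = max(0, -r0), max(0, -c0)
        kr1 = side - max(0, r1 - h)
        kc1 = side - max(0, c1 - w)
        values[max(r0, 0) : min(r1, h), max(c0, 0) : min(c1, w)] += (
            d * kernel[kr0:kr1, kc0:kc1]
        )
    return DensityMap(values=values, d=d, sigma=sigma, side=side)
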