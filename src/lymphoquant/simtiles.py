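"""Synthetic IHC-like tile and cohort generation with known ground truth.

Tiles mimic DAB-stained (brown) lymphocytes on a textured tissue
background.  Every rendered blob is centred on a recorded annotation, so
the simulator doubles as an exact oracle for the detection pipeline.

Coordinate convention (used package-wide): ``x`` is the column index,
``y`` is the row index, both 0-based — matching VIA point exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TileMorphology",
    "AnnotatedTile",
    "CohortManifest",
    "generate_tile",
    "generate_cohort",
    "default_count_sampler",
    "tile_seed",
]

# DAB chromogen, roughly; background is pale eosin-like tissue.
_CELL_RGB = np.array([105.0, 65.0, 35.0])
_BG_RGB = np.array([222.0, 205.0, 212.0])


@dataclass(frozen=True)
class TileMorphology:
    """Rendering parameters for synthetic lymphocytes.

    ``radius_mean`` defaults to 4 px: a ~4 µm diameter cell imaged at
    0.5 µm/pixel spans 8 px, i.e. radius 4 px.
    """

    radius_mean: float = 4.0
    radius_sd: float = 0.8
    eccentricity_max: float = 0.35
    cluster_fraction: float = 0.3
    cluster_spread: float = 12.0
    background_amplitude: float = 12.0
    stroma_streaks: int = 2
    min_separation: float = 3.0
    noise_sd: float = 2.0


@dataclass(frozen=True)
class AnnotatedTile:
    """An RGB tile plus its ground-truth lymphocyte centers."""

    image: np.ndarray  # H x W x 3 uint8
    annotations: np.ndarray  # n x 2 float, columns (x, y)
    slide_id: str
    tile_id: str = ""
    resolution: float = 0.5  # micrometers per pixel

    def __post_init__(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be H x W x 3")
        if not self.slide_id:
            raise ValueError("slide_id must be non-empty")
        ann = np.asarray(self.annotations, dtype=float).reshape(-1, 2)
        h, w = self.image.shape[:2]
        if ann.size and (
            (ann[:, 0] < 0).any()
            or (ann[:, 0] > w - 1).any()
            or (ann[:, 1] < 0).any()
            or (ann[:, 1] > h - 1).any()
        ):
            raise ValueError("annotation outside image bounds")
        object.__setattr__(self, "annotations", ann)

    @property
    def n_cells(self) -> int:
        return int(self.annotations.shape[0])


@dataclass
class CohortManifest:
    """Tile records plus leakage-safe split/fold assignment.

    One row per tile: id, slide, split ("train"/"test"), fold index
    (-1 for test tiles), planted cell count, and the per-tile seed so the
    tile can be re-rendered on demand.
    """

    tile_ids: list[str]
    slide_ids: list[str]
    splits: list[str]
    folds: list[int]
    n_cells: list[int]
    seeds: list[int]
    width: int
    height: int
    morphology: TileMorphology = field(default_factory=TileMorphology)

    def __len__(self) -> int:
        return len(self.tile_ids)

    def train_slides(self) -> set[str]:
        return {s for s, sp in zip(self.slide_ids, self.splits) if sp == "train"}

    def test_slides(self) -> set[str]:
        return {s for s, sp in zip(self.slide_ids, self.splits) if sp == "test"}

    def render_tile(self, index: int) -> AnnotatedTile:
        tile = generate_tile(
            self.width,
            self.height,
            self.n_cells[index],
            seed=self.seeds[index],
            morphology=self.morphology,
            slide_id=self.slide_ids[index],
        )
        return AnnotatedTile(
            image=tile.image,
            annotations=tile.annotations,
            slide_id=self.slide_ids[index],
            tile_id=self.tile_ids[index],
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "tile_id": self.tile_ids,
                "slide_id": self.slide_ids,
                "split": self.splits,
                "fold": self.folds,
                "n_cells": self.n_cells,
                "seed": self.seeds,
            }
        )


def tile_seed(master_seed: int, index: int) -> int:
    """Per-tile seed: master seed expanded by tile counter.

    Uses ``numpy.random.SeedSequence(master, spawn_key=(index,))`` so
    cohorts are reproducible tile-by-tile regardless of generation order.
    """
    return int(np.random.SeedSequence(master_seed, spawn_key=(index,)).generate_state(1)[0])


def _background(rng: np.random.Generator, h: int, w: int, m: TileMorphology) -> np.ndarray:
    """Low-frequency noise field plus optional darker stroma streaks."""
    coarse = rng.normal(0.0, 1.0, size=(max(h // 32, 2), max(w // 32, 2)))
    # bilinear upsample of the coarse field: cheap low-frequency texture
    yi = np.linspace(0, coarse.shape[0] - 1, h)
    xi = np.linspace(0, coarse.shape[1] - 1, w)
    y0 = np.floor(yi).astype(int)
    x0 = np.floor(xi).astype(int)
    y1 = np.minimum(y0 + 1, coarse.shape[0] - 1)
    x1 = np.minimum(x0 + 1, coarse.shape[1] - 1)
    fy = (yi - y0)[:, None]
    fx = (xi - x0)[None, :]
    field = (
        coarse[np.ix_(y0, x0)] * (1 - fy) * (1 - fx)
        + coarse[np.ix_(y1, x0)] * fy * (1 - fx)
        + coarse[np.ix_(y0, x1)] * (1 - fy) * fx
        + coarse[np.ix_(y1, x1)] * fy * fx
    )
    img = _BG_RGB[None, None, :] + m.background_amplitude * field[:, :, None]
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(m.stroma_streaks):
        theta = rng.uniform(0, np.pi)
        offset = rng.uniform(0, np.hypot(h, w))
        width = rng.uniform(6.0, 20.0)
        dist = np.abs(np.cos(theta) * xx + np.sin(theta) * yy - offset)
        img -= (18.0 * np.exp(-0.5 * (dist / width) ** 2))[:, :, None]
    img += rng.normal(0.0, m.noise_sd, size=(h, w, 3))
    return img


def _sample_centers(
    rng: np.random.Generator, h: int, w: int, n: int, m: TileMorphology
) -> np.ndarray:
    """Rejection-sample centers with a minimum pairwise separation.

    A ``cluster_fraction`` share of cells is packed around cluster seeds
    to emulate dense T-cell aggregates.
    """
    margin = m.radius_mean
    centers: list[np.ndarray] = []
    n_cluster = int(round(n * m.cluster_fraction))
    n_seeds = max(1, n_cluster // 6) if n_cluster else 0
    seeds = rng.uniform([margin, margin], [w - 1 - margin, h - 1 - margin], size=(n_seeds, 2)) if n_seeds else np.empty((0, 2))
    attempts = 0
    max_attempts = 200 * max(n, 1) + 1000
    while len(centers) < n:
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n} cells with min_separation={m.min_separation}"
            )
        attempts += 1
        if len(centers) < n_cluster and n_seeds:
            s = seeds[rng.integers(n_seeds)]
            c = s + rng.normal(0.0, m.cluster_spread, size=2)
        else:
            c = rng.uniform([margin, margin], [w - 1 - margin, h - 1 - margin])
        c = np.clip(c, [0.0, 0.0], [w - 1.0, h - 1.0])
        ok = True
        for prev in centers:
            if np.hypot(*(c - prev)) < m.min_separation:
                ok = False
                break
        if ok:
            centers.append(c)
    return np.array(centers).reshape(-1, 2)


def _render_cells(
    img: np.ndarray, centers: np.ndarray, rng: np.random.Generator, m: TileMorphology
) -> None:
    h, w = img.shape[:2]
    for cx, cy in centers:
        r = max(1.5, rng.normal(m.radius_mean, m.radius_sd))
        ecc = rng.uniform(0.0, m.eccentricity_max)
        theta = rng.uniform(0.0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        rx, ry = r * (1 + ecc), r * (1 - ecc)
        ext = int(np.ceil(3 * max(rx, ry)))
        x0, x1 = max(0, int(cx) - ext), min(w, int(cx) + ext + 1)
        y0, y1 = max(0, int(cy) - ext), min(h, int(cy) + ext + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dx, dy = xx - cx, yy - cy
        u = ct * dx + st * dy
        v = -st * dx + ct * dy
        # Gaussian radial profile -> soft, slightly irregular blob
        alpha = np.exp(-0.5 * ((u / (0.6 * rx)) ** 2 + (v / (0.6 * ry)) ** 2))
        alpha = np.clip(alpha * rng.uniform(0.85, 1.0), 0.0, 1.0)
        patch = img[y0:y1, x0:x1]
        patch *= (1 - alpha)[:, :, None]
        patch += alpha[:, :, None] * _CELL_RGB[None, None, :]


def generate_tile(
    width: int,
    height: int,
    n_cells: int,
    seed: int,
    morphology: TileMorphology | None = None,
    slide_id: str = "sim",
    **morph_overrides,
) -> AnnotatedTile:
    """Render one annotated tile.

    Identical ``(width, height, n_cells, seed, morphology)`` give
    byte-identical output.  Keyword overrides (e.g. ``min_separation=16``)
    patch individual morphology fields.
    """
    if width < 64 or height < 64:
        raise ValueError("width and height must be >= 64")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    m = morphology or TileMorphology()
    if morph_overrides:
        from dataclasses import replace

        m = replace(m, **morph_overrides)
    rng = np.random.default_rng(seed)
    img = _background(rng, height, width, m)
    centers = _sample_centers(rng, height, width, n_cells, m)
    _render_cells(img, centers, rng, m)
    image = np.clip(img, 0, 255).astype(np.uint8)
    return AnnotatedTile(image=image, annotations=centers, slide_id=slide_id)


def default_count_sampler(rng: np.random.Generator, n_tiles: int) -> np.ndarray:
    """Per-slide count sampler spanning all seven ordinal count classes.

    Each slide draws a log-uniform mean density; tile counts are Poisson
    around it with occasional empty tiles, so a few-hundred-tile cohort
    hits class 0 (count 0) through class 6 (count > 200).
    """
    lam = np.exp(rng.uniform(np.log(0.2), np.log(350.0)))
    counts = rng.poisson(lam, size=n_tiles)
    empty = rng.random(n_tiles) < 0.08
    counts[empty] = 0
    return counts.astype(int)


def generate_cohort(
    n_slides: int,
    tiles_per_slide: int,
    count_distribution: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int = 0,
    width: int = 512,
    height: int = 512,
    test_fraction: float = 0.25,
    n_folds: int | None = None,
    morphology: TileMorphology | None = None,
    max_cells: int | None = None,
) -> CohortManifest:
    """Generate a multi-slide cohort manifest with a grouped split.

    The train/test split (default ratio 3/4–1/4) and any CV folds are
    assigned at the slide level, never at the tile level, so tiles from
    one slide cannot leak across subsets.
    """
    if n_slides < 2:
        raise ValueError("n_slides must be >= 2 for a grouped split")
    if tiles_per_slide < 1:
        raise ValueError("tiles_per_slide must be >= 1")
    sampler = count_distribution or default_count_sampler
    rng = np.random.default_rng(seed)

    slide_names = [f"slide_{i:03d}" for i in range(n_slides)]
    order = rng.permutation(n_slides)
    n_test = max(1, int(round(n_slides * test_fraction)))
    if n_test >= n_slides:
        n_test = n_slides - 1
    test_set = {slide_names[i] for i in order[:n_test]}
    train_list = [slide_names[i] for i in order[n_test:]]

    folds_of: dict[str, int] = {}
    if n_folds is not None:
        if n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if len(train_list) < n_folds:
            raise ValueError(
                f"cannot form {n_folds} slide-grouped folds from "
                f"{len(train_list)} training slides"
            )
        for i, s in enumerate(train_list):
            folds_of[s] = i % n_folds

    tile_ids, slide_col, splits, folds, n_cells, seeds = [], [], [], [], [], []
    idx = 0
    for s in slide_names:
        counts = np.asarray(sampler(rng, tiles_per_slide), dtype=int)
        if max_cells is not None:
            counts = np.minimum(counts, max_cells)
        if counts.shape != (tiles_per_slide,) or (counts < 0).any():
            raise ValueError("count sampler must return nonnegative counts per tile")
        for t in range(tiles_per_slide):
            tile_ids.append(f"{s}_t{t:04d}")
            slide_col.append(s)
            if s in test_set:
                splits.append("test")
                folds.append(-1)
            else:
                splits.append("train")
                folds.append(folds_of.get(s, -1))
            n_cells.append(int(counts[t]))
            seeds.append(tile_seed(seed, idx))
            idx += 1

    return CohortManifest(
        tile_ids=tile_ids,
        slide_ids=slide_col,
        splits=splits,
        folds=folds,
        n_cells=n_cells,
        seeds=seeds,
        width=width,
        height=height,
        morphology=morphology or TileMorphology(),
    )
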