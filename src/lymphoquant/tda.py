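"""Topological introspection: Vietoris-Rips persistence, Betti curves,
TwoNN intrinsic dimension, and embedding-based clustering of deep
features.

Persistence is computed from scratch: H0 by union-find over edges sorted
by length (finite deaths are exactly the Euclidean minimum-spanning-tree
edge lengths), H1 by boundary-matrix reduction over Z/2 on the filtered
1- and 2-skeleton.  An edge enters the filtration at its length
(diameter convention), a triangle at the length of its longest edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PersistenceDiagram",
    "BettiCurve",
    "IDEstimate",
    "ClusterResult",
    "vr_persistence",
    "betti_curve",
    "default_grid",
    "twonn_id",
    "id_profile",
    "embed_and_cluster",
]


@dataclass(frozen=True)
class PersistenceDiagram:
    """Multiset of (birth, death, dimension) features; death may be inf."""

    births: np.ndarray
    deaths: np.ndarray
    dims: np.ndarray

    def features(self, dim: int) -> np.ndarray:
        sel = self.dims == dim
        return np.column_stack([self.births[sel], self.deaths[sel]])

    def finite_deaths(self, dim: int) -> np.ndarray:
        f = self.features(dim)
        return np.sort(f[np.isfinite(f[:, 1]), 1])

    def __len__(self) -> int:
        return len(self.births)


@dataclass(frozen=True)
class BettiCurve:
    scales: np.ndarray
    values: dict[int, np.ndarray]  # dimension -> counts per scale

    def at(self, dim: int, scale: float) -> int:
        """Curve value at an arbitrary scale (piecewise-constant lookup)."""
        idx = np.searchsorted(self.scales, scale, side="right") - 1
        if idx < 0:
            raise ValueError(f"scale {scale} below the grid start")
        exact = np.isclose(self.scales, scale)
        if exact.any():
            idx = int(np.argmax(exact))
        return int(self.values[dim][idx])


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[rj] = ri
        return True


def vr_persistence(
    points: np.ndarray, max_dimension: int = 1, max_scale: float | None = None
) -> PersistenceDiagram:
    """Vietoris-Rips persistence of a Euclidean point cloud (H0 and H1).

    With the default ``max_scale`` (the cloud diameter) every H1 class
    dies within the filtration and the diagram contains exactly one
    infinite H0 feature.  Zero-persistence pairs (death == birth) are
    dropped.  The diagram is independent of the input point order.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 1:
        raise ValueError("need an (n, d) array with n >= 1")
    n = len(pts)
    if max_scale is not None and max_scale <= 0:
        raise ValueError("max_scale must be positive")
    births, deaths, dims = [], [], []
    if n == 1:
        return PersistenceDiagram(
            births=np.zeros(1), deaths=np.array([np.inf]), dims=np.zeros(1, dtype=int)
        )
    dm = squareform(pdist(pts))
    if max_scale is None:
        max_scale = float(dm.max())

    # --- H0: union-find over edges sorted by length -----------------------
    edges = [(dm[i, j], i, j) for i, j in combinations(range(n), 2) if dm[i, j] <= max_scale]
    edges.sort()
    uf = _UnionFind(n)
    positive_edges: list[int] = []  # indices into `edges` that create cycles
    for rank, (length, i, j) in enumerate(edges):
        if uf.union(i, j):
            if length > 0:
                births.append(0.0)
                deaths.append(length)
                dims.append(0)
        else:
            positive_edges.append(rank)
    n_roots = len({uf.find(i) for i in range(n)})
    births.extend([0.0] * n_roots)
    deaths.extend([np.inf] * n_roots)
    dims.extend([0] * n_roots)

    # --- H1: Z/2 reduction of triangle columns over edge rows -------------
    if max_dimension >= 1 and n >= 3:
        edge_length = {rank: e[0] for rank, e in enumerate(edges)}
        edge_rank = {(e[1], e[2]): rank for rank, e in enumerate(edges)}
        positive = set(positive_edges)
        triangles = []
        for a, b, c in combinations(range(n), 3):
            diam = max(dm[a, b], dm[a, c], dm[b, c])
            if diam <= max_scale:
                triangles.append((diam, a, b, c))
        triangles.sort()
        paired: dict[int, set[int]] = {}
        for diam, a, b, c in triangles:
            col = {edge_rank[(a, b)], edge_rank[(a, c)], edge_rank[(b, c)]}
            while col:
                low = max(col)
                if low in paired:
                    col ^= paired[low]
                else:
                    break
            if not col:
                continue  # positive triangle (would create H2)
            low = max(col)
            paired[low] = col
            birth = edge_length[low]
            if diam > birth:
                births.append(birth)
                deaths.append(diam)
                dims.append(1)
            positive.discard(low)
        for rank in sorted(positive):
            births.append(edge_length[rank])  # survives past max_scale
            deaths.append(np.inf)
            dims.append(1)

    order = np.lexsort((np.asarray(deaths), np.asarray(births), np.asarray(dims)))
    return PersistenceDiagram(
        births=np.asarray(births, dtype=float)[order],
        deaths=np.asarray(deaths, dtype=float)[order],
        dims=np.asarray(dims, dtype=int)[order],
    )


def default_grid(pd_: PersistenceDiagram, n_points: int = 100) -> np.ndarray:
    """100 uniform scales on [0, 1.1 * max finite death]."""
    finite = pd_.deaths[np.isfinite(pd_.deaths)]
    top = 1.1 * float(finite.max()) if finite.size else 1.0
    return np.linspace(0.0, top, n_points)


def betti_curve(
    pd_: PersistenceDiagram, grid: np.ndarray | None = None, tol: float = 1e-9
) -> BettiCurve:
    """Number of features alive (birth <= r < death) at each grid scale.

    Membership uses a relative tolerance so that a feature whose birth or
    death differs from a grid scale only by floating-point rounding is
    classified as if the values coincided (born at r: alive; dying at r:
    dead).  Infinite features count at every scale >= their birth.
    """
    if grid is None:
        grid = default_grid(pd_)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty scale grid")
    if (np.diff(grid) <= 0).any():
        raise ValueError("scale grid must be strictly increasing")
    values: dict[int, np.ndarray] = {}
    for dim in (0, 1):
        sel = pd_.dims == dim
        b = pd_.births[sel][None, :]
        d = pd_.deaths[sel][None, :]
        r = grid[:, None]
        eps = tol * np.maximum(1.0, np.abs(r))
        values[dim] = ((b <= r + eps) & (d > r + eps)).sum(axis=1).astype(int)
    return BettiCurve(scales=grid, values=values)


@dataclass(frozen=True)
class IDEstimate:
    """TwoNN intrinsic-dimension estimate."""

    d_hat: float
    mu: np.ndarray  # all second/first neighbor distance ratios
    n_retained: int
    discard_fraction: float
    n_points: int
    method: str


def twonn_id(
    points: np.ndarray,
    discard_fraction: float = 0.1,
    method: str = "linfit",
) -> IDEstimate:
    """TwoNN intrinsic dimension from two-nearest-neighbor ratios.

    For each point, mu_i = d_2 / d_1 (second to first neighbor distance);
    under uniform sampling on a d-manifold, mu follows a Pareto law
    p(mu; d) = d * mu^-(d+1).  The largest ``discard_fraction`` of the
    ratios is dropped, then:

    - ``linfit`` (default): least-squares fit through the origin of
      -log(1 - F_emp(mu)) against log(mu), using full-sample empirical
      CDF positions (this correctly accounts for the truncation);
    - ``mle``: closed-form Pareto maximum likelihood over the retained
      ratios, d_hat = m / sum(log mu_i).

    Exact duplicate points are removed with a warning.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2:
        raise ValueError("points must be an (n, d) array")
    uniq = np.unique(x, axis=0)
    if len(uniq) < len(x):
        warnings.warn(
            f"removed {len(x) - len(uniq)} duplicate points before TwoNN",
            stacklevel=2,
        )
        x = uniq
    if len(x) < 10:
        raise ValueError("need at least 10 distinct points")
    if not 0 <= discard_fraction < 1:
        raise ValueError("discard_fraction must be in [0, 1)")

    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=3).fit(x)
    dist, _ = nn.kneighbors(x)
    d1, d2 = dist[:, 1], dist[:, 2]
    if (d1 == 0).any():
        raise ValueError("zero first-neighbor distance after deduplication")
    mu = np.sort(d2 / d1)
    n = len(mu)
    m = int(np.floor(n * (1.0 - discard_fraction)))
    m = max(m, 2)
    retained = mu[:m]
    log_mu = np.log(retained)
    if method == "mle":
        s = log_mu.sum()
        if s <= 0:
            raise ValueError("all retained ratios equal 1; dimension unbounded")
        d_hat = m / s
    elif method == "linfit":
        f = np.arange(1, m + 1) / n  # full-sample CDF positions
        y = -np.log(1.0 - f)
        denom = (log_mu**2).sum()
        if denom <= 0:
            raise ValueError("all retained ratios equal 1; dimension unbounded")
        d_hat = float((log_mu * y).sum() / denom)
    else:
        raise ValueError(f"unknown method {method!r}; use 'linfit' or 'mle'")
    return IDEstimate(
        d_hat=float(d_hat),
        mu=mu,
        n_retained=m,
        discard_fraction=discard_fraction,
        n_points=n,
        method=method,
    )


def id_profile(model, tiles, checkpoints: dict[int, dict], blocks=None, **twonn_kwargs):
    """Intrinsic dimension of each inner block's features per checkpoint.

    ``checkpoints`` maps epoch -> model state dict (as produced by the
    trainer).  Returns a DataFrame with columns epoch, block, d_hat, n.
    """
    import pandas as pd

    from .nn.network import INNER_BLOCKS, extract_features

    blocks = list(blocks or INNER_BLOCKS)
    rows = []
    for epoch in sorted(checkpoints):
        state = checkpoints[epoch]
        if state is None:
            raise ValueError(f"missing checkpoint for epoch {epoch}")
        for block in blocks:
            feats = extract_features(model, tiles, block, state=state)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = twonn_id(feats, **twonn_kwargs)
            rows.append(
                {"epoch": epoch, "block": block, "d_hat": est.d_hat, "n": est.n_points}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray  # -1 marks noise
    coords2d: np.ndarray  # display-only 2-D projection
    embedding: np.ndarray  # the b-dimensional projection fed to clustering

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels >= 0])))


def embed_and_cluster(
    cloud: np.ndarray,
    metric: str = "cosine",
    embed_dim: int = 4,
    n_neighbors: int = 25,
    min_dist: float = 0.0,
    min_cluster_size: int = 5,
    min_samples: int = 16,
    seed: int = 0,
) -> ClusterResult:
    """UMAP projection to ``embed_dim`` dims + HDBSCAN density clustering.

    A separate 2-D UMAP projection is produced for display only.  The
    metric applies in the original feature space; hyperparameter defaults
    follow the reference configuration (b=4, 25 neighbors, min_dist 0,
    min cluster size 5, min samples 16).
    """
    x = np.asarray(cloud, dtype=float)
    if x.ndim != 2:
        raise ValueError("cloud must be an (n, D) matrix")
    if metric not in {"l1", "l2", "cosine", "manhattan", "euclidean"}:
        raise ValueError(f"unsupported metric {metric!r}")
    umap_metric = {"l1": "manhattan", "l2": "euclidean"}.get(metric, metric)
    if len(x) < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors + 1 = {n_neighbors + 1} points, have {len(x)}"
        )
    import umap
    from sklearn.cluster import HDBSCAN

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = umap.UMAP(
            n_components=embed_dim,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            metric=umap_metric,
            random_state=seed,
        ).fit_transform(x)
        view = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            metric=umap_metric,
            random_state=seed + 1,
        ).fit_transform(x)
    labels = HDBSCAN(
        min_cluster_size=min_cluster_size, min_samples=min_samples, copy=True
    ).fit_predict(emb)
    return ClusterResult(labels=labels, coords2d=np.asarray(view), embedding=np.asarray(emb))
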