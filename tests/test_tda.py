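from itertools import combinations

import numpy as np
import pytest
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from lymphoquant.tda import (
    betti_curve,
    default_grid,
    embed_and_cluster,
    id_profile,
    twonn_id,
    vr_persistence,
)


def brute_vr_diagram(points, max_scale=None):
    """Independent oracle: enumerate every simplex up to dimension 2 and
    reduce the full boundary matrix over Z/2."""
    pts = np.asarray(points, float)
    n = len(pts)
    dm = squareform(pdist(pts))
    if max_scale is None:
        max_scale = dm.max()
    simplices = [((i,), 0.0) for i in range(n)]
    for i, j in combinations(range(n), 2):
        if dm[i, j] <= max_scale:
            simplices.append(((i, j), dm[i, j]))
    for tri in combinations(range(n), 3):
        diam = max(dm[a, b] for a, b in combinations(tri, 2))
        if diam <= max_scale:
            simplices.append((tri, diam))
    simplices.sort(key=lambda s: (s[1], len(s[0]), s[0]))
    index = {s[0]: k for k, s in enumerate(simplices)}
    columns = []
    for verts, _ in simplices:
        if len(verts) == 1:
            columns.append(set())
        else:
            columns.append({index[f] for f in combinations(verts, len(verts) - 1)})
    low_of = {}
    pairs = []
    for j, col in enumerate(columns):
        while col and max(col) in low_of:
            col ^= columns[low_of[max(col)]]
        columns[j] = col
        if col:
            low_of[max(col)] = j
            pairs.append((max(col), j))
    paired = {k for pair in pairs for k in pair}
    births, deaths, dims = [], [], []
    for i, j in pairs:
        b, d = simplices[i][1], simplices[j][1]
        if d > b:
            births.append(b)
            deaths.append(d)
            dims.append(len(simplices[i][0]) - 1)
    for k, (verts, val) in enumerate(simplices):
        if k not in paired and len(verts) <= 2:
            births.append(val)
            deaths.append(np.inf)
            dims.append(len(verts) - 1)
    return (
        np.asarray(births, float),
        np.asarray(deaths, float),
        np.asarray(dims, int),
    )


def _sorted_features(births, deaths, dims, dim):
    sel = dims == dim
    arr = np.column_stack([births[sel], deaths[sel]])
    return arr[np.lexsort((arr[:, 1], arr[:, 0]))]


class TestVRPersistence:
    def test_hexagon_h0(self, hexagon):
        pd_ = vr_persistence(hexagon, max_dimension=1)
        finite = pd_.finite_deaths(0)
        assert len(finite) == 5
        assert np.allclose(finite, 1.0)
        h0 = pd_.features(0)
        assert np.isinf(h0[:, 1]).sum() == 1
        assert len(h0) == 6  # one H0 feature per input point
        assert (h0[:, 0] == 0).all()

    def test_hexagon_h1_birth_and_death(self, hexagon):
        pd_ = vr_persistence(hexagon, max_dimension=1)
        h1 = pd_.features(1)
        assert h1.shape == (1, 2)
        assert h1[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert h1[0, 1] == pytest.approx(np.sqrt(3.0), abs=1e-12)

    def test_two_points(self):
        pd_ = vr_persistence(np.array([[0.0, 0.0], [5.0, 0.0]]))
        h0 = pd_.features(0)
        deaths = np.sort(h0[:, 1])
        assert deaths[0] == 5.0 and np.isinf(deaths[1])
        assert len(pd_.features(1)) == 0

    def test_single_point(self):
        pd_ = vr_persistence(np.array([[1.0, 2.0]]))
        assert len(pd_) == 1
        assert np.isinf(pd_.deaths[0])

    def test_h0_equals_mst_edge_lengths(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 50))
            pts = rng.uniform(0, 10, size=(n, rng.integers(2, 4)))
            pd_ = vr_persistence(pts, max_dimension=0)
            mst = minimum_spanning_tree(squareform(pdist(pts))).toarray()
            mst_lengths = np.sort(mst[mst > 0])
            assert np.allclose(pd_.finite_deaths(0), mst_lengths, atol=1e-12)

    def test_full_reduction_oracle_small_clouds(self, rng):
        for _ in range(15):
            n = int(rng.integers(3, 9))
            pts = rng.uniform(0, 5, size=(n, 2))
            pd_ = vr_persistence(pts, max_dimension=1)
            ob, od, odim = brute_vr_diagram(pts)
            for dim in (0, 1):
                ours = _sorted_features(pd_.births, pd_.deaths, pd_.dims, dim)
                ref = _sorted_features(ob, od, odim, dim)
                assert ours.shape == ref.shape, f"dim {dim}"
                finite = np.isfinite(ref)
                assert np.allclose(ours[finite], ref[finite], atol=1e-10)
                assert (np.isinf(ours) == np.isinf(ref)).all()

    def test_permutation_invariance(self, rng):
        pts = rng.uniform(0, 3, size=(12, 2))
        a = vr_persistence(pts, max_dimension=1)
        perm = rng.permutation(12)
        b = vr_persistence(pts[perm], max_dimension=1)
        for dim in (0, 1):
            fa = _sorted_features(a.births, a.deaths, a.dims, dim)
            fb = _sorted_features(b.births, b.deaths, b.dims, dim)
            finite = np.isfinite(fa)
            assert fa.shape == fb.shape
            assert np.allclose(fa[finite], fb[finite], atol=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            vr_persistence(np.empty((0, 2)))
        with pytest.raises(ValueError):
            vr_persistence(np.array([[0.0, 0.0], [1.0, 0.0]]), max_scale=-1.0)


class TestBettiCurve:
    def test_hexagon_h0_values(self, hexagon):
        pd_ = vr_persistence(hexagon, max_dimension=1)
        curve = betti_curve(pd_, np.linspace(0, 2, 401))
        assert curve.at(0, 0.5) == 6
        assert curve.at(0, 1.0) == 1

    def test_hexagon_h1_values(self, hexagon):
        pd_ = vr_persistence(hexagon, max_dimension=1)
        curve = betti_curve(pd_, np.linspace(0, 2, 401))
        assert curve.at(1, 1.0) == 1
        assert curve.at(1, 1.5) == 1
        assert curve.at(1, 2.0) == 0
        # on a grid containing sqrt(3) exactly: the loop is dead at its death scale
        exact = betti_curve(pd_, np.array([1.0, 1.5, np.sqrt(3.0), 2.0]))
        assert list(exact.values[1]) == [1, 1, 0, 0]

    def test_empty_diagram_zero_curve(self):
        from lymphoquant.tda import PersistenceDiagram

        pd_ = PersistenceDiagram(np.empty(0), np.empty(0), np.empty(0, int))
        curve = betti_curve(pd_, np.linspace(0, 1, 11))
        assert (curve.values[0] == 0).all()
        assert (curve.values[1] == 0).all()

    def test_grid_validation(self, hexagon):
        pd_ = vr_persistence(hexagon, max_dimension=0)
        with pytest.raises(ValueError):
            betti_curve(pd_, np.array([]))
        with pytest.raises(ValueError):
            betti_curve(pd_, np.array([1.0, 0.5]))

    def test_jump_consistency_with_diagram(self, rng):
        # every H0 decrement on a fine grid corresponds to a death
        pts = rng.uniform(0, 4, size=(15, 2))
        pd_ = vr_persistence(pts, max_dimension=0)
        grid = default_grid(pd_, 2000)
        curve = betti_curve(pd_, grid)
        drops = -np.diff(curve.values[0]).sum()
        assert drops == len(pd_.finite_deaths(0))

    def test_default_grid_span(self, hexagon):
        pd_ = vr_persistence(hexagon, max_dimension=1)
        grid = default_grid(pd_)
        assert len(grid) == 100
        assert grid[0] == 0.0
        assert grid[-1] == pytest.approx(1.1 * np.sqrt(3.0))


class TestTwoNN:
    def test_uniform_square_recovery(self):
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            est = twonn_id(rng.uniform(size=(2000, 2)))
            assert 1.8 <= est.d_hat <= 2.2, f"seed {seed}: {est.d_hat}"

    def test_line_recovery(self):
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 10, 500)
            pts = np.column_stack([x, rng.normal(0, 5e-4, 500)])
            est = twonn_id(pts)
            assert 0.8 <= est.d_hat <= 1.3, f"seed {seed}: {est.d_hat}"

    def test_mle_closed_form_equals_grid_search(self, rng):
        for _ in range(5):
            pts = rng.uniform(size=(400, int(rng.integers(1, 4))))
            est = twonn_id(pts, method="mle")
            mu = est.mu[: est.n_retained]
            grid = np.geomspace(0.01, 50.0, 40000)
            ll = len(mu) * np.log(grid) - (grid + 1) * np.log(mu).sum()
            d_grid = grid[np.argmax(ll)]
            assert est.d_hat == pytest.approx(d_grid, abs=1e-2)

    def test_ratios_at_least_one(self, rng):
        est = twonn_id(rng.normal(size=(200, 3)))
        assert (est.mu >= 1.0).all()
        assert est.d_hat > 0

    def test_duplicates_removed_with_warning(self, rng):
        pts = rng.uniform(size=(50, 2))
        doubled = np.vstack([pts, pts])
        with pytest.warns(UserWarning, match="duplicate"):
            est = twonn_id(doubled)
        assert est.n_points == 50

    def test_too_few_points(self, rng):
        with pytest.raises(ValueError):
            twonn_id(rng.uniform(size=(5, 2)))

    def test_all_identical_rejected(self):
        with pytest.warns(UserWarning, match="duplicate"), pytest.raises(ValueError):
            twonn_id(np.ones((30, 2)))

    def test_discard_fraction_validation(self, rng):
        with pytest.raises(ValueError):
            twonn_id(rng.uniform(size=(50, 2)), discard_fraction=1.0)


class TestIDProfile:
    def test_smoke_on_tiny_model(self):
        from lymphoquant.nn import NetworkConfig, build_model
        from lymphoquant.simtiles import generate_tile

        model = build_model(NetworkConfig(encoder_preset="tiny", seed=0))
        tiles = [generate_tile(64, 64, 4, seed=300 + i).image for i in range(12)]
        checkpoints = {6: model.state_dict()}
        table = id_profile(model, tiles, checkpoints)
        assert len(table) == 6
        assert (table["d_hat"] > 0).all()
        assert np.isfinite(table["d_hat"]).all()
        assert set(table["epoch"]) == {6}

    def test_duplicate_tiles_exercise_dedup(self):
        from lymphoquant.nn import NetworkConfig, build_model
        from lymphoquant.simtiles import generate_tile

        model = build_model(NetworkConfig(encoder_preset="tiny", seed=0))
        base = [generate_tile(64, 64, 4, seed=400 + i).image for i in range(11)]
        tiles = base + [base[0]]  # one exact duplicate
        table = id_profile(model, tiles, {1: model.state_dict()}, blocks=["bottleneck"])
        assert len(table) == 1
        assert table["d_hat"].iloc[0] > 0

    def test_missing_checkpoint_named(self):
        from lymphoquant.nn import NetworkConfig, build_model

        model = build_model(NetworkConfig(encoder_preset="tiny", seed=0))
        with pytest.raises(ValueError, match="epoch 7"):
            id_profile(model, [], {7: None})


class TestEmbedAndCluster:
    def test_planted_two_blob_recovery(self, rng):
        a = rng.normal(0, 1, size=(200, 50))
        b = rng.normal(12, 1, size=(200, 50))
        cloud = np.vstack([a, b])
        res = embed_and_cluster(cloud, metric="l2", seed=0)
        assert res.n_clusters == 2
        truth = np.repeat([0, 1], 200)
        ok = 0
        for lab in (0, 1):
            members = truth[res.labels == lab]
            if len(members):
                ok += max((members == 0).sum(), (members == 1).sum())
        assert ok >= 0.95 * (res.labels >= 0).sum()
        assert res.coords2d.shape == (400, 2)
        assert res.embedding.shape == (400, 4)

    def test_single_blob_no_structure(self, rng):
        # at the reference min_cluster_size (5) an unstructured Gaussian can
        # fragment into micro-clusters; with a size-scaled minimum (20% of n)
        # the null case yields no clusters at all
        cloud = rng.normal(size=(200, 30))
        res = embed_and_cluster(cloud, metric="l2", seed=1, min_cluster_size=40)
        assert res.n_clusters <= 1
        # and at the reference defaults no cluster may dominate
        res_default = embed_and_cluster(cloud, metric="l2", seed=1)
        for lab in set(res_default.labels[res_default.labels >= 0]):
            assert (res_default.labels == lab).sum() < 0.25 * len(cloud)

    def test_cosine_scale_invariance(self, rng):
        # sparse nonnegative vectors differing only in scale co-cluster
        d1 = np.zeros(20)
        d1[:4] = [2.0, 1.0, 3.0, 0.5]
        d2 = np.zeros(20)
        d2[10:14] = [1.0, 4.0, 2.0, 1.5]
        rows = []
        truth = []
        for i in range(40):
            scale = rng.uniform(0.1, 10)
            base = d1 if i % 2 == 0 else d2
            rows.append(scale * base + rng.uniform(0, 1e-4, 20))
            truth.append(i % 2)
        cloud = np.asarray(rows)
        res = embed_and_cluster(cloud, metric="cosine", n_neighbors=10, seed=2)
        truth = np.asarray(truth)
        assert res.n_clusters == 2
        for lab in set(res.labels[res.labels >= 0]):
            members = truth[res.labels == lab]
            assert (members == members[0]).all()

    def test_too_few_points(self, rng):
        with pytest.raises(ValueError):
            embed_and_cluster(rng.normal(size=(10, 5)), n_neighbors=25)

    def test_bad_metric(self, rng):
        with pytest.raises(ValueError):
            embed_and_cluster(rng.normal(size=(100, 5)), metric="hamming")

    def test_seed_determinism(self, rng):
        cloud = rng.normal(size=(60, 10))
        a = embed_and_cluster(cloud, metric="l2", n_neighbors=10, seed=3)
        b = embed_and_cluster(cloud, metric="l2", n_neighbors=10, seed=3)
        assert np.array_equal(a.labels, b.labels)
        assert np.allclose(a.embedding, b.embedding)
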