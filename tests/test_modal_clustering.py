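import numpy as np
import pytest

from epp.errors import WidenSignal
from epp.kde import compute_weights, kde_dct
from epp.modal_clustering import (BOUNDARY, assign_events, build_cluster_graph,
                                  modal_cluster, noise_floor,
                                  resolve_face_grid)
from epp.synthetic import Component, MixtureSpec, generate
from oracles import gaussian_bump_density, naive_noise_floor


class TestNoiseFloor:
    def test_matches_naive_sliding_window_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            G = 33
            x, y = rng.random(300), rng.random(300)
            w = compute_weights(x, y, G)
            d = kde_dct(w, 0.05)
            assert noise_floor(d, w, 0.05) == naive_noise_floor(d, w, 0.05)

    def test_sigma_three_requires_over_nine_events(self):
        # mass spread over exactly one window of the lowest-density cells:
        # 9 events is not enough (strict inequality), 9 + epsilon is
        G, W = 33, 0.1
        L = int(round((4 * W * (G - 1)) ** 2))
        d = np.arange(G * G, dtype=float).reshape(G, G)
        for total in (9.0, 9.001):
            w = np.zeros(G * G)
            w[:L] = total / L
            floor = noise_floor(d, w.reshape(G, G), W=W, sigma=3.0)
            if total > 9.0:
                assert np.isfinite(floor)
            else:
                assert np.isinf(floor)

    def test_five_events_found_no_cluster(self):
        rng = np.random.default_rng(1)
        w = compute_weights(rng.random(5), rng.random(5))
        d = kde_dct(w, 0.01)
        assert np.isinf(noise_floor(d, w, 0.01))
        # and the caller's contract: nothing can be founded

    def test_dense_blob_threshold_below_bulk(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.5, 0.05, 100_000).clip(0, 1)
        y = rng.normal(0.5, 0.05, 100_000).clip(0, 1)
        w = compute_weights(x, y)
        d = kde_dct(w, 0.01)
        floor = noise_floor(d, w, 0.01)
        assert np.isfinite(floor)
        assert floor < d.max() / 10  # bulk of the blob is far above the floor
        lab = modal_cluster(d, floor)
        assert lab.n_clusters == 1


class TestModalCluster:
    def test_single_bump_one_cluster_no_boundary(self):
        d = gaussian_bump_density([(0.5, 0.5)], [0.1], [1.0])
        lab = modal_cluster(d, d.max() * 1e-6)
        assert lab.n_clusters == 1
        assert not (lab.labels == BOUNDARY).any()
        assert (lab.labels == 1).all()

    def test_monotone_ramp_one_cluster(self):
        xs = np.linspace(0, 1, 65)
        d = np.add.outer(xs, xs) + 0.1
        lab = modal_cluster(d, 0.0)
        assert lab.n_clusters == 1

    def test_two_bumps_boundary_at_valley(self):
        d = gaussian_bump_density([(0.3, 0.5), (0.7, 0.5)], [0.07, 0.07],
                                  [1.0, 1.0], grid_size=129)
        lab = modal_cluster(d, d.max() * 1e-6)
        assert lab.n_clusters == 2
        cols = np.argwhere(lab.labels == BOUNDARY)[:, 1]
        assert np.all(np.abs(cols - 64) <= 2)  # valley is the x=0.5 column

    def test_mode_locations_match_bump_centers(self):
        d = gaussian_bump_density([(0.3, 0.5), (0.7, 0.5)], [0.07, 0.07],
                                  [1.0, 0.9], grid_size=129)
        lab = modal_cluster(d, d.max() * 1e-6)
        pts = sorted(pt for pt, _ in lab.modes.values())
        assert pts[0] == (64, int(round(0.3 * 128)))
        assert pts[1] == (64, int(round(0.7 * 128)))

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(3)
        w = compute_weights(rng.random(2000), rng.random(2000), 129)
        d = kde_dct(w, 0.05)
        floor = noise_floor(d, w, 0.05)
        a = modal_cluster(d, floor, max_clusters=200)
        b = modal_cluster(d.copy(), floor, max_clusters=200)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.modes == b.modes

    def test_too_many_clusters_signals_widen(self):
        centers = [(x, y) for x in np.linspace(0.1, 0.9, 5)
                   for y in np.linspace(0.1, 0.9, 4)]
        d = gaussian_bump_density(centers, [0.02] * 20, [1.0] * 20,
                                  grid_size=129)
        with pytest.raises(WidenSignal):
            modal_cluster(d, d.max() * 1e-6, max_clusters=12)

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_recovers_k_well_separated_components(self, k):
        centers = [(0.2, 0.2), (0.8, 0.2), (0.2, 0.8), (0.8, 0.8)][:k]
        comps = tuple(Component(1 / k, c, (0.03, 0.03)) for c in centers)
        ev, _ = generate(MixtureSpec(2, comps, n=5000 * k, seed=k))
        x, y = ev.values[:, 0], ev.values[:, 1]
        w = compute_weights(x, y)
        d = kde_dct(w, 0.01)
        lab = modal_cluster(d, noise_floor(d, w, 0.01))
        assert lab.n_clusters == k


class TestBuildClusterGraph:
    def test_two_faces_one_edge(self):
        d = gaussian_bump_density([(0.3, 0.5), (0.7, 0.5)], [0.07, 0.07],
                                  [1.0, 1.0], grid_size=129)
        lab = modal_cluster(d, d.max() * 1e-6)
        g = build_cluster_graph(lab, d)
        assert g.n_faces == 2
        assert len(g.edges) == 1
        assert g.edges[0].faces == (1, 2)
        assert len(g.vertices) == 0
        # saddle sits in the valley column
        assert abs(g.edges[0].saddle_point[1] - 64) <= 2

    def test_triangle_three_edges_one_vertex(self):
        d = gaussian_bump_density([(0.3, 0.3), (0.7, 0.3), (0.5, 0.75)],
                                  [0.09, 0.09, 0.09], [1, 1, 1], grid_size=129)
        lab = modal_cluster(d, d.max() * 1e-6)
        g = build_cluster_graph(lab, d)
        assert g.n_faces == 3
        assert len(g.edges) == 3
        assert {e.faces for e in g.edges} == {(1, 2), (1, 3), (2, 3)}
        assert len(g.vertices) >= 1

    def test_chain_two_edges(self):
        d = gaussian_bump_density([(0.2, 0.5), (0.5, 0.5), (0.8, 0.5)],
                                  [0.06, 0.06, 0.06], [1, 1, 1], grid_size=129)
        lab = modal_cluster(d, d.max() * 1e-6)
        g = build_cluster_graph(lab, d)
        assert g.n_faces == 3
        assert len(g.edges) == 2
        # the middle component borders both outer ones; they never touch
        middle = next(c for c, (pt, _) in lab.modes.items()
                      if abs(pt[1] - 64) <= 2)
        assert all(middle in e.faces for e in g.edges)
        assert len({f for e in g.edges for f in e.faces}) == 3

    def test_face_count_equals_cluster_count(self):
        rng = np.random.default_rng(9)
        for seed in range(5):
            from oracles import random_cluster_graph
            res = random_cluster_graph(seed)
            if res is None:
                continue
            g, lab = res
            assert g.n_faces == lab.n_clusters


class TestAssignEvents:
    def test_partition_property(self):
        d = gaussian_bump_density([(0.3, 0.5), (0.7, 0.5)], [0.07, 0.07],
                                  [1.0, 1.0], grid_size=129)
        lab = modal_cluster(d, d.max() * 1e-6)
        grid = resolve_face_grid(lab.labels)
        rng = np.random.default_rng(4)
        ids = assign_events(rng.random(5000), rng.random(5000), grid)
        assert np.isin(ids, [1, 2]).all()

    def test_mode_location_gets_own_cluster(self):
        d = gaussian_bump_density([(0.3, 0.5), (0.7, 0.5)], [0.07, 0.07],
                                  [1.0, 1.0], grid_size=129)
        lab = modal_cluster(d, d.max() * 1e-6)
        grid = resolve_face_grid(lab.labels)
        for cid, (pt, _) in lab.modes.items():
            x = np.array([pt[1] / 128])
            y = np.array([pt[0] / 128])
            assert assign_events(x, y, grid)[0] == cid

    def test_two_bump_events_split_by_valley(self):
        ev, labels = generate(MixtureSpec(
            2, (Component(0.5, (0.3, 0.5), (0.03, 0.03)),
                Component(0.5, (0.7, 0.5), (0.03, 0.03))), n=10_000, seed=5))
        x, y = ev.values[:, 0], ev.values[:, 1]
        w = compute_weights(x, y)
        d = kde_dct(w, 0.01)
        lab = modal_cluster(d, noise_floor(d, w, 0.01))
        ids = assign_events(x, y, resolve_face_grid(lab.labels))
        # majority mapping component -> cluster, then mismatch rate
        mismatch = 0
        for comp in (0, 1):
            sel = labels == comp
            majority = np.bincount(ids[sel]).argmax()
            mismatch += int((ids[sel] != majority).sum())
        assert mismatch / len(ids) < 0.01
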