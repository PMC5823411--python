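import numpy as np
import pytest
from scipy.optimize import minimize

from conftest import block_label_map
from salseg.rbd import (
    background_probability,
    boundary_connectivity,
    compute_superpixels,
    foreground_probability,
    graph_from_labels,
    optimize_saliency,
    project_to_pixels,
    rbd_cost,
    smoothness_weights,
)

# Well-separated RGB anchors: adjacent-block Lab distances are large enough
# that cross-region affinities exp(-d^2 / 2*10^2) vanish below 1e-8.
FAR_COLORS = {
    "white": (1.0, 1.0, 1.0),
    "navy": (0.0, 0.0, 0.30),
    "red": (0.85, 0.05, 0.05),
    "green": (0.05, 0.60, 0.05),
}


def colored_block_image(label_map: np.ndarray, color_of: dict[int, tuple]) -> np.ndarray:
    img = np.zeros(label_map.shape + (3,))
    for label, color in color_of.items():
        img[label_map == label] = color
    return img


def floyd_warshall(k: int, edges: np.ndarray, dist: np.ndarray) -> np.ndarray:
    d = np.full((k, k), np.inf)
    np.fill_diagonal(d, 0.0)
    for (i, j), w in zip(edges, dist):
        d[i, j] = d[j, i] = min(d[i, j], w)
    for m in range(k):
        d = np.minimum(d, d[:, m : m + 1] + d[m : m + 1, :])
    return d


def random_graph(rng, k: int):
    """A random connected superpixel-like graph on a k-block strip image."""
    label_map = np.repeat(np.arange(k)[None, :], 8, axis=0)
    label_map = np.repeat(label_map, 3, axis=1)
    img = np.zeros(label_map.shape + (3,))
    for label in range(k):
        img[label_map == label] = rng.random(3)
    return graph_from_labels(label_map, img)


class TestSuperpixels:
    def test_count_and_contiguity(self, smear_scene):
        img, _, _ = smear_scene
        from salseg.imaging import downsample

        graph = compute_superpixels(downsample(img, 64), n_segments=100)
        assert 50 <= graph.n_superpixels <= 200
        assert set(np.unique(graph.label_map)) == set(range(graph.n_superpixels))
        assert graph.is_boundary.any()
        assert (graph.area > 0).all()

    def test_two_tone_image_not_bridged(self):
        img = np.zeros((64, 64, 3))
        img[:, 32:] = (1.0, 1.0, 0.0)
        graph = compute_superpixels(img, n_segments=16)
        for label in range(graph.n_superpixels):
            cols = np.where(graph.label_map == label)[1]
            assert cols.max() < 32 or cols.min() >= 32

    def test_adjacency_symmetric_irreflexive(self, smear_scene):
        img, _, _ = smear_scene
        from salseg.imaging import downsample

        graph = compute_superpixels(downsample(img, 64), n_segments=60)
        assert (graph.edges[:, 0] < graph.edges[:, 1]).all()
        pairs = {tuple(e) for e in graph.edges}
        assert len(pairs) == len(graph.edges)

    def test_too_many_superpixels_rejected(self, rng):
        with pytest.raises(ValueError):
            compute_superpixels(rng.random((8, 8, 3)), n_segments=100)


class TestBoundaryConnectivity:
    def test_interior_region_near_zero(self):
        label_map = block_label_map(block=8, grid=4)
        colors = {i: FAR_COLORS["white"] for i in range(16)}
        colors[10] = FAR_COLORS["red"]  # block (2, 2): interior
        graph = graph_from_labels(label_map, colored_block_image(label_map, colors))
        bndcon = boundary_connectivity(graph, sigma_clr=10.0)
        assert bndcon[10] < 1e-3

    def test_hard_region_limit_two_of_four_on_border(self):
        label_map = block_label_map(block=8, grid=4)
        colors = {i: FAR_COLORS["white"] for i in range(16)}
        # region: blocks (0,1), (0,2) on the top border, (1,1), (1,2) interior
        for label in (1, 2, 5, 6):
            colors[label] = FAR_COLORS["navy"]
        graph = graph_from_labels(label_map, colored_block_image(label_map, colors))
        bndcon = boundary_connectivity(graph, sigma_clr=10.0)
        for label in (1, 2, 5, 6):
            assert abs(bndcon[label] - 2.0 / np.sqrt(4.0)) < 1e-3

    def test_matches_floyd_warshall_oracle(self, rng):
        for k in (5, 12, 25):
            graph = random_graph(rng, k)
            d = floyd_warshall(k, graph.edges, graph.edge_dist)
            aff = np.exp(-(d**2) / (2 * 10.0**2))
            aff[~np.isfinite(d)] = 0.0
            expected = aff[:, graph.is_boundary].sum(axis=1) / np.sqrt(aff.sum(axis=1))
            got = boundary_connectivity(graph, sigma_clr=10.0)
            np.testing.assert_allclose(got, expected, atol=1e-8)


class TestBackgroundProbability:
    def test_closed_form_values(self):
        got = background_probability(np.array([0.0, 1.0, 100.0]), sigma_bndcon=1.0)
        np.testing.assert_allclose(
            got, [0.0, 1.0 - np.exp(-0.5), 1.0], atol=1e-10
        )
        assert (np.diff(background_probability(np.linspace(0, 5, 50))) >= 0).all()

    def test_rejects_bad_sigma(self):
        with pytest.raises(ValueError):
            background_probability(np.array([1.0]), sigma_bndcon=0.0)


class TestForegroundProbability:
    def test_per_superpixel_mean_oracle(self, rng):
        label_map = block_label_map(block=4, grid=4)
        img = rng.random(label_map.shape + (3,))
        graph = graph_from_labels(label_map, img)
        coarse = rng.random(label_map.shape)
        got = foreground_probability(coarse, graph)
        for label in range(16):
            assert got[label] == pytest.approx(coarse[label_map == label].mean())

    def test_indicator_map(self):
        label_map = block_label_map(block=4, grid=2)
        img = np.full(label_map.shape + (3,), 0.5)
        graph = graph_from_labels(label_map, img)
        coarse = (label_map == 3).astype(float)
        got = foreground_probability(coarse, graph)
        np.testing.assert_allclose(got, [0, 0, 0, 1.0], atol=1e-12)


class TestOptimizeSaliency:
    def test_pure_foreground_and_background(self, rng):
        graph = random_graph(rng, 6)
        k = graph.n_superpixels
        s = optimize_saliency(np.zeros(k), np.ones(k), graph)
        np.testing.assert_allclose(s, 1.0, atol=1e-8)
        s = optimize_saliency(np.ones(k), np.zeros(k), graph)
        np.testing.assert_allclose(s, 0.0, atol=1e-8)

    def test_beats_multistart_numeric_oracle(self, rng):
        graph = random_graph(rng, 8)
        k = graph.n_superpixels
        w_bg = rng.random(k)
        w_fg = rng.random(k)
        s = optimize_saliency(w_bg, w_fg, graph)
        cost = rbd_cost(s, w_bg, w_fg, graph)
        best = np.inf
        for _ in range(20):
            res = minimize(
                rbd_cost, rng.random(k), args=(w_bg, w_fg, graph), method="L-BFGS-B"
            )
            best = min(best, res.fun)
        assert cost <= best + 1e-8

    def test_stationarity_and_range(self, rng):
        graph = random_graph(rng, 10)
        k = graph.n_superpixels
        w_bg = rng.random(k)
        w_fg = rng.random(k)
        s = optimize_saliency(w_bg, w_fg, graph)
        assert s.min() >= 0.0 and s.max() <= 1.0
        # gradient of the cost at the solution
        w_ij = smoothness_weights(graph)
        grad = 2 * (w_bg * s + w_fg * (s - 1.0))
        for (i, j), w in zip(graph.edges, w_ij):
            grad[i] += 2 * w * (s[i] - s[j])
            grad[j] += 2 * w * (s[j] - s[i])
        assert np.abs(grad).max() < 1e-6

    def test_monotone_in_foreground_weight(self, rng):
        for _ in range(10):
            graph = random_graph(rng, int(rng.integers(4, 10)))
            k = graph.n_superpixels
            w_bg = rng.random(k)
            w_fg = rng.random(k) * 0.8
            target = int(rng.integers(0, k))
            s0 = optimize_saliency(w_bg, w_fg, graph)
            w_fg2 = w_fg.copy()
            w_fg2[target] += 0.2
            s1 = optimize_saliency(w_bg, w_fg2, graph)
            assert s1[target] >= s0[target] - 1e-10


class TestProjectToPixels:
    def test_piecewise_constant_projection(self, rng):
        label_map = block_label_map(block=4, grid=3)
        img = np.full(label_map.shape + (3,), 0.5)
        graph = graph_from_labels(label_map, img)
        s = rng.permutation(9) / 10.0
        out = project_to_pixels(s, graph)
        assert len(np.unique(out)) == 9
        # round trip: per-superpixel mean recovers s up to the normalization
        back = foreground_probability(out, graph)
        rescaled = (s - s.min()) / (s.max() - s.min())
        np.testing.assert_allclose(back, rescaled, atol=1e-12)

    def test_constant_saliency_flagged_to_zero(self):
        label_map = block_label_map(block=4, grid=2)
        img = np.full(label_map.shape + (3,), 0.5)
        graph = graph_from_labels(label_map, img)
        out = project_to_pixels(np.full(4, 0.7), graph)
        np.testing.assert_array_equal(out, 0.0)
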