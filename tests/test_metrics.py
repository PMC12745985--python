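"""Coherence metrics: Gram spectra, dimension fits, spatial constant, MDS."""

import json

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist, squareform

from netcoherence import (
    SpatialGraph,
    coherence_report,
    distance_correlation_r2,
    estimate_dimension,
    euclidean_spatial_constant,
    gram_from_distances,
    reconstruct_classical_mds,
    shortest_path_matrix,
    spatial_constant,
    spatial_constant_profile,
    spectral_scores,
)
from netcoherence.metrics import CoherenceReport

from .conftest import grid_graph, random_connected_graph


def euclidean_gram(points: np.ndarray) -> np.ndarray:
    return gram_from_distances(cdist(points, points))


class TestGram:
    def test_two_point_hand_computation(self):
        g = gram_from_distances(np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert np.allclose(g, [[1.0, -1.0], [-1.0, 1.0]])
        ev = np.sort(np.linalg.eigvalsh(g))
        assert np.allclose(ev, [0.0, 2.0])

    def test_unit_square_corners(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        ev = np.linalg.eigvalsh(euclidean_gram(pts))[::-1]
        assert np.allclose(ev[:2], [1.0, 1.0])
        assert np.allclose(ev[2:], 0.0, atol=1e-12)

    def test_zero_distances_give_zero_gram(self):
        assert np.allclose(gram_from_distances(np.zeros((4, 4))), 0.0)

    def test_double_centering_rows_sum_to_zero(self):
        rng = np.random.default_rng(1)
        d = squareform(pdist(rng.uniform(size=(10, 3))))
        g = gram_from_distances(d)
        assert np.allclose(g.sum(axis=0), 0.0, atol=1e-10)
        assert np.allclose(g, g.T)


class TestSpectralScores:
    @pytest.mark.parametrize(
        "spectrum,cd,gap",
        [([3.0, 1.0, 0.0, 0.0], 1.0, 1.0), ([2.0, 1.0, 1.0, 0.0], 0.75, 0.0)],
    )
    def test_arithmetic_examples(self, spectrum, cd, gap):
        s = spectral_scores(np.diag(spectrum), target_dim=2)
        assert s.variance_contribution == pytest.approx(cd)
        assert s.spectral_gap == pytest.approx(gap)

    @pytest.mark.parametrize("dim", [1, 2, 3])
    def test_exact_euclidean_input_scores_one(self, dim):
        rng = np.random.default_rng(dim)
        pts = rng.uniform(size=(200, dim))
        s = spectral_scores(euclidean_gram(pts), target_dim=dim)
        assert s.variance_contribution == pytest.approx(1.0, abs=1e-9)
        assert s.spectral_gap == pytest.approx(1.0, abs=1e-9)

    def test_gap_flagged_when_lambda_d_nonpositive(self):
        s = spectral_scores(np.diag([2.0, 0.0, 0.0, -1.0]), target_dim=2)
        assert not s.gap_defined
        assert np.isnan(s.spectral_gap)

    def test_abs_denominator_convention(self):
        s = spectral_scores(np.diag([3.0, 1.0, -1.0, 0.0]), 2, denominator="abs")
        assert s.variance_contribution == pytest.approx(4.0 / 5.0)
        s_pos = spectral_scores(np.diag([3.0, 1.0, -1.0, 0.0]), 2)
        assert s_pos.variance_contribution == pytest.approx(1.0)


class TestDimensionEstimate:
    def test_cycle_is_one_dimensional(self):
        n = 1000
        g = SpatialGraph.from_edges(n, [[i, (i + 1) % n] for i in range(n)])
        d = estimate_dimension(g, origins=[0, 250, 500])
        assert d.pooled_dimension == pytest.approx(1.0, abs=0.1)

    def test_square_lattice_is_two_dimensional(self):
        side = 60
        g = grid_graph(side)
        center = (side // 2) * side + side // 2
        d = estimate_dimension(g, origins=[center], max_depth=25)
        assert d.pooled_dimension == pytest.approx(2.0, abs=0.1)

    def test_too_shallow_graph_errors(self):
        g = SpatialGraph.from_edges(3, [[0, 1], [1, 2], [0, 2]])
        with pytest.raises(ValueError, match="3 usable depths"):
            estimate_dimension(g, origins=[0])


class TestSpatialConstant:
    def test_profile_at_full_depth_matches_direct_definition(self):
        g, _ = random_connected_graph(40, 0.15, seed=4)
        diam = int(shortest_path_matrix(g, "hop").matrix.max())
        prof = spatial_constant_profile(g, target_dim=2, depths=[diam], seed=0)
        assert prof.constants[0] == pytest.approx(spatial_constant(g, 2))

    def test_small_subgraphs_are_skipped(self):
        n = 60
        g = SpatialGraph.from_edges(n, [[i, (i + 1) % n] for i in range(n)])
        prof = spatial_constant_profile(
            g, target_dim=1, depths=[2, 8], seed=0, min_subgraph=10
        )
        assert prof.depths.tolist() == [8]


class TestEuclideanReference:
    def test_disk_mean_distance_and_beta(self):
        rng = np.random.default_rng(0)
        r = np.sqrt(rng.uniform(size=10_000))
        theta = rng.uniform(0, 2 * np.pi, size=10_000)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        ref = euclidean_spatial_constant(pts, target_dim=2, seed=0)
        assert ref.mean_distance == pytest.approx(0.9054, abs=0.01)  # 128/(45 pi)
        assert ref.beta == pytest.approx(0.9 / np.sqrt(np.pi), abs=0.01)

    def test_two_points_exact_mean(self):
        ref = euclidean_spatial_constant(
            np.array([[0.0, 0.0], [3.0, 4.0]]), target_dim=2
        )
        assert ref.mean_distance == pytest.approx(5.0)
        assert np.isnan(ref.beta)  # degenerate hull


class TestDistanceCorrelation:
    def test_exact_affine_relationship_gives_one(self):
        n = 30
        g = SpatialGraph.from_edges(
            n,
            [[i, i + 1] for i in range(n - 1)],
            positions=np.column_stack([np.arange(n) * 2.5, np.zeros(n)]),
        )
        assert distance_correlation_r2(g) == pytest.approx(1.0)

    def test_matches_ols_oracle_on_sampled_pairs(self):
        g, _ = random_connected_graph(12, 0.3, seed=8)
        rng = np.random.default_rng(0)
        g = SpatialGraph(
            n_nodes=12, edges=g.edges, positions=rng.uniform(size=(12, 2))
        )
        r2 = distance_correlation_r2(g)
        m = shortest_path_matrix(g, "hop").matrix
        iu, ju = np.triu_indices(12, k=1)
        x, y = m[iu, ju], np.linalg.norm(g.positions[iu] - g.positions[ju], axis=1)
        coef = np.polyfit(x, y, 1)
        ss_res = np.sum((y - np.polyval(coef, x)) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert r2 == pytest.approx(1 - ss_res / ss_tot)

    def test_requires_positions(self, path5):
        with pytest.raises(ValueError, match="positions"):
            distance_correlation_r2(path5)


def procrustes_rms(a: np.ndarray, b: np.ndarray) -> float:
    """RMS residual after optimal translation/rotation/reflection (no scaling)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    u, _, vt = np.linalg.svd(b.T @ a)
    return float(np.sqrt(np.mean((a - b @ (u @ vt)) ** 2)))


class TestClassicalMds:
    def test_two_points_one_dimension(self):
        coords = reconstruct_classical_mds(
            gram_from_distances(np.array([[0.0, 2.0], [2.0, 0.0]])), 1
        )
        assert np.allclose(np.sort(coords.ravel()), [-1.0, 1.0])

    def test_recovers_planar_points_up_to_isometry(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(size=(50, 2))
        coords = reconstruct_classical_mds(euclidean_gram(pts), 2)
        assert procrustes_rms(coords, pts) < 1e-6

    def test_output_is_centered(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(size=(20, 3))
        coords = reconstruct_classical_mds(euclidean_gram(pts), 3)
        assert np.allclose(coords.mean(axis=0), 0.0, atol=1e-10)

    def test_pads_when_rank_deficient(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5)])  # truly 1D
        coords = reconstruct_classical_mds(euclidean_gram(pts), 2)
        assert np.allclose(coords[:, 1], 0.0, atol=1e-6)


class TestCoherenceReport:
    def test_json_round_trip_is_lossless(self):
        g, _ = random_connected_graph(60, 0.1, seed=6)
        rep = coherence_report(g, target_dim=2, seed=3)
        back = CoherenceReport.from_json(rep.to_json(max_eigenvalues=1000))
        assert back.to_dict(max_eigenvalues=1000) == rep.to_dict(max_eigenvalues=1000)
        assert json.loads(rep.to_json())["seed"] == 3
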