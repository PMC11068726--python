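"""Consensus-ICA stage: component-count selection, single-run recovery,
cross-run clustering, credibility filtering, mixing estimation and the
end-to-end decomposition."""

import numpy as np
import pytest

from consica import cica, synthetic
from consica.cica import ComponentCluster, ICAConvergenceError, ICARunResult
from consica.containers import ExpressionMatrix, MixingMatrix, TCSet


def _matched_abs_r(estimated: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Greedy sign/permutation matching; returns the matched |r| values."""
    k1 = len(estimated)
    R = np.abs(np.corrcoef(np.vstack([estimated, truth]))[:k1, k1:]).copy()
    out = []
    for _ in range(min(R.shape)):
        i, j = np.unravel_index(np.argmax(R), R.shape)
        out.append(R[i, j])
        R[i, :] = -1.0
        R[:, j] = -1.0
    return np.array(out)


class TestSelectNComponents:
    def test_rank_one_matrix(self):
        v = np.linspace(1, 2, 40)
        X = ExpressionMatrix(
            [f"g{i}" for i in range(40)],
            [f"s{j}" for j in range(6)],
            np.outer(v, np.arange(1, 7)),
        )
        assert cica.select_n_components(X) == 1

    def test_ten_equal_variance_directions(self):
        # orthonormal design: 10 equal singular values -> need 9 for 85%.
        # Sample-space directions are built orthogonal to the ones vector so
        # gene centering (which removes that direction) leaves all 10 intact.
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.normal(size=(100, 10)))
        M = rng.normal(size=(11, 10))
        M -= M.mean(axis=0, keepdims=True)
        B, _ = np.linalg.qr(M)  # 11 x 10, columns orthonormal, sum zero
        X = ExpressionMatrix(
            [f"g{i}" for i in range(100)],
            [f"s{j}" for j in range(11)],
            Q @ B.T,
        )
        Xc = X.values - X.values.mean(axis=1, keepdims=True)
        # guard: construction really has (near-)equal nonzero eigenvalues
        s = np.linalg.svd(Xc, compute_uv=False)
        assert s[0] / s[8] < 1.5
        assert cica.select_n_components(X, 0.85) == 9

    def test_five_source_mixture(self, mixture):
        X, _ = mixture
        assert cica.select_n_components(X) == 5

    def test_constant_matrix_errors(self):
        X = ExpressionMatrix(["g1", "g2"], ["s1", "s2"], np.ones((2, 2)))
        with pytest.raises(ValueError, match="variance"):
            cica.select_n_components(X)


class TestRunSingleICA:
    def test_two_source_zero_noise_recovery(self):
        src = synthetic.generate_sources(800, 2, 0.05, seed=2)
        X, _ = synthetic.generate_expression(src, 60, 1.0, 0.0, seed=3)
        run = cica.run_single_ica(X, 2, seed=11)
        r = _matched_abs_r(run.components, src.weights)
        assert (r > 0.999).all()

    def test_seed_determinism(self, mixture):
        X, _ = mixture
        a = cica.run_single_ica(X, 5, seed=5)
        b = cica.run_single_ica(X, 5, seed=5)
        np.testing.assert_array_equal(a.components, b.components)

    def test_gaussian_data_flagged(self):
        rng = np.random.default_rng(4)
        X = ExpressionMatrix(
            [f"g{i}" for i in range(400)],
            [f"s{j}" for j in range(60)],
            rng.normal(size=(400, 60)),
        )
        with pytest.raises(ICAConvergenceError, match="seed"):
            cica.run_single_ica(X, 5, seed=8, max_iter=50)

    def test_unit_variance_components(self, mixture):
        X, _ = mixture
        run = cica.run_single_ica(X, 5, seed=6)
        np.testing.assert_allclose(run.components.std(axis=1), 1, atol=1e-9)


class TestClusterComponents:
    def _runs_from(self, comps, n_runs, flip_runs=()):
        runs = []
        for r in range(n_runs):
            c = comps.copy()
            if r in flip_runs:
                c = -c
            runs.append(ICARunResult(run_seed=r, components=c))
        return runs

    def test_sign_flip_clusters_together(self):
        rng = np.random.default_rng(5)
        comps = rng.normal(size=(1, 300))
        comps = (comps - comps.mean(1, keepdims=True)) / comps.std(1, keepdims=True)
        clusters = cica.cluster_components(self._runs_from(comps, 2, flip_runs=[1]))
        assert len(clusters) == 1
        signs = sorted(s for _, _, s in clusters[0].members)
        assert signs == [-1, 1]

    def test_below_threshold_stays_singleton(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=300)
        b = 0.5 * a + np.sqrt(1 - 0.25) * rng.normal(size=300)  # r ~ 0.5
        runs = [
            ICARunResult(0, (a[None, :] - a.mean()) / a.std()),
            ICARunResult(1, (b[None, :] - b.mean()) / b.std()),
        ]
        clusters = cica.cluster_components(runs)
        assert len(clusters) == 2

    def test_cluster_size_capped_at_n_runs(self):
        rng = np.random.default_rng(7)
        comps = rng.normal(size=(3, 500))
        comps = (comps - comps.mean(1, keepdims=True)) / comps.std(1, keepdims=True)
        clusters = cica.cluster_components(self._runs_from(comps, 25))
        assert len(clusters) == 3
        assert all(c.size == 25 for c in clusters)


class TestBuildConsensus:
    def _cluster(self, size, p=100, seed=0):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=p)
        return ComponentCluster(
            members=[(r, 0, 1) for r in range(size)], consensus=v
        )

    @pytest.mark.parametrize(
        "size,retained", [(25, True), (13, True), (12, False)]
    )
    def test_credibility_arithmetic(self, size, retained):
        clusters = [self._cluster(25, seed=1), self._cluster(size, seed=2)]
        tcs = cica.build_consensus(clusters, n_runs=25)
        expected_n = 2 if retained else 1
        assert tcs.n_components == expected_n
        if retained:
            assert np.isclose(sorted(tcs.credibility)[0], size / 25)

    def test_empty_retained_set_errors(self):
        with pytest.raises(ValueError, match="credibility"):
            cica.build_consensus([self._cluster(5)], n_runs=25)

    def test_consensus_restandardized_and_ordered(self):
        clusters = [self._cluster(13, seed=3), self._cluster(25, seed=4)]
        tcs = cica.build_consensus(clusters, n_runs=25)
        np.testing.assert_allclose(tcs.weights.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(tcs.weights.std(axis=1), 1, atol=1e-9)
        assert list(tcs.credibility) == sorted(tcs.credibility, reverse=True)


class TestEstimateMixing:
    def test_exact_recovery_on_orthogonal_basis(self):
        rng = np.random.default_rng(8)
        Q, _ = np.linalg.qr(rng.normal(size=(200, 3)))
        S = (Q.T - Q.T.mean(1, keepdims=True)) / Q.T.std(1, keepdims=True)
        A = rng.normal(size=(3, 12))
        A -= A.mean(axis=1, keepdims=True)  # centered activities
        X = ExpressionMatrix(
            [f"g{i}" for i in range(200)], [f"s{j}" for j in range(12)], S.T @ A
        )
        tcs = TCSet([f"c{i}" for i in range(3)], X.gene_ids, S, np.ones(3))
        mix = cica.estimate_mixing(X, tcs)
        np.testing.assert_allclose(mix.activities, A, atol=1e-8)

    def test_zero_variance_sample_zero_activities(self, sources5):
        V = np.zeros((1000, 3))
        V[:, 0] = sources5.weights[0]
        X = ExpressionMatrix(sources5.gene_ids, ["a", "b", "c"], V)
        mix = cica.estimate_mixing(X, sources5)
        np.testing.assert_allclose(mix.activities[:, 1], 0, atol=1e-12)

    def test_noisy_recovery_correlates_with_truth(self, sources5, mixture):
        X, A_true = mixture
        mix = cica.estimate_mixing(X, sources5)
        for k in range(5):
            r = np.corrcoef(mix.activities[k], A_true.activities[k])[0, 1]
            assert r > 0.95

    def test_collinear_components_error(self, sources5):
        W = np.vstack([sources5.weights[0], sources5.weights[0] * 1.0000001])
        W = (W - W.mean(1, keepdims=True)) / W.std(1, keepdims=True)
        tcs = TCSet(["c1", "c2"], sources5.gene_ids, W, np.ones(2))
        X = ExpressionMatrix(sources5.gene_ids, ["a", "b"], np.zeros((1000, 2)))
        with pytest.raises(ValueError, match="collinear"):
            cica.estimate_mixing(X, tcs)


class TestReconstruct:
    def test_round_trip_zero_noise(self, sources5):
        X, _ = synthetic.generate_expression(sources5, 40, 1.0, 0.0, seed=9)
        mix = cica.estimate_mixing(X, sources5)
        rec = cica.reconstruct(sources5, mix, original=X)
        assert rec.r2_overall > 0.999

    def test_zero_activity_zero_reconstruction(self, sources5):
        mix = MixingMatrix(sources5.component_ids, ["a", "b"], np.zeros((5, 2)))
        rec = cica.reconstruct(sources5, mix)
        np.testing.assert_array_equal(rec.expression.values, 0)

    def test_dimension_mismatch_errors(self, sources5):
        mix = MixingMatrix(["other"], ["a"], np.zeros((1, 1)))
        with pytest.raises(ValueError):
            cica.reconstruct(sources5, mix)

    def test_variance_threshold_bookkeeping(self, sources5, mixture):
        X, _ = mixture
        tcs, mix = cica.decompose(X, n_runs=5, master_seed=2)
        rec = cica.reconstruct(tcs, mix, original=X)
        assert rec.r2_overall >= 0.85


class TestDecompose:
    def test_recovers_well_separated_sources(self, sources5, mixture):
        X, _ = mixture
        tcs, _ = cica.decompose(X, n_runs=10, master_seed=4)
        assert tcs.n_components == 5
        np.testing.assert_array_equal(tcs.credibility, 1.0)
        r = _matched_abs_r(tcs.weights, sources5.weights)
        assert r.mean() > 0.95

    def test_single_run_degenerate(self, mixture):
        X, _ = mixture
        tcs, _ = cica.decompose(X, n_runs=1, master_seed=5)
        np.testing.assert_array_equal(tcs.credibility, 1.0)

    def test_master_seed_determinism(self, mixture):
        X, _ = mixture
        t1, m1 = cica.decompose(X, n_runs=5, master_seed=6)
        t2, m2 = cica.decompose(X, n_runs=5, master_seed=6)
        np.testing.assert_array_equal(t1.weights, t2.weights)
        np.testing.assert_array_equal(m1.activities, m2.activities)

    def test_near_orthogonal_consensus(self, mixture):
        X, _ = mixture
        tcs, _ = cica.decompose(X, n_runs=5, master_seed=7)
        R = np.corrcoef(tcs.weights)
        np.fill_diagonal(R, 0)
        assert np.abs(R).max() < 0.3

    def test_credibility_invariant_to_run_order(self, mixture):
        X, _ = mixture
        runs = [cica.run_single_ica(X, 5, seed=s) for s in (3, 14, 159, 2653)]
        c1 = cica.cluster_components(runs)
        c2 = cica.cluster_components(runs[::-1])
        assert sorted(c.size for c in c1) == sorted(c.size for c in c2)
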