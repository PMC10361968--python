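import numpy as np
import pytest

from v1drift.drift import (
    BetaPanel,
    GOFMatrix,
    adjacent_profile,
    cross_session_gof,
    drift_statistic,
    fit_all_sessions,
    interval_profile,
    normalize_session_variance,
    permutation_test,
    session_series_stats,
    subtract_session_mean,
)
from v1drift.synthetic_data import DriftSpec

from conftest import make_experiment


def gof_stat(exp, norm=None, metric="cvR2", n_perm=500, seed=0):
    panel = exp.panel if norm is None else norm(exp.panel)
    fits = fit_all_sessions(exp.designs, panel)
    M = cross_session_gof(fits, exp.designs, panel, metric=metric)
    return M, permutation_test([M], n_perm=n_perm, seed=seed)


# --------------------------------------------------------------------------
# GOF matrix
# --------------------------------------------------------------------------

class TestCrossSessionGof:
    def test_noiseless_no_drift_all_cells_one(self, fitted):
        exp, fits = fitted
        M = cross_session_gof(fits, exp.designs, exp.panel)
        np.testing.assert_allclose(M.values, 1.0, atol=1e-6)

    def test_two_sessions_not_symmetric(self):
        exp = make_experiment(
            n_sessions=2,
            noise_sd=1.0,
            drift_spec=DriftSpec(baseline_walk_sd=1.0),
            seed=4,
        )
        fits = fit_all_sessions(exp.designs, exp.panel)
        M = cross_session_gof(fits, exp.designs, exp.panel)
        assert M.values.shape == (2, 2)
        assert M.values[0, 1] != M.values[1, 0]

    def test_baseline_walk_decays_with_interval(self, baseline_walk_experiment):
        exp = baseline_walk_experiment
        fits = fit_all_sessions(exp.designs, exp.panel)
        M = cross_session_gof(fits, exp.designs, exp.panel)
        prof = interval_profile(M)
        assert prof.means[4] < prof.means[0]  # d = 5 below d = 1

    def test_missing_session_fit_reported(self, fitted):
        exp, fits = fitted
        with pytest.raises(ValueError, match="missing session fits"):
            cross_session_gof(fits[:-1], exp.designs, exp.panel)

    def test_voxel_inclusion_rule(self, fitted):
        exp, fits = fitted
        panel = exp.panel
        panel.prf_r2[:] = -1.0
        with pytest.raises(ValueError, match="inclusion"):
            cross_session_gof(fits, exp.designs, panel)

    def test_permutation_identity_of_generator(self, baseline_walk_experiment):
        """GOF of session-permuted input equals the permuted GOF matrix."""
        exp = baseline_walk_experiment
        fits = fit_all_sessions(exp.designs, exp.panel)
        M = cross_session_gof(fits, exp.designs, exp.panel)
        perm = np.random.default_rng(0).permutation(M.n_sessions)
        # relabel sessions: new session i is old session perm[i]
        relabel = np.empty_like(perm)
        relabel[perm] = np.arange(len(perm))
        panel2 = BetaPanel(
            betas=exp.panel.betas,
            sessions=relabel[exp.panel.sessions],
            image_ids=exp.panel.image_ids,
            prf_r2=exp.panel.prf_r2,
        )
        designs2 = exp.designs[perm]
        fits2 = fit_all_sessions(designs2, panel2)
        M2 = cross_session_gof(fits2, designs2, panel2)
        np.testing.assert_allclose(M2.values, M.permuted(perm).values, atol=1e-9)


# --------------------------------------------------------------------------
# interval profiles
# --------------------------------------------------------------------------

class TestIntervalProfile:
    def test_constant_matrix_flat_profile(self):
        M = GOFMatrix(values=np.full((8, 8), 0.7), metric="cvR2")
        prof = interval_profile(M)
        np.testing.assert_allclose(prof.means, 0.7)

    def test_thirty_sessions_profile_length_29(self):
        M = GOFMatrix(values=np.zeros((30, 30)), metric="cvR2")
        prof = interval_profile(M)
        assert len(prof.means) == 29
        assert prof.intervals[-1] == 29

    def test_counts_formula(self):
        S = 12
        M = GOFMatrix(values=np.zeros((S, S)), metric="cvR2")
        prof = interval_profile(M)
        np.testing.assert_array_equal(
            prof.counts, [2 * (S - d) for d in range(1, S)]
        )

    def test_exact_negative_distance_matrix(self):
        S = 10
        j, k = np.indices((S, S))
        M = GOFMatrix(values=-np.abs(j - k).astype(float), metric="cvR2")
        prof = interval_profile(M)
        np.testing.assert_allclose(prof.means, -np.arange(1, S))

    def test_adjacent_profile_modes(self):
        S = 5
        v = np.arange(S * S, dtype=float).reshape(S, S)
        M = GOFMatrix(values=v, metric="cvR2")
        upper = adjacent_profile(M, "upper")
        lower = adjacent_profile(M, "lower")
        avg = adjacent_profile(M)
        np.testing.assert_allclose(avg, (upper + lower) / 2)
        assert len(avg) == S - 1


# --------------------------------------------------------------------------
# drift statistic and permutation test
# --------------------------------------------------------------------------

class TestDriftStatistic:
    def test_perfect_linear_decay(self):
        j, k = np.indices((10, 10))
        M = GOFMatrix(values=-np.abs(j - k).astype(float), metric="cvR2")
        assert drift_statistic([M]).r_empirical == pytest.approx(-1.0)

    def test_interval_independent_entries_near_zero(self):
        # entries depend on j + k, which is uncorrelated with |j - k|
        j, k = np.indices((12, 12))
        M = GOFMatrix(values=(j + k).astype(float), metric="cvR2")
        assert abs(drift_statistic([M]).r_empirical) < 1e-10

    def test_baseline_walk_negative(self, baseline_walk_experiment):
        _, stat = gof_stat(baseline_walk_experiment, n_perm=1)
        assert stat.r_empirical < 0

    def test_degenerate_matrix_rejected(self):
        M = GOFMatrix(values=np.ones((5, 5)), metric="cvR2")
        with pytest.raises(ValueError, match="degenerate"):
            drift_statistic([M])

    def test_constant_shift_invariance_and_sign_flip(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal((8, 8))
        r0 = drift_statistic([GOFMatrix(values=v, metric="m")]).r_empirical
        r_shift = drift_statistic(
            [GOFMatrix(values=v + 5.0, metric="m")]
        ).r_empirical
        r_neg = drift_statistic([GOFMatrix(values=-v, metric="m")]).r_empirical
        assert r_shift == pytest.approx(r0)
        assert r_neg == pytest.approx(-r0)

    def test_mean_across_subjects(self):
        j, k = np.indices((6, 6))
        M1 = GOFMatrix(values=-np.abs(j - k).astype(float), metric="m")
        M2 = GOFMatrix(values=np.abs(j - k).astype(float), metric="m")
        assert drift_statistic([M1, M2]).r_empirical == pytest.approx(0.0)


class TestPermutationTest:
    def test_identity_permutation_reproduces_empirical(self):
        rng = np.random.default_rng(1)
        M = GOFMatrix(values=rng.standard_normal((8, 8)), metric="m")
        emp = drift_statistic([M]).r_empirical
        assert drift_statistic([M.permuted(np.arange(8))]).r_empirical == emp

    def test_p_zero_when_empirical_below_all_null(self):
        j, k = np.indices((15, 15))
        M = GOFMatrix(
            values=-np.abs(j - k).astype(float) * 10.0, metric="cvR2"
        )
        stat = permutation_test([M], n_perm=200, seed=0)
        assert stat.p == 0.0

    def test_null_length_and_seed_reproducibility(self):
        rng = np.random.default_rng(2)
        M = GOFMatrix(values=rng.standard_normal((8, 8)), metric="m")
        s1 = permutation_test([M], n_perm=50, seed=7)
        s2 = permutation_test([M], n_perm=50, seed=7)
        assert s1.n_perm == 50
        np.testing.assert_array_equal(s1.null, s2.null)

    def test_session_count_mismatch_rejected(self):
        A = GOFMatrix(values=np.zeros((4, 4)), metric="m")
        B = GOFMatrix(values=np.zeros((5, 5)), metric="m")
        with pytest.raises(ValueError, match="session count"):
            permutation_test([A, B], n_perm=10)


# --------------------------------------------------------------------------
# normalization interventions
# --------------------------------------------------------------------------

class TestNormalization:
    def test_subtract_mean_zeroes_session_means(self, baseline_walk_experiment):
        panel = subtract_session_mean(baseline_walk_experiment.panel)
        for s in range(panel.n_sessions):
            np.testing.assert_allclose(
                panel.session_betas(s).mean(axis=1), 0.0, atol=1e-12
            )

    def test_subtract_mean_idempotent(self, baseline_walk_experiment):
        once = subtract_session_mean(baseline_walk_experiment.panel)
        twice = subtract_session_mean(once)
        np.testing.assert_allclose(once.betas, twice.betas, atol=1e-12)

    def test_subtract_mean_abolishes_baseline_drift(
        self, baseline_walk_experiment
    ):
        _, raw = gof_stat(baseline_walk_experiment)
        _, fixed = gof_stat(baseline_walk_experiment, norm=subtract_session_mean)
        assert raw.p < 0.05
        assert fixed.p > 0.05

    def test_normalize_variance_sets_sd_keeps_mean(
        self, baseline_walk_experiment
    ):
        orig = baseline_walk_experiment.panel
        panel = normalize_session_variance(orig)
        for s in range(panel.n_sessions):
            np.testing.assert_allclose(
                panel.session_betas(s).std(axis=1), 1.0, atol=1e-12
            )
            np.testing.assert_allclose(
                panel.session_betas(s).mean(axis=1),
                orig.session_betas(s).mean(axis=1),
                atol=1e-12,
            )

    def test_normalize_variance_keeps_baseline_drift(
        self, baseline_walk_experiment
    ):
        _, stat = gof_stat(
            baseline_walk_experiment, norm=normalize_session_variance
        )
        assert stat.r_empirical < 0
        assert stat.p < 0.05

    def test_normalize_variance_removes_gain_drift(self):
        exp = make_experiment(
            n_sessions=10,
            n_voxels=100,
            images_per_session=80,
            noise_sd=0.1,
            drift_spec=DriftSpec(gain_walk_sd=0.05),
            seed=5,
        )
        _, raw = gof_stat(exp)
        _, fixed = gof_stat(exp, norm=normalize_session_variance)
        assert raw.p < 0.05
        assert fixed.p > 0.05

    def test_zero_variance_session_rejected(self, baseline_walk_experiment):
        panel = baseline_walk_experiment.panel
        bad = BetaPanel(
            betas=panel.betas.copy(),
            sessions=panel.sessions,
            image_ids=panel.image_ids,
            prf_r2=panel.prf_r2,
        )
        bad.betas[3, bad.session_trials(0)] = 2.0
        with pytest.raises(ValueError, match="zero-variance"):
            normalize_session_variance(bad)


# --------------------------------------------------------------------------
# session-series statistics
# --------------------------------------------------------------------------

class TestSessionSeries:
    def test_identical_series_cross_correlation_one(self):
        S, n = 6, 10
        series = np.sin(np.arange(S))
        betas = np.repeat(np.repeat(series, n)[None, :], 2, axis=0)
        panel = BetaPanel(
            betas=betas,
            sessions=np.repeat(np.arange(S), n),
            image_ids=np.arange(S * n),
            prf_r2=np.ones(2),
        )
        stats = session_series_stats(panel)
        assert stats.cross_correlations[0] == pytest.approx(1.0)

    def test_random_walk_positive_lag1_autocorrelation(self):
        rng = np.random.default_rng(0)
        S, V = 30, 500
        walks = np.cumsum(rng.standard_normal((V, S)), axis=1)
        panel = BetaPanel(
            betas=np.repeat(walks, 2, axis=1),
            sessions=np.repeat(np.arange(S), 2),
            image_ids=np.arange(S * 2),
            prf_r2=np.ones(V),
        )
        stats = session_series_stats(panel)
        assert stats.autocorr[:, 0].mean() > 0.3

    def test_iid_noise_negative_bias_at_lag1(self):
        rng = np.random.default_rng(1)
        S, V = 30, 500
        noise = rng.standard_normal((V, S))
        panel = BetaPanel(
            betas=np.repeat(noise, 2, axis=1),
            sessions=np.repeat(np.arange(S), 2),
            image_ids=np.arange(S * 2),
            prf_r2=np.ones(V),
        )
        stats = session_series_stats(panel)
        mean_lag1 = stats.autocorr[:, 0].mean()
        assert -0.15 < mean_lag1 < 0.0  # small negative finite-sample bias

    def test_constant_series_excluded_with_warning(self):
        S, n = 5, 4
        betas = np.vstack(
            [np.zeros(S * n), np.repeat(np.arange(S, dtype=float), n)]
        )
        panel = BetaPanel(
            betas=betas,
            sessions=np.repeat(np.arange(S), n),
            image_ids=np.arange(S * n),
            prf_r2=np.ones(2),
        )
        with pytest.warns(UserWarning, match="excluding 1"):
            stats = session_series_stats(panel)
        assert stats.n_excluded == 1

    def test_needs_three_sessions(self):
        panel = BetaPanel(
            betas=np.random.default_rng(0).standard_normal((2, 4)),
            sessions=np.array([0, 0, 1, 1]),
            image_ids=np.arange(4),
            prf_r2=np.ones(2),
        )
        with pytest.raises(ValueError, match="3 sessions"):
            session_series_stats(panel)


# --------------------------------------------------------------------------
# end-to-end dissociation and stability
# --------------------------------------------------------------------------

class TestEndToEnd:
    def test_metric_dissociation(self, baseline_walk_experiment):
        """cvR2 detects the baseline walk; Pearson does not."""
        _, cv = gof_stat(baseline_walk_experiment, metric="cvR2")
        _, pe = gof_stat(baseline_walk_experiment, metric="pearson")
        assert cv.r_empirical < 0 and cv.p < 0.05
        assert pe.p > 0.05

    def test_adjacent_session_stability_under_stationary_snr(self):
        exp = make_experiment(
            n_sessions=20,
            n_voxels=40,
            images_per_session=40,
            noise_sd=1.0,
            seed=9,
        )
        fits = fit_all_sessions(exp.designs, exp.panel)
        M = cross_session_gof(fits, exp.designs, exp.panel)
        prof = adjacent_profile(M)
        idx = np.arange(len(prof), dtype=float)
        r = np.corrcoef(prof, idx)[0, 1]
        assert abs(r) < 0.5  # within ~2 SD of the null spread for 19 points
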