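import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nirselect import (
    MCUVE,
    InvalidConfigurationError,
    augment_noise,
    classical_cutoff,
    generate_dataset,
    mc_reliability,
    robust_cutoff,
    tolerance_k,
    SimulationConfig,
)
from nirselect.mcuve import MCUVEResult, _reliability_from_coefficients, mad


def _result_with_artificial(c_artif):
    """An MCUVEResult carrying given artificial reliabilities."""
    c_artif = np.asarray(c_artif, dtype=float)
    return MCUVEResult(
        reliability=np.array([10.0, 0.1]),
        reliability_artificial=c_artif,
        coefficient_matrix=np.empty((0, 0)),
        mean_coefficients=np.empty(0),
        coefficient_sd=np.empty(0),
        cutoff_value=np.nan,
        cutoff_kind="none",
        selected_mask=np.ones(2, dtype=bool),
    )


class TestAugmentNoise:
    def test_default_count_doubles_width(self, rng):
        X = rng.normal(size=(8, 5))
        X_aug, idx = augment_noise(X, rng=rng)
        assert X_aug.shape == (8, 10)
        np.testing.assert_array_equal(idx, np.arange(5, 10))
        np.testing.assert_array_equal(X_aug[:, :5], X)

    def test_seeded_noise_is_reproducible(self, rng):
        X = rng.normal(size=(6, 4))
        a, _ = augment_noise(X, rng=42)
        b, _ = augment_noise(X, rng=42)
        np.testing.assert_array_equal(a, b)

    def test_amplitude_bounds_column_sum_of_squares(self, rng):
        X = rng.normal(size=(20, 3))
        X_aug, idx = augment_noise(X, amplitude=1e-10, rng=0)
        ss = (X_aug[:, idx] ** 2).sum(axis=0)
        assert (ss <= 1e-20 * 20).all()


class TestReliability:
    def test_hand_computed_reliability(self):
        # coefficients {1, 3} over r=2: c = 2 / sqrt(2) = sqrt(2)
        B = np.array([[1.0], [3.0]])
        c, mean, sd, degen = _reliability_from_coefficients(B)
        assert c[0] == pytest.approx(np.sqrt(2.0))
        assert mean[0] == pytest.approx(2.0)
        assert sd[0] == pytest.approx(np.sqrt(2.0))
        assert not degen.any()

    def test_zero_spread_column_reported_maximally_reliable(self):
        B = np.array([[0.0, 2.0], [0.0, 2.0], [0.0, 2.0]])
        c, _, _, degen = _reliability_from_coefficients(B)
        assert degen.all()
        assert np.isinf(c).all() and c[1] > 0

    def test_reliability_definition_holds_on_real_run(self, small_xy):
        X, y = small_xy
        est = MCUVE(n_components=2, n_resamples=30, random_state=0).fit(X, y)
        B = est.result_.coefficient_matrix
        expect = B.mean(axis=0) / B.std(axis=0, ddof=1)
        got = np.concatenate([est.reliability_, est.reliability_artificial_])
        # column order: real block then artificial block
        np.testing.assert_allclose(got, expect, rtol=1e-10)

    def test_reliability_invariant_to_resample_order(self):
        rng = np.random.default_rng(5)
        B = rng.normal(size=(40, 6))
        c1, *_ = _reliability_from_coefficients(B)
        c2, *_ = _reliability_from_coefficients(B[rng.permutation(40)])
        np.testing.assert_allclose(c1, c2, rtol=1e-12)

    def test_important_variables_more_reliable_than_artificial(self):
        """On synthetic calibration data the truly informative columns
        should out-rank the appended noise columns (majority over seeds)."""
        wins = 0
        for seed in range(20):
            ds = generate_dataset(
                SimulationConfig(60, 101, iv_fraction=0.2, seed=seed)
            )
            X_aug, idx = augment_noise(ds.X, rng=seed)
            res = mc_reliability(
                X_aug, ds.y, idx, n_resamples=60, n_components=5, rng=seed
            )
            med_imp = np.median(np.abs(res.reliability[ds.important_index_set]))
            med_art = np.median(np.abs(res.reliability_artificial))
            wins += med_imp > med_art
        assert wins >= 15

    def test_subsample_too_small_rejected(self, small_xy):
        X, y = small_xy
        with pytest.raises(InvalidConfigurationError):
            mc_reliability(
                X, y, np.arange(0), n_resamples=10,
                subsample_fraction=0.1, n_components=5, rng=0,
            )


class TestClassicalCutoff:
    def test_max_absolute_value(self):
        res = _result_with_artificial([-3.0, 2.0])
        assert classical_cutoff(res) == 3.0
        # |c| >= cutoff stays selected
        np.testing.assert_array_equal(res.selected_mask, [True, False])

    def test_matches_brute_force_on_random_vectors(self, rng):
        c = rng.normal(size=50)
        res = _result_with_artificial(c)
        assert classical_cutoff(res) == max(abs(v) for v in c)

    def test_empty_artificial_set_is_an_error(self):
        with pytest.raises(InvalidConfigurationError):
            classical_cutoff(_result_with_artificial([]))


class TestToleranceK:
    def test_large_r_limit_is_the_gamma_quantile(self):
        tol = tolerance_k(0.95, 0.05, 10**6)
        assert tol.k_factor == pytest.approx(stats.norm.ppf(0.95), rel=5e-3)

    @pytest.mark.parametrize("r", [100, 500])
    def test_agrees_with_noncentral_t_construction(self, r):
        tol = tolerance_k(0.95, 0.05, r)
        z_g = stats.norm.ppf(0.95)
        exact = stats.nct.ppf(0.95, df=r - 1, nc=z_g * np.sqrt(r)) / np.sqrt(r)
        assert tol.k_factor == pytest.approx(exact, rel=0.02)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        gamma=st.floats(0.6, 0.995),
        alpha=st.floats(0.01, 0.4),
        r=st.integers(30, 5000),
    )
    def test_factor_bounds_property(self, gamma, alpha, r):
        """k exceeds the plain gamma-quantile (the confidence margin is
        one-sided upward) and stays within a factor covered by the exact
        noncentral-t construction."""
        tol = tolerance_k(gamma, alpha, r)
        z_g = stats.norm.ppf(gamma)
        assert tol.k_factor >= z_g - 1e-12
        exact = stats.nct.ppf(1 - alpha, df=r - 1, nc=z_g * np.sqrt(r)) / np.sqrt(r)
        assert tol.k_factor == pytest.approx(exact, rel=0.05)

    def test_monotone_in_gamma(self):
        assert (
            tolerance_k(0.99, 0.05, 100).k_factor
            > tolerance_k(0.95, 0.05, 100).k_factor
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            tolerance_k(0.95, 0.05, 2)  # r too small
        with pytest.raises(InvalidConfigurationError):
            tolerance_k(0.95, 0.001, 3)  # a <= 0
        with pytest.raises(InvalidConfigurationError):
            tolerance_k(1.2, 0.05, 100)


class TestRobustCutoff:
    def test_degenerate_spread_returns_the_constant(self):
        res = _result_with_artificial([4.2, 4.2, 4.2])
        tol = tolerance_k(0.95, 0.05, 100)
        assert robust_cutoff(res, tol) == pytest.approx(4.2)

    def test_hand_computation_with_raw_mad(self):
        res = _result_with_artificial([1.0, 2.0, 3.0])
        tol = tolerance_k(0.95, 0.05, 100)
        tol.k_factor = 1.0
        assert robust_cutoff(res, tol, mad_scale="raw") == pytest.approx(3.0)

    def test_selection_uses_signed_reliability(self):
        res = _result_with_artificial([0.0, 0.5, -0.5, 0.2, -0.2])
        tol = tolerance_k(0.95, 0.05, 100)
        cutoff = robust_cutoff(res, tol)
        np.testing.assert_array_equal(
            res.selected_mask, res.reliability > cutoff
        )

    def test_gaussian_coverage(self):
        """Under standard-normal artificial reliabilities the cut-off
        should exclude at least gamma of them (within MC tolerance)."""
        rng = np.random.default_rng(11)
        c = rng.normal(size=10**4)
        res = _result_with_artificial(c)
        tol = tolerance_k(0.95, 0.05, c.size)
        cutoff = robust_cutoff(res, tol)
        frac_above = (c > cutoff).mean()
        assert frac_above <= 0.05 + 0.02

    def test_too_few_artificial_values_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            robust_cutoff(
                _result_with_artificial([1.0, 2.0]), tolerance_k(0.95, 0.05, 10)
            )


class TestBreakdown:
    def test_robust_cutoff_resists_contamination_classical_does_not(self):
        rng = np.random.default_rng(2)
        clean = rng.normal(size=200)
        contaminated = clean.copy()
        contaminated[:50] = 1e6  # 25% gross outliers
        tol = tolerance_k(0.95, 0.05, 200)

        res_clean = _result_with_artificial(clean)
        res_dirty = _result_with_artificial(contaminated)
        robust_clean = robust_cutoff(res_clean, tol)
        robust_dirty = robust_cutoff(res_dirty, tol)
        assert abs(robust_dirty - robust_clean) / abs(robust_clean) < 1.0

        classical_clean = classical_cutoff(_result_with_artificial(clean))
        classical_dirty = classical_cutoff(_result_with_artificial(contaminated))
        assert classical_dirty == pytest.approx(1e6)
        assert classical_dirty > 1e4 * classical_clean


class TestMCUVEEstimator:
    def test_deterministic_given_random_state(self, small_xy):
        X, y = small_xy
        a = MCUVE(n_components=2, n_resamples=25, random_state=3).fit(X, y)
        b = MCUVE(n_components=2, n_resamples=25, random_state=3).fit(X, y)
        np.testing.assert_array_equal(a.reliability_, b.reliability_)
        assert a.cutoff_ == b.cutoff_

    def test_classical_mode_mask(self, small_xy):
        X, y = small_xy
        est = MCUVE(
            n_components=2, n_resamples=25, cutoff="classical", random_state=3
        ).fit(X, y)
        np.testing.assert_array_equal(
            est.selected_mask_, np.abs(est.reliability_) >= est.cutoff_
        )

    def test_reliability_table_layout(self, small_xy):
        X, y = small_xy
        est = MCUVE(n_components=2, n_resamples=25, random_state=3).fit(X, y)
        table = est.to_frame()
        assert set(table.columns) == {
            "variable", "reliability", "artificial", "cutoff", "selected",
        }
        assert len(table) == X.shape[1] * 2  # default: one noise col per real


def test_mad_consistency_factor():
    rng = np.random.default_rng(0)
    x = rng.normal(size=10**5)
    assert mad(x, "normal") == pytest.approx(1.0, rel=0.02)
    assert mad(np.array([1.0, 2.0, 3.0]), "raw") == 1.0
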