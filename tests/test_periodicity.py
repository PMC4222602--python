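import numpy as np
import pytest
from scipy import stats
from statsmodels.robust.norms import TukeyBiweight
from statsmodels.robust.robust_linear_model import RLM
from statsmodels.stats.multitest import multipletests

from hairwave.periodicity import (
    FourierBasis,
    GridError,
    RegressionError,
    UndefinedStatisticError,
    bh_fdr,
    build_frequency_grid,
    fit_fourier_robust,
    g_statistic,
    gpd_tail_pvalue,
    permutation_pvalue,
    phase_shift_days,
    power_spectrum,
    principal_component,
)


class TestFrequencyGrid:
    def test_default_synthetic_grid_contains_monthly_period(self, default_sim):
        ds, _ = default_sim
        basis = build_frequency_grid(ds.merged_day)
        assert np.any(np.isclose(basis.frequencies, 1.0 / 31.0))

    def test_all_frequencies_below_sampling_mask_bound(self, default_sim):
        ds, _ = default_sim
        basis = build_frequency_grid(ds.merged_day)
        min_dt = np.diff(np.unique(ds.merged_day)).min()
        assert np.all(basis.frequencies < 1.0 / (3.0 * min_dt) + 1e-12)

    def test_sparse_grid_raises(self):
        with pytest.raises(GridError):
            build_frequency_grid(np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0]))

    def test_too_few_times_raises(self):
        with pytest.raises(GridError):
            build_frequency_grid(np.array([0.0, 5.0, 10.0]))

    def test_basis_validation(self):
        with pytest.raises(GridError):
            FourierBasis(np.array([0.2, 0.1]))


class TestRobustFourierFit:
    times = np.linspace(0.0, 40.0, 28)
    basis = FourierBasis(np.array([1 / 31.0, 2 / 31.0]))

    def test_exact_harmonic_recovered(self):
        y = 5.0 + 2.0 * np.cos(2 * np.pi * self.times / 31.0)
        fit = fit_fourier_robust(y, self.times, self.basis)
        assert fit.a0 == pytest.approx(5.0, abs=1e-8)
        assert fit.a[0] == pytest.approx(2.0, abs=1e-8)
        assert fit.b[0] == pytest.approx(0.0, abs=1e-8)
        assert np.max(np.abs(fit.residuals)) < 1e-8
        np.testing.assert_array_equal(fit.weights, 1.0)

    def test_single_outlier_downweighted(self, rng):
        clean = 5.0 + 2.0 * np.cos(2 * np.pi * self.times / 31.0) + rng.normal(0, 0.1, 28)
        X = self.basis.design_matrix(self.times)
        beta_clean, *_ = np.linalg.lstsq(X, clean, rcond=None)
        y = clean.copy()
        y[7] += 10.0
        fit = fit_fourier_robust(y, self.times, self.basis)
        assert fit.weights[7] < 0.1
        assert abs(fit.a0 - beta_clean[0]) < 0.05
        assert abs(fit.a[0] - beta_clean[1]) < 0.05
        assert abs(fit.b[0] - beta_clean[2]) < 0.05

    def test_constant_signal_flat_fit(self):
        fit = fit_fourier_robust(np.full(28, 3.0), self.times, self.basis)
        assert fit.a0 == pytest.approx(3.0, abs=1e-9)
        np.testing.assert_allclose(fit.a, 0.0, atol=1e-9)
        np.testing.assert_allclose(fit.b, 0.0, atol=1e-9)

    def test_matches_statsmodels_rlm(self, rng):
        """Independent M-estimator oracle: statsmodels RLM, Tukey biweight."""
        y = 5.0 + 2.0 * np.cos(2 * np.pi * self.times / 31.0) + rng.normal(0, 0.3, 28)
        y[3] += 6.0
        X = self.basis.design_matrix(self.times)
        ours = fit_fourier_robust(y, self.times, self.basis)
        ref = RLM(y, X, M=TukeyBiweight(4.685)).fit()
        beta = np.concatenate([[ours.a0], np.ravel(np.column_stack([ours.a, ours.b]))])
        np.testing.assert_allclose(beta, ref.params, atol=0.05)

    def test_rank_deficient_design_raises(self):
        times = np.zeros(28)
        with pytest.raises(RegressionError):
            fit_fourier_robust(np.ones(28), times, self.basis)


class TestSpectrumAndG:
    def test_power_spectrum_hand_value(self):
        fit = type("F", (), {"a": np.array([3.0, 0.0]), "b": np.array([4.0, 0.0])})
        np.testing.assert_allclose(power_spectrum(fit, 20), [125.0, 0.0])

    def test_equal_amplitudes_equal_power(self):
        fit = type("F", (), {"a": np.array([1.0, 0.6]), "b": np.array([0.6, 1.0])})
        s = power_spectrum(fit, 10)
        assert s[0] == pytest.approx(s[1])

    @pytest.mark.parametrize(
        "spec,expected",
        [([25, 0, 0], 1.0), ([1, 1, 1, 1], 0.25), ([3, 1], 0.75)],
    )
    def test_g_oracle_values(self, spec, expected):
        assert g_statistic(np.array(spec, float)) == pytest.approx(expected)

    def test_g_scale_invariant(self, rng):
        s = rng.uniform(0.1, 5.0, size=8)
        assert g_statistic(s) == pytest.approx(g_statistic(137.0 * s))

    def test_zero_spectrum_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            g_statistic(np.zeros(4))


class TestPrincipalComponent:
    times = np.linspace(0.0, 62.0, 40)
    basis = FourierBasis(np.array([1 / 31.0, 2 / 31.0, 3 / 31.0]))

    def fit_of(self, y):
        return fit_fourier_robust(y, self.times, self.basis)

    def test_cosine_phase_zero(self):
        freq, amp, phase = principal_component(
            self.fit_of(np.cos(2 * np.pi * self.times / 31.0)), self.basis, 40
        )
        assert freq == pytest.approx(1 / 31.0)
        assert amp == pytest.approx(1.0, abs=1e-8)
        assert phase == pytest.approx(0.0, abs=1e-8)

    def test_sine_phase_quarter_period(self):
        freq, amp, phase = principal_component(
            self.fit_of(np.sin(2 * np.pi * self.times / 31.0)), self.basis, 40
        )
        assert phase == pytest.approx(np.pi / 2, abs=1e-8)
        assert phase_shift_days(freq, phase, 0.0) == pytest.approx(31.0 / 4, abs=1e-6)

    def test_dominant_monthly_among_harmonics(self):
        y = (
            2.0 * np.cos(2 * np.pi * self.times / 31.0)
            + 0.5 * np.cos(2 * np.pi * 2 * self.times / 31.0)
            + 0.3 * np.sin(2 * np.pi * 3 * self.times / 31.0)
        )
        freq, _, _ = principal_component(self.fit_of(y), self.basis, 40)
        assert freq == pytest.approx(1 / 31.0)


class TestPhaseShift:
    def test_max_at_day_33_from_ref_24(self):
        f = 1.0 / 31.0
        phase = 2 * np.pi * f * 33.0  # maximum at day 33
        assert phase_shift_days(f, phase, 24.0) == pytest.approx(9.0, abs=1e-9)

    def test_max_exactly_at_ref_is_zero(self):
        f = 1.0 / 31.0
        phase = 2 * np.pi * f * 24.0
        assert phase_shift_days(f, phase, 24.0) == pytest.approx(0.0, abs=1e-9)

    def test_out_of_phase_maxima_half_period_apart(self):
        f = 1.0 / 31.0
        s1 = phase_shift_days(f, 2 * np.pi * f * 33.0, 24.0)
        s2 = phase_shift_days(f, 2 * np.pi * f * 48.0, 24.0)
        assert s2 - s1 == pytest.approx(15.0, abs=1e-9)
        assert s2 - s1 == pytest.approx(31.0 / 2, abs=0.6)


class TestBenjaminiHochberg:
    def test_hand_executed_step_up(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.01, 0.02, 0.04])), [0.03, 0.03, 0.04])

    def test_all_ones_and_singleton(self):
        np.testing.assert_array_equal(bh_fdr(np.ones(5)), 1.0)
        assert bh_fdr(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(size=200) ** 2
        ours = bh_fdr(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, rtol=1e-12)

    def test_monotone_in_p_rank(self, rng):
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestPermutationPvalue:
    def test_pure_sinusoid_hits_floor(self, default_sim):
        ds, _ = default_sim
        t = ds.merged_day
        rng = np.random.default_rng(0)
        y = 8.0 + 4.0 * np.cos(2 * np.pi * t / 31.0) + rng.normal(0, 1.0, len(t))
        basis = build_frequency_grid(t)
        p, n_used, used_gpd = permutation_pvalue(
            y, t, basis, n_perm=999, seed=2, use_gpd=False
        )
        assert n_used == 999
        assert p == pytest.approx(1.0 / 1000.0)

    def test_weak_signal_large_p(self, default_sim, rng):
        ds, _ = default_sim
        t = ds.merged_day
        y = rng.normal(0, 1.0, len(t))
        basis = build_frequency_grid(t)
        p, _, _ = permutation_pvalue(y, t, basis, n_perm=200, seed=3)
        assert p > 0.05

    def test_seed_reproducible(self, default_sim):
        ds, _ = default_sim
        t = ds.merged_day
        y = np.log2(ds.values[0])
        basis = build_frequency_grid(t)
        a = permutation_pvalue(y, t, basis, n_perm=150, seed=11)
        b = permutation_pvalue(y, t, basis, n_perm=150, seed=11)
        assert a == b

    def test_too_few_permutations_rejected(self, default_sim):
        ds, _ = default_sim
        basis = build_frequency_grid(ds.merged_day)
        with pytest.raises(ValueError):
            permutation_pvalue(np.log2(ds.values[0]), ds.merged_day, basis, n_perm=10)


class TestGpdTail:
    def test_within_factor_three_of_large_sample_truth(self):
        """GPD refinement vs a one-million-draw empirical oracle on an
        exponential-tailed null."""
        rng = np.random.default_rng(1)
        big = rng.exponential(size=1_000_000)
        observed = np.quantile(big, 0.9995)
        p_true = np.mean(big >= observed)
        small = big[:500]
        p_gpd, ok = gpd_tail_pvalue(small, observed)
        assert ok
        assert p_true / 3 < p_gpd < p_true * 3

    def test_observed_below_threshold_fails_over_to_empirical(self):
        null = np.linspace(0, 1, 500)
        p, ok = gpd_tail_pvalue(null, observed=0.2)
        assert not ok and np.isnan(p)


class TestNullUniformity:
    def test_pvalues_uniform_on_pure_noise(self, default_sim):
        """Permutation p-values on noise probes are approximately uniform."""
        ds, _ = default_sim
        t = ds.merged_day
        basis = build_frequency_grid(t)
        rng = np.random.default_rng(7)
        pvals = []
        for j in range(200):
            y = rng.normal(0.0, 1.0, size=len(t))
            p, _, _ = permutation_pvalue(y, t, basis, n_perm=500, seed=j, use_gpd=False)
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
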