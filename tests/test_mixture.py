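import numpy as np
import pytest

from hairwave.mixture import (
    ScaleError,
    UnidentifiableError,
    assign_populations,
    cod_per_gene,
    feedback_candidates,
    fit_mixture,
    negative_control,
    population_expression_stats,
    solve_fractions,
)
from hairwave.simulate import (
    SimulationConfig,
    cycle_phase,
    simulate_dataset,
)


def canonical(f):
    return (f - f.min()) / np.ptp(f)


@pytest.fixture(scope="module")
def noiseless_fit():
    cfg = SimulationConfig(
        noise_sd_log2=0.0, phase_jitter_sd=0.0, n_noise_probes=0,
        n_feedback_probes=0, seed=2,
    )
    ds, truth = simulate_dataset(cfg)
    return ds, truth, fit_mixture(ds, tol=1e-10)


@pytest.fixture(scope="module")
def default_fit(default_sim):
    ds, truth = default_sim
    return ds, truth, fit_mixture(ds)


class TestSolveFractions:
    y1 = np.array([10.0, 1.0, 6.0])
    y2 = np.array([2.0, 9.0, 3.0])

    def test_pure_population_endpoints(self):
        assert solve_fractions(self.y1, self.y1, self.y2) == pytest.approx(1.0)
        assert solve_fractions(self.y2, self.y1, self.y2) == pytest.approx(0.0)

    def test_overshoot_clipped_to_one(self):
        x = self.y2 + 2.0 * (self.y1 - self.y2)
        assert solve_fractions(x, self.y1, self.y2) == 1.0

    def test_identical_populations_unidentifiable(self):
        with pytest.raises(UnidentifiableError):
            solve_fractions(self.y1, self.y1, self.y1)


class TestFitMixture:
    def test_noiseless_recovery_to_machine_precision(self, noiseless_fit):
        """Up to the affine gauge of the mixing model, the noiseless fit
        reproduces the generating fractions and the data exactly."""
        ds, truth, fit = noiseless_fit
        np.testing.assert_allclose(
            canonical(fit.fractions), canonical(truth.fractions), atol=1e-6
        )
        np.testing.assert_allclose(fit.fitted(), ds.values, rtol=1e-6)

    def test_objective_monotone_nonincreasing(self, default_fit):
        _, _, fit = default_fit
        obj = np.asarray(fit.objective)
        assert np.all(np.diff(obj) <= 1e-6 * obj[:-1])

    def test_fraction_rises_and_collapses(self, default_fit):
        ds, truth, fit = default_fit
        phase = cycle_phase(ds)
        f = canonical(fit.fractions)
        assert f[(phase > 10) & (phase < 16)].mean() > 0.7
        assert f[phase > 23].mean() < 0.1
        assert f[phase < 1].mean() < 0.3

    def test_recovery_rmse_over_seeds(self):
        """Across replicate simulations at default noise the gauge-matched
        fraction trajectory is recovered to RMSE < 0.05."""
        errs = []
        for seed in range(20):
            ds, truth = simulate_dataset(SimulationConfig(seed=seed))
            fit = fit_mixture(ds)
            errs.append(
                np.sqrt(np.mean((canonical(fit.fractions) - canonical(truth.fractions)) ** 2))
            )
        assert np.mean(errs) < 0.05
        assert np.max(errs) < 0.1

    def test_population_expression_relative_error(self, default_fit):
        ds, truth, fit = default_fit
        cl = np.isin(truth.labels, ["cluster1", "cluster2"])
        # the mixing model is identifiable up to an affine gauge of f;
        # estimate the gauge map truth = alpha f_hat + beta and extrapolate
        # the fitted line to true f = 1 and f = 0
        A = np.column_stack([fit.fractions, np.ones_like(fit.fractions)])
        (alpha, beta), *_ = np.linalg.lstsq(A, truth.fractions, rcond=None)
        d = fit.y_expanding - fit.y_background
        y1_pred = fit.y_background + d * (1.0 - beta) / alpha
        y2_pred = fit.y_background + d * (0.0 - beta) / alpha
        rel1 = np.abs(y1_pred - truth.y_expanding) / truth.y_expanding
        rel2 = np.abs(y2_pred - truth.y_background) / truth.y_background
        # pooled across both populations of all cluster genes
        assert np.median(np.concatenate([rel1[cl], rel2[cl]])) < 0.10
        # each cluster's dominant population is recovered tightly; the 8x
        # lower minor component is proportionally noisier
        c1 = truth.labels == "cluster1"
        c2 = truth.labels == "cluster2"
        assert np.median(rel1[c1]) < 0.10
        assert np.median(rel2[c2]) < 0.10

    def test_scale_equivariance(self, small_sim):
        ds, _ = small_sim
        fit1 = fit_mixture(ds)
        ds2 = ds.copy()
        ds2.values *= 3.7
        fit2 = fit_mixture(ds2)
        np.testing.assert_allclose(fit2.fractions, fit1.fractions, atol=1e-4)
        np.testing.assert_allclose(fit2.y_expanding, 3.7 * fit1.y_expanding, rtol=1e-3)

    def test_log2_input_rejected(self, small_sim):
        ds, _ = small_sim
        with pytest.raises(ScaleError):
            fit_mixture(ds.to_log2())


class TestExpressionStats:
    def test_matches_normal_equations_oracle(self):
        """Hand-computed 4-sample single-gene regression on [f, 1-f]."""
        f = np.array([0.1, 0.4, 0.7, 0.9])
        x = np.array([[3.0, 5.0, 8.0, 9.5]])
        D = np.column_stack([f, 1 - f])
        beta = np.linalg.solve(D.T @ D, D.T @ x[0])
        resid = x[0] - D @ beta
        sigma2 = resid @ resid / 2
        cov = sigma2 * np.linalg.inv(D.T @ D)
        se_diff = np.sqrt(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
        out = population_expression_stats(x, f)
        assert out["y1"][0] == pytest.approx(beta[0], abs=1e-10)
        assert out["y2"][0] == pytest.approx(beta[1], abs=1e-10)
        assert out["se_diff"][0] == pytest.approx(se_diff, abs=1e-10)
        assert out["t"][0] == pytest.approx((beta[0] - beta[1]) / se_diff, abs=1e-10)

    def test_equal_populations_zero_t(self):
        f = np.linspace(0, 1, 8)
        x = np.full((1, 8), 4.0)
        out = population_expression_stats(x, f)
        assert out["t"][0] == pytest.approx(0.0, abs=1e-8)

    def test_strong_separation_extreme_t(self, rng):
        f = np.linspace(0, 1, 20)
        x = (5000.0 * f + 10.0 * (1 - f) + rng.normal(0, 1, 20))[None, :]
        out = population_expression_stats(x, f)
        assert out["t"][0] > 10

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            population_expression_stats(np.ones((1, 2)), np.array([0.2, 0.8]))


class TestAssignments:
    def test_nearly_all_lfo_assigned(self, default_fit):
        ds, truth, fit = default_fit
        lfo = np.isin(truth.labels, ["cluster1", "cluster2", "feedback"])
        out = assign_populations(fit.t_stat, fit.q_value, lfo)
        assert np.mean(out[lfo] != "none") >= 0.95
        assert np.all(out[~lfo] == "none")

    def test_assignment_matches_true_population(self, default_fit):
        ds, truth, fit = default_fit
        out = assign_populations(
            fit.t_stat, fit.q_value, np.isin(truth.labels, ["cluster1", "cluster2"])
        )
        c1 = truth.labels == "cluster1"
        c2 = truth.labels == "cluster2"
        # assigned probes always land in their generating population
        assert np.all(out[c1 & (out != "none")] == "expanding")
        assert np.all(out[c2 & (out != "none")] == "background")
        assert np.mean(out[c1] == "expanding") > 0.9
        assert np.mean(out[c2] == "background") > 0.9

    def test_insignificant_q_left_unassigned(self):
        out = assign_populations(
            np.array([5.0, 5.0]), np.array([0.05, 0.2]), np.array([True, True]), fdr=0.10
        )
        assert list(out) == ["expanding", "none"]


class TestCod:
    def test_noiseless_gene_cod_one(self, noiseless_fit):
        _, _, fit = noiseless_fit
        assert np.nanmin(fit.cod) > 1 - 1e-9

    def test_pure_noise_cod_near_zero(self, default_fit):
        _, truth, fit = default_fit
        noise_cod = fit.cod[truth.labels == "noise"]
        assert abs(np.nanmedian(noise_cod)) < 0.1

    def test_feedback_cod_below_static_cluster2(self, default_fit):
        _, truth, fit = default_fit
        assert np.nanmax(fit.cod[truth.labels == "feedback"]) < np.nanmin(
            fit.cod[truth.labels == "cluster2"]
        )

    def test_zero_variance_gene_flagged_nan(self):
        f = np.linspace(0, 1, 6)
        cod = cod_per_gene(np.full((1, 6), 2.0), f, np.array([2.0]), np.array([2.0]))
        assert np.isnan(cod[0])


class TestNegativeControl:
    def test_no_phase_aligned_expansion(self, small_sim):
        """Shuffled time courses show no anagen-rise / telogen-collapse
        structure in the fitted fraction trajectory."""
        ds, truth = small_sim
        phase = cycle_phase(ds)
        anagen = (phase > 5) & (phase < 18)
        telogen = phase > 23
        real = fit_mixture(ds)
        contrast_real = canonical(real.fractions)[anagen].mean() - canonical(
            real.fractions
        )[telogen].mean()
        assert contrast_real > 0.5
        contrasts = []
        for seed in (0, 1, 2):
            null = negative_control(ds, seed=seed)
            fc = canonical(null.fractions)
            contrasts.append(fc[anagen].mean() - fc[telogen].mean())
        assert max(abs(c) for c in contrasts) < 0.5

    def test_lfo_cod_not_improved(self, small_sim):
        ds, truth = small_sim
        null = negative_control(ds, seed=1)
        lfo = np.isin(truth.labels, ["cluster1", "cluster2", "feedback"])
        diff = np.nanmedian(null.cod[lfo]) - np.nanmedian(null.cod[~lfo])
        assert abs(diff) < 0.1


class TestFeedbackScreen:
    def test_sensitivity_and_false_positives(self):
        """Planted catagen-onset signals are recovered by the screen with
        high mean sensitivity and essentially no false positives."""
        sens = []
        n_false = 0
        n_hits = 0
        for seed in (0, 1, 2):
            ds, truth = simulate_dataset(SimulationConfig(seed=seed))
            fit = fit_mixture(ds)
            lfo = np.isin(truth.labels, ["cluster1", "cluster2", "feedback"])
            clusters = np.zeros(ds.n_probes, dtype=int)
            clusters[truth.labels == "cluster1"] = 1
            clusters[np.isin(truth.labels, ["cluster2", "feedback"])] = 2
            table = feedback_candidates(ds, fit, clusters, lfo)
            hits = set(table["probe_id"])
            fb = set(ds.probe_ids[truth.labels == "feedback"])
            sens.append(len(hits & fb) / len(fb))
            n_false += len(hits - fb)
            n_hits += len(hits)
        assert np.mean(sens) >= 0.9
        assert min(sens) >= 0.75
        assert n_false <= 0.05 * n_hits + 1

    def test_static_cluster2_probe_excluded(self, default_fit):
        ds, truth, fit = default_fit
        clusters = np.where(truth.labels == "cluster2", 2, 0)
        lfo = truth.labels == "cluster2"
        table = feedback_candidates(ds, fit, clusters, lfo)
        assert len(table) == 0

    def test_empty_window_rejected(self, default_fit):
        ds, truth, fit = default_fit
        with pytest.raises(ValueError):
            feedback_candidates(
                ds, fit, np.full(ds.n_probes, 2), np.ones(ds.n_probes, bool),
                window=(200.0, 210.0),
            )
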