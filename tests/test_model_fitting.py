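import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fedbatch.model_fitting import (
    DEOptions,
    MAX_ELIMINATION_ITERATIONS,
    _layout,
    _predict,
    aicc,
    aicc_standard,
    eliminate_terms,
    elimination_path,
    f_test,
    fit_rate,
    goodness,
)
from fedbatch.records import RateObservations

from fedbatch.validation import exact_rate_observations as synthetic_observations

FAST = DEOptions.fast()


class TestFitRate:
    def test_exact_recovery_from_model_generated_rates(self, truth,
                                                       param_error_fn):
        """Observations computed directly from a known parameter set are
        recovered to better than 1% with essentially zero residual."""
        obs = synthetic_observations(truth, n=200, seed=1)
        fits = {}
        for rate in ("uptake", "maintenance", "production"):
            fits[rate] = fit_rate(obs, rate, mask=truth.rates[rate].mask,
                                  seed=2)
        from fedbatch.model_fitting import assemble_parameter_set
        fitted = assemble_parameter_set(fits, truth.Y_XrG, truth.Y_PG)
        errs = param_error_fn(truth, fitted)
        assert max(abs(v) for v in errs.values()) < 0.01, errs
        for rate, f in fits.items():
            assert f.rss < 1e-10 * max(f.tss, 1e-12)

    def test_constant_mask_returns_weighted_mean(self, truth):
        obs = synthetic_observations(truth, n=60, seed=3)
        mask = {"temp": False, "gamma_uptake": False, "G": False, "n": False,
                "PX": False, "X": False}
        fit = fit_rate(obs, "maintenance", mask, seed=0, de_options=FAST)
        y = obs.data["gamma_alpha_hat"].to_numpy()
        assert fit.rate_law.c == pytest.approx(float(np.mean(y)), rel=1e-6)
        assert fit.rss == pytest.approx(float(np.sum((y - y.mean()) ** 2)),
                                        rel=1e-9)

    def test_duplicated_rows_same_estimate_double_rss(self, truth):
        obs = synthetic_observations(truth, n=80, seed=4)
        dup = RateObservations(
            data=pd.concat([obs.data, obs.data], ignore_index=True),
            Y_XrG=obs.Y_XrG, Y_PG=obs.Y_PG)
        f1 = fit_rate(obs, "uptake", truth.uptake.mask, seed=5,
                      de_options=FAST)
        f2 = fit_rate(dup, "uptake", truth.uptake.mask, seed=5,
                      de_options=FAST)
        np.testing.assert_allclose(f2.theta, f1.theta, rtol=1e-4)
        assert f2.rss == pytest.approx(2 * f1.rss, rel=1e-3)

    def test_seeded_determinism(self, truth):
        obs = synthetic_observations(truth, n=60, seed=6)
        a = fit_rate(obs, "production", truth.production.mask, seed=7)
        b = fit_rate(obs, "production", truth.production.mask, seed=7)
        assert np.array_equal(a.theta, b.theta)
        assert a.rss == b.rss

    def test_predict_matches_rate_law_evaluation(self, truth):
        """The flat-vector prediction used inside the optimizer agrees with
        the RateLaw object evaluation (dual-route consistency)."""
        obs = synthetic_observations(truth, n=40, seed=8)
        from fedbatch.model_fitting import _rate_rows, _theta_to_rate_law
        for rate in ("uptake", "maintenance", "production"):
            rl_true = truth.rates[rate]
            y, covs, w = _rate_rows(obs, rate)
            names, lims = _layout(rate, rl_true.mask, covs, None)
            rng = np.random.default_rng(9)
            theta = np.array([rng.uniform(lo, hi) for lo, hi in lims])
            pred_flat = _predict(rate, rl_true.mask, names, theta, covs)
            rl = _theta_to_rate_law(rate, rl_true.mask, names, theta)
            scale = rl.scale(covs["T"])
            if rate == "maintenance":
                direct = scale * rl.modifier_factor(
                    {m: covs[m] for m in
                     ("gamma_uptake", "G", "n", "PX", "X")})
            else:
                x = covs["G"] if rate == "uptake" else covs["surplus"]
                sat = x / (rl.Km + x) if rl.mask.get("Km") else (x > 0)
                direct = scale * sat * rl.modifier_factor(
                    {m: covs[m] for m in ("G", "n", "PX", "X")})
            np.testing.assert_allclose(pred_flat, direct, rtol=1e-10)

    def test_population_prediction_matches_single(self, truth):
        obs = synthetic_observations(truth, n=30, seed=10)
        from fedbatch.model_fitting import _rate_rows
        y, covs, w = _rate_rows(obs, "production")
        mask = truth.production.mask
        names, lims = _layout("production", mask, covs, None)
        rng = np.random.default_rng(11)
        pop = np.column_stack([
            np.array([rng.uniform(lo, hi) for lo, hi in lims])
            for _ in range(5)
        ])
        batch = _predict("production", mask, names, pop, covs)
        for j in range(5):
            single = _predict("production", mask, names, pop[:, j], covs)
            np.testing.assert_allclose(batch[:, j], single, rtol=1e-14)

    def test_empty_data_rejected(self, truth):
        obs = synthetic_observations(truth, n=10, seed=12)
        obs.data["valid_uptake"] = False
        with pytest.raises(ValueError):
            fit_rate(obs, "uptake", truth.uptake.mask, seed=0)


class TestFTest:
    def test_no_improvement_p_one(self):
        assert f_test(1.0, 1.0, 1, 10) == 1.0

    def test_hand_value_against_t_distribution(self):
        """F(1, n) equals t(n)^2: an independent route to the p-value."""
        p = f_test(1.0, 2.0, 1, 10)
        p_t = 2 * stats.t.sf(np.sqrt(10.0), 10)
        assert p == pytest.approx(p_t, rel=1e-12)
        assert p == pytest.approx(0.0101195597, rel=1e-6)

    def test_scale_invariance(self):
        assert f_test(3.0, 4.5, 2, 17) == pytest.approx(
            f_test(6.0, 9.0, 2, 17), rel=1e-14)

    def test_perfect_fit_convention(self):
        assert f_test(0.0, 0.5, 1, 10) == 0.0
        assert f_test(0.0, 0.0, 1, 10) == 1.0

    def test_reduced_better_than_full_floored(self):
        assert f_test(2.0, 1.5, 1, 10) == 1.0

    def test_invalid_dof(self):
        with pytest.raises(ValueError):
            f_test(1.0, 2.0, 0, 10)


class TestAicc:
    def test_as_printed_hand_value(self):
        assert aicc(1.0, 1, 10) == pytest.approx(12.3333333333, rel=1e-10)

    def test_rss_scaling_shifts_by_n_points(self):
        base = aicc(2.0, 3, 40)
        assert aicc(2.0 * np.e, 3, 40) == pytest.approx(base + 40, rel=1e-12)

    def test_fewer_params_win_at_equal_rss_small_sample(self):
        # the small-sample penalty dominates at low n; direct evaluation
        assert aicc(1.0, 2, 8) < aicc(1.0, 3, 8)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            aicc(1.0, 7, 10)

    def test_standard_variant_differs(self):
        assert aicc_standard(1.0, 1, 10) != pytest.approx(aicc(1.0, 1, 10))


class TestGoodness:
    def test_perfect_prediction(self):
        y = np.arange(10.0)
        g = goodness(y, y, 2)
        assert g["R2"] == 1.0 and g["R2_adj"] == 1.0

    def test_mean_predictor_zero_r2(self):
        y = np.arange(10.0)
        g = goodness(np.full(10, y.mean()), y, 2)
        assert g["R2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        """10 points, 2 variables, RSS/TSS = 0.3 -> R2=0.7, adj 0.6143."""
        rng = np.random.default_rng(0)
        meas = rng.normal(5, 1, 10)
        resid = meas - meas.mean()
        tss = float(np.sum(resid**2))
        # build predictions with RSS exactly 0.3*TSS along the residual dir
        pred = meas - np.sqrt(0.3) * resid
        g = goodness(pred, meas, 2)
        assert g["R2"] == pytest.approx(0.7, rel=1e-12)
        assert g["R2_adj"] == pytest.approx(0.6142857142857143, rel=1e-12)

    def test_constant_measurements_rejected(self):
        with pytest.raises(ValueError):
            goodness(np.arange(5.0), np.full(5, 2.0), 1)


class TestElimination:
    def test_alpha_one_removes_every_uninformative_term(self, truth):
        """At the degenerate threshold alpha=1 every term whose removal does
        not change the fit (p = 1 exactly on noise-free data) is removed, one
        per iteration in p order; informative terms and the non-removable
        saturation constant survive."""
        obs = synthetic_observations(truth, n=120, seed=13)
        mask, fit, trace = eliminate_terms(obs, "uptake", alpha=1.0, seed=0,
                                           de_options=FAST)
        assert mask["Km"] is True  # non-removable
        assert mask == truth.uptake.mask  # exactly the informative structure
        removed = [s.removed for s in trace.steps if s.removed]
        assert sorted(removed) == ["PX", "X", "n", "temp"]
        assert len(trace.steps) <= MAX_ELIMINATION_ITERATIONS

    def test_trace_capped_at_seven_iterations(self, truth):
        assert MAX_ELIMINATION_ITERATIONS == 7
        obs = synthetic_observations(truth, n=120, seed=14)
        path = elimination_path(obs, "production", seed=0, de_options=FAST)
        assert len(path) <= 7

    def test_greedy_rss_monotone_along_path(self, truth):
        """Working-model RSS never decreases across iterations for
        exactly-nested removals.  Dropping the temperature unit is the one
        non-nested step (the activation-energy bound keeps an active law from
        being perfectly flat), so the path may dip by at most the forced-tilt
        amount there."""
        obs = synthetic_observations(truth, n=120, seed=15, noise=0.05)
        path = elimination_path(obs, "maintenance", seed=0, de_options=FAST)
        for i in range(len(path) - 1):
            _, fit, step = path[i]
            _, fit_next, _ = path[i + 1]
            slack = 0.05 if step.removed == "temp" else 0.01
            assert fit_next.rss >= fit.rss * (1 - slack), step.removed

    def test_recovers_true_structure_from_exact_rates(self, truth):
        """Backward elimination at alpha=0.2 keeps exactly the generating
        terms when the observations carry no estimation error."""
        obs = synthetic_observations(truth, n=200, seed=16)
        for rate in ("uptake", "maintenance", "production"):
            mask, _, _ = eliminate_terms(obs, rate, alpha=0.2, seed=1)
            assert mask == truth.rates[rate].mask, rate

    def test_removed_terms_never_reenter(self, truth):
        obs = synthetic_observations(truth, n=120, seed=17, noise=0.1)
        path = elimination_path(obs, "uptake", seed=0, de_options=FAST)
        removed = set()
        for mask, _, step in path:
            assert all(not mask[t] for t in removed)
            if step.removed is not None:
                removed.add(step.removed)


class TestExhaustiveAicc:
    def test_enumeration_count_and_agreement(self, truth):
        """All admissible masks are fitted; with a strong single-structure
        signal the AICc choice matches the F-test elimination choice."""
        from fedbatch.model_fitting import exhaustive_aicc_select

        obs = synthetic_observations(truth, n=200, seed=18)
        best_mask, table = exhaustive_aicc_select(obs, "uptake", seed=1,
                                                  de_options=FAST)
        assert len(table) == 2 ** 5  # Km always present; 5 toggles
        elim_mask, _, _ = eliminate_terms(obs, "uptake", alpha=0.2, seed=1)
        assert best_mask == elim_mask == truth.uptake.mask
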