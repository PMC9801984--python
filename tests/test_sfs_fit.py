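import math

import numpy as np
import pytest

from declinesim.sfs import FoldedSFS, expected_folded_sfs
from declinesim.sfs_fit import (
    MODEL_IDS,
    DemographyModel,
    FitResult,
    classify_trend,
    composite_loglik,
    fit_all_models,
    fit_model,
    select_model,
)

MU = 1e-8


def _expected_obs(model: DemographyModel, n=50, L=5e6, timepoints=(0,), gen_time=1.0):
    hist = model.history(gen_time)
    return [
        expected_folded_sfs(hist, n, L, MU, sample_time_generations=t / gen_time, timepoint=t)
        for t in timepoints
    ]


class TestCompositeLoglik:
    def test_single_bin_poisson_arithmetic(self):
        # a site class with expectation 10 observed 10 times:
        # term = 10 ln 10 - 10 - ln(10!)
        model = DemographyModel("M1_constant", {"N_constant": 250.0})
        hist = model.history(1.0)
        obs = _expected_obs(model, n=2, L=10.0 / (4 * 250.0 * MU))
        assert obs[0].counts[0] == pytest.approx(10.0)
        ll = composite_loglik(model, obs, 1.0, MU)
        mono = obs[0].L - 10.0
        expected_ll = (
            10 * math.log(10) - 10 - math.lgamma(11)
            + mono * math.log(mono) - mono - math.lgamma(mono + 1)
        )
        assert ll == pytest.approx(expected_ll, rel=1e-8)

    def test_maximum_at_truth(self):
        truth = DemographyModel("M1_constant", {"N_constant": 800.0})
        obs = _expected_obs(truth)
        ll_true = composite_loglik(truth, obs, 1.0, MU)
        for other in (700.0, 900.0):
            model = DemographyModel("M1_constant", {"N_constant": other})
            assert composite_loglik(model, obs, 1.0, MU) < ll_true

    def test_empty_timepoint_ignored(self):
        truth = DemographyModel("M1_constant", {"N_constant": 500.0})
        obs = _expected_obs(truth)
        padded = obs + [FoldedSFS(30, 0, obs[0].L, np.zeros(0))]
        assert composite_loglik(truth, padded, 1.0, MU) == pytest.approx(
            composite_loglik(truth, obs, 1.0, MU)
        )

    def test_multi_timepoint_additive(self):
        truth = DemographyModel(
            "M2_recent", {"N_contemp": 300.0, "N_historic": 900.0, "T_rc": 60.0}
        )
        obs = _expected_obs(truth, timepoints=(0, 120))
        ll_both = composite_loglik(truth, obs, 1.0, MU)
        ll_sep = sum(composite_loglik(truth, [o], 1.0, MU) for o in obs)
        assert ll_both == pytest.approx(ll_sep)


class TestFitModel:
    def test_m1_recovery(self):
        truth = DemographyModel("M1_constant", {"N_constant": 1234.0})
        fit = fit_model("M1_constant", _expected_obs(truth), 1.0, MU, n_starts=3, seed=1)
        assert fit.converged
        assert fit.Ne_C_hat == pytest.approx(1234.0, rel=0.01)

    def test_m2_recovery(self):
        truth = DemographyModel(
            "M2_recent", {"N_contemp": 300.0, "N_historic": 1000.0, "T_rc": 30.0}
        )
        fit = fit_model(
            "M2_recent", _expected_obs(truth, n=100, L=2e7), 1.0, MU, n_starts=5, seed=2
        )
        assert fit.converged
        assert fit.Ne_C_hat == pytest.approx(300.0, rel=0.1)
        assert fit.Ne_H_hat == pytest.approx(1000.0, rel=0.1)

    def test_bound_hit_flagged(self):
        # truth far outside the optimizer bounds pins a parameter at a bound
        obs = [
            FoldedSFS(0, 20, 1e6, np.full(10, 1e5))
        ]
        fit = fit_model("M1_constant", obs, 1.0, MU, n_starts=2, seed=3)
        assert fit.bound_hit

    def test_aic_definition(self):
        truth = DemographyModel("M1_constant", {"N_constant": 400.0})
        fit = fit_model("M1_constant", _expected_obs(truth), 1.0, MU, n_starts=2, seed=4)
        assert fit.aic == pytest.approx(2 * 1 - 2 * fit.loglik)


class TestSelectModel:
    def _fit(self, model_id, aic, converged=True):
        params = {
            "M1_constant": {"N_constant": 100.0},
            "M2_recent": {"N_contemp": 100.0, "N_historic": 200.0, "T_rc": 30.0},
            "M3_ancient": {"N_base": 100.0, "N_ancient": 200.0, "T_ac": 5000.0},
            "M4_both": {
                "N_contemp": 100.0, "N_historic": 200.0, "T_rc": 30.0,
                "N_ancient": 300.0, "T_ac": 5000.0,
            },
        }[model_id]
        model = DemographyModel(model_id, params)
        return FitResult(
            model=model, loglik=-aic / 2 + model.k, aic=aic,
            Ne_C_hat=100.0, Ne_H_hat=200.0, converged=converged, bound_hit=False,
        )

    def test_minimum_aic_wins(self):
        fits = [
            self._fit("M1_constant", 100),
            self._fit("M2_recent", 98),
            self._fit("M3_ancient", 102),
            self._fit("M4_both", 99),
        ]
        assert select_model(fits).model.id == "M2_recent"

    def test_tie_prefers_fewer_parameters(self):
        fits = [self._fit("M2_recent", 100), self._fit("M1_constant", 100)]
        assert select_model(fits).model.id == "M1_constant"

    def test_non_converged_excluded(self):
        fits = [
            self._fit("M1_constant", 90, converged=False),
            self._fit("M2_recent", 95),
        ]
        assert select_model(fits).model.id == "M2_recent"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_model([])


class TestClassifyTrend:
    def _result(self, model_id, ne_c, ne_h):
        fits = TestSelectModel()
        r = fits._fit(model_id, 100)
        r.Ne_C_hat, r.Ne_H_hat = ne_c, ne_h
        return r

    def test_constant_is_stable(self):
        assert classify_trend(self._result("M1_constant", 500, 500)) == "stable"

    def test_recent_decline(self):
        assert classify_trend(self._result("M2_recent", 300, 1000)) == "declining"

    def test_recent_expansion(self):
        assert classify_trend(self._result("M2_recent", 1200, 1000)) == "expanding"

    def test_ancient_only_is_stable(self):
        assert classify_trend(self._result("M3_ancient", 400, 400)) == "stable"


class TestModelSelectionSuite:
    def test_generating_class_recovered(self):
        # noise-free expected-SFS input: the generating model class should win
        # the AIC comparison in at least 90% of randomized cases
        rng = np.random.default_rng(99)
        cases = []
        for _ in range(10):
            n_h = 10 ** rng.uniform(2.5, 3.5)
            cases.append(DemographyModel("M1_constant", {"N_constant": n_h}))
        for _ in range(10):
            n_h = 10 ** rng.uniform(2.8, 3.5)
            ratio = rng.uniform(0.2, 0.5)
            cases.append(
                DemographyModel(
                    "M2_recent",
                    {
                        "N_contemp": n_h * ratio,
                        "N_historic": n_h,
                        "T_rc": rng.uniform(30, 120),
                    },
                )
            )
        hits = 0
        for i, truth in enumerate(cases):
            obs = _expected_obs(truth, n=50, L=7.5e6)
            fits = fit_all_models(obs, 1.0, MU, n_starts=2, seed=10 + i, maxiter=100)
            best = select_model(fits)
            constant_like = best.model.id in ("M1_constant", "M3_ancient")
            if truth.id == "M1_constant":
                hits += constant_like
            else:
                hits += best.model.id in ("M2_recent", "M4_both")
        assert hits >= 18  # >= 90% of 20


class TestModelHistories:
    def test_m2_size_interpolation(self):
        m = DemographyModel(
            "M2_recent", {"N_contemp": 100.0, "N_historic": 1000.0, "T_rc": 100.0}
        )
        assert m.size_at_ybp(0, 1.0) == pytest.approx(100.0)
        assert m.size_at_ybp(100, 1.0) == pytest.approx(1000.0)
        assert m.size_at_ybp(50, 1.0) == pytest.approx(np.sqrt(100 * 1000), rel=1e-6)

    def test_gen_time_scaling(self):
        m = DemographyModel(
            "M2_recent", {"N_contemp": 100.0, "N_historic": 1000.0, "T_rc": 120.0}
        )
        # with gen_time=3 the change spans 40 generations but the same years
        assert m.size_at_ybp(120, 3.0) == pytest.approx(1000.0)
        assert m.size_at_ybp(0, 3.0) == pytest.approx(100.0)

    def test_invalid_model_id(self):
        with pytest.raises(ValueError):
            DemographyModel("M5_everything", {})

    def test_missing_params(self):
        with pytest.raises(ValueError):
            DemographyModel("M2_recent", {"N_contemp": 100.0})
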