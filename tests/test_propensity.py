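"""Propensity scores, weighting estimators and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from gmethods import (
    CausalFrame,
    ModelSpec,
    PositivityError,
    balance_report,
    fit_propensity,
    ht_weights,
    iptw_ate,
    msm_ate,
    np_gformula,
    overlap_densities,
    stabilized_weights,
    trim_truncate,
)
from gmethods.synthetic import random_discrete_frame

WIDE = (1e-12, 1 - 1e-12)


class TestFitPropensity:
    def test_toy8_saturated_stratum_probabilities(self, toy8_frame, saturated_c):
        fit = fit_propensity(toy8_frame, saturated_c, bounds=WIDE)
        expected = np.where(toy8_frame.w["c"] == 0, 0.25, 0.75)
        assert np.allclose(fit.dps, expected, atol=1e-10)
        assert np.isclose(fit.nps, 0.5)

    def test_intercept_only_gives_marginal_probability(self, toy8_frame):
        fit = fit_propensity(toy8_frame, ModelSpec(terms=()))
        assert np.allclose(fit.dps, fit.nps, atol=1e-10)

    def test_single_arm_frame_rejected(self):
        f = CausalFrame([0, 1, 1], [1, 1, 1], pd.DataFrame({"c": [0, 1, 0]}),
                        {"c": "categorical"})
        with pytest.raises(PositivityError):
            fit_propensity(f, ModelSpec(terms=("c",)))

    def test_bounding_is_recorded(self, toy8_frame, saturated_c):
        fit = fit_propensity(toy8_frame, saturated_c, bounds=(0.4, 0.6))
        assert fit.n_bounded == toy8_frame.n
        assert fit.dps.min() >= 0.4 and fit.dps.max() <= 0.6


class TestWeights:
    def test_ht_weight_values(self, toy8_frame, saturated_c):
        fit = fit_propensity(toy8_frame, saturated_c, bounds=WIDE)
        w = ht_weights(fit, toy8_frame).weights
        a = np.asarray(toy8_frame.a)
        c = toy8_frame.w["c"].to_numpy()
        assert np.isclose(w[(a == 1) & (c == 0)][0], 4.0, atol=1e-9)       # 1/0.25
        assert np.isclose(w[(a == 0) & (c == 0)][0], 4.0 / 3.0, atol=1e-9)  # 1/0.75
        # saturated-fit identity: sum over treated of 1/g equals n
        assert np.isclose(np.sum(w[a == 1]), toy8_frame.n, atol=1e-8)

    def test_stabilized_weights_toy8(self, toy8_frame, saturated_c):
        fit = fit_propensity(toy8_frame, saturated_c, bounds=WIDE)
        ws = stabilized_weights(fit, toy8_frame)
        assert set(np.round(ws.weights, 10)) == {2.0, np.round(2.0 / 3.0, 10)}
        assert np.isclose(ws.weights.mean(), 1.0, atol=1e-10)

    def test_no_confounding_gives_unit_stabilized_weights(self, toy8_frame):
        fit = fit_propensity(toy8_frame, ModelSpec(terms=()))
        ws = stabilized_weights(fit, toy8_frame)
        assert np.allclose(ws.weights, 1.0, atol=1e-9)

    def test_extreme_mean_attaches_warning(self, toy8_frame, saturated_c):
        fit = fit_propensity(toy8_frame, saturated_c, bounds=WIDE)
        fit.dps = np.full(toy8_frame.n, 0.05)  # force pathological denominators
        ws = stabilized_weights(fit, toy8_frame)
        assert ws.warnings


class TestIptwAte:
    def test_toy8_ht_hand_sums(self, toy8_frame, saturated_c):
        fit = fit_propensity(toy8_frame, saturated_c, bounds=WIDE)
        est = iptw_ate(toy8_frame, ht_weights(fit, toy8_frame), "ht")
        assert np.isclose(est.mu1, 5.0 / 6.0, atol=1e-9)
        assert np.isclose(est.mu0, 1.0 / 6.0, atol=1e-9)
        assert np.isclose(est.ate, 2.0 / 3.0, atol=1e-9)

    def test_hajek_equals_ht_under_saturated_fit(self, rng):
        f = random_discrete_frame(rng, n_strata=3)
        fit = fit_propensity(
            f, ModelSpec(terms=("c",), saturated=True, include_intercept=False),
            bounds=WIDE)
        w = ht_weights(fit, f)
        assert np.isclose(iptw_ate(f, w, "ht").ate, iptw_ate(f, w, "hajek").ate,
                          atol=1e-9)

    def test_constant_propensity_recovers_unadjusted_difference(self, toy8_frame):
        fit = fit_propensity(toy8_frame, ModelSpec(terms=()))
        est = iptw_ate(toy8_frame, ht_weights(fit, toy8_frame), "hajek")
        a = np.asarray(toy8_frame.a, bool)
        assert np.isclose(est.ate, toy8_frame.y[a].mean() - toy8_frame.y[~a].mean(),
                          atol=1e-9)

    def test_iptw_equals_np_gformula_under_saturation(self, rng):
        """Nonparametric equivalence of weighting and standardization."""
        for _ in range(10):
            f = random_discrete_frame(rng, n_strata=int(rng.integers(2, 5)))
            fit = fit_propensity(
                f, ModelSpec(terms=("c",), saturated=True, include_intercept=False),
                bounds=WIDE)
            est = iptw_ate(f, ht_weights(fit, f), "ht")
            assert np.isclose(est.ate, np_gformula(f, ["c"]).ate, atol=1e-10)


class TestMsm:
    def test_toy8_treatment_coefficient(self, toy8_frame, saturated_c):
        fit = fit_propensity(toy8_frame, saturated_c, bounds=WIDE)
        est = msm_ate(toy8_frame, ht_weights(fit, toy8_frame))
        assert np.isclose(est.ate, 2.0 / 3.0, atol=1e-9)
        assert "robust_se" in est.diagnostics

    def test_point_estimate_invariant_to_stabilization(self, toy8_frame, saturated_c):
        fit = fit_propensity(toy8_frame, saturated_c, bounds=WIDE)
        e1 = msm_ate(toy8_frame, ht_weights(fit, toy8_frame))
        e2 = msm_ate(toy8_frame, stabilized_weights(fit, toy8_frame))
        assert np.isclose(e1.ate, e2.ate, atol=1e-10)

    def test_msm_equals_hajek_iptw(self, rng):
        f = random_discrete_frame(rng, n_strata=3)
        fit = fit_propensity(f, ModelSpec(terms=("c",)))
        w = ht_weights(fit, f)
        assert np.isclose(msm_ate(f, w).ate, iptw_ate(f, w, "hajek").ate, atol=1e-10)

    def test_unit_weights_give_unadjusted_difference(self, toy8_frame):
        from gmethods.propensity import WeightSet
        est = msm_ate(toy8_frame, WeightSet(weights=np.ones(8), kind="ht"))
        a = np.asarray(toy8_frame.a, bool)
        assert np.isclose(est.ate, toy8_frame.y[a].mean() - toy8_frame.y[~a].mean(),
                          atol=1e-10)


class TestTrimTruncate:
    def _weights(self, values):
        from gmethods.propensity import WeightSet
        return WeightSet(weights=np.asarray(values, float), kind="ht")

    def test_truncation_winsorizes_outlier(self):
        w = self._weights([1.0] * 99 + [100.0])
        out = trim_truncate(w, "truncate", (1, 99))
        assert out.weights.max() == np.percentile(w.weights, 99)
        assert out.kind == "truncated"
        assert out.provenance["n_affected"] >= 1

    def test_trim_keeps_all_equal_weights(self):
        w = self._weights(np.ones(50))
        out = trim_truncate(w, "trim", (5, 95))
        assert out.mask.all()

    def test_truncation_never_increases_max(self, rng):
        w = self._weights(rng.uniform(0.1, 30.0, 200))
        out = trim_truncate(w, "truncate", (5, 95))
        assert out.weights.max() <= w.weights.max()

    def test_inverted_bounds_error(self):
        with pytest.raises(ValueError, match="bound"):
            trim_truncate(self._weights(np.ones(5)), "truncate", (95, 5))


class TestBalance:
    def test_perfectly_balanced_column(self):
        c = np.tile([0, 1], 10)
        a = np.repeat([0, 1], 10)
        f = CausalFrame(np.zeros(20), a, pd.DataFrame({"c": c}), {"c": "categorical"})
        rep = balance_report(f)
        row = rep.iloc[0]
        assert row["std_diff_raw"] == pytest.approx(0.0, abs=1e-12)
        assert row["var_ratio_raw"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_weights_match_raw(self, rng):
        from gmethods.propensity import WeightSet
        f = random_discrete_frame(rng, n_strata=3)
        rep_raw = balance_report(f)
        rep_w = balance_report(f, WeightSet(weights=np.full(f.n, 2.5), kind="ht"))
        assert np.allclose(rep_raw["std_diff_raw"], rep_w["std_diff_weighted"], atol=1e-12)
        assert np.allclose(rep_raw["var_ratio_raw"], rep_w["var_ratio_weighted"], atol=1e-12)

    def test_weighting_improves_balance_on_confounded_frame(self, toy8_frame, saturated_c):
        fit = fit_propensity(toy8_frame, saturated_c, bounds=WIDE)
        rep = balance_report(toy8_frame, ht_weights(fit, toy8_frame))
        row = rep.iloc[0]
        assert abs(row["std_diff_weighted"]) < abs(row["std_diff_raw"])
        assert abs(row["std_diff_weighted"]) < 1e-9  # saturated fit balances exactly


class TestOverlap:
    def test_densities_integrate_to_one(self, rng):
        n = 400
        c = rng.integers(0, 3, n)
        a = rng.binomial(1, 0.2 + 0.2 * c)
        f = CausalFrame(np.zeros(n), a, pd.DataFrame({"c": c}), {"c": "categorical"})
        fit = fit_propensity(f, ModelSpec(terms=("c",)))
        dens = overlap_densities(fit, f)
        for col in ("density_treated", "density_control"):
            assert (dens[col] >= 0).all()
            integral = np.trapezoid(dens[col], dens["grid"])
            assert integral == pytest.approx(1.0, abs=1e-3)

    def test_grid_covers_propensity_support(self, toy8_frame, saturated_c):
        fit = fit_propensity(toy8_frame, saturated_c, bounds=WIDE)
        dens = overlap_densities(fit, toy8_frame, grid_size=256)
        assert dens["grid"].min() <= fit.dps.min()
        assert dens["grid"].max() >= fit.dps.max()
        assert len(dens) == 256
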