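"""TMLE: fluctuation, score equations, bounded outcomes, super learner."""

import numpy as np
import pandas as pd
import pytest

from gmethods import (
    CausalFrame,
    ModelSpec,
    aiptw,
    fit_propensity,
    fit_q,
    parametric_gcomp,
    scale_bounded_outcome,
    tmle_ate,
)
from gmethods.core import expit
from gmethods.synthetic import generate_sim_cohort, random_discrete_frame
from gmethods.tmle import LearnerLibrary, super_learner

WIDE = (1e-12, 1 - 1e-12)


class TestTmle:
    def test_saturated_nuisances_give_zero_fluctuation(self, toy8_frame, saturated_c):
        est = tmle_ate(toy8_frame, q_learner=saturated_c, g_learner=saturated_c,
                       q_bounds=WIDE, g_bounds=WIDE)
        comp = est.diagnostics["components"]
        assert abs(comp.eps1) < 1e-6 and abs(comp.eps2) < 1e-6
        assert np.isclose(est.ate, 2.0 / 3.0, atol=1e-10)

    def test_score_equations_solved_and_if_centered(self, rng):
        for _ in range(10):
            f = random_discrete_frame(rng, n_strata=int(rng.integers(2, 5)))
            est = tmle_ate(f, q_learner=ModelSpec(terms=("c",)),
                           g_learner=ModelSpec(terms=("c",)))
            comp = est.diagnostics["components"]
            assert abs(comp.score1) <= 1e-8
            assert abs(comp.score2) <= 1e-8
            assert abs(np.mean(comp.if_values)) <= 1e-10
            assert 0.0 <= est.mu1 <= 1.0 and 0.0 <= est.mu0 <= 1.0

    def test_plug_in_stays_in_unit_interval_under_near_positivity(self, rng):
        """Adversarial frame where extreme inverse weights push AIPTW outside
        the parameter space; the targeted plug-in must stay inside [0, 1]."""
        n = 120
        c = rng.integers(0, 2, n)
        p = np.where(c == 1, 0.97, 0.05)
        a = rng.binomial(1, p)
        while a[c == 1].min() == 1 or a[c == 0].max() == 0:  # keep cells mixed
            a = rng.binomial(1, p)
        y = rng.binomial(1, np.where(a == 1, 0.9, 0.05))
        f = CausalFrame(y, a, pd.DataFrame({"c": c}), {"c": "categorical"})
        spec = ModelSpec(terms=("c",))
        est = tmle_ate(f, q_learner=spec, g_learner=spec, g_bounds=(1e-6, 1 - 1e-6))
        assert 0.0 <= est.mu1 <= 1.0 and 0.0 <= est.mu0 <= 1.0
        comp = est.diagnostics["components"]
        assert abs(comp.score1) <= 1e-8 and abs(comp.score2) <= 1e-8

    def test_matches_gcomp_when_initial_q_already_solves_scores(self, rng):
        # saturated Q and g: the fluctuation is a no-op, so the targeted
        # estimate equals the plain regression standardization
        f = random_discrete_frame(rng, n_strata=3)
        sat = ModelSpec(terms=("c",), saturated=True, include_intercept=False)
        est = tmle_ate(f, q_learner=sat, g_learner=sat, q_bounds=WIDE, g_bounds=WIDE)
        ref = parametric_gcomp(f, sat, family="linear")
        assert np.isclose(est.ate, ref.ate, atol=1e-10)

    def test_continuous_outcome_default_uses_known_unit_bounds(self):
        cohort = generate_sim_cohort(1500, 5)
        f = cohort.to_frame()
        est = tmle_ate(f)
        assert not est.diagnostics["components"].scaled
        assert 0.0 <= est.mu0 <= est.mu1 <= 1.0
        assert est.se > 0

    def test_observed_range_scaling_path_agrees(self):
        cohort = generate_sim_cohort(1500, 5)
        f = cohort.to_frame()
        fixed = tmle_ate(f)
        stretched = tmle_ate(f, outcome_scaling="observed")
        assert stretched.diagnostics["components"].scaled
        assert 0.0 <= stretched.mu0 <= stretched.mu1 <= 1.0
        assert abs(stretched.ate - fixed.ate) < 0.02
        with pytest.raises(ValueError, match="outcome_scaling"):
            tmle_ate(f, outcome_scaling="bogus")

    def test_if_variance_comparable_to_aiptw(self):
        cohort = generate_sim_cohort(4000, 9)
        f = cohort.to_frame()
        spec = ModelSpec(terms=("w1", "w2", "w3", "w4"))
        t = tmle_ate(f, q_learner=spec, g_learner=spec)
        g = fit_propensity(f, spec)
        q = fit_q(f, spec, family="logistic")
        a = aiptw(f, q, g)
        assert abs(t.ate - a.ate) < 0.02
        assert 0.5 < t.se / a.se < 2.0


class TestScaleBoundedOutcome:
    def test_binary_passthrough(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        ys, scale = scale_bounded_outcome(y)
        assert np.array_equal(ys, y)
        assert scale.range == 1.0

    def test_affine_recovery(self):
        y = np.array([0.2, 0.5, 0.8])
        ys, scale = scale_bounded_outcome(y)
        assert ys.min() == 0.0 and ys.max() == 1.0
        assert np.allclose(scale.inverse(ys), y, atol=1e-12)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            scale_bounded_outcome(np.full(5, 0.4))


class TestSuperLearner:
    def _frame(self, n, seed):
        return generate_sim_cohort(n, seed).to_frame()

    def test_single_learner_gets_full_weight(self):
        f = self._frame(400, 3)
        sl = super_learner(f, target="treatment",
                           library=LearnerLibrary(learners=("glm-main",)), seed=0)
        assert sl.weights == {"glm-main": 1.0}
        assert sl.dps.shape == (f.n,)

    def test_duplicated_learner_predictions_unchanged(self):
        f = self._frame(400, 3)
        one = super_learner(f, target="treatment",
                            library=LearnerLibrary(learners=("glm-main",)), seed=0)
        two = super_learner(
            f, target="treatment",
            library=LearnerLibrary(learners=("glm-main", "glm-main")), seed=0)
        assert np.allclose(one.dps, two.dps, atol=1e-6)
        assert sum(two.weights.values()) == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_given_seed(self):
        f = self._frame(500, 4)
        a = super_learner(f, target="outcome", seed=11)
        b = super_learner(f, target="outcome", seed=11)
        assert np.array_equal(a.qaw, b.qaw)
        assert a.weights == b.weights

    def test_polynomial_learner_dominates_on_interaction_outcome(self):
        """The outcome surface contains a genuine w2*w4 interaction that the
        poly2+pairwise design can represent, so that learner should carry
        the largest ensemble weight in the vast majority of seeded runs."""
        wins = 0
        runs = 10
        for seed in range(runs):
            f = self._frame(1000, 100 + seed)
            sl = super_learner(f, target="outcome", seed=seed)
            best = max(sl.weights, key=sl.weights.get)
            wins += best == "glm-poly2-pairwise"
            assert min(sl.cv_loss.values()) <= sl.cv_loss["glm-main"] + 1e-9
        assert wins >= int(0.8 * runs)

    def test_unknown_learner_rejected(self):
        f = self._frame(200, 3)
        with pytest.raises(ValueError, match="unknown learner"):
            super_learner(f, target="treatment",
                          library=LearnerLibrary(learners=("mystery",)), seed=0)

    def test_seed_required(self):
        f = self._frame(200, 3)
        with pytest.raises(ValueError, match="seed"):
            super_learner(f, target="treatment", seed=None)

    def test_tmle_with_ensemble_nuisances_runs(self):
        f = self._frame(800, 21)
        est = tmle_ate(f, q_learner="super", g_learner="super", seed=5)
        assert 0.0 <= est.mu0 <= est.mu1 <= 1.0
        comp = est.diagnostics["components"]
        assert abs(comp.score1) <= 1e-8


def _ensemble_cv_loss(sl):
    # weights were chosen to minimize CV loss, so the weighted loss can be
    # bounded by the best single learner's loss
    return min(sl.cv_loss[k] for k, w in sl.weights.items() if w > 1e-6)
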