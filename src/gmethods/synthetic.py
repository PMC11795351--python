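"""Synthetic cohorts, the exact simulation truth, and the Monte Carlo runner.

The main data-generating process (DGP) emulates a cancer-epidemiology
cohort: deprivation quintile w1, age>65 indicator w2, stage w3 (four levels),
comorbidity count w4, a binary treatment whose assignment depends on all
four (with a w2*w4 interaction that induces near-positivity violations), and
potential-outcome *probabilities* Y1/Y0 so that the individual effect psi
and the population truth are known exactly.  The population ATE is available
without sampling by enumerating the discrete support with exact
rounding-interval probabilities.

Also here: ``toy8``, the canonical 8-row confounded worked example used
throughout the test-suite oracles, and an RHC-like mixed-type cohort
generator with stored generating coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CausalFrame, EffectEstimate, ModelSpec, expit
from .doubly_robust import aiptw, fit_q, iptw_ra
from .gformula import parametric_gcomp
from .propensity import fit_propensity, ht_weights, iptw_ate, stabilized_weights
from .tmle import tmle_ate

__all__ = [
    "SimulatedCohort",
    "MonteCarloReport",
    "generate_sim_cohort",
    "true_ate",
    "toy8",
    "generate_rhc_like",
    "RhcLikeCohort",
    "random_discrete_frame",
    "run_monte_carlo",
]

# treatment-assignment and outcome linear predictors of the simulation DGP
_A_COEF = dict(const=-3.0, w4=-0.5, w2=1.5, w3=0.75, w1=0.25, w2w4=0.8)
_Y_COEF = dict(const=-3.0, a=1.0, w4=0.25, w3=0.75, w2w4=0.8, w1=0.05)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """round() with halves away from zero (ties have probability zero here,
    but the convention is fixed: banker's rounding would change the pmfs)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class SimulatedCohort:
    """One simulated cohort with known potential-outcome probabilities."""

    w1: np.ndarray
    w2: np.ndarray
    w3: np.ndarray
    w4: np.ndarray
    a: np.ndarray
    y1: np.ndarray  # event probability under treatment
    y0: np.ndarray  # event probability under control
    psi: np.ndarray  # individual effect y1 - y0
    y: np.ndarray    # observed outcome = a*y1 + (1-a)*y0, continuous in (0,1)
    seed: int

    def to_frame(self) -> CausalFrame:
        w = pd.DataFrame({"w1": self.w1, "w2": self.w2, "w3": self.w3, "w4": self.w4})
        types = {k: "categorical" for k in w.columns}
        return CausalFrame(self.y, self.a, w, types)


def generate_sim_cohort(n: int, seed: int) -> SimulatedCohort:
    """Draw a cohort of size ``n`` from the simulation DGP.

    w1 = round(U(1,5)); w2 ~ Bern(0.45); w3 = round(U(0,1)+0.75 w2+0.8 w1)
    with raw values 5/6 recoded to 1; w4 = round(U(0,1)+1.2 w2+0.2 w1);
    A ~ Bern(expit(-3 - 0.5 w4 + 1.5 w2 + 0.75 w3 + 0.25 w1 + 0.8 w2 w4));
    Y1/Y0 are the event probabilities under A=1/A=0 and the observed outcome
    is their consistency mixture.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    w1 = _round_half_away(rng.uniform(1.0, 5.0, n))
    w2 = rng.binomial(1, 0.45, n).astype(float)
    w3 = _round_half_away(rng.uniform(0.0, 1.0, n) + 0.75 * w2 + 0.8 * w1)
    w3 = np.where((w3 == 5) | (w3 == 6), 1.0, w3)
    w4 = _round_half_away(rng.uniform(0.0, 1.0, n) + 1.2 * w2 + 0.2 * w1)
    c = _A_COEF
    pa = expit(c["const"] + c["w4"] * w4 + c["w2"] * w2 + c["w3"] * w3
               + c["w1"] * w1 + c["w2w4"] * w2 * w4)
    a = rng.binomial(1, pa).astype(float)
    o = _Y_COEF
    base = o["const"] + o["w4"] * w4 + o["w3"] * w3 + o["w2w4"] * w2 * w4 + o["w1"] * w1
    y1 = expit(base + o["a"])
    y0 = expit(base)
    psi = y1 - y0
    y = a * y1 + (1.0 - a) * y0
    return SimulatedCohort(w1=w1, w2=w2, w3=w3, w4=w4, a=a, y1=y1, y0=y0,
                           psi=psi, y=y, seed=seed)


def _interval_prob(k: int, c: float) -> float:
    """P(round(U(0,1) + c) == k) under half-away-from-zero rounding."""
    lo, hi = k - 0.5 - c, k + 0.5 - c
    return max(0.0, min(1.0, hi) - max(0.0, lo))


def enumerate_support() -> pd.DataFrame:
    """Exact joint pmf of (w1, w2, w3, w4) under the DGP, with psi per cell."""
    # w1 = round(U(1,5)): endpoints get half-width rounding intervals
    p_w1 = {1: 0.125, 2: 0.25, 3: 0.25, 4: 0.25, 5: 0.125}
    p_w2 = {0: 0.55, 1: 0.45}
    rows = []
    o = _Y_COEF
    for w1, p1 in p_w1.items():
        for w2, p2 in p_w2.items():
            c3 = 0.75 * w2 + 0.8 * w1
            pw3: dict[int, float] = {}
            for k in range(0, 7):
                p = _interval_prob(k, c3)
                if p > 0:
                    kk = 1 if k in (5, 6) else k
                    pw3[kk] = pw3.get(kk, 0.0) + p
            c4 = 1.2 * w2 + 0.2 * w1
            pw4 = {k: _interval_prob(k, c4) for k in range(0, 5)
                   if _interval_prob(k, c4) > 0}
            for w3, p3 in pw3.items():
                for w4, p4 in pw4.items():
                    base = (o["const"] + o["w4"] * w4 + o["w3"] * w3
                            + o["w2w4"] * w2 * w4 + o["w1"] * w1)
                    rows.append({
                        "w1": w1, "w2": w2, "w3": w3, "w4": w4,
                        "p": p1 * p2 * p3 * p4,
                        "psi": expit(base + o["a"]) - expit(base),
                    })
    return pd.DataFrame(rows)


def true_ate() -> float:
    """Exact population ATE of the DGP by enumeration (no sampling)."""
    table = enumerate_support()
    return float((table["p"] * table["psi"]).sum())


def toy8() -> CausalFrame:
    """The canonical 8-row confounded fixture.

    Rows (C, A, Y): (0,0,0) (0,0,0) (0,0,1) (0,1,1) (1,0,0) (1,1,0) (1,1,1)
    (1,1,1).  Hand stratification gives ATE = 2/3 while the unadjusted arm
    difference is 1/2; the stratum propensities are 1/4 and 3/4.
    """
    rows = [(0, 0, 0), (0, 0, 0), (0, 0, 1), (0, 1, 1),
            (1, 0, 0), (1, 1, 0), (1, 1, 1), (1, 1, 1)]
    c = [r[0] for r in rows]
    a = [r[1] for r in rows]
    y = [r[2] for r in rows]
    return CausalFrame(y, a, pd.DataFrame({"c": c}), {"c": "categorical"})


@dataclass
class RhcLikeCohort:
    """An RHC-like cohort plus the coefficients that generated it."""

    frame: CausalFrame
    treatment_coef: Mapping[str, float]
    outcome_coef: Mapping[str, float]
    seed: int

    def implied_truth(self, n: int = 200_000, seed: int = 0) -> float:
        """Population ATE implied by the stored outcome model, by
        large-sample g-computation over a fresh confounder draw."""
        w = _rhc_confounders(n, np.random.default_rng(seed))
        eta1 = _rhc_linpred(w, self.outcome_coef, a=1.0)
        eta0 = _rhc_linpred(w, self.outcome_coef, a=0.0)
        return float(np.mean(expit(eta1) - expit(eta0)))


_RHC_TREAT = {
    "const": -0.75, "sex": 0.25, "age": 0.010, "edu": -0.03,
    "race1": -0.15, "race2": 0.10, "carcinoma": -0.30,
}
_RHC_OUT = {
    "const": -1.05, "a": 0.35, "sex": 0.20, "age": 0.018, "edu": -0.03,
    "race1": 0.12, "race2": 0.06, "carcinoma": 0.45,
}


def _rhc_confounders(n: int, rng: np.random.Generator) -> pd.DataFrame:
    sex = rng.binomial(1, 0.56, n)           # 1 = male, 44% female
    age = np.clip(rng.normal(61.0, 16.0, n), 18.0, 100.0)
    edu = np.clip(rng.normal(12.0, 3.0, n), 0.0, 22.0)
    race = rng.choice([0, 1, 2], size=n, p=[0.78, 0.16, 0.06])
    carcinoma = rng.binomial(1, 0.25, n)
    return pd.DataFrame({"sex": sex, "age": age, "edu": edu,
                         "race": race, "carcinoma": carcinoma})


def _rhc_linpred(w: pd.DataFrame, coef: Mapping[str, float], a: float | np.ndarray = 0.0):
    eta = (coef["const"]
           + coef.get("a", 0.0) * np.asarray(a, dtype=float)
           + coef["sex"] * w["sex"].to_numpy()
           + coef["age"] * (w["age"].to_numpy() - 61.0)
           + coef["edu"] * (w["edu"].to_numpy() - 12.0)
           + coef["race1"] * (w["race"].to_numpy() == 1)
           + coef["race2"] * (w["race"].to_numpy() == 2)
           + coef["carcinoma"] * w["carcinoma"].to_numpy())
    return eta


def generate_rhc_like(n: int, seed: int) -> RhcLikeCohort:
    """A mixed-type cohort shaped like the right-heart-catheterization study.

    Binary outcome (30-day-mortality-like), binary treatment, confounders
    sex / age / education (continuous) / race (3 levels) / carcinoma, with
    mild confounding through sex, age and carcinoma.  The generating
    coefficients are stored so tests can recover the implied truth by
    large-sample g-computation.
    """
    rng = np.random.default_rng(seed)
    w = _rhc_confounders(n, rng)
    pa = expit(_rhc_linpred(w, _RHC_TREAT))
    a = rng.binomial(1, pa)
    py = expit(_rhc_linpred(w, _RHC_OUT, a=a))
    y = rng.binomial(1, py)
    types = {"sex": "categorical", "age": "continuous", "edu": "continuous",
             "race": "categorical", "carcinoma": "categorical"}
    frame = CausalFrame(y, a, w, types)
    return RhcLikeCohort(frame=frame, treatment_coef=dict(_RHC_TREAT),
                         outcome_coef=dict(_RHC_OUT), seed=seed)


def random_discrete_frame(
    rng: np.random.Generator,
    n_strata: int = 3,
    min_cell: int = 2,
    max_cell: int = 6,
) -> CausalFrame:
    """A random all-categorical frame with every (a, stratum) cell non-empty
    and every cell outcome mean strictly inside (0, 1).

    Used for exact-equivalence checks across estimators: strict interior
    cell means keep saturated logistic and linear fits away from the
    probability boundary.
    """
    ys, as_, cs = [], [], []
    for s in range(n_strata):
        for arm in (0, 1):
            m = int(rng.integers(max(min_cell, 2), max_cell + 1))
            ones = int(rng.integers(1, m))  # 1..m-1 -> mean in (0,1)
            yy = np.zeros(m)
            yy[:ones] = 1.0
            rng.shuffle(yy)
            ys.append(yy)
            as_.append(np.full(m, arm))
            cs.append(np.full(m, s))
    y = np.concatenate(ys)
    a = np.concatenate(as_)
    c = np.concatenate(cs)
    perm = rng.permutation(len(y))
    return CausalFrame(y[perm], a[perm], pd.DataFrame({"c": c[perm]}),
                       {"c": "categorical"})


# ---------------------------------------------------------------------------
# Monte Carlo experiment


@dataclass
class MonteCarloReport:
    """Per-estimator Monte Carlo performance against the exact truth."""

    truth: float
    n_reps: int
    n: int
    table: pd.DataFrame  # estimator, mean, bias, relative_bias, emp_se, coverage
    failures: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "truth": self.truth,
            "n_reps": self.n_reps,
            "n": self.n,
            "estimators": self.table.to_dict(orient="records"),
            "failures": self.failures,
        }


FACTOR_SPEC = ModelSpec(terms=("w1", "w2", "w3", "w4"))
"""Main-effects factor specification (i.w1 i.w2 i.w3 i.w4): omits the w2*w4
interaction of the DGP, i.e. the deliberate misspecification scenario."""

CORRECT_SPEC = ModelSpec(
    terms=("w1", "w2", "w3", "w4", "w2:w4"),
    types={"w1": "continuous", "w2": "continuous", "w3": "continuous", "w4": "continuous"},
)
"""Linear terms plus the w2*w4 product: the correctly specified form for
both the treatment and (with A added) the outcome mechanism."""


def _estimate_one(
    name: str,
    frame: CausalFrame,
    outcome_spec: ModelSpec,
    treatment_spec: ModelSpec,
    outcome_family: str = "linear",
) -> EffectEstimate:
    if name == "gcomp":
        return parametric_gcomp(frame, outcome_spec, family=outcome_family)
    if name == "iptw":
        g = fit_propensity(frame, treatment_spec)
        return iptw_ate(frame, ht_weights(g, frame), estimator="ht")
    if name == "iptw_ra":
        g = fit_propensity(frame, treatment_spec)
        return iptw_ra(frame, stabilized_weights(g, frame), outcome_spec,
                       family=outcome_family)
    if name == "aiptw":
        g = fit_propensity(frame, treatment_spec)
        q = fit_q(frame, outcome_spec, family="logistic", pooled=False)
        return aiptw(frame, q, g)
    if name == "tmle":
        return tmle_ate(frame, q_learner=outcome_spec, g_learner=treatment_spec)
    raise ValueError(f"unknown estimator {name!r}")


def run_monte_carlo(
    n_reps: int,
    n: int,
    estimators: Sequence[str] = ("gcomp", "iptw", "iptw_ra", "aiptw", "tmle"),
    nuisance_specs: Mapping[str, ModelSpec] | None = None,
    seed: int = 0,
    outcome_family: str = "linear",
) -> MonteCarloReport:
    """Monte Carlo experiment over fresh DGP cohorts.

    Each replicate draws a cohort of size ``n`` and runs every requested
    estimator with the given nuisance specifications (default: the
    main-effects factor specs, i.e. the deliberate-misspecification
    scenario).  ``outcome_family`` is the family of the regression-based
    outcome fits: ``"linear"`` (the usual default for a continuous outcome)
    or ``"logistic"`` (the DGP's own link, needed for a fully correct
    outcome specification).  Metrics are computed against the exact
    enumerated truth:
    mean estimate, mean bias, relative bias |mean - truth| / truth,
    empirical SE, and — for estimators that report a CI — empirical 95%
    coverage.  Estimator failures on a replicate are recorded, not fatal.
    Deterministic given ``seed``.
    """
    specs = nuisance_specs or {}
    outcome_spec = specs.get("outcome", FACTOR_SPEC)
    treatment_spec = specs.get("treatment", FACTOR_SPEC)
    truth = true_ate()
    rng = np.random.default_rng(seed)
    estimates: dict[str, list[float]] = {e: [] for e in estimators}
    covered: dict[str, list[bool]] = {e: [] for e in estimators}
    failures: dict[str, int] = {e: 0 for e in estimators}
    for _ in range(n_reps):
        cohort = generate_sim_cohort(n, int(rng.integers(0, 2**31 - 1)))
        frame = cohort.to_frame()
        for name in estimators:
            try:
                est = _estimate_one(name, frame, outcome_spec, treatment_spec,
                                    outcome_family=outcome_family)
            except Exception:
                failures[name] += 1
                continue
            estimates[name].append(est.ate)
            if est.ci_lower is not None and est.ci_upper is not None:
                covered[name].append(est.ci_lower <= truth <= est.ci_upper)
    rows = []
    for name in estimators:
        vals = np.asarray(estimates[name])
        if len(vals) == 0:
            rows.append({"estimator": name, "n_ok": 0})
            continue
        mean = float(np.mean(vals))
        rows.append({
            "estimator": name,
            "n_ok": len(vals),
            "mean": mean,
            "bias": mean - truth,
            "relative_bias": abs(mean - truth) / truth,
            "emp_se": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "mc_se": float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0,
            "coverage": float(np.mean(covered[name])) if covered[name] else np.nan,
        })
    return MonteCarloReport(truth=truth, n_reps=n_reps, n=n,
                            table=pd.DataFrame(rows), failures=failures)
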