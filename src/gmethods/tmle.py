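"""Targeted maximum likelihood estimation (TMLE) of the ATE.

TMLE takes an initial outcome-model estimate (Q), fits the treatment
mechanism (g), and then *targets* the initial estimate with a one-step
logistic fluctuation along the clever covariates H1W = A/g and
H0W = (1-A)/(1-g).  Separate fluctuation coefficients (eps1, eps2) are fit
for the two arms by an intercept-free logistic regression of Y on
{H1W, H0W} with offset logit(QAW); the updated predictions

    Q1W* = expit(logit(Q1W) + eps1/g),   Q0W* = expit(logit(Q0W) + eps2/(1-g))

solve the efficient-influence-function score equations exactly, so the
plug-in ATE = mean(Q1W*) - mean(Q0W*) is doubly robust, respects the [0, 1]
parameter space, and carries influence-function Wald inference.

A minimal native super learner (V-fold cross-validated convex ensemble of
GLM learners) is available for the nuisance fits via ``q_learner="super"`` /
``g_learner="super"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    CausalFrame,
    ConvergenceError,
    EffectEstimate,
    ModelSpec,
    expit,
    fit_logistic,
    logit,
)
from .doubly_robust import QFit, fit_q
from .inference import if_wald
from .propensity import PropensityFit, fit_propensity

__all__ = [
    "TmleComponents",
    "LearnerLibrary",
    "SuperLearnerFit",
    "tmle_ate",
    "scale_bounded_outcome",
    "super_learner",
]


@dataclass
class TmleComponents:
    q_init: QFit
    g: PropensityFit
    h1w: np.ndarray
    h0w: np.ndarray
    eps1: float
    eps2: float
    q1w_star: np.ndarray
    q0w_star: np.ndarray
    d1: np.ndarray
    d0: np.ndarray
    if_values: np.ndarray
    score1: float  # sum H1W (Y - Q1W*) after targeting
    score2: float  # sum H0W (Y - Q0W*) after targeting
    scaled: bool = False


@dataclass
class BoundedScale:
    lo: float
    hi: float

    @property
    def range(self) -> float:
        return self.hi - self.lo

    def forward(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.lo) / self.range

    def inverse(self, y_star: np.ndarray) -> np.ndarray:
        return np.asarray(y_star, dtype=float) * self.range + self.lo


def scale_bounded_outcome(y) -> tuple[np.ndarray, BoundedScale]:
    """Affine map of a bounded outcome onto [0, 1] with a stored inverse.

    Binary {0,1} outcomes pass through unchanged.  The ATE on the original
    scale is the scaled-scale ATE multiplied by (max - min).
    """
    y = np.asarray(y, dtype=float)
    lo, hi = float(np.min(y)), float(np.max(y))
    if np.isin(y, (0.0, 1.0)).all():
        return y, BoundedScale(0.0, 1.0)
    if hi <= lo:
        raise ValueError("constant outcome cannot be scaled to [0, 1]")
    scale = BoundedScale(lo, hi)
    return scale.forward(y), scale


def _fluctuation_eps(h: np.ndarray, y: np.ndarray, log_q: np.ndarray,
                     tol: float = 1e-11, maxiter: int = 200) -> float:
    """One-arm fluctuation coefficient by damped Newton.

    Maximizes the Bernoulli log-likelihood of ``y`` under
    p = expit(log_q + eps * h) over the rows where h > 0 (the clever
    covariates of the two arms have disjoint support, so the two-parameter
    fluctuation separates into two one-parameter problems).  Converges when
    the score sum |h (y - p)| drops below ``tol``, guaranteeing the score
    equation is solved to numerical precision.
    """
    mask = h > 0
    if not mask.any():
        return 0.0
    h, y, log_q = h[mask], y[mask], log_q[mask]
    eps = 0.0

    def score_at(e: float):
        p = expit(log_q + e * h)
        return float(np.sum(h * (y - p))), p

    score, p = score_at(eps)
    for _ in range(maxiter):
        if abs(score) < tol:
            return eps
        hess = float(np.sum(h * h * p * (1.0 - p)))
        if hess <= 0:
            return eps  # likelihood flat: predictions pinned at 0/1
        step = score / hess
        new_eps = eps + step
        new_score, new_p = score_at(new_eps)
        # damp if the step overshot (score magnitude must shrink)
        tries = 0
        while abs(new_score) > abs(score) and tries < 50:
            step /= 2.0
            new_eps = eps + step
            new_score, new_p = score_at(new_eps)
            tries += 1
        eps, score, p = new_eps, new_score, new_p
    raise ConvergenceError(f"TMLE fluctuation did not converge (|score|={abs(score):.3e})")


def _default_spec(frame: CausalFrame) -> ModelSpec:
    return ModelSpec(terms=tuple(frame.w.columns))


def tmle_ate(
    frame: CausalFrame,
    q_learner: "ModelSpec | str | LearnerLibrary | None" = None,
    g_learner: "ModelSpec | str | LearnerLibrary | None" = None,
    *,
    q_bounds: tuple[float, float] = (0.005, 0.995),
    g_bounds: tuple[float, float] = (0.01, 0.99),
    outcome_scaling: str = "fixed",
    ci_level: float = 0.95,
    seed: int | None = None,
) -> EffectEstimate:
    """Targeted maximum likelihood estimate of the ATE.

    ``q_learner`` / ``g_learner`` choose the nuisance estimators: ``None``
    for a main-effects logistic GLM over all confounders, a ``ModelSpec``
    for a custom GLM, or ``"super"`` / a ``LearnerLibrary`` for the native
    cross-validated ensemble (requires ``seed``).  Initial Q predictions are
    clipped into ``q_bounds`` before the logit transform; propensity
    predictions into ``g_bounds``.

    A continuous outcome is treated as a proportion on its *known* [0, 1]
    parameter space (``outcome_scaling="fixed"``, the default, since the
    frame contract already bounds the outcome).  ``outcome_scaling=
    "observed"`` instead stretches the observed min/max onto [0, 1] and maps
    the estimate back — useful when the attainable range is much narrower
    than [0, 1], at the cost of making a logistic Q specification on the
    original scale no longer exactly correct.
    """
    frame.require_both_arms()
    if outcome_scaling == "observed" and not frame.y_binary:
        y_scaled, scale = scale_bounded_outcome(frame.y)
    elif outcome_scaling in ("fixed", "observed"):
        y_scaled, scale = frame.y, BoundedScale(0.0, 1.0)
    else:
        raise ValueError(f"unknown outcome_scaling {outcome_scaling!r}")
    work = CausalFrame(y_scaled, frame.a, frame.w, frame.w_types, validate=False)

    # Step 1: initial outcome model Q
    if isinstance(q_learner, (str, LearnerLibrary)):
        sl = super_learner(work, target="outcome",
                           library=q_learner if isinstance(q_learner, LearnerLibrary) else None,
                           seed=_require_seed(seed))
        q = QFit(qaw=sl.qaw, q1w=sl.q1w, q0w=sl.q0w, family="logistic",
                 spec=_default_spec(work), pooled=True, detail={"super_learner": sl})
    else:
        q_spec = q_learner if isinstance(q_learner, ModelSpec) else _default_spec(work)
        q = fit_q(work, q_spec, family="logistic", pooled=True)

    # Step 2: treatment mechanism g and clever covariates
    if isinstance(g_learner, (str, LearnerLibrary)):
        sl_g = super_learner(work, target="treatment",
                             library=g_learner if isinstance(g_learner, LearnerLibrary) else None,
                             seed=_require_seed(seed))
        dps = np.clip(sl_g.dps, g_bounds[0], g_bounds[1])
        g = PropensityFit(dps=dps, nps=float(np.mean(work.a)), spec=_default_spec(work),
                          bounds=g_bounds,
                          n_bounded=int(np.sum((sl_g.dps < g_bounds[0]) | (sl_g.dps > g_bounds[1]))))
    else:
        g_spec = g_learner if isinstance(g_learner, ModelSpec) else _default_spec(work)
        g = fit_propensity(work, g_spec, bounds=g_bounds)

    a = np.asarray(work.a, dtype=float)
    h1w = a / g.dps
    h0w = (1.0 - a) / (1.0 - g.dps)

    # Step 3: fluctuation of the initial Q along the clever covariates
    lo, hi = q_bounds
    q1 = np.clip(q.q1w, lo, hi)
    q0 = np.clip(q.q0w, lo, hi)
    log_q1, log_q0 = logit(q1), logit(q0)
    eps1 = _fluctuation_eps(h1w, work.y, log_q1)
    eps2 = _fluctuation_eps(h0w, work.y, log_q0)

    # Step 4: targeted update of both surfaces
    q1w_star = expit(log_q1 + eps1 / g.dps)
    q0w_star = expit(log_q0 + eps2 / (1.0 - g.dps))

    # Step 5: plug-in ATE
    mu1_s = float(np.mean(q1w_star))
    mu0_s = float(np.mean(q0w_star))

    # Step 6: influence-function inference
    d1 = h1w * (work.y - q1w_star) + q1w_star - mu1_s
    d0 = h0w * (work.y - q0w_star) + q0w_star - mu0_s
    if_values_s = d1 - d0

    ate = (mu1_s - mu0_s) * scale.range
    mu1 = mu1_s * scale.range + scale.lo
    mu0 = mu0_s * scale.range + scale.lo
    if_values = if_values_s * scale.range
    se, (ci_lo, ci_hi) = if_wald(if_values, level=ci_level, center=ate)

    components = TmleComponents(
        q_init=q, g=g, h1w=h1w, h0w=h0w, eps1=eps1, eps2=eps2,
        q1w_star=q1w_star, q0w_star=q0w_star, d1=d1, d0=d0,
        if_values=if_values,
        score1=float(np.sum(h1w * (work.y - q1w_star))),
        score2=float(np.sum(h0w * (work.y - q0w_star))),
        scaled=scale.range != 1.0 or scale.lo != 0.0,
    )
    return EffectEstimate(
        method="tmle",
        ate=ate,
        mu1=mu1,
        mu0=mu0,
        se=se,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        ci_level=ci_level,
        ci_method="if_wald",
        diagnostics={"components": components},
    )


def _require_seed(seed):
    if seed is None:
        raise ValueError("a seed is required for super-learner nuisance estimation")
    return seed


# ---------------------------------------------------------------------------
# minimal native super learner


@dataclass
class LearnerLibrary:
    """Candidate learners for the cross-validated ensemble.

    The defaults mirror the common GLM library: main-effects GLM, a GLM with
    second-order polynomials and pairwise interactions, and a backward
    stepwise (AIC) selection starting from the polynomial design.  Loss is
    the negative Bernoulli log-likelihood; weights live on the simplex.
    """

    learners: Sequence[str] = ("glm-main", "glm-poly2-pairwise", "glm-stepwise")
    folds: int = 5


@dataclass
class SuperLearnerFit:
    weights: dict
    cv_loss: dict
    dropped: list
    # outcome target: predictions for the fitting frame
    qaw: np.ndarray | None = None
    q1w: np.ndarray | None = None
    q0w: np.ndarray | None = None
    # treatment target
    dps: np.ndarray | None = None


def _poly_design(w: np.ndarray, names: list[str]):
    cols = [np.ones(len(w))]
    labels = ["intercept"]
    p = w.shape[1]
    for j in range(p):
        cols.append(w[:, j])
        labels.append(names[j])
    for j in range(p):
        cols.append(w[:, j] ** 2)
        labels.append(f"{names[j]}^2")
    for j in range(p):
        for k in range(j + 1, p):
            cols.append(w[:, j] * w[:, k])
            labels.append(f"{names[j]}*{names[k]}")
    return np.column_stack(cols), labels


def _main_design(w: np.ndarray, names: list[str]):
    return np.column_stack([np.ones(len(w)), w]), ["intercept", *names]


def _stepwise_backward_aic(x: np.ndarray, y: np.ndarray, labels: list[str]):
    """Backward elimination on AIC, deterministic term order; intercept kept."""

    def aic(cols: list[int]) -> tuple[float, object]:
        fit = fit_logistic(x[:, cols], y, column_names=[labels[c] for c in cols])
        p = np.clip(fit.fitted, 1e-12, 1 - 1e-12)
        ll = float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))
        return -2.0 * ll + 2.0 * len(cols), fit

    current = list(range(x.shape[1]))
    best_aic, best_fit = aic(current)
    improved = True
    while improved and len(current) > 1:
        improved = False
        candidates = []
        for drop in current:
            if labels[drop] == "intercept":
                continue
            trial = [c for c in current if c != drop]
            try:
                a, f = aic(trial)
            except Exception:
                continue
            candidates.append((a, drop, f, trial))
        if candidates:
            a, drop, f, trial = min(candidates, key=lambda t: (t[0], t[1]))
            if a < best_aic - 1e-9:
                current, best_aic, best_fit, improved = trial, a, f, True
    return current, best_fit


class _GlmLearner:
    def __init__(self, name: str, kind: str):
        self.name = name
        self.kind = kind  # main | poly | stepwise
        self.fit_ = None
        self.cols_ = None

    def _design(self, w: np.ndarray, names: list[str], a: np.ndarray | None):
        if self.kind == "main":
            x, labels = _main_design(w, names)
        else:
            x, labels = _poly_design(w, names)
        if a is not None:
            x = np.column_stack([np.asarray(a, dtype=float), x])
            labels = ["a", *labels]
        return x, labels

    def fit(self, w, names, a, y):
        x, labels = self._design(w, names, a)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if self.kind == "stepwise":
                self.cols_, self.fit_ = _stepwise_backward_aic(x, y, labels)
            else:
                self.cols_ = list(range(x.shape[1]))
                self.fit_ = fit_logistic(x, y, column_names=labels)
        return self

    def predict(self, w, names, a):
        x, _ = self._design(w, names, a)
        return self.fit_.predict(x[:, self.cols_])


def _make_learner(name: str) -> _GlmLearner:
    kinds = {"glm-main": "main", "glm-poly2-pairwise": "poly", "glm-stepwise": "stepwise"}
    if name not in kinds:
        raise ValueError(f"unknown learner {name!r}")
    return _GlmLearner(name, kinds[name])


def _project_simplex(v: np.ndarray) -> np.ndarray:
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.flatnonzero(u + (1.0 - css) / np.arange(1, len(v) + 1) > 0)[-1]
    theta = (css[rho] - 1.0) / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def _bernoulli_loss(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def _simplex_weights(y: np.ndarray, preds: np.ndarray,
                     iters: int = 500, tol: float = 1e-9) -> np.ndarray:
    """Minimize CV Bernoulli loss over the simplex by projected gradient."""
    m = preds.shape[1]
    alpha = np.full(m, 1.0 / m)
    loss = _bernoulli_loss(y, preds @ alpha)
    step = 1.0
    for _ in range(iters):
        p = np.clip(preds @ alpha, 1e-12, 1 - 1e-12)
        grad = -(preds.T @ (y / p - (1.0 - y) / (1.0 - p))) / len(y)
        new = _project_simplex(alpha - step * grad)
        new_loss = _bernoulli_loss(y, preds @ new)
        tries = 0
        while new_loss > loss and tries < 30:
            step /= 2.0
            new = _project_simplex(alpha - step * grad)
            new_loss = _bernoulli_loss(y, preds @ new)
            tries += 1
        if abs(loss - new_loss) < tol and np.allclose(alpha, new, atol=1e-12):
            alpha = new
            break
        alpha, loss = new, new_loss
        step = min(step * 2.0, 8.0)
    return alpha


def super_learner(
    frame: CausalFrame,
    target: str = "outcome",
    library: LearnerLibrary | None = None,
    seed: int | None = 0,
) -> SuperLearnerFit:
    """V-fold cross-validated convex ensemble of GLM learners.

    For ``target="outcome"`` the learners model E(Y|A,W) with A as a main
    term and the ensemble returns QAW/Q1W/Q0W surfaces; for
    ``target="treatment"`` they model P(A=1|W) and the ensemble returns the
    propensity predictions.  Ensemble weights minimize the cross-validated
    negative Bernoulli log-likelihood over the simplex; learners that fail
    on any fold are dropped with a warning and the weights renormalized.
    Deterministic given ``seed``.
    """
    library = library or LearnerLibrary()
    if frame.n < library.folds:
        raise ValueError("need at least as many subjects as folds")
    rng = np.random.default_rng(_require_seed(seed))
    names = list(frame.w.columns)
    wmat = frame.w.to_numpy(dtype=float)
    if target == "outcome":
        y = frame.y
        a: np.ndarray | None = np.asarray(frame.a, dtype=float)
    elif target == "treatment":
        y = np.asarray(frame.a, dtype=float)
        a = None
    else:
        raise ValueError(f"unknown target {target!r}")

    order = rng.permutation(frame.n)
    fold_of = np.empty(frame.n, dtype=int)
    for k, chunk in enumerate(np.array_split(order, library.folds)):
        fold_of[chunk] = k

    for name in library.learners:
        _make_learner(name)  # validate names upfront (unknown learner is an error)

    active: list[str] = []  # duplicates allowed: tracked positionally
    cv_cols = []
    dropped = []
    for name in library.learners:
        col = np.full(frame.n, np.nan)
        try:
            for k in range(library.folds):
                test = fold_of == k
                train = ~test
                fit = _make_learner(name).fit(
                    wmat[train], names, None if a is None else a[train], y[train])
                col[test] = fit.predict(
                    wmat[test], names, None if a is None else a[test])
        except Exception as exc:
            warnings.warn(f"super-learner candidate {name!r} dropped: {exc}")
            dropped.append(name)
            continue
        active.append(name)
        cv_cols.append(col)
    if not active:
        raise ConvergenceError("all super-learner candidates failed")

    preds = np.column_stack(cv_cols)
    alpha = _simplex_weights(y, preds)
    cv_loss: dict[str, float] = {}
    weight_map: dict[str, float] = {}
    for j, name in enumerate(active):
        cv_loss[name] = min(cv_loss.get(name, np.inf), _bernoulli_loss(y, cv_cols[j]))
        weight_map[name] = weight_map.get(name, 0.0) + float(alpha[j])

    final = [_make_learner(name).fit(wmat, names, a, y) for name in active]

    def blend(a_vec):
        return sum(alpha[j] * final[j].predict(wmat, names, a_vec)
                   for j in range(len(active)))

    out = SuperLearnerFit(weights=weight_map, cv_loss=cv_loss, dropped=dropped)
    if target == "outcome":
        out.qaw = blend(a)
        out.q1w = blend(np.ones(frame.n))
        out.q0w = blend(np.zeros(frame.n))
    else:
        out.dps = blend(None)
    return out
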