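"""Doubly robust estimators: IPTW-RA and AIPTW.

Both combine an outcome regression (the Q model) with a treatment model (the
propensity score g) and remain consistent if either one is correctly
specified.  IPTW-RA reruns the arm-specific regression adjustment under
stabilized weights; AIPTW adds a weighted-residual augmentation term with
mean zero under a correct treatment model, and carries an influence-function
standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    CausalFrame,
    EffectEstimate,
    ModelSpec,
    encode,
    fit_linear,
    fit_logistic,
)
from .gformula import parametric_gcomp
from .inference import if_wald
from .propensity import PropensityFit, WeightSet

__all__ = ["QFit", "fit_q", "iptw_ra", "aiptw"]

Q_BOUNDS = (0.005, 0.995)


@dataclass
class QFit:
    """Outcome-model predictions under observed and counterfactual treatment."""

    qaw: np.ndarray  # prediction at the observed treatment
    q1w: np.ndarray  # prediction setting A=1
    q0w: np.ndarray  # prediction setting A=0
    family: str
    spec: ModelSpec
    pooled: bool
    detail: dict | None = None


def fit_q(
    frame: CausalFrame,
    outcome_spec: ModelSpec,
    family: str = "logistic",
    pooled: bool = False,
) -> QFit:
    """Fit the outcome (Q) model and predict both potential-outcome surfaces.

    ``pooled=False`` fits E(Y|W) separately within each arm for Q1W/Q0W and
    a pooled model with A as a covariate for QAW; ``pooled=True`` uses the
    single pooled fit for all three predictions (set A=a and re-predict).
    Logistic-family predictions are bounded inside (0, 1).
    """
    frame.require_both_arms()
    design = encode(frame, outcome_spec)
    a = np.asarray(frame.a, dtype=float)
    x_pooled = np.column_stack([a, design.matrix])
    names = ["a", *design.columns]
    x1 = x_pooled.copy()
    x1[:, 0] = 1.0
    x0 = x_pooled.copy()
    x0[:, 0] = 0.0

    if family == "logistic":
        fitter, predictor = fit_logistic, lambda f, x: f.predict(x)
    elif family == "linear":
        fitter, predictor = fit_linear, lambda f, x: f.predict(x)
    else:
        raise ValueError(f"unknown family {family!r}")

    pooled_fit = fitter(x_pooled, frame.y, column_names=names)
    qaw = predictor(pooled_fit, x_pooled)
    if pooled:
        q1w = predictor(pooled_fit, x1)
        q0w = predictor(pooled_fit, x0)
        detail = {"pooled_fit": pooled_fit}
    else:
        arm_fits = {}
        for arm in (1, 0):
            mask = a == arm
            arm_fits[arm] = fitter(design.matrix[mask], frame.y[mask],
                                   column_names=design.columns)
        q1w = predictor(arm_fits[1], design.matrix)
        q0w = predictor(arm_fits[0], design.matrix)
        detail = {"pooled_fit": pooled_fit, "fit_a1": arm_fits[1], "fit_a0": arm_fits[0]}
    return QFit(qaw=qaw, q1w=q1w, q0w=q0w, family=family,
                spec=outcome_spec, pooled=pooled, detail=detail)


def iptw_ra(
    frame: CausalFrame,
    weights: WeightSet,
    outcome_spec: ModelSpec,
    family: str = "linear",
) -> EffectEstimate:
    """IPTW-RA: weighted regression adjustment within each arm.

    The arm-specific outcome regressions of parametric g-computation are
    refit under the supplied (typically stabilized) weights; both surfaces
    are predicted for all subjects and averaged.  With unit weights this
    reduces exactly to :func:`gmethods.gformula.parametric_gcomp`.
    """
    if len(weights.weights) != frame.n:
        raise ValueError("weight set is not aligned with the frame")
    est = parametric_gcomp(frame, outcome_spec, family=family,
                           weights=weights.weights, method="iptw-ra")
    est.diagnostics["weight_summary"] = weights.summary
    est.diagnostics["weight_kind"] = weights.kind
    return est


def aiptw(
    frame: CausalFrame,
    q: QFit,
    g: PropensityFit,
    *,
    ci_level: float = 0.95,
    box_variant: bool = False,
) -> EffectEstimate:
    """Augmented IPTW estimator of the ATE with influence-function inference.

    Canonical form::

        mu1 = mean[ Q1W + A (Y - Q1W) / g ]
        mu0 = mean[ Q0W + (1-A) (Y - Q0W) / (1-g) ]

    The augmentation terms have mean zero when the treatment model is
    correct, so the estimator is consistent if either Q or g is right.  The
    per-subject influence values give SE = sd(IF)/sqrt(n) and a Wald CI.

    ``box_variant=True`` instead augments with the stabilized-weighted
    residual of the *observed*-treatment prediction,
    ``mu_a = mean[ sws (Y - QAW) + QaW ]`` — a code-level reproduction of a
    published worked example; it is not the canonical AIPW estimating
    function and is provided for comparison only.
    """
    frame.require_both_arms()
    if len(q.qaw) != frame.n or len(g.dps) != frame.n:
        raise ValueError("q or g fit is not aligned with the frame")
    a = np.asarray(frame.a, dtype=float)
    y = frame.y
    dps = g.dps

    if box_variant:
        sws = np.where(a == 1, g.nps / dps, (1.0 - g.nps) / (1.0 - dps))
        mu1 = float(np.mean(sws * (y - q.qaw) + q.q1w))
        mu0 = float(np.mean(sws * (y - q.qaw) + q.q0w))
    else:
        mu1 = float(np.mean(q.q1w + a * (y - q.q1w) / dps))
        mu0 = float(np.mean(q.q0w + (1.0 - a) * (y - q.q0w) / (1.0 - dps)))

    d1 = a * (y - q.q1w) / dps + q.q1w - mu1
    d0 = (1.0 - a) * (y - q.q0w) / (1.0 - dps) + q.q0w - mu0
    if_values = d1 - d0
    se, (lo, hi) = if_wald(if_values, level=ci_level, center=mu1 - mu0)

    diagnostics: dict = {
        "if_values": if_values,
        "augmentation_mean_a1": float(np.mean(a * (y - q.q1w) / dps)),
        "augmentation_mean_a0": float(np.mean((1.0 - a) * (y - q.q0w) / (1.0 - dps))),
        "variant": "box" if box_variant else "canonical",
    }
    if g.n_bounded > 0.05 * frame.n:
        diagnostics["near_positivity_warning"] = (
            f"{g.n_bounded} of {frame.n} propensity predictions hit the bounding "
            f"interval {g.bounds}")
    return EffectEstimate(
        method="aiptw",
        ate=mu1 - mu0,
        mu1=mu1,
        mu0=mu0,
        se=se,
        ci_lower=lo,
        ci_upper=hi,
        ci_level=ci_level,
        ci_method="if_wald",
        diagnostics=diagnostics,
    )
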