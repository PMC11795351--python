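"""Propensity scores, inverse-probability weights and their diagnostics.

The propensity score g(W) = P(A=1|W) is fit by logistic regression.  From it
the package derives Horvitz-Thompson weights (1/g for treated, 1/(1-g) for
controls), stabilized weights (multiplied by the marginal treatment
probability), the IPTW and marginal-structural-model estimators of the ATE,
weight hygiene (trimming / truncation), and the standard balance and overlap
diagnostics used to judge whether weighting removed confounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import (
    CausalFrame,
    Design,
    EffectEstimate,
    ModelSpec,
    PositivityError,
    encode,
    fit_logistic,
)

__all__ = [
    "PropensityFit",
    "WeightSet",
    "fit_propensity",
    "ht_weights",
    "stabilized_weights",
    "iptw_ate",
    "msm_ate",
    "trim_truncate",
    "balance_report",
    "overlap_densities",
]


@dataclass
class PropensityFit:
    """Fitted treatment mechanism: per-subject g(W) and the marginal P(A=1)."""

    dps: np.ndarray          # denominator probabilities g(A=1|W_i)
    nps: float               # numerator: marginal P(A=1), intercept-only fit
    spec: ModelSpec
    bounds: tuple[float, float]
    n_bounded: int = 0       # subjects whose dps hit the bounding interval
    design: Design | None = None

    @property
    def near_positivity(self) -> bool:
        return self.n_bounded > 0


@dataclass
class WeightSet:
    """Per-subject nonnegative weights with provenance."""

    weights: np.ndarray
    kind: str  # ht | stabilized | trimmed | truncated
    provenance: dict = field(default_factory=dict)
    mask: np.ndarray | None = None  # rows kept (trimming only)
    warnings: list = field(default_factory=list)

    @property
    def summary(self) -> dict:
        w = self.weights
        return {"mean": float(np.mean(w)), "min": float(np.min(w)), "max": float(np.max(w))}


def fit_propensity(
    frame: CausalFrame,
    spec: ModelSpec,
    bounds: tuple[float, float] = (0.01, 0.99),
) -> PropensityFit:
    """Logistic fit of A on W with bounded predicted probabilities.

    Predictions are clipped into ``bounds`` (default [0.01, 0.99]); any
    clipping is recorded, never silent.  The marginal probability ``nps``
    comes from an intercept-only fit and feeds the stabilized weights.
    """
    frame.require_both_arms()
    lo, hi = bounds
    if not (0 <= lo < hi <= 1):
        raise ValueError("invalid propensity bounds")
    design = encode(frame, spec)
    fit = fit_logistic(design.matrix, np.asarray(frame.a, dtype=float),
                       column_names=design.columns)
    raw = fit.fitted
    dps = np.clip(raw, lo, hi)
    n_bounded = int(np.sum((raw < lo) | (raw > hi)))
    nps = float(np.mean(frame.a))
    return PropensityFit(dps=dps, nps=nps, spec=spec, bounds=(lo, hi),
                         n_bounded=n_bounded, design=design)


def ht_weights(fit: PropensityFit, frame: CausalFrame) -> WeightSet:
    """Unstabilized Horvitz-Thompson weights A/g + (1-A)/(1-g)."""
    _check_aligned(fit, frame)
    a = np.asarray(frame.a, dtype=float)
    w = a / fit.dps + (1.0 - a) / (1.0 - fit.dps)
    return WeightSet(weights=w, kind="ht", provenance={"bounds": fit.bounds})


def stabilized_weights(fit: PropensityFit, frame: CausalFrame) -> WeightSet:
    """Stabilized weights nps/g for treated, (1-nps)/(1-g) for controls.

    Their mean should be close to 1; a mean outside [0.5, 2] attaches a
    near-positivity warning to the weight set.
    """
    _check_aligned(fit, frame)
    a = np.asarray(frame.a, dtype=float)
    w = np.where(a == 1, fit.nps / fit.dps, (1.0 - fit.nps) / (1.0 - fit.dps))
    ws = WeightSet(weights=w, kind="stabilized",
                   provenance={"bounds": fit.bounds, "nps": fit.nps})
    mean = float(np.mean(w))
    if not (0.5 <= mean <= 2.0):
        ws.warnings.append(
            f"mean stabilized weight {mean:.3f} far from 1: possible near-positivity violation")
    return ws


def _check_aligned(fit: PropensityFit, frame: CausalFrame) -> None:
    if len(fit.dps) != frame.n:
        raise ValueError("propensity fit is not aligned with the frame")


def iptw_ate(frame: CausalFrame, weights: WeightSet, estimator: str = "ht") -> EffectEstimate:
    """IPTW estimate of the ATE from a prepared weight set.

    ``estimator="ht"`` uses the Horvitz-Thompson form mu_a = (1/n) sum I(A=a) w Y;
    ``estimator="hajek"`` normalizes by the realized weight mass in each arm
    (ratio-of-sums), which is the form implied by stabilized weighting.
    """
    frame.require_both_arms()
    w = weights.weights
    if len(w) != frame.n:
        raise ValueError("weight set is not aligned with the frame")
    a = np.asarray(frame.a, dtype=float)
    y = frame.y
    if estimator == "ht":
        mu1 = float(np.mean(a * w * y))
        mu0 = float(np.mean((1 - a) * w * y))
    elif estimator == "hajek":
        s1, s0 = float(np.sum(a * w)), float(np.sum((1 - a) * w))
        if s1 <= 0 or s0 <= 0:
            raise PositivityError("zero total weight in a treatment arm")
        mu1 = float(np.sum(a * w * y) / s1)
        mu0 = float(np.sum((1 - a) * w * y) / s0)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return EffectEstimate(
        method=f"iptw-{estimator}",
        ate=mu1 - mu0,
        mu1=mu1,
        mu0=mu0,
        diagnostics={"weight_summary": weights.summary, "kind": weights.kind},
    )


def msm_ate(frame: CausalFrame, weights: WeightSet) -> EffectEstimate:
    """Marginal structural model: weighted regression of Y on {1, A}.

    The treatment coefficient is the ATE.  A robust (HC0 sandwich) SE is
    attached as a secondary diagnostic only; the bootstrap is the preferred
    inference route because the weighted pseudo-population breaks the usual
    independence assumptions.
    """
    frame.require_both_arms()
    a = np.asarray(frame.a, dtype=float)
    x = np.column_stack([np.ones(frame.n), a])
    res = sm.WLS(frame.y, x, weights=weights.weights).fit()
    robust = res.get_robustcov_results(cov_type="HC0")
    ate = float(res.params[1])
    mu0 = float(res.params[0])
    return EffectEstimate(
        method="msm",
        ate=ate,
        mu1=mu0 + ate,
        mu0=mu0,
        diagnostics={
            "robust_se": float(robust.bse[1]),
            "weight_summary": weights.summary,
            "kind": weights.kind,
        },
    )


def trim_truncate(
    weights: WeightSet,
    policy: str,
    bounds: tuple[float, float],
    *,
    percentile: bool = True,
) -> WeightSet:
    """Weight hygiene for near-positivity violations.

    ``policy="truncate"`` winsorizes the weights at the bounds (no rows
    lost); ``policy="trim"`` drops subjects whose weight falls outside the
    bounds and records the kept-row mask.  ``bounds`` are percentiles in
    [0, 100] when ``percentile=True`` (the common 1st/99th or 5th/95th
    choices), otherwise absolute weight values.
    """
    lo, hi = bounds
    if lo > hi:
        raise ValueError("lower bound exceeds upper bound")
    w = weights.weights
    if percentile:
        lo_v, hi_v = np.percentile(w, [lo, hi])
    else:
        lo_v, hi_v = float(lo), float(hi)
    if policy == "truncate":
        new = np.clip(w, lo_v, hi_v)
        affected = int(np.sum((w < lo_v) | (w > hi_v)))
        return WeightSet(
            weights=new, kind="truncated",
            provenance={**weights.provenance, "thresholds": (lo_v, hi_v),
                        "n_affected": affected, "parent": weights.kind})
    if policy == "trim":
        mask = (w >= lo_v) & (w <= hi_v)
        return WeightSet(
            weights=w[mask], kind="trimmed", mask=mask,
            provenance={**weights.provenance, "thresholds": (lo_v, hi_v),
                        "n_dropped": int(np.sum(~mask)), "parent": weights.kind})
    raise ValueError(f"unknown policy {policy!r}")


def _weighted_moments(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    sw = np.sum(w)
    mean = float(np.sum(w * x) / sw)
    var = float(np.sum(w * (x - mean) ** 2) / sw)  # frequency-weight convention
    return mean, var


def balance_report(frame: CausalFrame, weights: WeightSet | None = None) -> pd.DataFrame:
    """Standardized differences and variance ratios per encoded confounder column.

    The standardized difference is (m1 - m0) / sqrt((v1 + v0) / 2) with arm
    means and variances computed unweighted for the raw rows and with the
    supplied weights (Hajek means, frequency-weighted variances) for the
    weighted rows.  The variance ratio v1/v0 uses the same moments.
    """
    frame.require_both_arms()
    spec = ModelSpec(terms=tuple(frame.w.columns), include_intercept=False)
    design = encode(frame, spec)
    a = np.asarray(frame.a)
    ones = np.ones(frame.n)
    w = ones if weights is None else weights.weights
    rows = []
    for j, name in enumerate(design.columns):
        col = design.matrix[:, j]
        entry = {"column": name}
        for label, wt in (("raw", ones), ("weighted", w)):
            m1, v1 = _weighted_moments(col[a == 1], wt[a == 1])
            m0, v0 = _weighted_moments(col[a == 0], wt[a == 0])
            pooled = (v1 + v0) / 2.0
            if pooled <= 0:
                if abs(m1 - m0) < 1e-12:
                    sd = 0.0
                else:
                    raise ZeroDivisionError(
                        f"zero pooled variance with unequal arm means for {name!r}")
            else:
                sd = (m1 - m0) / np.sqrt(pooled)
            entry[f"std_diff_{label}"] = sd
            entry[f"var_ratio_{label}"] = v1 / v0 if v0 > 0 else np.inf
        rows.append(entry)
    report = pd.DataFrame(rows)
    if weights is None:
        report["std_diff_weighted"] = report["std_diff_raw"]
        report["var_ratio_weighted"] = report["var_ratio_raw"]
    return report


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    std = np.std(x, ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    sigma = min(std, iqr / 1.349) if iqr > 0 else std
    if sigma <= 0:
        sigma = max(std, 1e-3)
    # Epanechnikov-optimal constant (2.345) applied to Silverman's rule
    return 2.345 * sigma * n ** (-0.2)


def overlap_densities(
    fit: PropensityFit,
    frame: CausalFrame,
    grid_size: int = 512,
) -> pd.DataFrame:
    """Kernel density of the propensity score within each arm on a common grid.

    Epanechnikov kernel with a Silverman-rule bandwidth.  The grid spans the
    union of both arms' supports (padded by one bandwidth, clipped to [0, 1])
    so each density integrates to ~1 on the grid; columns are ``grid``,
    ``density_treated`` and ``density_control``.
    """
    _check_aligned(fit, frame)
    a = np.asarray(frame.a)
    ps1, ps0 = fit.dps[a == 1], fit.dps[a == 0]
    h1, h0 = _silverman_bandwidth(ps1), _silverman_bandwidth(ps0)
    pad = max(h1, h0)
    lo = max(0.0, min(fit.dps.min() - pad, 1.0))
    hi = min(1.0, fit.dps.max() + pad)
    grid = np.linspace(lo, hi, grid_size)

    def kde(points: np.ndarray, h: float) -> np.ndarray:
        u = (grid[:, None] - points[None, :]) / h
        k = np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u ** 2), 0.0)
        return k.mean(axis=1) / h

    return pd.DataFrame({
        "grid": grid,
        "density_treated": kde(ps1, h1),
        "density_control": kde(ps0, h0),
    })
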