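"""G-computation estimators of the ATE.

Three routes to the same standardization estimand:

* :func:`np_gformula` — direct nonparametric standardization: stratum-specific
  treatment contrasts averaged over the empirical confounder distribution,
  ``ATE = sum_w [E(Y|A=1,w) - E(Y|A=0,w)] P(W=w)``.
* :func:`saturated_gformula` — the same estimand through a fully saturated
  cell-mean regression (one coefficient per treatment-by-stratum cell),
  averaging per-subject predicted contrasts.
* :func:`parametric_gcomp` — parametric outcome models fit separately in each
  arm, both potential-outcome surfaces predicted for every subject, and the
  ATE taken as the difference of the surface means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    CausalFrame,
    EffectEstimate,
    ModelSpec,
    PositivityError,
    encode,
    fit_linear,
    fit_logistic,
)

__all__ = ["np_gformula", "saturated_gformula", "parametric_gcomp", "stratum_table"]


def stratum_table(frame: CausalFrame, strata: list[str]) -> pd.DataFrame:
    """Per-stratum cell counts, conditional outcome means and stratum weights."""
    for name in strata:
        if frame.w_types[name] != "categorical":
            raise ValueError(f"stratification requires categorical confounders ({name!r})")
    df = frame.to_dataframe()
    if strata:
        key = df[strata].astype(str).agg("|".join, axis=1)
    else:
        key = pd.Series(["<all>"] * frame.n)
    out = []
    for label, grp in df.groupby(key, sort=True):
        n1 = int((grp["a"] == 1).sum())
        n0 = int((grp["a"] == 0).sum())
        out.append(
            {
                "stratum": label,
                "p_w": len(grp) / frame.n,
                "n1": n1,
                "n0": n0,
                "mean_y1": grp.loc[grp["a"] == 1, "y"].mean() if n1 else np.nan,
                "mean_y0": grp.loc[grp["a"] == 0, "y"].mean() if n0 else np.nan,
            }
        )
    return pd.DataFrame(out)


def np_gformula(frame: CausalFrame, strata: list[str]) -> EffectEstimate:
    """Nonparametric g-formula (standardization) over categorical strata.

    Requires every treatment-by-stratum cell to be non-empty (in-sample
    positivity); an empty cell raises :class:`PositivityError` naming the
    offending stratum.  No analytic variance is produced — use the bootstrap.
    """
    frame.require_both_arms()
    table = stratum_table(frame, list(strata))
    empty = table[(table["n1"] == 0) | (table["n0"] == 0)]
    if len(empty):
        raise PositivityError(
            "empty treatment-by-stratum cell(s): "
            + ", ".join(empty["stratum"].astype(str)))
    mu1 = float((table["mean_y1"] * table["p_w"]).sum())
    mu0 = float((table["mean_y0"] * table["p_w"]).sum())
    return EffectEstimate(
        method="np-gformula",
        ate=mu1 - mu0,
        mu1=mu1,
        mu0=mu0,
        diagnostics={"stratum_table": table},
    )


def saturated_gformula(frame: CausalFrame, strata: list[str]) -> EffectEstimate:
    """G-formula via a fully saturated (treatment x stratum) linear regression.

    Numerically identical to :func:`np_gformula`: the saturated least-squares
    fit reproduces the cell means exactly, and averaging the per-subject
    predicted contrast reweights them by the stratum frequencies.
    """
    frame.require_both_arms()
    spec = ModelSpec(terms=tuple(strata), saturated=True, include_intercept=False)
    design = encode(frame, spec, interact_with_treatment=True)
    k = design.matrix.shape[1] // 2
    counts = design.matrix.sum(axis=0)
    if (counts == 0).any():
        labels = [design.columns[j] for j in np.flatnonzero(counts == 0)]
        raise PositivityError(f"empty treatment-by-stratum cell(s): {', '.join(labels)}")
    fit = fit_linear(design.matrix, frame.y, column_names=design.columns)
    base = design.matrix[:, :k] + design.matrix[:, k:]  # stratum indicators
    x1 = np.hstack([np.zeros_like(base), base])  # everyone treated
    x0 = np.hstack([base, np.zeros_like(base)])  # everyone untreated
    mu1 = float(np.mean(fit.predict(x1)))
    mu0 = float(np.mean(fit.predict(x0)))
    return EffectEstimate(
        method="saturated-gformula",
        ate=mu1 - mu0,
        mu1=mu1,
        mu0=mu0,
        diagnostics={"coef": dict(zip(fit.columns, fit.coef))},
    )


def _arm_design(frame: CausalFrame, spec: ModelSpec):
    design = encode(frame, spec)
    return design


def parametric_gcomp(
    frame: CausalFrame,
    outcome_spec: ModelSpec,
    family: str = "linear",
    weights: np.ndarray | None = None,
    method: str = "gcomp",
) -> EffectEstimate:
    """Parametric g-computation: arm-specific outcome regressions.

    Fits E(Y|W) within A=1 and within A=0 (``family`` is ``"linear"`` for a
    linear probability model or ``"logistic"`` for bounded predictions),
    predicts both potential-outcome surfaces for all subjects, and averages.
    Optional per-subject ``weights`` turn this into the weighted regression
    adjustment used by the IPTW-RA doubly robust estimator.
    """
    frame.require_both_arms()
    design = _arm_design(frame, outcome_spec)
    x = design.matrix
    preds = {}
    fits = {}
    for arm in (1, 0):
        mask = np.asarray(frame.a) == arm
        xa, ya = x[mask], frame.y[mask]
        if xa.shape[0] < xa.shape[1]:
            raise np.linalg.LinAlgError(
                f"arm A={arm} has fewer rows ({xa.shape[0]}) than design columns ({xa.shape[1]})")
        wa = None if weights is None else np.asarray(weights, dtype=float)[mask]
        if family == "linear":
            fit = fit_linear(xa, ya, weights=wa, column_names=design.columns)
            preds[arm] = fit.predict(x)
        elif family == "logistic":
            fit = fit_logistic(xa, ya, weights=wa, column_names=design.columns)
            preds[arm] = fit.predict(x)
        else:
            raise ValueError(f"unknown family {family!r}")
        fits[arm] = fit
    mu1 = float(np.mean(preds[1]))
    mu0 = float(np.mean(preds[0]))
    return EffectEstimate(
        method=method,
        ate=mu1 - mu0,
        mu1=mu1,
        mu0=mu0,
        diagnostics={"fit_a1": fits[1], "fit_a0": fits[0], "family": family,
                     "y1_hat": preds[1], "y0_hat": preds[0]},
    )
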