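"""Resampling and analytic inference shared by the estimators.

Model-based standard errors are wrong for multi-step causal estimators, so
the package offers (a) the nonparametric bootstrap with normal, percentile
and bias-corrected intervals, and (b) Wald intervals from the variance of a
per-subject influence function for the estimators that have one (AIPTW,
TMLE).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .core import CausalFrame, GmethodsError

__all__ = ["BootstrapResult", "bootstrap", "if_wald"]


@dataclass
class BootstrapResult:
    estimate: float              # point estimate on the full data
    replicates: np.ndarray       # successful replicate statistics
    seed: int
    level: float
    n_failed: int = 0
    failures: list = field(default_factory=list)

    @property
    def se(self) -> float:
        return float(np.std(self.replicates, ddof=1))

    def ci(self, method: str = "bc") -> tuple[float, float]:
        """Interval by ``method`` in {"normal", "percentile", "bc"}."""
        alpha = 1.0 - self.level
        reps = self.replicates
        if method == "normal":
            z = stats.norm.ppf(1.0 - alpha / 2.0)
            return (self.estimate - z * self.se, self.estimate + z * self.se)
        if method == "percentile":
            lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])  # type-7
            return (float(lo), float(hi))
        if method == "bc":
            frac = np.mean(reps < self.estimate)
            frac = min(max(frac, 1.0 / (len(reps) + 1)), len(reps) / (len(reps) + 1))
            z0 = stats.norm.ppf(frac)
            zlo, zhi = stats.norm.ppf([alpha / 2.0, 1.0 - alpha / 2.0])
            plo = stats.norm.cdf(2.0 * z0 + zlo)
            phi = stats.norm.cdf(2.0 * z0 + zhi)
            lo, hi = np.quantile(reps, [plo, phi])
            return (float(lo), float(hi))
        raise ValueError(f"unknown interval method {method!r}")

    def intervals(self) -> dict:
        return {m: self.ci(m) for m in ("normal", "percentile", "bc")}


def bootstrap(
    estimator: Callable[[CausalFrame], float],
    frame: CausalFrame,
    b: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
    max_failure_rate: float = 0.10,
) -> BootstrapResult:
    """Nonparametric bootstrap of a frame -> scalar estimator.

    Draws ``b`` resamples of n rows with replacement (seeded, reproducible),
    recomputes the statistic on each, and exposes normal, percentile and
    bias-corrected intervals.  Replicates on which the estimator raises
    (e.g. an empty stratum under the nonparametric g-formula) are excluded
    and counted; more than ``max_failure_rate`` failures is an error
    recommending a larger sample or a parametric method.
    """
    if b < 2:
        raise ValueError("bootstrap needs at least 2 replicates")
    if seed is None:
        raise ValueError("a seed is required for reproducible bootstrap inference")
    point = float(estimator(frame))
    rng = np.random.default_rng(seed)
    reps = []
    failures = []
    n = frame.n
    for _ in range(b):
        idx = rng.integers(0, n, size=n)
        try:
            reps.append(float(estimator(frame.take(idx))))
        except Exception as exc:  # failed replicate: recorded, excluded
            failures.append(str(exc))
    if len(failures) > max_failure_rate * b:
        raise GmethodsError(
            f"{len(failures)} of {b} bootstrap replicates failed "
            f"(e.g. {failures[0]!r}); consider a larger sample or a parametric estimator")
    return BootstrapResult(
        estimate=point,
        replicates=np.asarray(reps),
        seed=seed,
        level=level,
        n_failed=len(failures),
        failures=failures[:10],
    )


def if_wald(
    if_values: np.ndarray,
    level: float = 0.95,
    center: float | None = None,
) -> tuple[float, tuple[float | None, float | None]]:
    """SE and Wald interval from per-subject influence values.

    SE = sqrt(Var(IF) / n).  The interval is centered at ``center`` (the
    point estimate) when given, otherwise only the SE is meaningful and the
    interval is (None, None).
    """
    vals = np.asarray(if_values, dtype=float)
    n = len(vals)
    se = float(np.sqrt(np.var(vals, ddof=1) / n)) if n > 1 else 0.0
    if center is None:
        return se, (None, None)
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    return se, (center - z * se, center + z * se)
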