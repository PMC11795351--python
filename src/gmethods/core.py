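"""Shared data containers, design-matrix encoding and GLM fitting kernels.

Every estimator in the package operates on a :class:`CausalFrame` — a
validated cohort with a binary treatment ``a``, an outcome ``y`` that is
either binary or bounded in [0, 1], and a named set of confounders ``w``
each declared categorical or continuous.  Results are returned as
:class:`EffectEstimate` objects carrying the marginal mean potential
outcomes mu1/mu0 and their difference, the average treatment effect on the
risk-difference (probability) scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

__all__ = [
    "CausalFrame",
    "EffectEstimate",
    "ModelSpec",
    "Design",
    "encode",
    "fit_logistic",
    "fit_linear",
    "read_cohort_csv",
    "GmethodsError",
    "SeparationError",
    "ConvergenceError",
    "PositivityError",
    "expit",
    "logit",
]

PROB_FLOOR = 1e-10  # fitted probabilities clipped into [floor, 1-floor]


class GmethodsError(Exception):
    """Base class for estimation errors."""


class SeparationError(GmethodsError):
    """Complete (or quasi-complete) separation in a logistic fit."""


class ConvergenceError(GmethodsError):
    """Iterative fit did not converge; carries the last iterate."""

    def __init__(self, message: str, last_coef=None):
        super().__init__(message)
        self.last_coef = last_coef


class PositivityError(GmethodsError):
    """Empty (a, w) cell or zero weight mass in an arm."""


def expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


# ---------------------------------------------------------------------------
# containers


class CausalFrame:
    """One row per subject: outcome, binary treatment and typed confounders.

    Parameters
    ----------
    y : array-like
        Outcome. Either strictly binary {0, 1} or continuous in [0, 1]
        (the latter arises for simulated cohorts whose outcome is an event
        probability).
    a : array-like
        Treatment indicator in {0, 1}.
    w : pandas.DataFrame or mapping of name -> column
        Confounders.
    w_types : mapping name -> {"categorical", "continuous"}
        Declared type per confounder.
    """

    def __init__(self, y, a, w, w_types: Mapping[str, str], *, validate: bool = True):
        self.y = np.asarray(y, dtype=float)
        self.a = np.asarray(a)
        if not isinstance(w, pd.DataFrame):
            w = pd.DataFrame(dict(w))
        self.w = w.reset_index(drop=True)
        self.w_types = dict(w_types)
        if validate:
            self._validate()
        self.a = self.a.astype(np.int8)

    def _validate(self) -> None:
        n = len(self.y)
        if n == 0:
            raise ValueError("empty cohort")
        if len(self.a) != n or len(self.w) != n:
            raise ValueError("y, a and w must have equal length")
        if np.isnan(self.y).any():
            raise ValueError("missing values in outcome are rejected at construction")
        a = np.asarray(self.a, dtype=float)
        if np.isnan(a).any():
            raise ValueError("missing values in treatment are rejected at construction")
        if not np.isin(a, (0.0, 1.0)).all():
            raise ValueError("treatment must take only values {0, 1}")
        if self.y.min() < 0.0 or self.y.max() > 1.0:
            raise ValueError("outcome must be binary {0,1} or continuous in [0, 1]")
        if set(self.w_types) != set(self.w.columns):
            raise ValueError("w_types must name exactly the confounder columns")
        if len(set(self.w.columns)) != len(self.w.columns):
            raise ValueError("confounder names must be unique")
        for name, kind in self.w_types.items():
            if kind not in ("categorical", "continuous"):
                raise ValueError(f"unknown confounder type {kind!r} for {name!r}")
            col = self.w[name]
            if col.isna().any():
                raise ValueError(f"missing values in confounder {name!r}")
            if kind == "categorical" and col.nunique() < 2:
                raise ValueError(f"categorical confounder {name!r} has < 2 observed levels")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def y_binary(self) -> bool:
        return bool(np.isin(self.y, (0.0, 1.0)).all())

    def require_both_arms(self) -> None:
        if not (self.a == 1).any() or not (self.a == 0).any():
            raise PositivityError("both treatment arms must be non-empty")

    def take(self, indices) -> "CausalFrame":
        idx = np.asarray(indices)
        return CausalFrame(
            self.y[idx],
            self.a[idx],
            self.w.iloc[idx].reset_index(drop=True),
            self.w_types,
            validate=False,
        )

    def to_dataframe(self, outcome: str = "y", treatment: str = "a") -> pd.DataFrame:
        df = self.w.copy()
        df.insert(0, treatment, self.a)
        df.insert(0, outcome, self.y)
        return df

    def __repr__(self) -> str:  # pragma: no cover
        return f"CausalFrame(n={self.n}, confounders={list(self.w.columns)})"


@dataclass
class EffectEstimate:
    """A marginal treatment-effect estimate on the probability scale."""

    method: str
    ate: float
    mu1: float | None = None
    mu0: float | None = None
    se: float | None = None
    ci_lower: float | None = None
    ci_upper: float | None = None
    ci_level: float = 0.95
    ci_method: str = "none"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mu1 is not None and self.mu0 is not None:
            if abs(self.ate - (self.mu1 - self.mu0)) > 1e-12:
                raise ValueError("ate must equal mu1 - mu0")
        if self.ci_lower is not None and self.ci_upper is not None:
            if self.ci_lower > self.ci_upper:
                raise ValueError("ci_lower must not exceed ci_upper")
        if self.ci_method not in (
            "if_wald",
            "bootstrap_normal",
            "bootstrap_percentile",
            "bootstrap_bc",
            "none",
        ):
            raise ValueError(f"unknown ci_method {self.ci_method!r}")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "ate": self.ate,
            "mu1": self.mu1,
            "mu0": self.mu0,
            "se": self.se,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "ci_level": self.ci_level,
            "ci_method": self.ci_method,
        }


@dataclass
class ModelSpec:
    """Right-hand-side specification for a nuisance regression.

    ``terms`` lists confounder names; a term of the form ``"x:z"`` denotes
    the elementwise product of the raw (numeric) columns x and z.  Per-term
    type overrides in ``types`` replace the frame's declared type, so a
    categorical code can be entered linearly (``{"w1": "continuous"}``).
    ``saturated=True`` builds one indicator per observed combination of the
    (all categorical) terms with no intercept.
    """

    terms: Sequence[str] = ()
    types: Mapping[str, str] | None = None
    include_intercept: bool = True
    saturated: bool = False

    def term_type(self, frame: CausalFrame, term: str) -> str:
        if ":" in term:
            return "continuous"
        if self.types and term in self.types:
            return self.types[term]
        return frame.w_types[term]


# ---------------------------------------------------------------------------
# encoding


class Design:
    """An encoded design matrix plus the recipe to re-apply it.

    ``transform`` re-encodes another frame with the same column layout and
    raises on confounder levels not seen at construction time.
    """

    def __init__(self, matrix: np.ndarray, columns: list[str], spec: ModelSpec,
                 levels: dict[str, list], strata: pd.Series | None = None):
        self.matrix = matrix
        self.columns = columns
        self.spec = spec
        self.levels = levels
        self.strata = strata  # observed stratum label per row (saturated only)

    def transform(self, frame: CausalFrame) -> np.ndarray:
        return _build_design(frame, self.spec, reference=self).matrix


def _term_values(frame: CausalFrame, term: str) -> np.ndarray:
    if ":" in term:
        left, right = term.split(":", 1)
        return (np.asarray(frame.w[left], dtype=float)
                * np.asarray(frame.w[right], dtype=float))
    return np.asarray(frame.w[term])


def _build_design(frame: CausalFrame, spec: ModelSpec, reference: Design | None = None) -> Design:
    for term in spec.terms:
        for name in term.split(":"):
            if name not in frame.w.columns:
                raise KeyError(f"unknown confounder {name!r} in model spec")

    if spec.saturated:
        for term in spec.terms:
            if spec.term_type(frame, term) != "categorical":
                raise ValueError("saturated specification requires all terms categorical")
        if spec.terms:
            labels = frame.w[list(spec.terms)].astype(str).agg("|".join, axis=1)
        else:
            labels = pd.Series(["<all>"] * frame.n)
        if reference is None:
            strata = sorted(labels.unique())
        else:
            strata = reference.levels["<strata>"]
            unseen = set(labels.unique()) - set(strata)
            if unseen:
                raise ValueError(f"unseen confounder stratum at prediction time: {sorted(unseen)}")
        cols = [f"stratum[{s}]" for s in strata]
        mat = np.column_stack([(labels == s).to_numpy(dtype=float) for s in strata])
        return Design(mat, cols, spec, {"<strata>": list(strata)}, strata=labels)

    blocks: list[np.ndarray] = []
    names: list[str] = []
    levels: dict[str, list] = {}
    if spec.include_intercept:
        blocks.append(np.ones((frame.n, 1)))
        names.append("intercept")
    for term in spec.terms:
        vals = _term_values(frame, term)
        if spec.term_type(frame, term) == "continuous":
            blocks.append(np.asarray(vals, dtype=float).reshape(-1, 1))
            names.append(term)
        else:
            if reference is None:
                obs = sorted(pd.unique(vals))
                levels[term] = obs
            else:
                obs = reference.levels[term]
                unseen = set(pd.unique(vals)) - set(obs)
                if unseen:
                    raise ValueError(
                        f"unseen level(s) {sorted(unseen)} of {term!r} at prediction time")
            # lowest sort-order level is the reference and is dropped
            for lev in obs[1:]:
                blocks.append((vals == lev).astype(float).reshape(-1, 1))
                names.append(f"{term}[{lev}]")
    mat = np.hstack(blocks) if blocks else np.empty((frame.n, 0))
    return Design(mat, names, spec, levels)


def encode(frame: CausalFrame, spec: ModelSpec, *, interact_with_treatment: bool = False) -> Design:
    """Build a design matrix for ``spec`` on ``frame``.

    Categorical terms are one-hot encoded with the lowest sort-order level
    as the dropped reference; continuous terms pass through; column order is
    deterministic (term order, then level order).  With ``saturated=True``
    one indicator per observed stratum is produced and no intercept.  With
    ``interact_with_treatment=True`` (saturated only) each stratum indicator
    is crossed with both treatment levels, yielding the fully saturated
    cell-mean design.
    """
    design = _build_design(frame, spec)
    if interact_with_treatment:
        if not spec.saturated:
            raise ValueError("treatment interaction is only supported for saturated specs")
        a = np.asarray(frame.a, dtype=float).reshape(-1, 1)
        mats, cols = [], []
        for a_level, mask in ((0, 1.0 - a), (1, a)):
            mats.append(design.matrix * mask)
            cols.extend(f"a={a_level}:{c}" for c in design.columns)
        out = Design(np.hstack(mats), cols, design.spec, design.levels, design.strata)
        return out
    return design


# ---------------------------------------------------------------------------
# fitting kernels


@dataclass
class LinearFit:
    coef: np.ndarray
    fitted: np.ndarray
    columns: list[str]
    dropped: list[str]

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float)[:, self._keep] @ self.coef

    _keep: np.ndarray = field(default=None, repr=False)


@dataclass
class LogisticFit:
    coef: np.ndarray
    fitted: np.ndarray
    columns: list[str]
    dropped: list[str]
    converged: bool

    def predict(self, x: np.ndarray, offset=None) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        eta = np.zeros(len(x)) if offset is None else np.asarray(offset, dtype=float).copy()
        if x.shape[1]:
            eta = eta + x[:, self._keep] @ self.coef
        return np.clip(expit(eta), PROB_FLOOR, 1.0 - PROB_FLOOR)

    _keep: np.ndarray = field(default=None, repr=False)


def _independent_columns(x: np.ndarray, weights=None) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (pivoted QR)."""
    if x.shape[1] == 0:
        return np.array([], dtype=int)
    xs = x if weights is None else x * np.sqrt(np.asarray(weights, dtype=float))[:, None]
    from scipy.linalg import qr

    r = qr(xs, mode="r", pivoting=True)
    diag = np.abs(np.diag(r[0]))[: min(xs.shape)]
    scale = diag[0] if diag.size and diag[0] > 0 else 1.0
    rank = int(np.sum(diag > 1e-10 * scale))
    keep = np.sort(r[1][:rank])
    return keep


def _resolve_columns(x, column_names):
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x.reshape(-1, 1)
    if column_names is None:
        column_names = [f"x{j}" for j in range(x.shape[1])]
    return x, list(column_names)


def fit_linear(x, y, weights=None, *, column_names=None) -> LinearFit:
    """(Weighted) least squares; degenerate columns dropped with a warning."""
    x, names = _resolve_columns(x, column_names)
    y = np.asarray(y, dtype=float)
    keep = _independent_columns(x, weights)
    dropped = [names[j] for j in range(x.shape[1]) if j not in keep]
    if dropped:
        warnings.warn(f"dropping rank-deficient design column(s): {dropped}", stacklevel=2)
    xk = x[:, keep]
    if xk.shape[1] == 0:
        coef = np.empty(0)
        fitted = np.zeros(len(y))
    else:
        if weights is None:
            coef, *_ = np.linalg.lstsq(xk, y, rcond=None)
        else:
            sw = np.sqrt(np.asarray(weights, dtype=float))
            coef, *_ = np.linalg.lstsq(xk * sw[:, None], y * sw, rcond=None)
        fitted = xk @ coef
    fit = LinearFit(coef=coef, fitted=fitted, columns=[names[j] for j in keep], dropped=dropped)
    fit._keep = keep
    return fit


def fit_logistic(x, y, *, offset=None, weights=None, column_names=None,
                 tol: float = 1e-12, maxiter: int = 100) -> LogisticFit:
    """Maximum-likelihood logistic fit (IRLS via statsmodels GLM).

    Supports a per-row linear-predictor ``offset`` and nonnegative prior
    ``weights`` (weighted Bernoulli log-likelihood).  ``y`` may be a
    proportion in [0, 1].  Fitted probabilities are clipped into
    ``[1e-10, 1 - 1e-10]`` so downstream logit transforms stay finite.
    """
    x, names = _resolve_columns(x, column_names)
    y = np.asarray(y, dtype=float)
    n = len(y)
    off = None if offset is None else np.asarray(offset, dtype=float)

    if x.shape[1] == 0:
        eta = np.zeros(n) if off is None else off
        fit = LogisticFit(coef=np.empty(0), fitted=np.clip(expit(eta), PROB_FLOOR, 1 - PROB_FLOOR),
                          columns=[], dropped=[], converged=True)
        fit._keep = np.array([], dtype=int)
        return fit

    w = None
    rows = slice(None)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        rows = w > 0

    keep = _independent_columns(x[rows], None if w is None else w[rows])
    dropped = [names[j] for j in range(x.shape[1]) if j not in keep]
    if dropped:
        warnings.warn(f"dropping rank-deficient design column(s): {dropped}", stacklevel=2)
    xk = x[:, keep]
    if xk.shape[1] == 0:
        raise ValueError("design matrix has no usable columns")

    kwargs = {}
    if off is not None:
        kwargs["offset"] = off[rows] if rows is not slice(None) else off
    if w is not None:
        kwargs["var_weights"] = w[rows]

    separation_seen = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(y[rows], xk[rows] if rows is not slice(None) else xk,
                       family=sm.families.Binomial(), **kwargs)
        try:
            res = model.fit(maxiter=maxiter, tol=tol)
        except Exception as exc:  # statsmodels raises on some degenerate inputs
            raise ConvergenceError(f"logistic fit failed: {exc}") from None
    for item in caught:
        if issubclass(item.category, PerfectSeparationWarning):
            separation_seen = True

    coef = np.asarray(res.params, dtype=float)
    eta = np.zeros(n) if off is None else off.copy()
    eta += xk @ coef
    raw_prob = expit(eta)

    pinned = (raw_prob <= PROB_FLOOR) | (raw_prob >= 1 - PROB_FLOOR)
    if separation_seen and pinned.any() and np.max(np.abs(coef)) > 20:
        worst = names[keep[int(np.argmax(np.abs(coef)))]]
        raise SeparationError(
            f"complete separation detected in logistic fit (column {worst!r}); "
            "consider trimming or respecifying the model")
    if not res.converged:
        raise ConvergenceError(
            f"logistic fit did not converge in {maxiter} iterations", last_coef=coef)

    fit = LogisticFit(coef=coef, fitted=np.clip(raw_prob, PROB_FLOOR, 1 - PROB_FLOOR),
                      columns=[names[j] for j in keep], dropped=dropped, converged=True)
    fit._keep = keep
    return fit


# ---------------------------------------------------------------------------
# i/o


def read_cohort_csv(path, outcome: str, treatment: str,
                    confounders: Mapping[str, str]) -> CausalFrame:
    """Read a cohort CSV (header row required; '.' decimal) into a CausalFrame."""
    df = pd.read_csv(path)
    missing = [c for c in [outcome, treatment, *confounders] if c not in df.columns]
    if missing:
        raise KeyError(f"columns not found in {path}: {missing}")
    return CausalFrame(df[outcome].to_numpy(), df[treatment].to_numpy(),
                       df[list(confounders)], dict(confounders))
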