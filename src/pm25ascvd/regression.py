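"""Logistic-regression fitting contract shared by every analysis module.

Two adjustment sets are used throughout: Model 1 is crude (intercept +
exposure only) and Model 2 additionally adjusts for gender, marital status,
educational level, average monthly income, physical activity, high-fat diet,
drinking status, and fruit-and-vegetable intake.  Categorical covariates are
dummy-encoded against the first listed level of their pandas Categorical.

``fit_logistic`` wraps statsmodels' Newton ML fit with explicit convergence,
separation and conditioning diagnostics.  ``oracle_fit`` maximizes the same
likelihood by a derivative-free simplex/Powell search and exists solely so
tests can cross-check the main path on small instances; it is intentionally
restricted to tiny problems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
import statsmodels.api as sm

__all__ = [
    "MODEL2_COVARIATES",
    "ModelSpec",
    "FitResult",
    "SeparationError",
    "build_design",
    "fit_logistic",
    "fit_exposure_model",
    "percent_excess",
    "oracle_fit",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

#: Adjustment covariates of Model 2, in cohort-table column naming.
MODEL2_COVARIATES = (
    "gender",
    "marital_status",
    "education",
    "income",
    "physical_activity",
    "high_fat_diet",
    "drinking",
    "fruit_veg",
)

CONDITION_WARN = 1e8


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


@dataclass
class ModelSpec:
    """Specification of one single-exposure logistic model.

    ``covariates`` is "model1" (none) or "model2" (the fixed adjustment set);
    ``extra_terms`` holds additional numeric regressors (e.g. total PM2.5 mass
    in proportion models).
    """

    outcome: str = "high_risk"
    exposure: str | None = None
    covariates: str = "model2"
    extra_terms: tuple = ()
    scale: float = 1.0  # exposure divided by this => OR per `scale` units

    def covariate_list(self) -> tuple:
        if self.covariates == "model1":
            return ()
        if self.covariates == "model2":
            return MODEL2_COVARIATES
        raise ValueError(f"unknown covariate set {self.covariates!r}")


@dataclass
class FitResult:
    """Inference for the exposure term of one fitted logistic model."""

    term: str
    beta: float
    se: float
    n: int
    loglik: float
    converged: bool
    cond_number: float
    params: pd.Series = field(repr=False, default=None)
    cov: pd.DataFrame = field(repr=False, default=None)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - Z_95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + Z_95 * self.se))

    def as_row(self) -> dict:
        return {
            "term": self.term,
            "beta": self.beta,
            "se": self.se,
            "or": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n,
            "loglik": self.loglik,
            "converged": self.converged,
        }


def _encode_categoricals(df: pd.DataFrame, columns) -> pd.DataFrame:
    """Dummy-encode against the first category; numeric columns pass through."""
    pieces = []
    for col in columns:
        s = df[col]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            cat = s.astype("category")
            dummies = pd.get_dummies(cat, prefix=col, drop_first=True, dtype=float)
            pieces.append(dummies)
        else:
            pieces.append(s.astype(float).to_frame(col))
    if not pieces:
        return pd.DataFrame(index=df.index)
    return pd.concat(pieces, axis=1)


def build_design(
    cohort: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix (with intercept) and response for one model spec.

    Complete cases only: rows missing any used column are dropped.  Constant
    non-intercept columns trigger a warning; an empty complete-case set or a
    rank-deficient design is an error.
    """
    used = [spec.outcome]
    if spec.exposure is not None:
        used.append(spec.exposure)
    used += list(spec.covariate_list()) + list(spec.extra_terms)
    missing_cols = [c for c in used if c not in cohort.columns]
    if missing_cols:
        raise KeyError(f"cohort lacks columns {missing_cols}")
    data = cohort[used].dropna()
    if data.empty:
        raise ValueError("no complete cases for the requested model")

    parts = [pd.Series(1.0, index=data.index, name="const").to_frame()]
    if spec.exposure is not None:
        parts.append(
            (data[spec.exposure].astype(float) / spec.scale).to_frame(spec.exposure)
        )
    for col in spec.extra_terms:
        parts.append(data[col].astype(float).to_frame(col))
    parts.append(_encode_categoricals(data, spec.covariate_list()))
    X = pd.concat(parts, axis=1)

    nunique = X.nunique()
    constant = [c for c in X.columns if c != "const" and nunique[c] <= 1]
    if constant:
        warnings.warn(f"constant design column(s): {constant}", stacklevel=2)
    y = data[spec.outcome].astype(float)
    if not set(np.unique(y)).issubset({0.0, 1.0}):
        raise ValueError(f"outcome {spec.outcome!r} is not binary 0/1")
    return X, y


def _design_condition(X: np.ndarray) -> float:
    sv = np.linalg.svd(X, compute_uv=False)
    return float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf


def _detect_separation(X: np.ndarray, y: np.ndarray, params: np.ndarray) -> bool:
    p = special.expit(X @ params)
    pinned = ((p > 1 - 1e-8) & (y == 1)) | ((p < 1e-8) & (y == 0))
    return bool(pinned.all()) or bool(np.abs(params).max() > 50)


def fit_logistic(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    term: str | None = None,
    tol: float = 1e-10,
    maxiter: int = 200,
) -> FitResult:
    """Maximum-likelihood logistic fit with Wald 95% CI for ``term``.

    Raises :class:`SeparationError` on (quasi-)complete separation and
    ``np.linalg.LinAlgError`` on a rank-deficient design; near-collinearity
    (condition number above 1e8) is a warning recorded on the result.
    """
    X = pd.DataFrame(X)
    if term is None:
        # first non-intercept column by convention
        term = next((c for c in X.columns if c != "const"), X.columns[0])
    y_arr = np.asarray(y, dtype=float)
    X_arr = X.to_numpy(dtype=float)
    if y_arr.min() == y_arr.max():
        raise SeparationError("response is constant; logistic MLE does not exist")
    rank = np.linalg.matrix_rank(X_arr)
    if rank < X_arr.shape[1]:
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {X_arr.shape[1]} columns)"
        )
    cond = _design_condition(X_arr)
    if cond > CONDITION_WARN:
        warnings.warn(
            f"design condition number {cond:.3g} exceeds {CONDITION_WARN:.0e}",
            stacklevel=2,
        )

    model = sm.Logit(y_arr, X_arr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", tol=tol, maxiter=maxiter, disp=0)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            raise SeparationError("perfect separation detected during fitting")
    params = np.asarray(res.params, dtype=float)
    if _detect_separation(X_arr, y_arr, params):
        raise SeparationError("fitted probabilities pinned at 0/1: separation")
    grad_norm = float(np.abs(model.score(params)).max())
    converged = bool(res.mle_retvals.get("converged", False)) and grad_norm < 1e-6

    cov = np.asarray(res.cov_params(), dtype=float)
    params_s = pd.Series(params, index=X.columns)
    cov_df = pd.DataFrame(cov, index=X.columns, columns=X.columns)
    j = list(X.columns).index(term)
    return FitResult(
        term=str(term),
        beta=float(params[j]),
        se=float(np.sqrt(cov[j, j])),
        n=int(len(y_arr)),
        loglik=float(res.llf),
        converged=converged,
        cond_number=cond,
        params=params_s,
        cov=cov_df,
    )


def fit_exposure_model(cohort: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Convenience: build the design for ``spec`` and fit, reporting the exposure."""
    X, y = build_design(cohort, spec)
    return fit_logistic(X, y, term=spec.exposure)


def percent_excess(odds_ratio: float) -> float:
    """Excess risk percentage (OR - 1) * 100, reported to one decimal."""
    if odds_ratio <= 0:
        raise ValueError(f"odds ratio must be > 0, got {odds_ratio}")
    from .rounding import round_half_up

    return round_half_up((odds_ratio - 1.0) * 100.0, 1)


def _nll(params: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ params
    # log(1 + exp(eta)) - y*eta, numerically stable
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta))


def oracle_fit(
    X: pd.DataFrame | np.ndarray, y: pd.Series | np.ndarray
) -> np.ndarray:
    """Independent small-instance ML estimate by derivative-free search.

    Restricted to <= 30 rows and <= 4 columns; maximizes the Bernoulli
    likelihood with Nelder-Mead followed by a Powell polish.  Used only to
    cross-check :func:`fit_logistic` in the test suite.
    """
    X_arr = pd.DataFrame(X).to_numpy(dtype=float)
    y_arr = np.asarray(y, dtype=float)
    n, k = X_arr.shape
    if n > 30 or k > 4:
        raise ValueError("oracle_fit is restricted to <= 30 rows and <= 4 columns")
    if y_arr.min() == y_arr.max():
        raise SeparationError("response is constant; logistic MLE does not exist")

    best = None
    for start in (np.zeros(k), 0.1 * np.ones(k)):
        r = optimize.minimize(
            _nll, start, args=(X_arr, y_arr), method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000,
                     "maxfev": 20000},
        )
        r = optimize.minimize(
            _nll, r.x, args=(X_arr, y_arr), method="Powell",
            options={"xtol": 1e-12, "ftol": 1e-14, "maxiter": 20000},
        )
        if best is None or r.fun < best.fun:
            best = r
    if np.abs(best.x).max() > 50:
        raise SeparationError("oracle search diverged: separation suspected")
    return best.x
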