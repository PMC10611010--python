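"""Synthetic cohort generation for constituent-resolved PM2.5 / ASCVD-risk analyses.

This module builds per-participant tables with the statistical structure the
downstream models assume: six chemically speciated PM2.5 constituents (black
carbon, ammonium, nitrate, organic matter, sulfate, soil dust) that are
strongly and positively correlated with one another and close (exactly or
approximately) to total PM2.5 mass, together with the demographic, lifestyle
and clinical covariates used both as logistic-model adjustments and as inputs
to a Cox-score 10-year ASCVD risk equation.

Exposures are drawn from a Gaussian copula with configurable marginals
(zero-truncated normal or moment-matched lognormal) so that means, SDs and the
correlation structure can be set independently.  The default configuration
emulates a high-pollution rural-China setting: total PM2.5 around 75 µg/m³
and pairwise constituent correlations spanning roughly 0.51-0.99.

The binary outcome (predicted 10-year atherosclerotic cardiovascular disease
risk >= 10%) can be assigned either from a user-supplied logistic mechanism
with a calibrated intercept -- giving known ground-truth coefficients for
parameter-recovery tests -- or by scoring the cohort through the risk engine
and thresholding at 10%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "CONSTITUENTS",
    "ExposureConfig",
    "CovariateConfig",
    "OutcomeConfig",
    "MonthlySeries",
    "CalibrationError",
    "CoverageError",
    "sample_exposures",
    "sample_covariates",
    "assign_outcome",
    "generate_cohort",
    "window_average",
    "apply_exclusions",
]

#: Canonical ordering of the six PM2.5 constituents used throughout.
CONSTITUENTS = ("BC", "NH4", "NO3", "OM", "SO4", "SOIL")

# Exposure summary (mean, SD in µg/m³) emulating a rural-China cohort with
# heavy PM2.5 burden.  The constituent means sum to 73.838; the remaining
# 1.400 µg/m³ of the 75.238 µg/m³ total is unspeciated residual mass.
_DEFAULT_MU = {
    "BC": 5.190,
    "NH4": 10.694,
    "NO3": 18.016,
    "OM": 15.659,
    "SO4": 14.624,
    "SOIL": 9.655,
}
_DEFAULT_SIGMA = {
    "BC": 0.947,
    "NH4": 1.431,
    "NO3": 2.619,
    "OM": 1.746,
    "SO4": 1.827,
    "SOIL": 1.579,
}
TOTAL_PM25_MEAN = 75.238
TOTAL_PM25_SD = 9.602

# One-factor loadings chosen so pairwise correlations span [0.51, 0.99]:
# min off-diagonal 0.7142^2 ~= 0.510, max 0.9950^2 ~= 0.990.
_DEFAULT_LOADINGS = np.array([0.9950, 0.8500, 0.9950, 0.7142, 0.9000, 0.7142])


def default_correlation() -> np.ndarray:
    """One-factor correlation matrix for the six constituents.

    corr[j, k] = lam[j] * lam[k] off the diagonal; positive semi-definite by
    construction and spanning [0.51, 0.99] off-diagonal.
    """
    lam = _DEFAULT_LOADINGS
    corr = np.outer(lam, lam)
    np.fill_diagonal(corr, 1.0)
    return corr


class CalibrationError(ValueError):
    """Requested outcome prevalence cannot be reached by any intercept."""


class CoverageError(ValueError):
    """A monthly exposure series does not cover the requested window."""


@dataclass
class ExposureConfig:
    """Generative parameters for correlated constituent exposures.

    Parameters
    ----------
    constituent_names : tuple of str
        Ordered labels for the six constituents.
    mu, sigma : dict
        Marginal mean and SD per constituent, µg/m³.
    corr : ndarray, shape (6, 6)
        Copula correlation matrix; symmetric, unit diagonal, PSD.
    closure_mode : {"exact_sum", "residual_mass"}
        ``exact_sum`` sets total mass identically equal to the constituent
        sum; ``residual_mass`` adds an independent non-negative unspeciated
        remainder so closure is only approximate, as in real speciation data.
    residual_mass_mean, residual_mass_sd : float
        Mean/SD (µg/m³) of the unspeciated remainder (residual_mass mode).
    distribution : {"truncated_normal", "lognormal"}
        Marginal family; both are parameterized by (mu, sigma) above.
    """

    constituent_names: tuple = CONSTITUENTS
    mu: dict = field(default_factory=lambda: dict(_DEFAULT_MU))
    sigma: dict = field(default_factory=lambda: dict(_DEFAULT_SIGMA))
    corr: np.ndarray = field(default_factory=default_correlation)
    closure_mode: str = "residual_mass"
    residual_mass_mean: float = 1.400
    residual_mass_sd: float = 0.400
    distribution: str = "truncated_normal"

    def validate(self) -> None:
        k = len(self.constituent_names)
        corr = np.asarray(self.corr, dtype=float)
        if corr.shape != (k, k):
            raise ValueError(f"corr must be {k}x{k}, got {corr.shape}")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValueError("corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ValueError("corr must have unit diagonal")
        eigmin = float(np.linalg.eigvalsh(corr)[0])
        if eigmin < -1e-10:
            raise ValueError(
                f"corr is not positive semi-definite (smallest eigenvalue {eigmin:.3e})"
            )
        for name in self.constituent_names:
            if name not in self.mu or name not in self.sigma:
                raise ValueError(f"mu/sigma missing constituent {name!r}")
            if self.sigma[name] <= 0:
                raise ValueError(f"sigma[{name!r}] must be > 0, got {self.sigma[name]}")
        if self.closure_mode not in ("exact_sum", "residual_mass"):
            raise ValueError(f"unknown closure_mode {self.closure_mode!r}")
        if self.distribution not in ("truncated_normal", "lognormal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.closure_mode == "residual_mass":
            if self.residual_mass_mean < 0 or self.residual_mass_sd < 0:
                raise ValueError("residual mass mean/sd must be >= 0")


# Covariate distribution defaults emulate a middle-aged rural Chinese cohort
# (n = 31,162 in the reference population).  Categorical probabilities are
# stored as exact count fractions so each vector sums to 1 to machine
# precision; the first listed level is the modelling reference level.
_N_REF = 31_162


def _frac(*counts: int) -> tuple:
    return tuple(c / _N_REF for c in counts)


@dataclass
class CovariateConfig:
    """Sampling distributions for covariates and risk-factor fields."""

    # categorical: level -> probability (insertion order fixes the reference level)
    gender: dict = field(
        default_factory=lambda: dict(zip(("female", "male"), _frac(18_999, 12_163)))
    )
    marital_status: dict = field(
        default_factory=lambda: dict(zip(("married", "unmarried"), _frac(28_558, 2_604)))
    )
    education: dict = field(
        default_factory=lambda: dict(
            zip(("primary_or_below", "junior_high", "high_or_above"),
                _frac(13_920, 13_011, 4_231))
        )
    )
    income: dict = field(
        default_factory=lambda: dict(
            zip(("low", "middle", "high"), _frac(10_993, 10_479, 9_690))
        )
    )
    smoking: dict = field(
        default_factory=lambda: dict(
            zip(("never", "former", "current"), _frac(22_727, 2_323, 6_112))
        )
    )
    drinking: dict = field(
        default_factory=lambda: dict(
            zip(("never", "former", "current"), _frac(24_063, 1_259, 5_840))
        )
    )
    physical_activity: dict = field(
        default_factory=lambda: dict(
            zip(("low", "moderate", "high"), _frac(9_360, 11_887, 9_915))
        )
    )
    high_fat_diet: dict = field(
        default_factory=lambda: dict(zip(("no", "yes"), _frac(31_162 - 6_063, 6_063)))
    )
    fruit_veg: dict = field(
        default_factory=lambda: dict(zip(("no", "yes"), _frac(31_162 - 13_221, 13_221)))
    )
    # the emulated cohort is drawn from a single (northern) province, so the
    # region used by Cox-score risk tables is constant by default
    region: dict = field(default_factory=lambda: {"north": 1.0})

    # continuous risk factors: (mean, SD)
    age: tuple = (55.898, 9.782)            # years
    waist_circumference: tuple = (84.232, 10.209)   # cm
    sbp: tuple = (125.566, 19.478)          # mmHg
    total_cholesterol: tuple = (184.676, 37.361)    # mg/dL
    hdl_cholesterol: tuple = (51.287, 12.891)       # mg/dL

    # binary prevalences
    diabetes: float = 2_824 / _N_REF
    family_history_ascvd: float = 4_777 / _N_REF
    bp_treated: float = 4_365 / _N_REF

    def categorical_fields(self) -> dict:
        return {
            "gender": self.gender,
            "marital_status": self.marital_status,
            "education": self.education,
            "income": self.income,
            "smoking": self.smoking,
            "drinking": self.drinking,
            "physical_activity": self.physical_activity,
            "high_fat_diet": self.high_fat_diet,
            "fruit_veg": self.fruit_veg,
            "region": self.region,
        }

    def continuous_fields(self) -> dict:
        return {
            "age": self.age,
            "waist_circumference": self.waist_circumference,
            "sbp": self.sbp,
            "total_cholesterol": self.total_cholesterol,
            "hdl_cholesterol": self.hdl_cholesterol,
        }

    def binary_fields(self) -> dict:
        return {
            "diabetes": self.diabetes,
            "family_history_ascvd": self.family_history_ascvd,
            "bp_treated": self.bp_treated,
        }

    def validate(self) -> None:
        for name, probs in self.categorical_fields().items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{name} category probabilities sum to {total!r}, not 1"
                )
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} has a negative probability")
        for name, (mean, sd) in self.continuous_fields().items():
            if sd <= 0:
                raise ValueError(f"{name} SD must be > 0, got {sd}")
        for name, p in self.binary_fields().items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} prevalence {p} outside [0, 1]")


@dataclass
class OutcomeConfig:
    """Ground-truth outcome mechanism.

    ``logistic``: Y ~ Bernoulli(expit(alpha + sum beta_j x_j)) with the
    intercept alpha calibrated by bisection so the expected prevalence matches
    ``target_prevalence``; ``true_beta`` maps numeric cohort columns to
    log-odds-per-unit coefficients and is the simulation ground truth for
    recovery tests.

    ``chinapar``: score each row through a Cox-score risk table and threshold
    predicted 10-year risk at 10%.
    """

    mechanism: str = "logistic"
    true_beta: dict = field(default_factory=dict)
    target_prevalence: float = 8_770 / _N_REF  # 0.28143
    seed: int = 0

    def validate(self) -> None:
        if self.mechanism not in ("logistic", "chinapar"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must be in (0, 1)")


@dataclass
class MonthlySeries:
    """Monthly exposure series for one participant and one pollutant.

    ``values`` is a DataFrame with integer ``year``/``month`` columns and a
    ``value`` column (µg/m³); ``baseline`` is the (year, month) of the
    baseline visit.  Averaging windows end with the month *before* baseline.
    """

    participant_id: object
    pollutant: str
    values: pd.DataFrame
    baseline: tuple

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.values)
        required = {"year", "month", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"values needs columns {sorted(required)}")
        idx = pd.PeriodIndex.from_fields(
            year=df["year"].astype(int), month=df["month"].astype(int), freq="M"
        )
        if idx.duplicated().any():
            raise ValueError("duplicate months in series")
        if not idx.is_monotonic_increasing:
            df = df.assign(_p=idx).sort_values("_p").drop(columns="_p")
            idx = pd.PeriodIndex.from_fields(
                year=df["year"].astype(int), month=df["month"].astype(int), freq="M"
            )
        if (df["value"].to_numpy() < 0).any():
            raise ValueError("monthly values must be >= 0")
        self.values = df.reset_index(drop=True)
        self._periods = idx


def _copula_normals(corr: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n rows of standard normals with the given correlation (PSD-safe)."""
    # eigen decomposition tolerates exactly singular matrices (e.g. corr ~ 1)
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)
    z = rng.standard_normal((n, corr.shape[0]))
    return z @ root.T


def sample_exposures(
    config: ExposureConfig, n: int, seed: int
) -> pd.DataFrame:
    """Draw ``n`` rows of the six constituents plus total PM2.5 (column ``pm25``).

    Marginals follow ``config.distribution`` with the configured means/SDs;
    dependence comes from a Gaussian copula with ``config.corr``.  Total mass
    honours ``config.closure_mode``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config.validate()
    rng = np.random.default_rng(seed)
    names = list(config.constituent_names)
    z = _copula_normals(np.asarray(config.corr, dtype=float), n, rng)
    u = stats.norm.cdf(z)
    cols = {}
    for j, name in enumerate(names):
        mu, sd = config.mu[name], config.sigma[name]
        if config.distribution == "truncated_normal":
            a = -mu / sd  # truncate at zero in standardized units
            cols[name] = stats.truncnorm.ppf(u[:, j], a, np.inf, loc=mu, scale=sd)
        else:  # lognormal, moment matched to (mu, sd)
            s2 = np.log1p((sd / mu) ** 2)
            cols[name] = stats.lognorm.ppf(
                u[:, j], np.sqrt(s2), scale=mu * np.exp(-s2 / 2)
            )
    out = pd.DataFrame(cols)
    total = out.to_numpy().sum(axis=1)
    if config.closure_mode == "residual_mass":
        rm_mu, rm_sd = config.residual_mass_mean, config.residual_mass_sd
        if rm_sd > 0:
            a = -rm_mu / rm_sd
            resid = stats.truncnorm.rvs(
                a, np.inf, loc=rm_mu, scale=rm_sd, size=n, random_state=rng
            )
        else:
            resid = np.full(n, rm_mu)
        total = total + resid
    out["pm25"] = total
    return out


def sample_covariates(config: CovariateConfig, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` rows of covariates and risk-factor fields.

    Categorical columns come back as ordered pandas Categoricals whose first
    level is the reference level used downstream in design matrices.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config.validate()
    rng = np.random.default_rng(seed)
    cols = {}
    for name, probs in config.categorical_fields().items():
        levels = list(probs)
        draws = rng.choice(len(levels), size=n, p=list(probs.values()))
        cols[name] = pd.Categorical.from_codes(
            draws, categories=levels, ordered=False
        )
    for name, (mean, sd) in config.continuous_fields().items():
        cols[name] = mean + sd * rng.standard_normal(n)
    for name, p in config.binary_fields().items():
        cols[name] = (rng.random(n) < p).astype(int)
    return pd.DataFrame(cols)


def _calibrate_intercept(
    eta: np.ndarray, target: float, lo: float = -20.0, hi: float = 20.0,
    tol: float = 1e-4,
) -> float:
    """Bisect alpha so that mean expit(alpha + eta) hits ``target``.

    Raises :class:`CalibrationError` when the target prevalence is outside
    what the linear predictor can reach on [lo, hi].
    """
    def prev(alpha: float) -> float:
        return float(np.mean(special.expit(alpha + eta)))

    p_lo, p_hi = prev(lo), prev(hi)
    if not (p_lo - tol <= target <= p_hi + tol):
        raise CalibrationError(
            f"target prevalence {target:.5f} unreachable: attainable range "
            f"[{p_lo:.5f}, {p_hi:.5f}] for intercept in [{lo}, {hi}]"
        )
    a, b = lo, hi
    for _ in range(200):
        mid = 0.5 * (a + b)
        p = prev(mid)
        if abs(p - target) <= tol:
            return mid
        if p < target:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


def assign_outcome(
    cohort: pd.DataFrame,
    config: OutcomeConfig,
    risk_table=None,
) -> pd.DataFrame:
    """Return a copy of ``cohort`` with ``risk`` and ``high_risk`` columns filled.

    With the logistic mechanism, ``risk`` holds each row's event probability
    under the calibrated model and ``high_risk`` the Bernoulli draw.  With the
    chinapar mechanism, ``risk`` is the predicted 10-year ASCVD risk from
    ``risk_table`` and ``high_risk`` indicates risk >= 0.10.
    """
    config.validate()
    out = cohort.copy()
    if config.mechanism == "chinapar":
        if risk_table is None:
            raise ValueError("chinapar mechanism requires a risk coefficient table")
        from .risk import score_cohort

        scored = score_cohort(out, risk_table)
        out["risk"] = scored["risk"].to_numpy()
        out["high_risk"] = scored["high_risk"].to_numpy()
        return out

    missing = [c for c in config.true_beta if c not in out.columns]
    if missing:
        raise ValueError(f"true_beta names absent from cohort: {missing}")
    eta = np.zeros(len(out))
    for col, beta in config.true_beta.items():
        eta = eta + beta * out[col].to_numpy(dtype=float)
    alpha = _calibrate_intercept(eta, config.target_prevalence)
    p = special.expit(alpha + eta)
    rng = np.random.default_rng(config.seed)
    out["risk"] = p
    out["high_risk"] = (rng.random(len(out)) < p).astype(int)
    out.attrs["outcome_intercept"] = alpha
    return out


def generate_cohort(
    n: int,
    seed: int,
    exposure_config: ExposureConfig | None = None,
    covariate_config: CovariateConfig | None = None,
    outcome_config: OutcomeConfig | None = None,
    risk_table=None,
) -> pd.DataFrame:
    """One-call cohort: covariates + exposures + outcome, reproducible by seed.

    Independent substreams are derived from ``seed`` for exposures,
    covariates and the outcome so that stages can be regenerated separately.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]
    expo = sample_exposures(exposure_config or ExposureConfig(), n, sub[0])
    cov = sample_covariates(covariate_config or CovariateConfig(), n, sub[1])
    cohort = pd.concat([cov, expo], axis=1)
    cohort.insert(0, "id", np.arange(1, n + 1))
    oc = outcome_config or OutcomeConfig()
    oc = OutcomeConfig(
        mechanism=oc.mechanism,
        true_beta=dict(oc.true_beta),
        target_prevalence=oc.target_prevalence,
        seed=sub[2] if outcome_config is None or outcome_config.seed == 0 else oc.seed,
    )
    return assign_outcome(cohort, oc, risk_table=risk_table)


def window_average(series: MonthlySeries, years: int) -> float:
    """Mean of exactly ``years`` x 12 monthly values ending the month before baseline.

    Raises :class:`CoverageError` naming the first missing month when the
    series does not cover the window.
    """
    if years not in (3, 5, 8, 10):
        raise ValueError("years must be one of 3, 5, 8, 10")
    b_year, b_month = int(series.baseline[0]), int(series.baseline[1])
    end = pd.Period(year=b_year, month=b_month, freq="M") - 1
    start = end - (years * 12 - 1)
    wanted = pd.period_range(start, end, freq="M")
    have = pd.Series(
        series.values["value"].to_numpy(), index=series._periods
    )
    missing = wanted.difference(have.index)
    if len(missing) > 0:
        first = missing[0]
        raise CoverageError(
            f"series for participant {series.participant_id!r} missing "
            f"{first.year}-{first.month:02d} (needs {years * 12} months ending "
            f"{end.year}-{end.month:02d})"
        )
    return float(have.loc[wanted].mean())


def apply_exclusions(
    n0: int, missing: int, age_out: int, prior_ascvd: int
) -> tuple[int, list[dict]]:
    """Sequential exclusion cascade with an audit trail.

    Applies three exclusion steps in order -- missing risk-factor data,
    age outside [35, 75), prior ASCVD history -- and returns the remaining
    count plus a per-step audit list.  Any negative intermediate count is an
    error (the cascade is infeasible as stated).
    """
    steps = [
        ("enrolled", 0),
        ("missing_risk_predictors", missing),
        ("age_below_35_or_75_plus", age_out),
        ("prior_ascvd_history", prior_ascvd),
    ]
    if min(n0, missing, age_out, prior_ascvd) < 0:
        raise ValueError("exclusion counts must be >= 0")
    audit = []
    remaining = n0
    for name, removed in steps:
        remaining -= removed
        if remaining < 0:
            raise ValueError(
                f"exclusion step {name!r} removes {removed} from "
                f"{remaining + removed} participants"
            )
        audit.append({"step": name, "removed": removed, "remaining": remaining})
    return remaining, audit
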