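"""Subgroup analyses, interaction tests and the exposure-window sensitivity driver.

Stratified analysis refits the covariate-adjusted single-pollutant model
within each level of a stratifier (gender, educational level, average monthly
income, physical activity, high-fat diet), dropping the stratifier from its
own adjustment set since it is constant within a stratum.  Effect-measure
modification is tested in the pooled model by comparing fits with and without
exposure x stratifier product terms: a likelihood-ratio test with
(levels - 1) degrees of freedom by default, or Wald on the product terms.

The sensitivity driver recomputes each participant's exposure as the mean of
the monthly concentration series over 3/5/8/10-year windows ending the month
before baseline and refits the concentration model per window.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CoverageError, MonthlySeries, window_average
from .regression import (
    MODEL2_COVARIATES,
    ModelSpec,
    build_design,
    fit_exposure_model,
    fit_logistic,
)

__all__ = [
    "STRATIFIERS",
    "fit_subgroups",
    "interaction_test",
    "stratified_table",
    "sensitivity_by_window",
]

logger = logging.getLogger(__name__)

STRATIFIERS = (
    "gender",
    "education",
    "income",
    "physical_activity",
    "high_fat_diet",
)


def _covariates_excluding(stratifier: str) -> tuple:
    return tuple(c for c in MODEL2_COVARIATES if c != stratifier)


def fit_subgroups(
    cohort: pd.DataFrame,
    pollutant: str,
    stratifier: str,
    model: int = 2,
) -> pd.DataFrame:
    """Independent per-stratum fits of the single-pollutant model.

    Strata too small to identify the model (n <= number of parameters) are
    skipped with a log entry and flagged in the output.
    """
    if stratifier not in cohort.columns:
        raise KeyError(f"cohort lacks stratifier {stratifier!r}")
    levels = (
        list(cohort[stratifier].cat.categories)
        if isinstance(cohort[stratifier].dtype, pd.CategoricalDtype)
        else sorted(cohort[stratifier].dropna().unique())
    )
    if len(levels) < 2:
        raise ValueError(f"stratifier {stratifier!r} has fewer than 2 levels")
    extra = _covariates_excluding(stratifier) if model == 2 else ()
    rows = []
    for level in levels:
        sub = cohort[cohort[stratifier] == level]
        # drop unused categories so the subgroup design has no empty dummies
        sub = sub.copy()
        for c in sub.columns:
            if isinstance(sub[c].dtype, pd.CategoricalDtype):
                sub[c] = sub[c].cat.remove_unused_categories()
        spec = ModelSpec(exposure=pollutant, covariates="model1", extra_terms=())
        n_params = 2 + sum(
            max(sub[c].nunique() - 1, 0) for c in extra
        )
        if len(sub) <= n_params or sub["high_risk"].nunique() < 2:
            logger.warning(
                "skipping stratum %s=%s (n=%d too small)", stratifier, level, len(sub)
            )
            rows.append(
                {"pollutant": pollutant, "stratifier": stratifier, "stratum": level,
                 "n": len(sub), "fitted": False}
            )
            continue
        if model == 2:
            work = sub
            X, y = build_design(
                work,
                ModelSpec(exposure=pollutant, covariates="model1"),
            )
            # append reduced covariate set manually (model2 minus stratifier)
            from .regression import _encode_categoricals

            X = pd.concat([X, _encode_categoricals(work, extra)], axis=1)
            fit = fit_logistic(X, y, term=pollutant)
        else:
            fit = fit_exposure_model(sub, spec)
        row = fit.as_row()
        row.update(
            {"pollutant": pollutant, "stratifier": stratifier, "stratum": level,
             "fitted": True}
        )
        rows.append(row)
    return pd.DataFrame(rows)


def interaction_test(
    cohort: pd.DataFrame,
    pollutant: str,
    stratifier: str,
    model: int = 2,
    method: str = "lrt",
) -> float:
    """p-value for exposure x stratifier effect-measure modification.

    ``lrt``: likelihood-ratio test of the (levels - 1) product terms.
    ``wald``: Wald chi-square on the same terms from the full fit.
    """
    if method not in ("lrt", "wald"):
        raise ValueError("method must be 'lrt' or 'wald'")
    work = cohort.copy()
    strat = work[stratifier]
    if not isinstance(strat.dtype, pd.CategoricalDtype):
        strat = strat.astype("category")
    levels = list(strat.cat.categories)
    if len(levels) < 2:
        raise ValueError(f"stratifier {stratifier!r} has fewer than 2 levels")
    x = work[pollutant].to_numpy(dtype=float)
    product_names = []
    for level in levels[1:]:
        name = f"{pollutant}_x_{stratifier}_{level}"
        work[name] = x * (strat == level).to_numpy(dtype=float)
        product_names.append(name)

    covset = "model1" if model == 1 else "model2"
    X_red, y = build_design(work, ModelSpec(exposure=pollutant, covariates=covset))
    if model == 1 or stratifier not in MODEL2_COVARIATES:
        # stratifier main effects must be in both models regardless
        from .regression import _encode_categoricals

        X_red = pd.concat(
            [X_red, _encode_categoricals(work.loc[X_red.index], (stratifier,))], axis=1
        )
    fit_red = fit_logistic(X_red, y, term=pollutant)

    X_full = pd.concat(
        [X_red, work.loc[X_red.index, product_names].astype(float)], axis=1
    )
    fit_full = fit_logistic(X_full, y, term=pollutant)

    df = len(product_names)
    if method == "lrt":
        lr = 2.0 * (fit_full.loglik - fit_red.loglik)
        return float(stats.chi2.sf(max(lr, 0.0), df))
    beta = fit_full.params[product_names].to_numpy()
    cov = fit_full.cov.loc[product_names, product_names].to_numpy()
    w = float(beta @ np.linalg.solve(cov, beta))
    return float(stats.chi2.sf(w, df))


def stratified_table(
    cohort: pd.DataFrame,
    pollutant: str,
    stratifiers=STRATIFIERS,
    model: int = 2,
    method: str = "lrt",
) -> pd.DataFrame:
    """Forest-plot-ready table: per-stratum ORs plus a shared interaction p."""
    pieces = []
    for stratifier in stratifiers:
        sub = fit_subgroups(cohort, pollutant, stratifier, model)
        sub["interaction_p"] = interaction_test(
            cohort, pollutant, stratifier, model, method
        )
        pieces.append(sub)
    return pd.concat(pieces, ignore_index=True)


def sensitivity_by_window(
    cohort: pd.DataFrame,
    monthly: pd.DataFrame,
    pollutant: str,
    baseline: tuple,
    windows=(3, 5, 8, 10),
    model: int = 2,
) -> pd.DataFrame:
    """Refit the concentration model with exposures averaged over each window.

    ``monthly`` is long format (id, pollutant, year, month, value).
    Participants without full coverage for a window are excluded from that
    window's fit; the exclusion count is recorded per window.
    """
    sub = monthly[monthly["pollutant"] == pollutant]
    if sub.empty:
        raise ValueError(f"no monthly series for pollutant {pollutant!r}")
    series_by_id = {
        pid: MonthlySeries(pid, pollutant, grp[["year", "month", "value"]], baseline)
        for pid, grp in sub.groupby("id")
    }
    rows = []
    for years in windows:
        means, excluded = {}, 0
        for pid, series in series_by_id.items():
            try:
                means[pid] = window_average(series, years)
            except CoverageError:
                excluded += 1
        col = f"_mean_{pollutant}_{years}y"
        work = cohort.copy()
        work[col] = work["id"].map(means)
        work = work.dropna(subset=[col])
        if work.empty:
            raise ValueError(f"no participants with {years}-year coverage")
        fit = fit_exposure_model(
            work,
            ModelSpec(exposure=col, covariates="model1" if model == 1 else "model2"),
        )
        row = fit.as_row()
        row.update(
            {"pollutant": pollutant, "window_years": years, "model": model,
             "n_excluded_coverage": excluded}
        )
        rows.append(row)
    return pd.DataFrame(rows)
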