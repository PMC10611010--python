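"""The three constituent analysis methods: concentration, proportion, residual.

Each method asks how one PM2.5 constituent relates to the odds of high
predicted 10-year ASCVD risk while handling the near-collinearity between
constituents and total mass differently:

* concentration — the constituent's absolute concentration (µg/m³) is the
  exposure in a single-pollutant model (total PM2.5 gets its own model);
* proportion — the constituent's share of total mass, in percentage points,
  is the exposure, with total PM2.5 mass as an additional adjustment;
* residual — the exposure is the residual of the constituent OLS-regressed on
  total mass, which is orthogonal to total mass by construction, so total is
  not re-entered.

All three are fitted under Model 1 (crude) and Model 2 (covariate-adjusted)
and collected into a tidy table, one row per method x pollutant x model.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cohort import CONSTITUENTS
from .regression import FitResult, ModelSpec, fit_exposure_model

__all__ = [
    "compute_proportion",
    "compute_residual",
    "run_concentration_analysis",
    "run_proportion_analysis",
    "run_residual_analysis",
    "constituent_result_table",
]


def compute_proportion(c, m):
    """Constituent share of total mass in percent: 100 * c / m.

    One unit of the returned exposure is one percentage point of total PM2.5
    mass.  ``m <= 0`` anywhere is an error; ``c > m`` (possible under noisy
    mass closure) warns but still returns the >100% value.
    """
    c = np.asarray(c, dtype=float)
    m = np.asarray(m, dtype=float)
    if (m <= 0).any():
        raise ValueError("total PM2.5 mass must be > 0 for proportions")
    if (c < 0).any():
        raise ValueError("constituent concentrations must be >= 0")
    if (c > m).any():
        warnings.warn(
            "constituent exceeds total mass for some rows; proportion > 100%",
            stacklevel=2,
        )
    return 100.0 * c / m


def compute_residual(c, m):
    """Residual of the constituent OLS-regressed on total mass.

    r = c - (a + b*m) with (a, b) the least-squares fit of c on m; the result
    has zero mean and is exactly orthogonal to m.  Requires >= 3 points and
    non-constant m (the slope is undefined otherwise).
    """
    c = np.asarray(c, dtype=float)
    m = np.asarray(m, dtype=float)
    if c.shape != m.shape or c.ndim != 1:
        raise ValueError("c and m must be 1-D arrays of equal length")
    if len(m) < 3:
        raise ValueError("residualization needs at least 3 points")
    if np.ptp(m) == 0:
        raise ValueError("total mass is constant; regression slope undefined")
    b, a = np.polyfit(m, c, 1)
    return c - (a + b * m)


def _fit_rows(
    cohort: pd.DataFrame,
    exposures: dict,
    model: int,
    method: str,
    extra_terms: tuple = (),
) -> pd.DataFrame:
    covariates = "model1" if model == 1 else "model2"
    rows = []
    work = cohort.copy()
    for label, series in exposures.items():
        col = f"_exposure_{label}"
        work[col] = np.asarray(series, dtype=float)
        spec = ModelSpec(exposure=col, covariates=covariates, extra_terms=extra_terms)
        fit: FitResult = fit_exposure_model(work, spec)
        row = fit.as_row()
        row.update({"method": method, "pollutant": label, "model": model,
                    "term": label})
        rows.append(row)
        work.drop(columns=col, inplace=True)
    cols = ["method", "pollutant", "model", "or", "ci_low", "ci_high", "beta",
            "se", "n", "loglik", "converged", "term"]
    return pd.DataFrame(rows)[cols]


def run_concentration_analysis(
    cohort: pd.DataFrame, model: int, adjust_total: bool = False
) -> pd.DataFrame:
    """Single-pollutant concentration models, per 1 µg/m³.

    One logistic fit for total PM2.5 and one per constituent.  By default each
    constituent is modelled alone; ``adjust_total=True`` co-adjusts every
    constituent model for total mass instead.
    """
    exposures = {"PM2.5": cohort["pm25"]}
    rows = [_fit_rows(cohort, exposures, model, "concentration")]
    extra = ("pm25",) if adjust_total else ()
    exposures = {name: cohort[name] for name in CONSTITUENTS}
    rows.append(_fit_rows(cohort, exposures, model, "concentration", extra))
    return pd.concat(rows, ignore_index=True)


def run_proportion_analysis(cohort: pd.DataFrame, model: int) -> pd.DataFrame:
    """Proportion models, per percentage point of total mass, adjusted for total."""
    exposures = {
        name: compute_proportion(cohort[name], cohort["pm25"])
        for name in CONSTITUENTS
    }
    return _fit_rows(cohort, exposures, model, "proportion", extra_terms=("pm25",))


def run_residual_analysis(cohort: pd.DataFrame, model: int) -> pd.DataFrame:
    """Residual models, per 1 µg/m³ of mass-adjusted constituent concentration."""
    m = cohort["pm25"].to_numpy(dtype=float)
    exposures = {
        name: compute_residual(cohort[name].to_numpy(dtype=float), m)
        for name in CONSTITUENTS
    }
    return _fit_rows(cohort, exposures, model, "residual")


def constituent_result_table(
    cohort: pd.DataFrame, models=(1, 2), adjust_total: bool = False
) -> pd.DataFrame:
    """All three methods for the requested models in one tidy table.

    With both models the table has 38 rows: per model, 7 concentration rows
    (total PM2.5 + 6 constituents) plus 6 proportion and 6 residual rows.
    """
    pieces = []
    for model in models:
        pieces.append(run_concentration_analysis(cohort, model, adjust_total))
        pieces.append(run_proportion_analysis(cohort, model))
        pieces.append(run_residual_analysis(cohort, model))
    return pd.concat(pieces, ignore_index=True)
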