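"""Isochronous substitution model (ISM) for PM2.5 constituent reallocation.

The ISM estimates the effect of replacing 1 µg/m³ of one constituent with
1 µg/m³ of another while holding total PM2.5 mass fixed.  Operationally: drop
constituent j from the design, keep total mass m and the remaining five
constituents, and fit the usual logistic model.  Because m is held fixed, a
unit increase in a retained constituent k is implicitly a unit decrease of
the dropped constituent j, so exp(beta_k) in the leave-j-out model is the
odds ratio for substituting j by k.

Under exact mass closure (m identically equal to the constituent sum) the
leave-j-out model is an exact reparameterization of the all-constituent model
without total mass, giving the algebraic identities

    beta_k^(-j) = beta_k^full - beta_j^full,
    log OR(j->k) = -log OR(k->j)              (reciprocity),
    log OR(j->k) + log OR(k->l) = log OR(j->l) (transitivity),

which the test suite verifies to solver precision.  With realistic
(approximate) closure these hold only approximately.  Constituent designs
are strongly collinear; fits proceed under near-collinearity with a warning,
and the per-fit condition number is recorded.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .cohort import CONSTITUENTS
from .regression import ModelSpec, build_design, fit_logistic

__all__ = [
    "fit_substitution_model",
    "substitution_matrix",
    "check_reciprocity",
    "check_transitivity",
]


def fit_substitution_model(
    cohort: pd.DataFrame, drop: str, model: int = 2
) -> pd.DataFrame:
    """Leave-one-constituent-out fit: covariates + total mass + 5 constituents.

    Returns one row per retained constituent k with the substitution odds
    ratio OR(drop->k), its Wald 95% CI, and fit metadata.
    """
    if drop not in CONSTITUENTS:
        raise ValueError(f"unknown constituent {drop!r}")
    retained = [c for c in CONSTITUENTS if c != drop]
    spec = ModelSpec(
        exposure=None,
        covariates="model1" if model == 1 else "model2",
        extra_terms=("pm25", *retained),
    )
    X, y = build_design(cohort, spec)
    fit = fit_logistic(X, y, term=retained[0])
    z = 1.959963984540054
    rows = []
    for k in retained:
        beta = float(fit.params[k])
        se = float(np.sqrt(fit.cov.loc[k, k]))
        rows.append(
            {
                "drop": drop,
                "retain": k,
                "model": model,
                "beta": beta,
                "se": se,
                "or": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - z * se)),
                "ci_high": float(np.exp(beta + z * se)),
                "n": fit.n,
                "converged": fit.converged,
                "cond_number": fit.cond_number,
            }
        )
    return pd.DataFrame(rows)


def substitution_matrix(cohort: pd.DataFrame, model: int = 2) -> pd.DataFrame:
    """All 30 ordered substitution pairs from the six leave-one-out fits.

    Long format (drop, retain, OR, CI) suitable for forest plots.
    """
    return pd.concat(
        [fit_substitution_model(cohort, drop, model) for drop in CONSTITUENTS],
        ignore_index=True,
    )


def _log_or_lookup(matrix: pd.DataFrame) -> dict:
    return {
        (r["drop"], r["retain"]): float(np.log(r["or"]))
        for _, r in matrix.iterrows()
    }


def check_reciprocity(matrix: pd.DataFrame) -> float:
    """max |log OR(j->k) + log OR(k->j)| over unordered pairs.

    Zero (to solver tolerance) under exact mass closure.
    """
    logs = _log_or_lookup(matrix)
    worst = 0.0
    for j, k in itertools.combinations(CONSTITUENTS, 2):
        if (j, k) in logs and (k, j) in logs:
            worst = max(worst, abs(logs[(j, k)] + logs[(k, j)]))
    return worst


def check_transitivity(matrix: pd.DataFrame) -> float:
    """max |log OR(j->k) + log OR(k->l) - log OR(j->l)| over ordered triples."""
    logs = _log_or_lookup(matrix)
    worst = 0.0
    for j, k, l in itertools.permutations(CONSTITUENTS, 3):
        keys = ((j, k), (k, l), (j, l))
        if all(key in logs for key in keys):
            worst = max(
                worst, abs(logs[(j, k)] + logs[(k, l)] - logs[(j, l)])
            )
    return worst
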