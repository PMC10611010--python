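"""Table-driven 10-year ASCVD risk scoring in the China-PAR / Framingham family.

Risk equations of this family are Cox-model scores: a linear predictor
LP = sum_i beta_i * g_i(x_i) over transformed risk factors, and a predicted
10-year risk

    risk = 1 - S0 ** exp(LP - LPbar),   LPbar = sum_i beta_i * xbar_i,

where ``S0`` is the baseline 10-year survival at the risk-factor means and
``xbar_i`` are the derivation-cohort means of the transformed terms.  The
engine is deliberately table-driven: coefficients, means and S0 are loaded
from a versioned YAML file, never hard-coded, so published sex-specific
equations (e.g. the China-PAR equations for ASCVD in Chinese adults) can be
dropped in verbatim.  Predicted risk is classified as high when >= 10%, the
conventional threshold for this outcome.

Supported term transforms: ``identity``, ``log`` (natural log), ``indicator``
(equality against a level), and ``product`` (interaction of two already
defined transforms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RiskTerm",
    "RiskCoefficientTable",
    "RiskResult",
    "load_coefficient_table",
    "example_coefficient_table",
    "linear_predictor",
    "ten_year_risk",
    "classify_risk",
    "score_cohort",
]

HIGH_RISK_THRESHOLD = 0.10

#: Soft plausibility ranges; violations warn (configurable), never hard-fail.
DEFAULT_VALIDATOR_RANGES = {
    "age": (18.0, 110.0),
    "sbp": (60.0, 260.0),
    "waist_circumference": (40.0, 200.0),
    "total_cholesterol": (50.0, 500.0),
    "hdl_cholesterol": (5.0, 150.0),
}


@dataclass
class RiskTerm:
    """One scored term: transform of a raw field times a Cox coefficient."""

    name: str
    transform: str            # identity | log | indicator | product
    coefficient: float
    mean: float               # derivation-cohort mean of the transformed term
    field: str | None = None  # raw column (identity/log/indicator)
    level: object = None      # indicator: value compared for equality
    factors: tuple = ()       # product: names of two previously defined terms

    def evaluate(self, record: pd.DataFrame, computed: dict) -> np.ndarray:
        if self.transform in ("identity", "log", "indicator"):
            if self.field not in record.columns:
                raise KeyError(f"risk term {self.name!r} needs field {self.field!r}")
            x = record[self.field]
        if self.transform == "identity":
            return x.to_numpy(dtype=float)
        if self.transform == "log":
            vals = x.to_numpy(dtype=float)
            if (vals <= 0).any():
                raise ValueError(f"log transform of non-positive {self.field!r}")
            return np.log(vals)
        if self.transform == "indicator":
            return (x == self.level).to_numpy(dtype=float)
        if self.transform == "product":
            a, b = self.factors
            for f in (a, b):
                if f not in computed:
                    raise ValueError(
                        f"product term {self.name!r} references undefined term {f!r}"
                    )
            return computed[a] * computed[b]
        raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class RiskCoefficientTable:
    """Sex-specific coefficient table: terms, means, and baseline survival S0."""

    sex: str
    terms: list
    s0: float
    version: str = "unversioned"
    validator_ranges: dict = field(default_factory=lambda: dict(DEFAULT_VALIDATOR_RANGES))

    def __post_init__(self) -> None:
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("term names must be unique")
        if not 0.0 < self.s0 < 1.0:
            raise ValueError(f"baseline survival S0 must be in (0, 1), got {self.s0}")

    @property
    def lp_mean(self) -> float:
        """LPbar = sum of coefficient * derivation-cohort mean over terms."""
        return float(sum(t.coefficient * t.mean for t in self.terms))


@dataclass
class RiskResult:
    """Per-record scoring output."""

    lp: np.ndarray
    risk: np.ndarray
    high_risk: np.ndarray


def _term_from_dict(d: dict) -> RiskTerm:
    return RiskTerm(
        name=d["name"],
        transform=d.get("transform", "identity"),
        coefficient=float(d["coefficient"]),
        mean=float(d.get("mean", 0.0)),
        field=d.get("field"),
        level=d.get("level"),
        factors=tuple(d.get("factors", ())),
    )


def load_coefficient_table(source) -> dict:
    """Load ``{sex: RiskCoefficientTable}`` from a YAML file path or stream.

    Expected layout::

        version: "..."
        tables:
          female:
            s0: 0.98
            terms:
              - {name: age, transform: identity, field: age,
                 coefficient: 0.08, mean: 52.0}
              ...
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    version = str(doc.get("version", "unversioned"))
    out = {}
    for sex, spec in doc["tables"].items():
        out[sex] = RiskCoefficientTable(
            sex=sex,
            terms=[_term_from_dict(t) for t in spec["terms"]],
            s0=float(spec["s0"]),
            version=version,
        )
    return out


def example_coefficient_table() -> dict:
    """Synthetic demonstration tables shipped with the package.

    These are NOT published China-PAR coefficients; they are synthetic values
    with the same structure, suitable for tests and demonstrations only.
    """
    ref = resources.files("pm25ascvd.data") / "synthetic_risk_coefficients.yaml"
    with ref.open() as fh:
        return load_coefficient_table(fh)


def _check_ranges(record: pd.DataFrame, ranges: dict, warn: bool = True) -> None:
    if not warn:
        return
    for col, (lo, hi) in ranges.items():
        if col in record.columns:
            vals = pd.to_numeric(record[col], errors="coerce")
            bad = ((vals < lo) | (vals > hi)).sum()
            if bad:
                warnings.warn(
                    f"{bad} value(s) of {col!r} outside plausible range "
                    f"[{lo}, {hi}]",
                    stacklevel=3,
                )


def linear_predictor(
    record: pd.DataFrame, table: RiskCoefficientTable, validate_ranges: bool = True
) -> np.ndarray:
    """LP = sum_i beta_i * g_i(x_i) for every row of ``record``."""
    _check_ranges(record, table.validator_ranges, validate_ranges)
    computed: dict = {}
    lp = np.zeros(len(record))
    for term in table.terms:
        g = term.evaluate(record, computed)
        computed[term.name] = g
        lp = lp + term.coefficient * g
    return lp


def ten_year_risk(lp, table: RiskCoefficientTable) -> RiskResult:
    """Predicted 10-year risk 1 - S0^exp(LP - LPbar), classified at 10%."""
    lp = np.atleast_1d(np.asarray(lp, dtype=float))
    risk = 1.0 - table.s0 ** np.exp(lp - table.lp_mean)
    return RiskResult(lp=lp, risk=risk, high_risk=(risk >= HIGH_RISK_THRESHOLD))


def classify_risk(risk) -> np.ndarray:
    """'high' when predicted risk >= 10% (boundary inclusive), else 'low'."""
    risk = np.atleast_1d(np.asarray(risk, dtype=float))
    if ((risk < 0) | (risk > 1)).any():
        raise ValueError("risk values must lie in [0, 1]")
    return np.where(risk >= HIGH_RISK_THRESHOLD, "high", "low")


def score_cohort(
    cohort: pd.DataFrame,
    tables: dict | RiskCoefficientTable,
    sex_column: str = "gender",
    validate_ranges: bool = True,
) -> pd.DataFrame:
    """Score every row, dispatching on sex when a table mapping is given.

    Returns a DataFrame with ``lp``, ``risk`` and ``high_risk`` columns
    aligned to ``cohort``.
    """
    out = pd.DataFrame(index=cohort.index, columns=["lp", "risk", "high_risk"],
                       dtype=float)
    if isinstance(tables, RiskCoefficientTable):
        groups = [(None, cohort.index)]
        lookup = {None: tables}
    else:
        if sex_column not in cohort.columns:
            raise KeyError(f"cohort lacks sex column {sex_column!r}")
        sexes = cohort[sex_column].astype(str)
        unknown = sorted(set(sexes.unique()) - set(tables))
        if unknown:
            raise ValueError(f"no coefficient table for sex value(s) {unknown}")
        groups = [(s, cohort.index[sexes == s]) for s in sexes.unique()]
        lookup = tables
    for sex, idx in groups:
        if len(idx) == 0:
            continue
        table = lookup[sex]
        lp = linear_predictor(cohort.loc[idx], table, validate_ranges)
        res = ten_year_risk(lp, table)
        out.loc[idx, "lp"] = res.lp
        out.loc[idx, "risk"] = res.risk
        out.loc[idx, "high_risk"] = res.high_risk.astype(float)
    out["high_risk"] = out["high_risk"].astype(int)
    return out
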