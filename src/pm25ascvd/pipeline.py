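"""Configuration-driven pipeline runner and publication-shaped table export.

A pipeline run is described by a YAML/JSON-style config (see
:class:`PipelineConfig`): which stages to execute, which adjustment models,
the output directory, and the seed from which all stage-level randomness is
derived.  Each stage writes a tidy CSV; a JSON manifest records versions,
seeds, row counts and warnings so every exported number traces to a stage.
"""

from __future__ import annotations

import json
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CovariateConfig,
    ExposureConfig,
    OutcomeConfig,
    generate_cohort,
)
from .constituents import constituent_result_table
from .ism import substitution_matrix
from .risk import example_coefficient_table, load_coefficient_table, score_cohort
from .rounding import round_half_up
from .splines import fit_spline_curve
from .stratified import STRATIFIERS, stratified_table

__all__ = ["PipelineConfig", "run_pipeline", "summarize_table1", "COHORT_SCHEMA"]

#: Header contract for cohort CSVs: column -> (kind, unit/levels note).
COHORT_SCHEMA = {
    "id": ("integer", "participant identifier"),
    "gender": ("categorical", "female/male"),
    "marital_status": ("categorical", "married/unmarried"),
    "education": ("categorical", "primary_or_below/junior_high/high_or_above"),
    "income": ("categorical", "low/middle/high average monthly income"),
    "smoking": ("categorical", "never/former/current"),
    "drinking": ("categorical", "never/former/current"),
    "physical_activity": ("categorical", "low/moderate/high"),
    "high_fat_diet": ("categorical", "no/yes"),
    "fruit_veg": ("categorical", "no/yes adequate fruit & vegetable intake"),
    "region": ("categorical", "region code used by risk tables"),
    "age": ("continuous", "years"),
    "waist_circumference": ("continuous", "cm"),
    "sbp": ("continuous", "mmHg, systolic blood pressure"),
    "total_cholesterol": ("continuous", "mg/dL"),
    "hdl_cholesterol": ("continuous", "mg/dL"),
    "diabetes": ("binary", "0/1"),
    "family_history_ascvd": ("binary", "0/1"),
    "bp_treated": ("binary", "0/1 on antihypertensive treatment"),
    "BC": ("continuous", "µg/m³ black carbon"),
    "NH4": ("continuous", "µg/m³ ammonium"),
    "NO3": ("continuous", "µg/m³ nitrate"),
    "OM": ("continuous", "µg/m³ organic matter"),
    "SO4": ("continuous", "µg/m³ sulfate"),
    "SOIL": ("continuous", "µg/m³ soil dust"),
    "pm25": ("continuous", "µg/m³ total PM2.5 mass"),
    "risk": ("continuous", "event probability / predicted 10-year risk"),
    "high_risk": ("binary", "1 if predicted 10-year ASCVD risk >= 10%"),
}

KNOWN_STAGES = (
    "simulate",
    "score",
    "concentration",
    "proportion",
    "residual",
    "ism",
    "spline",
    "stratify",
    "report",
)

#: default log-odds per µg/m³ used by the simulate stage so downstream
#: stages have signal to find; black carbon carries the largest effect
DEFAULT_TRUE_BETA = {"BC": 0.25, "pm25": 0.02}


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs."""

    output_dir: str = "pm25ascvd_output"
    stages: tuple = ("simulate", "concentration", "proportion", "residual")
    n: int = 10_000
    seed: int = 0
    models: tuple = (1, 2)
    cohort_csv: str | None = None       # skip simulate, load this instead
    coefficient_table: str | None = None  # YAML path for the score stage
    true_beta: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_BETA))
    target_prevalence: float = 0.28143
    spline_pollutants: tuple = ("pm25", "BC")
    stratify_pollutant: str = "pm25"
    decimals: int = 3

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "models", "spline_pollutants"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def validate(self) -> None:
        unknown = set(self.stages) - set(KNOWN_STAGES)
        if unknown:
            raise ValueError(f"unknown stage name(s): {sorted(unknown)}")
        if self.cohort_csv is None and "simulate" not in self.stages:
            needs_cohort = set(self.stages) - {"report"}
            if needs_cohort:
                raise ValueError(
                    "stages need a cohort: provide cohort_csv or add 'simulate'"
                )
        if self.cohort_csv is not None and not Path(self.cohort_csv).exists():
            raise FileNotFoundError(self.cohort_csv)
        if self.coefficient_table is not None and not Path(self.coefficient_table).exists():
            raise FileNotFoundError(self.coefficient_table)


def _round_cols(df: pd.DataFrame, cols, decimals: int) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        if c in out.columns:
            out[c] = out[c].map(lambda v: round_half_up(v, decimals))
    return out


def load_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV, restoring categorical dtypes from string columns."""
    df = pd.read_csv(path)
    for c in df.columns:
        if df[c].dtype == object:
            df[c] = df[c].astype("category")
    return df


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns {stage: output path or frame}.

    Deterministic for a fixed (config, seed): stage seeds are spawned from
    the config seed via named substreams.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": list(config.stages),
        "warnings": [],
        "row_counts": {},
    }
    outputs: dict = {}

    def export(stage: str, df: pd.DataFrame, round_cols=("or", "ci_low", "ci_high")):
        tidy = _round_cols(df, round_cols, config.decimals)
        path = outdir / f"{stage}.csv"
        tidy.to_csv(path, index=False)
        manifest["row_counts"][stage] = int(len(tidy))
        outputs[stage] = path

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        if config.cohort_csv is not None:
            cohort = load_cohort_csv(config.cohort_csv)
        elif "simulate" in config.stages:
            cohort = generate_cohort(
                n=config.n,
                seed=config.seed,
                exposure_config=ExposureConfig(),
                covariate_config=CovariateConfig(),
                outcome_config=OutcomeConfig(
                    mechanism="logistic",
                    true_beta=dict(config.true_beta),
                    target_prevalence=config.target_prevalence,
                ),
            )
            path = outdir / "cohort.csv"
            cohort.to_csv(path, index=False)
            schema = {
                col: {"kind": COHORT_SCHEMA[col][0], "note": COHORT_SCHEMA[col][1]}
                for col in cohort.columns if col in COHORT_SCHEMA
            }
            with open(outdir / "cohort_schema.json", "w") as fh:
                json.dump(schema, fh, indent=2)
            manifest["row_counts"]["simulate"] = int(len(cohort))
            outputs["simulate"] = path
        else:
            cohort = None

        if "score" in config.stages:
            tables = (
                load_coefficient_table(config.coefficient_table)
                if config.coefficient_table
                else example_coefficient_table()
            )
            scored = score_cohort(cohort, tables)
            export("score", pd.concat([cohort[["id"]], scored], axis=1),
                   round_cols=("lp", "risk"))

        method_stage = {"concentration", "proportion", "residual"} & set(config.stages)
        if method_stage:
            table = constituent_result_table(cohort, models=config.models)
            table = table[table["method"].isin(method_stage)]
            export("constituent_models", table)

        if "ism" in config.stages:
            export("ism", substitution_matrix(cohort, model=2))

        if "spline" in config.stages:
            frames = []
            for pollutant in config.spline_pollutants:
                sc = fit_spline_curve(cohort, pollutant, model=2)
                frame = sc.curve.assign(
                    pollutant=pollutant, p_nonlinear=sc.p_nonlinear,
                    x_ref=sc.x_ref,
                )
                frames.append(frame)
            export("spline", pd.concat(frames, ignore_index=True))

        if "stratify" in config.stages:
            export(
                "stratify",
                stratified_table(cohort, config.stratify_pollutant,
                                 STRATIFIERS, model=2),
            )

        if "report" in config.stages and cohort is not None:
            export("table1", summarize_table1(cohort), round_cols=("value",))

        manifest["warnings"] = [str(w.message) for w in caught]

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    outputs["manifest"] = outdir / "manifest.json"
    return outputs


def summarize_table1(cohort: pd.DataFrame, decimals: int = 3) -> pd.DataFrame:
    """Descriptive characteristics table: mean +/- SD or n (%) per variable.

    Percentages use half-up rounding to ``decimals`` places, so a binary
    outcome with 8,770 of 31,162 positives prints as ``8770 (28.143)``.
    """
    rows = []
    n_total = len(cohort)
    for col in cohort.columns:
        if col == "id":
            continue
        s = cohort[col]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            counts = s.value_counts(sort=False)
            for level, count in counts.items():
                pct = round_half_up(100.0 * count / n_total, decimals)
                rows.append(
                    {"variable": col, "level": str(level), "statistic": "n_pct",
                     "value": float(count), "display": f"{count} ({pct:.{decimals}f})"}
                )
        elif set(pd.unique(s.dropna())) <= {0, 1}:
            count = int(s.sum())
            pct = round_half_up(100.0 * count / n_total, decimals)
            rows.append(
                {"variable": col, "level": "yes", "statistic": "n_pct",
                 "value": float(count), "display": f"{count} ({pct:.{decimals}f})"}
            )
        else:
            mean = float(s.mean())
            sd = float(s.std(ddof=1)) if n_total > 1 else 0.0
            if n_total == 1:
                warnings.warn(f"single-row cohort: SD of {col!r} reported as 0",
                              stacklevel=2)
            mean_r = round_half_up(mean, decimals)
            sd_r = round_half_up(sd, decimals)
            rows.append(
                {"variable": col, "level": "", "statistic": "mean_sd",
                 "value": mean,
                 "display": f"{mean_r:.{decimals}f} ± {sd_r:.{decimals}f}"}
            )
    return pd.DataFrame(rows)
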