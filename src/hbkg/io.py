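"""Schema-validated cohort I/O and the end-to-end pipeline.

The interchange format is a flat CSV, one row per patient, UTF-8 with a
header and decimal points. ``read_cohort`` validates it against the column
dictionary (types and plausible unit ranges, e.g. Hb in 30-220 g/L) and
returns the typed table with a row-level validation report; nothing is ever
dropped silently. ``run_pipeline`` chains simulate -> index -> stats ->
model and stamps every artifact with the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import index as index_mod
from . import models as models_mod
from . import simulate as sim_mod
from . import stats as stats_mod
from .index import CTD_HOUR_COLUMNS

__all__ = [
    "SchemaError",
    "COLUMN_RANGES",
    "read_cohort",
    "write_cohort",
    "PipelineConfig",
    "run_pipeline",
]


class SchemaError(ValueError):
    """The CSV header does not match the documented column dictionary."""


#: Plausible-unit ranges for warning-level validation (not hard failures).
COLUMN_RANGES = {
    "age": (18, 100),
    "height_m": (1.2, 2.2),
    "weight_kg": (30, 250),
    "bmi": (12, 60),
    **{f"hb_{tp}": (30, 220) for tp in ("t0", "t1", "t6", "t18")},
    **{f"hct_{tp}": (0.10, 0.65) for tp in ("t0", "t1", "t6", "t18")},
    **{f"rbc_{tp}": (1.0, 8.0) for tp in ("t0", "t1", "t6", "t18")},
    "drain_hb": (0, 180),
    "prbc_units": (0, 10),
    **{c: (0, 2000) for c in CTD_HOUR_COLUMNS},
}

_REQUIRED_COLUMNS = (
    "sex", "height_m", "weight_kg", "hb_t0", "hb_t1", "drain_hb", "prbc_units",
) + CTD_HOUR_COLUMNS

_KNOWN_PREFIXES = ("noise_", "ctd_", "hb_", "hct_", "rbc_", "fib_")
_KNOWN_COLUMNS = set(_REQUIRED_COLUMNS) | set(COLUMN_RANGES) | {
    "patient_id", "sex", "age", "bmi", "surgery_type", "n_grafts",
    "pt", "aptt", "inr", "ddimer", "fib_t1", "fib_t6", "fib_t18",
}


def read_cohort(path, strict: bool = True):
    """Read and validate a cohort CSV.

    Returns ``(table, report)`` where ``report`` is a DataFrame with one row
    per issue: columns ``row`` (-1 for header issues), ``column``, ``level``
    (error/warning) and ``reason``. Unknown columns raise :class:`SchemaError`
    when ``strict``; rows with unparseable cells are quarantined (kept in the
    report, absent from the table).
    """
    df = pd.read_csv(path)
    issues = []

    unknown = [c for c in df.columns
               if c not in _KNOWN_COLUMNS and not c.startswith(_KNOWN_PREFIXES)]
    if unknown and strict:
        raise SchemaError(f"unknown columns: {', '.join(unknown)}")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {', '.join(missing)}")

    numeric_cols = [c for c in df.columns if c not in ("sex", "surgery_type")]
    bad_rows = set()
    for c in numeric_cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        newly_bad = df[c].notna() & coerced.isna()
        for i in df.index[newly_bad]:
            issues.append({"row": i, "column": c, "level": "error",
                           "reason": f"unparseable value {df.at[i, c]!r}"})
            bad_rows.add(i)
        df[c] = coerced

    for c, (lo, hi) in COLUMN_RANGES.items():
        if c not in df.columns:
            continue
        out = df[c].notna() & ((df[c] < lo) | (df[c] > hi))
        for i in df.index[out]:
            issues.append({"row": i, "column": c, "level": "warning",
                           "reason": f"value {df.at[i, c]} outside [{lo}, {hi}]"})

    for c in _REQUIRED_COLUMNS:
        for i in df.index[df[c].isna()]:
            issues.append({"row": i, "column": c, "level": "warning",
                           "reason": "required field missing; row excluded from index stage"})

    table = df.drop(index=sorted(bad_rows))
    report = pd.DataFrame(issues, columns=["row", "column", "level", "reason"])
    return table, report


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort table as the documented CSV schema."""
    table.to_csv(path, index=False)


@dataclasses.dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips losslessly through YAML."""

    cohort: sim_mod.CohortConfig = dataclasses.field(default_factory=sim_mod.CohortConfig)
    index_mode: str = "consistent"  # 'consistent' or 'literal'
    grams_per_unit: float = 43.0
    alpha: float = 0.05
    cv_splits: int = 5
    cv_repeats: int = 10
    seed: int = 0

    #: per-stage seed offsets so stages re-run independently yet reproducibly
    _STAGE_OFFSETS = {"simulate": 0, "model": 104729}

    def stage_seed(self, stage: str) -> int:
        return (self.seed + self._STAGE_OFFSETS[stage]) % (2**31 - 1)

    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = yaml.safe_load(text)
        cohort = sim_mod.CohortConfig.from_dict(d.pop("cohort", {}))
        return cls(cohort=cohort, **d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _stamp(cfg: PipelineConfig) -> dict:
    return {"config_hash": cfg.config_hash(), "seed": cfg.seed}


def run_pipeline(config: PipelineConfig, outdir, table: pd.DataFrame | None = None) -> Path:
    """Run simulate (unless a table is supplied) -> index -> stats -> model.

    Writes cohort.csv, truth.csv, index.csv, comparisons.csv, screening.csv,
    model_report.csv/json, summary.json and run_log.json under ``outdir``;
    every JSON artifact carries the config hash and seed. Returns ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = {"stamp": _stamp(config), "stages": {}}

    try:
        if table is None:
            cohort = sim_mod.generate_cohort(config.cohort,
                                             seed=config.stage_seed("simulate"))
            table = cohort.table
            write_cohort(table, outdir / "cohort.csv")
            cohort.truth.to_csv(outdir / "truth.csv", index=False)
            log["stages"]["simulate"] = {"n_patients": len(table)}

        results, exclusions = index_mod.compute_index_table(
            table, mode=config.index_mode, grams_per_unit=config.grams_per_unit)
        merged = table.join(results, how="inner")
        merged.to_csv(outdir / "index.csv", index=False)
        log["stages"]["index"] = {
            "n_computed": len(results),
            "n_excluded": len(exclusions),
            "exclusions": exclusions.to_dict(orient="records"),
        }

        y = merged["hbkg_index"].to_numpy()
        comps = []
        comps.append(stats_mod.compare_two_groups(y, merged["sex"], "gender"))
        bmi_groups = merged["bmi"].map(index_mod.classify_bmi_group)
        comps.append(stats_mod.compare_k_groups(y, bmi_groups, "bmi_group"))
        comps.append(stats_mod.compare_k_groups(y, merged["surgery_type"], "surgery_type"))
        ctd_total = merged[list(CTD_HOUR_COLUMNS)].sum(axis=1)
        ctd_groups = ctd_total.map(index_mod.classify_ctd_group)
        comps.append(stats_mod.compare_two_groups(y, ctd_groups, "ctd_group"))
        comp_rows = []
        for c in comps:
            comp_rows.append({
                "stratification": c.stratification,
                "groups": "|".join(map(str, c.group_labels)),
                "ns": "|".join(map(str, c.group_ns)),
                "means": "|".join(f"{m:.4f}" for m in c.group_means),
                "sds": "|".join(f"{s:.4f}" for s in c.group_sds),
                "statistic": c.statistic,
                "dfs": "|".join(f"{d:g}" for d in c.dfs),
                "p_value": c.p_value,
                "eta_squared": "" if c.eta_squared is None else c.eta_squared,
                "degenerate": c.degenerate,
            })
        pd.DataFrame(comp_rows).to_csv(outdir / "comparisons.csv", index=False)
        age_r, age_p = stats_mod.correlate_age(y, merged["age"])

        predictors = sim_mod.candidate_predictor_columns(merged)
        screening = stats_mod.screen_predictors(merged, y, predictors,
                                                alpha=config.alpha)
        screening.to_csv(outdir / "screening.csv", index=False)
        retained = screening.loc[screening["retained"], "predictor"].tolist()
        log["stages"]["stats"] = {
            "n_screened": len(screening),
            "n_retained": len(retained),
            "n_degenerate": int(screening["degenerate"].sum()),
            "age_pearson_r": age_r,
            "age_pearson_p": age_p,
        }

        report = models_mod.run_comparison(
            merged[predictors], y,
            specs=models_mod.default_model_specs(config.stage_seed("model")),
            retained=retained, n_splits=config.cv_splits,
            n_repeats=config.cv_repeats, seed=config.stage_seed("model"))
        report.to_csv(outdir / "model_report.csv", index=False)
        (outdir / "model_report.json").write_text(json.dumps(
            {"stamp": _stamp(config),
             "models": report.to_dict(orient="records")}, indent=2))
        log["stages"]["model"] = {"best_by_mse": report.iloc[0]["model"]}

        summary = {
            "stamp": _stamp(config),
            "n_patients": int(len(merged)),
            "index_mean": float(np.mean(y)),
            "index_sd": float(np.std(y, ddof=1)),
            "index_decomposition_mean_g": {
                "intraop_loss": float(merged["intraop_loss_g"].mean()),
                "ctd_loss": float(merged["ctd_loss_g"].mean()),
                "transfused_hb": float(merged["transfused_hb_g"].mean()),
            },
            "transfused_fraction": float((merged["prbc_units"] > 0).mean()),
            "ctd_ge_500ml_fraction": float((ctd_total >= 500).mean()),
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    except Exception as err:
        log["failed"] = repr(err)
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
        raise
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return outdir
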