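"""Cohort CSV reading/writing and the end-to-end pipeline runner.

The canonical interchange is one wide UTF-8 CSV, one row per patient x
timepoint, with columns ``patient_id, timepoint, mos_q1..mos_q12,
eortc_q10, eortc_q11, eortc_q18, anamnesis_sleep, sleep_med, sex, age,
bmi, treatment_intent, tumour_group, biomarker_*``; an empty cell is a
missing value.  ``run_pipeline`` chains simulate (optional) -> score ->
factor analysis -> Rasch (per factor) -> validation, writing each
stage's outputs plus a manifest (input hashes, seed, config echo) so a
run can be reproduced byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .efa import OrdinalFactorModel
from .instruments import (
    DEFAULT_DTS_CUTOFF,
    DEFAULT_SQ_CUTOFF,
    DTS_ITEMS,
    EORTC_RANK_MAX,
    EORTC_RANK_MIN,
    MOS_RANK_MAX,
    MOS_RANK_MIN,
    SQ_ITEMS,
    score_dataframe,
)
from .rasch import PartialCreditModel
from .simulate import GeneratorConfig, generate_cohort, severity_matrix
from .validation import (
    biomarker_null_screen,
    correlate,
    cutoff_confusion,
    group_ttest,
    wilcoxon_signed_rank,
)

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ["patient_id", "timepoint"] + [f"mos_q{i}" for i in range(1, 13)]
KNOWN_COLUMNS = MANDATORY_COLUMNS + [
    "eortc_q10",
    "eortc_q11",
    "eortc_q18",
    "anamnesis_sleep",
    "sleep_med",
    "sex",
    "age",
    "bmi",
    "treatment_intent",
    "tumour_group",
]

_RANK_BOUNDS = {
    **{f"mos_q{i}": (MOS_RANK_MIN, MOS_RANK_MAX) for i in range(1, 13)},
    **{f"eortc_q{q}": (EORTC_RANK_MIN, EORTC_RANK_MAX) for q in (10, 11, 18)},
    "anamnesis_sleep": (0, 1),
    "sleep_med": (0, 2),
}


class SchemaError(ValueError):
    """The cohort CSV violates the documented schema."""


def read_cohort(path, schema: str = "strict") -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Strict mode rejects out-of-range codes with an error naming the row
    and column; lenient mode coerces them to missing with a warning.
    Unknown columns (other than ``biomarker_*``) only warn; absent
    mandatory columns are an error listing them.
    """
    if schema not in ("strict", "lenient"):
        raise ValueError(f"unknown schema mode {schema!r}")
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory columns: {missing_cols}")
    unknown = [
        c for c in df.columns if c not in KNOWN_COLUMNS and not c.startswith("biomarker_")
    ]
    if unknown:
        logger.warning("ignoring unknown columns: %s", unknown)
    dup = df.duplicated(subset=["patient_id", "timepoint"])
    if dup.any():
        raise SchemaError(
            f"duplicate (patient_id, timepoint) rows: {df.loc[dup, 'patient_id'].tolist()}"
        )
    bad_tp = ~df["timepoint"].isin(["baseline", "followup"])
    if bad_tp.any():
        raise SchemaError(
            f"timepoint must be baseline/followup; bad rows {df.index[bad_tp].tolist()}"
        )
    for col, (lo, hi) in _RANK_BOUNDS.items():
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        coded = vals.notna()
        bad = coded & ((vals < lo) | (vals > hi) | (vals != vals.round()))
        if bad.any():
            rows = df.index[bad].tolist()
            if schema == "strict":
                raise SchemaError(
                    f"column {col}: values outside {lo}..{hi} at rows {rows} "
                    f"(e.g. {df.loc[rows[0], col]!r})"
                )
            logger.warning("column %s: %d out-of-range values coerced to missing",
                           col, int(bad.sum()))
            vals[bad] = np.nan
        df[col] = vals
    for col in df.columns:
        miss = int(df[col].isna().sum())
        if miss:
            logger.info("column %s: %d missing values", col, miss)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


@dataclasses.dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    input_csv: str | None = None  # None -> simulate a cohort first
    out_dir: str = "sleepfactor_run"
    seed: int = 0
    n_patients: int = 90
    cutoff_sq: int = DEFAULT_SQ_CUTOFF
    cutoff_dts: int = DEFAULT_DTS_CUTOFF
    missing_policy: str = "strict"
    rotation: str = "varimax"
    retention_threshold: float = 2.0
    rasch_tol: float = 1e-5
    rasch_max_iter: int = 200
    log_level: str = "INFO"


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate (optional) -> score -> efa -> rasch -> validate.

    Returns the manifest dict; all stage outputs are written under
    ``config.out_dir``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if config.input_csv is None:
        cohort = generate_cohort(
            GeneratorConfig.scaled(config.n_patients, seed=config.seed)
        )
        cohort_path = out / "cohort.csv"
        write_cohort(cohort.records, cohort_path)
        written.append(cohort_path)
        truth_path = out / "truth.csv"
        cohort.truth.to_csv(truth_path, index=False, float_format="%.10g")
        written.append(truth_path)
        df = read_cohort(cohort_path, schema=config.missing_policy and "strict")
        input_hash = _sha256(cohort_path)
        input_name = str(cohort_path)
    else:
        df = read_cohort(config.input_csv, schema="strict")
        input_hash = _sha256(Path(config.input_csv))
        input_name = str(config.input_csv)

    scored = score_dataframe(df, policy=config.missing_policy,
                             cutoff_sq=config.cutoff_sq, cutoff_dts=config.cutoff_dts)
    scored_path = out / "scored.csv"
    write_cohort(scored, scored_path)
    written.append(scored_path)

    baseline = df[df["timepoint"] == "baseline"]
    efa_res = OrdinalFactorModel.from_dataframe(
        baseline, columns=[f"mos_q{i}" for i in range(3, 13)]
    ).fit(rotation=config.rotation, retention_threshold=config.retention_threshold)
    efa_path = out / "efa.json"
    efa_path.write_text(json.dumps(efa_res.to_dict(), indent=2))
    written.append(efa_path)
    loadings_path = out / "loadings.csv"
    efa_res.loadings_table().to_csv(loadings_path)
    written.append(loadings_path)

    rasch_report = {}
    for name, items in (("sq", SQ_ITEMS), ("dts", DTS_ITEMS)):
        sev = severity_matrix(baseline, items)
        fit = PartialCreditModel(sev).fit(max_iter=config.rasch_max_iter,
                                          tol=config.rasch_tol)
        rasch_report[name] = {
            "items": {
                str(it.item_id): {"delta": it.delta, "tau": it.tau.tolist(),
                                  "disordered": it.disordered}
                for it in fit.items
            },
            "n_persons": len(fit.persons),
            "n_excluded": fit.n_excluded,
            "converged": fit.converged,
            "loglik": fit.loglik,
            "targeting_spread": fit.targeting_spread(),
        }
        persons_path = out / f"rasch_{name}_persons.csv"
        fit.persons.to_csv(persons_path, float_format="%.10g")
        written.append(persons_path)
        dist = fit.person_item_distribution()
        bins_path = out / f"rasch_{name}_bins.csv"
        pd.DataFrame(
            {
                "bin_left": dist.bin_edges[:-1],
                "bin_right": dist.bin_edges[1:],
                "person_count": dist.person_counts,
                "threshold_count": dist.threshold_counts,
            }
        ).to_csv(bins_path, index=False, float_format="%.10g")
        written.append(bins_path)
    rasch_path = out / "rasch.json"
    rasch_path.write_text(json.dumps(_jsonable(rasch_report), indent=2))
    written.append(rasch_path)

    validation = _validation_report(scored, config)
    val_path = out / "validation.json"
    val_path.write_text(json.dumps(_jsonable(validation), indent=2))
    written.append(val_path)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _jsonable(dataclasses.asdict(config)),
        "input": {"path": input_name, "sha256": input_hash},
        "outputs": {str(p.name): _sha256(p) for p in written},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _validation_report(scored: pd.DataFrame, config: RunConfig) -> dict:
    report: dict = {"correlations": {}, "change_tests": {}, "group_tests": {},
                    "cutoff_tables": {}, "biomarkers": []}
    for tp in ("baseline", "followup"):
        sub = scored[scored["timepoint"] == tp]
        for score in ("sq", "dts"):
            try:
                res = correlate(sub[score], sub["slp9"], "spearman")
            except ValueError:
                continue
            report["correlations"][f"{score}_slp9_{tp}"] = dataclasses.asdict(res)
    wide = scored.pivot(index="patient_id", columns="timepoint", values=["sq", "dts"])
    for score in ("sq", "dts"):
        try:
            pre = wide[(score, "baseline")]
            post = wide[(score, "followup")]
        except KeyError:
            continue
        res = wilcoxon_signed_rank(pre, post)
        report["change_tests"][score] = dataclasses.asdict(res)
    base = scored[scored["timepoint"] == "baseline"]
    if base["sex"].nunique() == 2:
        for score in ("sq", "dts"):
            try:
                report["group_tests"][f"{score}_by_sex"] = dataclasses.asdict(
                    group_ttest(base[score], base["sex"])
                )
            except ValueError:
                pass
    if "anamnesis_sleep" in base.columns:
        try:
            tab = cutoff_confusion(base["sq"], base["anamnesis_sleep"], config.cutoff_sq)
            report["cutoff_tables"]["sq_vs_anamnesis"] = {
                "counts": tab.counts.tolist(),
                "cutoff": tab.cutoff,
                "sensitivity": tab.sensitivity,
                "specificity": tab.specificity,
            }
        except ValueError:
            pass
    bio = biomarker_null_screen(scored)
    report["biomarkers"] = bio.to_dict(orient="records") if len(bio) else []
    return report
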