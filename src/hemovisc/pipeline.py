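"""Cohort file I/O and the end-to-end estimation/validation pipeline.

Pipeline stage order: load -> outlier exclusion -> random split ->
calibration (fit on the experimental group, or load the literature-fixed
models) -> personalized estimation -> correlation validation. Every input
subject appears exactly once in the per-subject output with a status of
``ok``, ``excluded-outlier``, ``invalid-r6`` or ``row-error``; all
randomness flows through the configured seed so two runs with identical
inputs and config produce byte-identical outputs.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .calibration import (
    CalibrationModel,
    build_design,
    fit_group,
    predict_r6,
    reference_models,
)
from .errors import ConfigError, DomainError, HemoviscError, SchemaError
from .hemodynamics import BMIClass, SubjectRecord, derive_all
from .validation import check_balance, exclude_outliers, random_split, run_validation
from .viscosity import DEFAULT_CONSTANTS, ModelConstants, closed_form_viscosity, invert_r6

__all__ = [
    "PipelineConfig",
    "CohortLoadResult",
    "read_cohort",
    "write_cohort",
    "run_pipeline",
    "PipelineReport",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "subject_id", "height_cm", "weight_kg", "heart_rate_bpm",
    "sbp_mmHg", "dbp_mmHg", "lv_edd_mm", "lv_esd_mm",
]
OPTIONAL_COLUMNS = ["measured_viscosity_cp"]

FIT_FROM_DATA = "fit_from_data"
REFERENCE_MODELS = "reference_models"

DEFAULT_BALANCE_PARAMETERS = ("bmi", "pp", "sv", "co", "bsa")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    input_path: Path
    output_dir: Path
    constants: ModelConstants = DEFAULT_CONSTANTS
    split_ratio: float = 0.5
    split_seed: int = 0
    outlier_field: str = "pp"
    outlier_z: float = 3.0
    calibration_source: str = FIT_FROM_DATA
    balance_parameters: Tuple[str, ...] = DEFAULT_BALANCE_PARAMETERS

    def __post_init__(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise ConfigError(f"split_ratio must be in (0, 1), got {self.split_ratio!r}")
        if not self.outlier_z > 0:
            raise ConfigError(f"outlier_z must be > 0, got {self.outlier_z!r}")
        if self.calibration_source not in (FIT_FROM_DATA, REFERENCE_MODELS):
            raise ConfigError(
                f"calibration_source must be {FIT_FROM_DATA!r} or "
                f"{REFERENCE_MODELS!r}, got {self.calibration_source!r}"
            )

    @classmethod
    def from_json_file(cls, path: Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        try:
            return cls(
                input_path=Path(raw["input_path"]),
                output_dir=Path(raw["output_dir"]),
                constants=ModelConstants.from_mapping(raw.get("constants")),
                split_ratio=float(raw.get("split_ratio", 0.5)),
                split_seed=int(raw.get("split_seed", 0)),
                outlier_field=str(raw.get("outlier_field", "pp")),
                outlier_z=float(raw.get("outlier_z", 3.0)),
                calibration_source=str(raw.get("calibration_source", FIT_FROM_DATA)),
                balance_parameters=tuple(raw.get("balance_parameters",
                                                 DEFAULT_BALANCE_PARAMETERS)),
            )
        except KeyError as exc:
            raise ConfigError(f"missing config key: {exc}") from exc


@dataclass(frozen=True)
class CohortLoadResult:
    """Validated records plus per-row failures (line number, id, message)."""

    records: Tuple[SubjectRecord, ...]
    row_errors: Tuple[Tuple[int, Optional[str], str], ...]

    @property
    def partial(self) -> bool:
        return len(self.row_errors) > 0


def read_cohort(path: Path) -> CohortLoadResult:
    """Read and validate a cohort CSV.

    A missing required column is a schema error; an unparseable or
    invariant-violating row is collected with its line number while the
    remaining rows load normally.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    records: List[SubjectRecord] = []
    errors: List[Tuple[int, Optional[str], str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file")
        missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            sid = (row.get("subject_id") or "").strip() or None
            try:
                mu_raw = (row.get("measured_viscosity_cp") or "").strip()
                records.append(SubjectRecord(
                    subject_id=sid or f"row{lineno}",
                    height_cm=float(row["height_cm"]),
                    weight_kg=float(row["weight_kg"]),
                    heart_rate_bpm=float(row["heart_rate_bpm"]),
                    sbp_mmHg=float(row["sbp_mmHg"]),
                    dbp_mmHg=float(row["dbp_mmHg"]),
                    lv_edd_mm=float(row["lv_edd_mm"]),
                    lv_esd_mm=float(row["lv_esd_mm"]),
                    measured_viscosity_cp=float(mu_raw) if mu_raw else None,
                ))
            except (ValueError, TypeError, DomainError) as exc:
                errors.append((lineno, sid, str(exc)))
    return CohortLoadResult(records=tuple(records), row_errors=tuple(errors))


def write_cohort(records: Sequence[SubjectRecord], path: Path) -> None:
    """Write records to the cohort CSV schema (blank viscosity if absent)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REQUIRED_COLUMNS + OPTIONAL_COLUMNS)
        for r in records:
            writer.writerow([
                r.subject_id, repr(float(r.height_cm)), repr(float(r.weight_kg)),
                repr(float(r.heart_rate_bpm)), repr(float(r.sbp_mmHg)),
                repr(float(r.dbp_mmHg)), repr(float(r.lv_edd_mm)),
                repr(float(r.lv_esd_mm)),
                "" if r.measured_viscosity_cp is None
                else repr(float(r.measured_viscosity_cp)),
            ])


@dataclass(frozen=True)
class PipelineReport:
    """In-memory mirror of the files a pipeline run writes."""

    subject_rows: Tuple[Dict[str, object], ...]
    models: Tuple[CalibrationModel, ...]
    summary: Dict[str, object]
    output_files: Dict[str, Path] = field(default_factory=dict)


def _fmt(value: Optional[float], decimals: int) -> str:
    return "" if value is None else f"{value:.{decimals}f}"


def _validation_summary(cohort, models, constants) -> Dict[str, object]:
    report = run_validation(cohort, models, constants)
    return report.summary()


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full pipeline and write models/per-subject/summary files.

    Writes ``models.json``, ``subjects.csv`` and ``summary.json`` into
    ``config.output_dir``. Correlation summaries are computed on the
    validation group (primary), the experimental group and the full
    kept cohort, each labelled. Raises a stage-labelled error on failure.
    """
    logger.info("[load] reading cohort from %s", config.input_path)
    load = read_cohort(config.input_path)
    statuses: Dict[str, Dict[str, object]] = {}
    order: List[str] = []

    for lineno, sid, msg in load.row_errors:
        key = sid or f"row{lineno}"
        statuses[key] = {"subject_id": key, "status": "row-error", "reason": msg}
        order.append(key)
        logger.warning("[load] line %d rejected: %s", lineno, msg)
    for rec in load.records:
        statuses[rec.subject_id] = {"subject_id": rec.subject_id, "status": "ok",
                                    "reason": ""}
        order.append(rec.subject_id)
    if len(load.records) == 0:
        raise SchemaError(f"[load] no valid subjects in {config.input_path}")

    has_viscosity = all(r.measured_viscosity_cp is not None for r in load.records)
    any_viscosity = any(r.measured_viscosity_cp is not None for r in load.records)
    if config.calibration_source == FIT_FROM_DATA and not any_viscosity:
        raise ConfigError(
            "[calibrate] calibration_source=fit_from_data requires measured "
            "viscosity in the input"
        )

    logger.info("[outliers] z-score rule on %s at threshold %.2f",
                config.outlier_field, config.outlier_z)
    kept, excluded = exclude_outliers(load.records, config.outlier_field, config.outlier_z)
    for rec, reason in excluded:
        statuses[rec.subject_id].update(status="excluded-outlier", reason=reason)
        logger.info("[outliers] excluded %s: %s", rec.subject_id, reason)

    estimation_only = not has_viscosity
    split = None
    balance = []
    if not estimation_only:
        logger.info("[split] ratio %.4f seed %d", config.split_ratio, config.split_seed)
        split = random_split(kept, config.split_ratio, config.split_seed)
        balance = check_balance(split, kept, config.balance_parameters)
        for rep in balance:
            logger.info("[split] balance %s: var p=%.3f mean p=%.3f -> %s",
                        rep.parameter_name, rep.variance_test_p, rep.mean_test_p,
                        "balanced" if rep.balanced else "UNBALANCED")

    by_id = {r.subject_id: r for r in kept}
    if config.calibration_source == REFERENCE_MODELS:
        models = reference_models()
        logger.info("[calibrate] using literature-fixed models")
    else:
        fit_subjects = ([by_id[i] for i in split.experimental_ids] if split is not None
                        else list(kept))
        groups: Dict[int, List[SubjectRecord]] = {0: [], 1: []}
        for rec in fit_subjects:
            derived = derive_all(rec)
            if derived.bmi_class is BMIClass.THIN:
                continue
            if rec.measured_viscosity_cp is None:
                continue
            groups[derived.bmi_class.indicator].append(rec)
        fitted = []
        for g in (1, 0):
            try:
                design = build_design(groups[g], g, config.constants)
                fitted.append(fit_group(design, g))
                logger.info("[calibrate] group %d fitted on n=%d", g, len(design))
            except HemoviscError as exc:
                raise type(exc)(f"[calibrate] group {g}: {exc}") from exc
        models = tuple(fitted)

    # Per-subject estimation for every kept subject.
    by_group = {m.group: m for m in models}
    split_of: Dict[str, str] = {}
    if split is not None:
        split_of.update({i: "experimental" for i in split.experimental_ids})
        split_of.update({i: "validation" for i in split.validation_ids})
    for rec in kept:
        row = statuses[rec.subject_id]
        row["split"] = split_of.get(rec.subject_id, "")
        derived = derive_all(rec)
        if derived.bmi_class is BMIClass.THIN:
            row.update(status="invalid-r6",
                       reason="thin-class: no calibration model")
            continue
        g = derived.bmi_class.indicator
        row["group"] = g
        r6_hat = predict_r6(by_group[g], rec, derived)
        row["predicted_r6"] = r6_hat
        result = closed_form_viscosity(r6_hat, derived.pp_mmHg, derived.bsa_m2,
                                       derived.co_ml_min, config.constants,
                                       provenance="personalized")
        if not result.valid:
            row.update(status="invalid-r6",
                       reason=f"nonpositive predicted R^6 ({r6_hat:.4g})")
            continue
        row["mu_estimated_cp"] = result.mu_cp
        if rec.measured_viscosity_cp is not None:
            row["mu_measured_cp"] = rec.measured_viscosity_cp
            row["target_r6"] = invert_r6(rec.measured_viscosity_cp, derived.bsa_m2,
                                         derived.co_ml_min, derived.pp_mmHg,
                                         config.constants)

    correlations: Dict[str, object] = {}
    if not estimation_only and split is not None:
        subsets = {
            "validation": [by_id[i] for i in split.validation_ids],
            "experimental": [by_id[i] for i in split.experimental_ids],
            "all": list(kept),
        }
        for label, subjects in subsets.items():
            usable = [s for s in subjects if s.measured_viscosity_cp is not None]
            try:
                correlations[label] = _validation_summary(usable, models, config.constants)
            except HemoviscError as exc:
                correlations[label] = {"error": str(exc)}
                logger.warning("[validate] %s subset: %s", label, exc)
    else:
        logger.info("[validate] skipped: no measured viscosity in input "
                    "(estimation-only mode)")

    summary: Dict[str, object] = {
        "n_input": len(order),
        "n_loaded": len(load.records),
        "n_row_errors": len(load.row_errors),
        "n_outliers_excluded": len(excluded),
        "split": None if split is None else {
            "seed": split.seed, "ratio": split.ratio,
            "n_experimental": len(split.experimental_ids),
            "n_validation": len(split.validation_ids),
            "experimental_ids": list(split.experimental_ids),
            "validation_ids": list(split.validation_ids),
        },
        "balance": [
            {"parameter": b.parameter_name,
             "group_means": list(b.group_means),
             "group_variances": list(b.group_variances),
             "variance_test_p": b.variance_test_p,
             "mean_test_p": b.mean_test_p,
             "balanced": b.balanced}
            for b in balance
        ],
        "calibration_source": config.calibration_source,
        "correlations": correlations,
        "estimation_only": estimation_only,
    }

    config.output_dir.mkdir(parents=True, exist_ok=True)
    models_path = config.output_dir / "models.json"
    subjects_path = config.output_dir / "subjects.csv"
    summary_path = config.output_dir / "summary.json"

    with open(models_path, "w", encoding="utf-8") as fh:
        json.dump([m.to_json_dict() for m in models], fh, indent=2, sort_keys=True)
        fh.write("\n")

    columns = ["subject_id", "status", "split", "group", "predicted_r6",
               "target_r6", "mu_estimated_cp", "mu_measured_cp", "reason"]
    subject_rows = []
    with open(subjects_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for key in order:
            row = statuses[key]
            subject_rows.append(dict(row))
            writer.writerow([
                row.get("subject_id", ""),
                row.get("status", ""),
                row.get("split", ""),
                "" if row.get("group") is None else row.get("group"),
                _fmt(row.get("predicted_r6"), 6),
                _fmt(row.get("target_r6"), 6),
                _fmt(row.get("mu_estimated_cp"), 2),
                _fmt(row.get("mu_measured_cp"), 2),
                row.get("reason", ""),
            ])

    with open(summary_path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineReport(
        subject_rows=tuple(subject_rows),
        models=tuple(models),
        summary=summary,
        output_files={"models": models_path, "subjects": subjects_path,
                      "summary": summary_path},
    )
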