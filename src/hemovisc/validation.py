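"""Cohort evaluation workflow: outlier exclusion, random split, balance
checks and Pearson-correlation validation of the calibrated model.

The workflow mirrors a standard clinical-calibration protocol: drop gross
outliers on one field (default pulse pressure, z-score rule), split the
cohort near 1:1 into experimental and validation groups, verify the split
introduced no between-group imbalance (Levene for variances, Welch for
means), then correlate the model's predicted R^6 and personalized
viscosity against their measurement-derived references.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .calibration import CalibrationModel, predict_r6
from .errors import DomainError, HemoviscError
from .hemodynamics import BMIClass, SubjectRecord, derive_all
from .viscosity import DEFAULT_CONSTANTS, ModelConstants, closed_form_viscosity, invert_r6

__all__ = [
    "SplitResult",
    "CorrelationResult",
    "BalanceReport",
    "SubjectEvaluation",
    "ValidationReport",
    "subject_parameter",
    "exclude_outliers",
    "random_split",
    "check_balance",
    "pearson",
    "run_validation",
]

ALPHA = 0.05


@dataclass(frozen=True)
class SplitResult:
    """A seeded two-way cohort partition."""

    experimental_ids: Tuple[str, ...]
    validation_ids: Tuple[str, ...]
    seed: int
    ratio: float


@dataclass(frozen=True)
class CorrelationResult:
    """Sample Pearson correlation with its two-sided p-value."""

    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class BalanceReport:
    """Between-group comparability check for one parameter."""

    parameter_name: str
    group_means: Tuple[float, float]
    group_variances: Tuple[float, float]
    variance_test_p: float
    mean_test_p: float
    balanced: bool


@dataclass(frozen=True)
class SubjectEvaluation:
    """Per-subject validation row."""

    subject_id: str
    group_indicator: Optional[int]
    predicted_r6: Optional[float]
    target_r6: Optional[float]
    mu_estimated_cp: Optional[float]
    mu_measured_cp: Optional[float]
    valid: bool
    reason: str = ""


@dataclass(frozen=True)
class ValidationReport:
    rows: Tuple[SubjectEvaluation, ...]
    r_r6: CorrelationResult
    r_mu: CorrelationResult
    n_valid: int
    n_excluded: int

    def summary(self) -> Dict[str, float]:
        return {
            "r_r6": self.r_r6.r,
            "p_r6": self.r_r6.p_value,
            "r_mu": self.r_mu.r,
            "p_mu": self.r_mu.p_value,
            "n_valid": self.n_valid,
            "n_excluded": self.n_excluded,
        }


# Parameter accessors for exclude_outliers / check_balance. Raw fields come
# straight off the record; derived ones go through derive_all.
_RAW_FIELDS = {
    "height": "height_cm",
    "weight": "weight_kg",
    "heart_rate": "heart_rate_bpm",
    "sbp": "sbp_mmHg",
    "dbp": "dbp_mmHg",
    "lv_edd": "lv_edd_mm",
    "lv_esd": "lv_esd_mm",
    "measured_viscosity": "measured_viscosity_cp",
}
_DERIVED_FIELDS = {"pp": "pp_mmHg", "bmi": "bmi", "bsa": "bsa_m2",
                   "sv": "sv_ml", "co": "co_ml_min"}


def subject_parameter(record: SubjectRecord, name: str) -> float:
    """Look up a raw or derived scalar parameter by short name."""
    if name in _RAW_FIELDS:
        value = getattr(record, _RAW_FIELDS[name])
        if value is None:
            raise DomainError(f"subject {record.subject_id!r} has no {name}")
        return float(value)
    if name in _DERIVED_FIELDS:
        return float(getattr(derive_all(record), _DERIVED_FIELDS[name]))
    if hasattr(record, name):
        return float(getattr(record, name))
    raise DomainError(f"unknown parameter {name!r}")


def exclude_outliers(
    subjects: Sequence[SubjectRecord],
    field: str = "pp",
    z_threshold: float = 3.0,
) -> Tuple[List[SubjectRecord], List[Tuple[SubjectRecord, str]]]:
    """Drop subjects deviating more than ``z_threshold`` cohort SDs on ``field``.

    Returns (kept, excluded) where each exclusion carries a human-readable
    reason. A zero cohort SD excludes nothing.
    """
    if not z_threshold > 0:
        raise DomainError(f"z_threshold must be > 0, got {z_threshold!r}")
    values = np.array([subject_parameter(s, field) for s in subjects], dtype=float)
    mean = values.mean()
    sd = values.std(ddof=1) if len(values) > 1 else 0.0
    if sd == 0:
        return list(subjects), []
    kept: List[SubjectRecord] = []
    excluded: List[Tuple[SubjectRecord, str]] = []
    for subject, value in zip(subjects, values):
        z = abs(value - mean) / sd
        if z > z_threshold:
            excluded.append((subject, f"{field}={value:.2f} deviates {z:.2f} SD "
                                      f"from cohort mean {mean:.2f} (threshold {z_threshold})"))
        else:
            kept.append(subject)
    return kept, excluded


def random_split(subjects: Sequence[SubjectRecord], ratio: float, seed: int) -> SplitResult:
    """Seeded uniform-shuffle partition into experimental and validation groups.

    The experimental group gets round(n * ratio) subjects; equal seeds give
    identical assignments. n = 78 at ratio 40/78 reproduces a 40/38 split.
    """
    n = len(subjects)
    if n < 6:
        raise DomainError(f"need at least 6 subjects to split, got {n}")
    if not 0.0 < ratio < 1.0:
        raise DomainError(f"ratio must be in (0, 1), got {ratio!r}")
    n_exp = int(round(n * ratio))
    if n_exp == 0 or n_exp == n:
        raise DomainError(f"ratio {ratio!r} gives a degenerate split at n={n}")
    ids = [str(s.subject_id) for s in subjects]
    perm = np.random.default_rng(seed).permutation(n)
    experimental = tuple(ids[i] for i in sorted(perm[:n_exp]))
    validation = tuple(ids[i] for i in sorted(perm[n_exp:]))
    return SplitResult(experimental_ids=experimental, validation_ids=validation,
                       seed=seed, ratio=ratio)


def check_balance(
    split: SplitResult,
    subjects: Sequence[SubjectRecord],
    parameter_names: Iterable[str],
) -> List[BalanceReport]:
    """Levene (variances) and Welch (means) comparability tests per parameter.

    ``balanced`` means both p-values are >= 0.05.
    """
    by_id = {str(s.subject_id): s for s in subjects}
    groups = []
    for ids in (split.experimental_ids, split.validation_ids):
        if len(ids) < 3:
            raise DomainError(f"group size {len(ids)} < 3; balance tests undefined")
        groups.append([by_id[i] for i in ids])
    reports = []
    for name in parameter_names:
        a = np.array([subject_parameter(s, name) for s in groups[0]], dtype=float)
        b = np.array([subject_parameter(s, name) for s in groups[1]], dtype=float)
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            var_p, mean_p = 1.0, 1.0  # identical constant groups: trivially balanced
        else:
            var_p = float(stats.levene(a, b).pvalue)
            mean_p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        reports.append(BalanceReport(
            parameter_name=name,
            group_means=(float(a.mean()), float(b.mean())),
            group_variances=(float(a.var(ddof=1)), float(b.var(ddof=1))),
            variance_test_p=var_p,
            mean_test_p=mean_p,
            balanced=bool(var_p >= ALPHA and mean_p >= ALPHA),
        ))
    return reports


def pearson(x_values: Sequence[float], y_values: Sequence[float]) -> CorrelationResult:
    """Sample Pearson correlation with a two-sided t-based p-value (n-2 dof)."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError(f"length mismatch: {x.shape} vs {y.shape}")
    n = len(x)
    if n < 3:
        raise DomainError(f"need n >= 3 for a defined p-value, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=n)


def run_validation(
    cohort: Sequence[SubjectRecord],
    calibration_models: Sequence[CalibrationModel],
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> ValidationReport:
    """Correlate model predictions against measurement-derived references.

    For every subject: predicted R^6 (group model), reference R^6 (closed
    form inverted at the measured viscosity), personalized mu' and the
    measured mu. Subjects that are thin-class or whose predicted R^6 is
    nonpositive are excluded from the correlations but kept in the
    per-subject rows with a reason.
    """
    if len(cohort) == 0:
        raise DomainError("empty cohort")
    missing = [s.subject_id for s in cohort if s.measured_viscosity_cp is None]
    if missing:
        raise DomainError(
            f"validation requires measured viscosity for all subjects; "
            f"missing for {missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
    by_group = {m.group: m for m in calibration_models}
    rows: List[SubjectEvaluation] = []
    pred_r6, targ_r6, mu_est, mu_meas = [], [], [], []
    n_excluded = 0
    for rec in cohort:
        derived = derive_all(rec)
        if derived.bmi_class is BMIClass.THIN:
            rows.append(SubjectEvaluation(
                subject_id=str(rec.subject_id), group_indicator=None,
                predicted_r6=None, target_r6=None, mu_estimated_cp=None,
                mu_measured_cp=rec.measured_viscosity_cp,
                valid=False, reason="thin-class: no calibration model"))
            n_excluded += 1
            continue
        group = derived.bmi_class.indicator
        model = by_group.get(group)
        if model is None:
            raise DomainError(f"no calibration model supplied for group {group}")
        r6_hat = predict_r6(model, rec, derived)
        r6_ref = invert_r6(rec.measured_viscosity_cp, derived.bsa_m2,
                           derived.co_ml_min, derived.pp_mmHg, constants)
        result = closed_form_viscosity(r6_hat, derived.pp_mmHg, derived.bsa_m2,
                                       derived.co_ml_min, constants,
                                       provenance="personalized")
        if not result.valid:
            rows.append(SubjectEvaluation(
                subject_id=str(rec.subject_id), group_indicator=group,
                predicted_r6=r6_hat, target_r6=r6_ref, mu_estimated_cp=None,
                mu_measured_cp=rec.measured_viscosity_cp,
                valid=False, reason=f"nonpositive predicted R^6 ({r6_hat:.4g})"))
            n_excluded += 1
            continue
        rows.append(SubjectEvaluation(
            subject_id=str(rec.subject_id), group_indicator=group,
            predicted_r6=r6_hat, target_r6=r6_ref,
            mu_estimated_cp=result.mu_cp, mu_measured_cp=rec.measured_viscosity_cp,
            valid=True))
        pred_r6.append(r6_hat)
        targ_r6.append(r6_ref)
        mu_est.append(result.mu_cp)
        mu_meas.append(rec.measured_viscosity_cp)
    if len(pred_r6) < 3:
        raise HemoviscError(
            f"only {len(pred_r6)} valid subjects; correlations undefined"
        )
    return ValidationReport(
        rows=tuple(rows),
        r_r6=pearson(pred_r6, targ_r6),
        r_mu=pearson(mu_est, mu_meas),
        n_valid=len(pred_r6),
        n_excluded=n_excluded,
    )
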