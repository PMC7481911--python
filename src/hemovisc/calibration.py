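"""BMI-stratified regression calibration of the latent radius R^6.

For overweight subjects (group indicator 1) R^6 is regressed on SV/PP and
heart rate; for normal-BMI subjects (group 0) on SV/PP and weight. The
regression target is R^6 obtained by inverting the closed-form viscosity
equation at each subject's clinically measured viscosity. Fitted models
then yield a personalized viscosity estimate for subjects without a
measurement.

``reference_models`` returns the literature-fixed coefficient sets
(-0.334, 0.196, 0.004 on HR) and (-0.18, 0.151, 0.003 on W).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    DomainError,
    FitError,
    InsufficientDataError,
    RankDeficiencyError,
    UnsupportedClassError,
)
from .hemodynamics import BMIClass, DerivedHemodynamics, SubjectRecord, derive_all
from .viscosity import DEFAULT_CONSTANTS, ModelConstants, ViscosityResult, closed_form_viscosity, invert_r6

__all__ = [
    "CalibrationModel",
    "DesignRow",
    "build_design",
    "fit_group",
    "reference_models",
    "predict_r6",
    "personalized_viscosity",
]

logger = logging.getLogger(__name__)

_SECOND_PREDICTOR = {1: "HR", 0: "W"}


@dataclass(frozen=True)
class CalibrationModel:
    """One BMI group's affine model for R^6.

    predicted R^6 = intercept + coeff_sv_pp * (SV/PP) + coeff_second * X,
    where X is heart rate for group 1 and weight for group 0.
    ``fit_n`` is None for literature-fixed models.
    """

    group: int
    intercept: float
    coeff_sv_pp: float
    coeff_second: float
    second_predictor_name: str
    fit_n: Optional[int] = None
    fit_diagnostics: Optional[Dict[str, object]] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.group not in (0, 1):
            raise DomainError(f"group must be 0 or 1, got {self.group!r}")
        expected = _SECOND_PREDICTOR[self.group]
        if self.second_predictor_name != expected:
            raise DomainError(
                f"group {self.group} uses second predictor {expected}, "
                f"got {self.second_predictor_name!r}"
            )
        if self.fit_n is not None and self.fit_n < 3:
            raise DomainError("fit_n must be >= 3 for fitted models")

    def to_json_dict(self) -> Dict[str, object]:
        d: Dict[str, object] = {
            "group": self.group,
            "intercept": self.intercept,
            "coeff_sv_pp": self.coeff_sv_pp,
            "coeff_second": self.coeff_second,
            "second_predictor": self.second_predictor_name,
        }
        if self.fit_n is not None:
            d["fit_n"] = self.fit_n
        if self.fit_diagnostics is not None:
            d["fit_diagnostics"] = self.fit_diagnostics
        return d

    @classmethod
    def from_json_dict(cls, d: Dict[str, object]) -> "CalibrationModel":
        return cls(
            group=int(d["group"]),
            intercept=float(d["intercept"]),
            coeff_sv_pp=float(d["coeff_sv_pp"]),
            coeff_second=float(d["coeff_second"]),
            second_predictor_name=str(d["second_predictor"]),
            fit_n=int(d["fit_n"]) if "fit_n" in d else None,
            fit_diagnostics=d.get("fit_diagnostics"),  # type: ignore[arg-type]
        )


@dataclass(frozen=True)
class DesignRow:
    """One calibration observation: regressors and the inverted R^6 target."""

    subject_id: str
    sv_over_pp: float
    second_value: float
    target_r6: float

    def __post_init__(self) -> None:
        if not self.sv_over_pp > 0:
            raise DomainError(f"sv_over_pp must be > 0, got {self.sv_over_pp!r}")
        if not np.isfinite(self.target_r6):
            raise DomainError(f"target_r6 must be finite, got {self.target_r6!r}")


def reference_models() -> Tuple[CalibrationModel, CalibrationModel]:
    """The literature-fixed (group 1, group 0) coefficient sets."""
    overweight = CalibrationModel(
        group=1, intercept=-0.334, coeff_sv_pp=0.196, coeff_second=0.004,
        second_predictor_name="HR",
    )
    normal = CalibrationModel(
        group=0, intercept=-0.18, coeff_sv_pp=0.151, coeff_second=0.003,
        second_predictor_name="W",
    )
    return overweight, normal


def build_design(
    subjects: Iterable[SubjectRecord],
    group_indicator: int,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> List[DesignRow]:
    """Assemble the regression design for one BMI group.

    Each subject contributes (SV/PP, HR-or-W, target R^6 from the inverted
    closed form at their measured viscosity). Subjects without a measured
    viscosity are excluded with a logged reason; a thin-class subject is
    an error because no model is defined for that class.
    """
    if group_indicator not in (0, 1):
        raise DomainError(f"group_indicator must be 0 or 1, got {group_indicator!r}")
    rows: List[DesignRow] = []
    for rec in subjects:
        derived = derive_all(rec)
        if derived.bmi_class is BMIClass.THIN:
            raise UnsupportedClassError(
                f"subject {rec.subject_id!r} is thin-class (BMI {derived.bmi:.1f}); "
                "no calibration model is defined"
            )
        if derived.bmi_class.indicator != group_indicator:
            raise DomainError(
                f"subject {rec.subject_id!r} has group indicator "
                f"{derived.bmi_class.indicator}, expected {group_indicator}"
            )
        if rec.measured_viscosity_cp is None:
            logger.warning(
                "subject %r excluded from calibration design: no measured viscosity",
                rec.subject_id,
            )
            continue
        target = invert_r6(
            rec.measured_viscosity_cp, derived.bsa_m2, derived.co_ml_min,
            derived.pp_mmHg, constants,
        )
        second = rec.heart_rate_bpm if group_indicator == 1 else rec.weight_kg
        rows.append(DesignRow(
            subject_id=str(rec.subject_id),
            sv_over_pp=derived.sv_ml / derived.pp_mmHg,
            second_value=second,
            target_r6=target,
        ))
    return rows


def fit_group(design_rows: Sequence[DesignRow], group_indicator: int) -> CalibrationModel:
    """Ordinary least squares on one group's design rows.

    Plain OLS (no regularization, no robust errors). Raises on fewer than
    3 rows or a rank-deficient design; diagnostics carry R^2 and the
    coefficient standard errors.
    """
    n = len(design_rows)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 rows to fit, got {n}")
    x1 = np.array([r.sv_over_pp for r in design_rows], dtype=float)
    x2 = np.array([r.second_value for r in design_rows], dtype=float)
    y = np.array([r.target_r6 for r in design_rows], dtype=float)
    X = np.column_stack([np.ones(n), x1, x2])
    rank = np.linalg.matrix_rank(X)
    if rank < 3:
        bad = []
        if np.ptp(x1) == 0:
            bad.append("sv_over_pp")
        if np.ptp(x2) == 0:
            bad.append(_SECOND_PREDICTOR[group_indicator])
        if not bad:
            bad.append("sv_over_pp/" + _SECOND_PREDICTOR[group_indicator] + " (collinear)")
        raise RankDeficiencyError(
            f"design matrix rank {rank} < 3; degenerate column(s): {', '.join(bad)}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    dof = n - 3
    if dof > 0:
        sigma2 = ss_res / dof
        try:
            cov = sigma2 * np.linalg.inv(X.T @ X)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:  # pragma: no cover - rank already checked
            se = np.full(3, np.nan)
    else:
        se = np.full(3, np.nan)
    diagnostics = {
        "r_squared": r_squared,
        "coef_se": {"intercept": float(se[0]), "sv_over_pp": float(se[1]),
                    _SECOND_PREDICTOR[group_indicator]: float(se[2])},
    }
    return CalibrationModel(
        group=group_indicator,
        intercept=float(beta[0]),
        coeff_sv_pp=float(beta[1]),
        coeff_second=float(beta[2]),
        second_predictor_name=_SECOND_PREDICTOR[group_indicator],
        fit_n=n,
        fit_diagnostics=diagnostics,
    )


def predict_r6(
    model: CalibrationModel,
    subject: SubjectRecord,
    derived: Optional[DerivedHemodynamics] = None,
) -> float:
    """Predict R^6 for a subject whose BMI class matches the model's group.

    The prediction is affine in the regressors and may be nonpositive;
    callers must treat such values as invalid (see closed_form_viscosity).
    The subject's measured viscosity is never consulted.
    """
    derived = derived if derived is not None else derive_all(subject)
    if derived.bmi_class is BMIClass.THIN:
        raise UnsupportedClassError(
            f"subject {subject.subject_id!r} is thin-class; no model defined"
        )
    if derived.bmi_class.indicator != model.group:
        raise DomainError(
            f"subject {subject.subject_id!r} is group "
            f"{derived.bmi_class.indicator}, model is group {model.group}"
        )
    second = subject.heart_rate_bpm if model.group == 1 else subject.weight_kg
    return (model.intercept
            + model.coeff_sv_pp * (derived.sv_ml / derived.pp_mmHg)
            + model.coeff_second * second)


def personalized_viscosity(
    subject: SubjectRecord,
    models: Tuple[CalibrationModel, CalibrationModel],
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> ViscosityResult:
    """Personalized viscosity estimate mu' for one subject.

    Selects the group model by the subject's BMI class, predicts R^6 and
    applies the closed form. Thin-class subjects are unsupported; a
    nonpositive predicted R^6 yields an invalid-flagged result.
    """
    derived = derive_all(subject)
    if derived.bmi_class is BMIClass.THIN:
        raise UnsupportedClassError(
            f"subject {subject.subject_id!r} is thin-class (BMI {derived.bmi:.1f}); "
            "personalized estimation undefined"
        )
    by_group = {m.group: m for m in models}
    try:
        model = by_group[derived.bmi_class.indicator]
    except KeyError as exc:
        raise FitError(
            f"no model supplied for group {derived.bmi_class.indicator}"
        ) from exc
    r6 = predict_r6(model, subject, derived)
    return closed_form_viscosity(
        r6, derived.pp_mmHg, derived.bsa_m2, derived.co_ml_min,
        constants, provenance="personalized",
    )


def models_to_json(models: Iterable[CalibrationModel]) -> str:
    """Serialize models to a deterministic JSON string."""
    return json.dumps([m.to_json_dict() for m in models], indent=2, sort_keys=True)


def models_from_json(text: str) -> Tuple[CalibrationModel, ...]:
    return tuple(CalibrationModel.from_json_dict(d) for d in json.loads(text))
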