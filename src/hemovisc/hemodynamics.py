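"""Per-subject clinical records and derived hemodynamic parameters.

Raw inputs are height (cm), weight (kg), heart rate (beat/min), brachial
systolic/diastolic pressures (mmHg) and left-ventricular end-diastolic /
end-systolic diameters (mm). From these the module derives body surface
area (BSA), body mass index (BMI) and its class, stroke volume (SV),
cardiac output (CO) and pulse pressure (PP).

Unit conventions are deliberate and asymmetric: the BSA formula takes
height in **cm**, while BMI takes height in **m**. Records store cm once;
:func:`compute_bmi` converts internally via :meth:`SubjectRecord.height_m`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .errors import DomainError, ImplausibleInputError, SubjectValidationError, UnsupportedClassError

__all__ = [
    "BMIClass",
    "SubjectRecord",
    "DerivedHemodynamics",
    "compute_bsa",
    "compute_bmi",
    "classify_bmi",
    "compute_sv",
    "compute_co",
    "compute_pp",
    "derive_all",
]

#: Linear BSA formula coefficients: BSA = a*H_cm + b*W_kg + c  [m^2]
BSA_COEFFS = (0.0061, 0.0128, -0.1592)

#: Cubic stroke-volume formula constants (mm-diameter variant, /100 scale).
SV_A = 7.0
SV_B = 2.4
SV_SCALE = 100.0

#: BMI class boundaries (kg/m^2): 25.0 exactly -> overweight, 18.5 exactly -> normal.
BMI_OVERWEIGHT = 25.0
BMI_THIN = 18.5


class BMIClass(enum.Enum):
    """BMI stratum used to select the calibration model.

    Everything at or above 25 kg/m^2 (preobese, obese, severe) collapses
    into ``OVERWEIGHT`` because the calibration only distinguishes the
    binary indicator 1 (overweight) vs 0 (normal). The thin class is
    representable but has no calibrated model downstream.
    """

    THIN = "thin"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"

    @property
    def indicator(self) -> int:
        """Binary group subscript: 1 for overweight, 0 for normal."""
        if self is BMIClass.OVERWEIGHT:
            return 1
        if self is BMIClass.NORMAL:
            return 0
        raise UnsupportedClassError("thin class has no group indicator")


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise DomainError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class SubjectRecord:
    """One person's raw clinical measurements.

    ``measured_viscosity_cp`` is the clinically measured whole-blood
    viscosity at low shear (cp), present only for calibration/validation
    subjects.
    """

    subject_id: str
    height_cm: float
    weight_kg: float
    heart_rate_bpm: float
    sbp_mmHg: float
    dbp_mmHg: float
    lv_edd_mm: float
    lv_esd_mm: float
    measured_viscosity_cp: Optional[float] = None

    def __post_init__(self) -> None:
        try:
            _require_positive("height_cm", self.height_cm)
            _require_positive("weight_kg", self.weight_kg)
            _require_positive("heart_rate_bpm", self.heart_rate_bpm)
            _require_positive("dbp_mmHg", self.dbp_mmHg)
            if not self.sbp_mmHg > self.dbp_mmHg:
                raise DomainError(
                    f"sbp_mmHg ({self.sbp_mmHg!r}) must exceed dbp_mmHg ({self.dbp_mmHg!r})"
                )
            _require_positive("lv_esd_mm", self.lv_esd_mm)
            if not self.lv_edd_mm > self.lv_esd_mm:
                raise DomainError(
                    f"lv_edd_mm ({self.lv_edd_mm!r}) must exceed lv_esd_mm ({self.lv_esd_mm!r})"
                )
            if self.measured_viscosity_cp is not None:
                _require_positive("measured_viscosity_cp", self.measured_viscosity_cp)
        except DomainError as exc:
            raise SubjectValidationError(str(self.subject_id), str(exc)) from exc

    @property
    def height_m(self) -> float:
        return self.height_cm / 100.0


@dataclass(frozen=True)
class DerivedHemodynamics:
    """Derived physiological parameters for one subject."""

    bsa_m2: float
    bmi: float
    bmi_class: BMIClass
    sv_ml: float
    co_ml_min: float
    pp_mmHg: float


def compute_bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m^2) from the linear height/weight formula.

    BSA = 0.0061*H + 0.0128*W - 0.1592 with H in cm, W in kg.
    """
    _require_positive("height_cm", height_cm)
    _require_positive("weight_kg", weight_kg)
    a, b, c = BSA_COEFFS
    bsa = a * height_cm + b * weight_kg + c
    if bsa <= 0:
        raise ImplausibleInputError(
            f"BSA formula gives {bsa!r} m^2 <= 0 for H={height_cm}, W={weight_kg}"
        )
    return bsa


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index W/H^2 (kg/m^2). Height here is in metres."""
    _require_positive("weight_kg", weight_kg)
    _require_positive("height_m", height_m)
    return weight_kg / height_m**2


def classify_bmi(bmi: float) -> BMIClass:
    """Total, monotone step classification: <18.5 thin, [18.5, 25) normal, >=25 overweight."""
    _require_positive("bmi", bmi)
    if bmi < BMI_THIN:
        return BMIClass.THIN
    if bmi < BMI_OVERWEIGHT:
        return BMIClass.NORMAL
    return BMIClass.OVERWEIGHT


def compute_sv(lv_edd_mm: float, lv_esd_mm: float) -> float:
    """Stroke volume (ml/beat) from LV diameters in mm.

    SV = [7*D^3/(2.4+D) - 7*S^3/(2.4+S)] / 100 with D, S in **mm**.
    This mm/scale-100 variant is the calibrated form; it is NOT the
    classical cm-based Teichholz formula, which gives materially smaller
    values for the same anatomy.
    """
    _require_positive("lv_esd_mm", lv_esd_mm)
    if not lv_edd_mm > lv_esd_mm:
        raise DomainError(
            f"lv_edd_mm ({lv_edd_mm!r}) must exceed lv_esd_mm ({lv_esd_mm!r}); "
            "equal or inverted diameters give SV <= 0"
        )
    edv = SV_A * lv_edd_mm**3 / (SV_B + lv_edd_mm)
    esv = SV_A * lv_esd_mm**3 / (SV_B + lv_esd_mm)
    return (edv - esv) / SV_SCALE


def compute_co(sv_ml: float, heart_rate_bpm: float) -> float:
    """Cardiac output (ml/min) = stroke volume * heart rate."""
    _require_positive("sv_ml", sv_ml)
    _require_positive("heart_rate_bpm", heart_rate_bpm)
    return sv_ml * heart_rate_bpm


def compute_pp(sbp_mmHg: float, dbp_mmHg: float) -> float:
    """Brachial pulse pressure (mmHg) = systolic - diastolic."""
    _require_positive("dbp_mmHg", dbp_mmHg)
    if not sbp_mmHg > dbp_mmHg:
        raise DomainError(f"sbp_mmHg ({sbp_mmHg!r}) must exceed dbp_mmHg ({dbp_mmHg!r})")
    return sbp_mmHg - dbp_mmHg


def derive_all(record: SubjectRecord) -> DerivedHemodynamics:
    """Compute every derived parameter for one validated record.

    Deterministic and idempotent; any domain error is re-raised with the
    subject id attached.
    """
    try:
        bsa = compute_bsa(record.height_cm, record.weight_kg)
        bmi = compute_bmi(record.weight_kg, record.height_m)
        sv = compute_sv(record.lv_edd_mm, record.lv_esd_mm)
        co = compute_co(sv, record.heart_rate_bpm)
        pp = compute_pp(record.sbp_mmHg, record.dbp_mmHg)
    except SubjectValidationError:
        raise
    except DomainError as exc:
        raise SubjectValidationError(str(record.subject_id), str(exc)) from exc
    return DerivedHemodynamics(
        bsa_m2=bsa,
        bmi=bmi,
        bmi_class=classify_bmi(bmi),
        sv_ml=sv,
        co_ml_min=co,
        pp_mmHg=pp,
    )
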