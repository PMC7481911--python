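"""Poiseuille capillary-network viscosity model.

The whole microvascular bed is idealized as a single slender tube of
latent radius R and length l carrying steady laminar Newtonian flow at a
fixed low shear rate. Two computation routes to the same viscosity exist:

* the *chain* route: flow intermediates (volumetric flow Q, half-update
  rate ALK, residence time t_m, mean velocity u_m, tube length l) fed
  through the raw Poiseuille law; and
* the *closed form*: mu = k * R^6 * PP / (BSA * CO), where the
  consolidated constant k collapses the whole chain algebraically.

With pi = 3.14 and 1 mmHg = 133.3 Pa the consolidation yields
k = 14903.99, i.e. the conventional rounded constant 14904.

A note on units: R is an empirical model radius, not a measurable vessel
radius. The closed form treats CO in ml/min, BSA in m^2, PP in mmHg and R
in units of 10^-2 m, and reports mu in cp as conventionally printed; the
latent unit inconsistency is absorbed into R because R^6 is fitted
against clinically measured viscosity in cp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional

from .errors import DomainError

__all__ = [
    "ModelConstants",
    "FlowIntermediates",
    "ViscosityResult",
    "derive_constant",
    "poiseuille_viscosity",
    "flow_intermediates",
    "chain_viscosity",
    "closed_form_viscosity",
    "invert_r6",
]

#: ALK coefficient: half-update rate per unit of CO/BSA (ml/min per m^2).
ALK_COEFF = 25.2e-3
#: Seconds per minute, used to convert CO (ml/min) to Q (cm^3/s).
_SEC_PER_MIN = 60.0


def derive_constant(pi_value: float, mmHg_to_pa: float) -> float:
    """Re-derive the consolidated closed-form coefficient k.

    Symbolic consolidation of the chain: substituting Q = CO/60,
    t_m = BSA/(0.0252*CO), l = u_m*t_m and u_m = Q/(pi R^2) into
    mu = pi R^4 dp / (8 Q l), with dp = mmHg_to_pa * PP, gives

        k = pi^2 * mmHg_to_pa * (60 * 60 * 0.0252) / 8

    for CO in ml/min, BSA in m^2, PP in mmHg and R in units of 10^-2 m.
    derive_constant(3.14, 133.3) = 14903.99, rounding to 14904;
    exact constants (math.pi, 133.322) give 14921.6 instead.
    """
    if not (pi_value > 0 and mmHg_to_pa > 0):
        raise DomainError("pi_value and mmHg_to_pa must be > 0")
    return pi_value**2 * mmHg_to_pa * (_SEC_PER_MIN**2 * ALK_COEFF) / 8.0


@dataclass(frozen=True)
class ModelConstants:
    """Every fixed numeric of the model equations.

    Defaults reproduce the conventional consolidated constant 14904
    (pi = 3.14, 1 mmHg = 133.3 Pa). Use :meth:`exact` for true pi and the
    exact pressure conversion, which yields k = 14921.6.
    """

    pi_value: float = 3.14
    mmHg_to_pa: float = 133.3
    alk_coeff: float = ALK_COEFF
    teichholz_a: float = 7.0
    teichholz_b: float = 2.4
    teichholz_scale: float = 100.0
    bsa_coeffs: tuple = (0.0061, 0.0128, -0.1592)
    k_consolidated: float = 14904.0

    def __post_init__(self) -> None:
        for name in ("pi_value", "mmHg_to_pa", "alk_coeff", "teichholz_a",
                     "teichholz_b", "teichholz_scale", "k_consolidated"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0")

    @classmethod
    def exact(cls) -> "ModelConstants":
        """Exact-constants mode: true pi, 133.322 Pa/mmHg, derived k."""
        k = derive_constant(math.pi, 133.322)
        return cls(pi_value=math.pi, mmHg_to_pa=133.322, k_consolidated=k)

    @classmethod
    def from_mapping(cls, overrides: Optional[Mapping] = None) -> "ModelConstants":
        """Build constants from a JSON-style mapping; omitted keys keep defaults."""
        if not overrides:
            return cls()
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(overrides) - known
        if unknown:
            raise DomainError(f"unknown constant overrides: {sorted(unknown)}")
        return replace(cls(), **dict(overrides))

    def derived_k(self) -> float:
        """k re-derived from this instance's pi and pressure conversion."""
        return derive_constant(self.pi_value, self.mmHg_to_pa)


DEFAULT_CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class FlowIntermediates:
    """Flow quantities of the chain route (CGS-flavoured units).

    q_cm3_s = CO/60; alk_per_s = 0.0252*CO/BSA; t_m_s = 1/ALK;
    u_m_cm_s = Q/(pi r^2); l_cm = u_m * t_m.
    """

    q_cm3_s: float
    alk_per_s: float
    t_m_s: float
    u_m_cm_s: float
    l_cm: float
    r_model: float


@dataclass(frozen=True)
class ViscosityResult:
    """A viscosity estimate with its provenance and validity flag.

    ``valid`` is False when the supplied R^6 is nonpositive (e.g. a
    nonphysical calibration prediction); the arithmetic value is still
    recorded for auditability.
    """

    mu_cp: float
    r6: float
    valid: bool
    provenance: str  # "closed-form" | "chain" | "personalized"


def poiseuille_viscosity(radius: float, delta_p: float, flow: float, length: float) -> float:
    """Raw Poiseuille law: mu = pi R^4 dp / (8 Q l).

    All arguments must be in one self-consistent unit system (CGS
    recommended); the result is in that system's viscosity unit. Uses
    machine pi — the 3.14 approximation enters only via the consolidated
    constant route.
    """
    for name, v in (("radius", radius), ("delta_p", delta_p), ("flow", flow), ("length", length)):
        if not v > 0:
            raise DomainError(f"{name} must be > 0, got {v!r}")
    return math.pi * radius**4 * delta_p / (8.0 * flow * length)


def flow_intermediates(
    co_ml_min: float,
    bsa_m2: float,
    r_model: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> FlowIntermediates:
    """Compute the chain-route flow intermediates from CO, BSA and R."""
    for name, v in (("co_ml_min", co_ml_min), ("bsa_m2", bsa_m2), ("r_model", r_model)):
        if not v > 0:
            raise DomainError(f"{name} must be > 0, got {v!r}")
    q = co_ml_min / _SEC_PER_MIN
    alk = constants.alk_coeff * co_ml_min / bsa_m2
    t_m = 1.0 / alk
    u_m = q / (constants.pi_value * r_model**2)
    l = u_m * t_m
    return FlowIntermediates(q_cm3_s=q, alk_per_s=alk, t_m_s=t_m,
                             u_m_cm_s=u_m, l_cm=l, r_model=r_model)


def chain_viscosity(
    r_model: float,
    pp_mmHg: float,
    bsa_m2: float,
    co_ml_min: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> ViscosityResult:
    """Viscosity via the explicit flow chain (the closed form's oracle).

    The tube pressure drop is the brachial pulse pressure converted at
    ``constants.mmHg_to_pa``; the Poiseuille evaluation uses
    ``constants.pi_value`` so the route is algebraically identical to the
    closed form with k = derive_constant(pi_value, mmHg_to_pa).
    """
    if not pp_mmHg > 0:
        raise DomainError(f"pp_mmHg must be > 0, got {pp_mmHg!r}")
    fi = flow_intermediates(co_ml_min, bsa_m2, r_model, constants)
    delta_p = constants.mmHg_to_pa * pp_mmHg
    # Same formula as poiseuille_viscosity but with the constants' pi,
    # so that chain and closed form consolidate to the identical k.
    mu = constants.pi_value * r_model**4 * delta_p / (8.0 * fi.q_cm3_s * fi.l_cm)
    return ViscosityResult(mu_cp=mu, r6=r_model**6, valid=True, provenance="chain")


def closed_form_viscosity(
    r6: float,
    pp_mmHg: float,
    bsa_m2: float,
    co_ml_min: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    provenance: str = "closed-form",
) -> ViscosityResult:
    """Closed form mu = k * R^6 * PP / (BSA * CO), in cp.

    Nonpositive ``r6`` (e.g. from a failed calibration prediction) yields
    an invalid-flagged result rather than an exception so cohort runs can
    complete and report per-subject validity.
    """
    for name, v in (("pp_mmHg", pp_mmHg), ("bsa_m2", bsa_m2), ("co_ml_min", co_ml_min)):
        if not v > 0:
            raise DomainError(f"{name} must be > 0, got {v!r}")
    mu = constants.k_consolidated * r6 * pp_mmHg / (bsa_m2 * co_ml_min)
    return ViscosityResult(mu_cp=mu, r6=r6, valid=r6 > 0, provenance=provenance)


def invert_r6(
    mu_cp: float,
    bsa_m2: float,
    co_ml_min: float,
    pp_mmHg: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Invert the closed form: R^6 = mu * BSA * CO / (k * PP).

    Strictly increasing in mu; exact round trip with
    :func:`closed_form_viscosity`.
    """
    for name, v in (("mu_cp", mu_cp), ("bsa_m2", bsa_m2),
                    ("co_ml_min", co_ml_min), ("pp_mmHg", pp_mmHg)):
        if not v > 0:
            raise DomainError(f"{name} must be > 0, got {v!r}")
    return mu_cp * bsa_m2 * co_ml_min / (constants.k_consolidated * pp_mmHg)
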