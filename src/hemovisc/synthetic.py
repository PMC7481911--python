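"""Seeded synthetic-cohort generator with a planted ground truth.

Draws correlated Gaussian basic measurements (height, weight, heart rate,
SBP/DBP, LV diameters) with configurable moments, rejection-samples rows
that violate physiological invariants, then plants a known linear R^6
relation per BMI group so the calibration and validation stages can be
tested end to end: measured viscosity is computed from the planted R^6
through the closed form, plus optional measurement noise.

Only pairwise correlations for (height, weight), (SBP, DBP) and
(EDD, ESD) are modelled; the defaults (0.5, 0.6, 0.7) are plausible
physiological values, not fitted ones. Marginals are Gaussian because
only means and SDs are specified. Thin-BMI rows (< 18.5) are rejected
along with the physical invariants so every generated subject belongs to
a calibratable group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .calibration import CalibrationModel, reference_models
from .errors import ConfigError, DomainError, GenerationError
from .hemodynamics import (
    BMI_THIN,
    SubjectRecord,
    compute_bmi,
    compute_bsa,
    compute_co,
    compute_pp,
    compute_sv,
)
from .validation import pearson, random_split
from .viscosity import DEFAULT_CONSTANTS, ModelConstants

__all__ = [
    "CohortSpec",
    "GeneratorConfig",
    "PlantedTruth",
    "default_spec",
    "generate",
    "calibrate_noise_for_target_r",
]

_VARIABLES = ("height", "weight", "heart_rate", "sbp", "dbp", "lv_edd", "lv_esd")

#: Reference cohort moments (mean, SD) for each basic measurement.
DEFAULT_MOMENTS: Dict[str, Tuple[float, float]] = {
    "height": (168.80, 5.87),
    "weight": (74.11, 10.84),
    "heart_rate": (72.10, 7.50),
    "sbp": (128.59, 15.04),
    "dbp": (74.16, 10.15),
    "lv_edd": (50.27, 5.73),
    "lv_esd": (34.12, 6.36),
}

DEFAULT_CORRELATIONS: Dict[Tuple[str, str], float] = {
    ("height", "weight"): 0.5,
    ("sbp", "dbp"): 0.6,
    ("lv_edd", "lv_esd"): 0.7,
}


@dataclass(frozen=True)
class CohortSpec:
    """Target moments, correlations and composition for generation."""

    n: int = 79
    moments: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MOMENTS))
    correlations: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CORRELATIONS))
    overweight_fraction: float = 22.0 / 40.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError(f"n must be >= 1, got {self.n}")
        missing = set(_VARIABLES) - set(self.moments)
        if missing:
            raise ConfigError(f"moments missing for {sorted(missing)}")
        for name, (_, sd) in self.moments.items():
            if not sd > 0:
                raise ConfigError(f"SD for {name} must be > 0, got {sd}")
        for pair, rho in self.correlations.items():
            if not -1.0 < rho < 1.0:
                raise ConfigError(f"correlation for {pair} must be in (-1, 1), got {rho}")
        if not 0.0 < self.overweight_fraction < 1.0:
            raise ConfigError("overweight_fraction must be in (0, 1)")


@dataclass(frozen=True)
class GeneratorConfig:
    """Seed, noise levels and planted models for one generation run."""

    seed: int = 0
    r6_noise_sd: float = 0.0
    viscosity_noise_sd: float = 0.0
    planted_models: Optional[Tuple[CalibrationModel, CalibrationModel]] = None

    def __post_init__(self) -> None:
        if self.r6_noise_sd < 0 or self.viscosity_noise_sd < 0:
            raise ConfigError("noise SDs must be >= 0")

    def models(self) -> Tuple[CalibrationModel, CalibrationModel]:
        return self.planted_models if self.planted_models is not None else reference_models()


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of one generated cohort, aligned with the records.

    ``true_r6`` is the planted radius term actually used (including R^6
    noise); ``true_mu_cp`` is the closed-form viscosity from that R^6
    before measurement noise.
    """

    subject_ids: Tuple[str, ...]
    true_r6: Tuple[float, ...]
    true_mu_cp: Tuple[float, ...]
    group_indicator: Tuple[int, ...]


def default_spec() -> CohortSpec:
    """Cohort spec preloaded with the reference moments, n = 79."""
    return CohortSpec()


def _covariance(spec: CohortSpec) -> np.ndarray:
    sds = np.array([spec.moments[v][1] for v in _VARIABLES])
    corr = np.eye(len(_VARIABLES))
    idx = {v: i for i, v in enumerate(_VARIABLES)}
    for (a, b), rho in spec.correlations.items():
        if a not in idx or b not in idx:
            raise ConfigError(f"unknown variable in correlation pair ({a}, {b})")
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    return corr * np.outer(sds, sds)


def generate(
    spec: CohortSpec,
    config: GeneratorConfig,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> Tuple[List[SubjectRecord], PlantedTruth]:
    """Generate a cohort with a planted R^6 / viscosity ground truth.

    Rows are drawn in vectorized batches from the correlated Gaussian and
    rejected (never clamped) when they violate any invariant: positivity,
    SBP > DBP, EDD > ESD, BMI >= 18.5, and positivity of the planted R^6
    and of the noisy measured viscosity. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    means = np.array([spec.moments[v][0] for v in _VARIABLES])
    cov = _covariance(spec)
    model1, model0 = config.models()
    if model1.group != 1 or model0.group != 0:
        raise ConfigError("planted_models must be (group 1, group 0)")

    records: List[SubjectRecord] = []
    truths: List[Tuple[float, float, int]] = []
    n_drawn = 0
    n_accepted = 0
    while len(records) < spec.n:
        batch = max(64, 2 * (spec.n - len(records)))
        draws = rng.multivariate_normal(means, cov, size=batch, method="cholesky")
        eps_r6 = rng.normal(0.0, config.r6_noise_sd, size=batch) if config.r6_noise_sd else np.zeros(batch)
        eps_mu = rng.normal(0.0, config.viscosity_noise_sd, size=batch) if config.viscosity_noise_sd else np.zeros(batch)
        n_drawn += batch
        for row, e_r6, e_mu in zip(draws, eps_r6, eps_mu):
            h, w, hr, sbp, dbp, edd, esd = (float(v) for v in row)
            e_r6, e_mu = float(e_r6), float(e_mu)
            if min(h, w, hr, dbp, esd) <= 0 or sbp <= dbp or edd <= esd:
                continue
            bmi = compute_bmi(w, h / 100.0)
            if bmi < BMI_THIN:
                continue
            sv = compute_sv(edd, esd)
            if sv <= 0:
                continue
            pp = compute_pp(sbp, dbp)
            bsa = compute_bsa(h, w)
            co = compute_co(sv, hr)
            group = 1 if bmi >= 25.0 else 0
            model = model1 if group == 1 else model0
            second = hr if group == 1 else w
            r6 = (model.intercept + model.coeff_sv_pp * (sv / pp)
                  + model.coeff_second * second + e_r6)
            if r6 <= 0:
                continue
            mu_true = constants.k_consolidated * r6 * pp / (bsa * co)
            mu_measured = mu_true + e_mu
            if mu_measured <= 0:
                continue
            sid = f"S{len(records) + 1:04d}"
            records.append(SubjectRecord(
                subject_id=sid, height_cm=h, weight_kg=w, heart_rate_bpm=hr,
                sbp_mmHg=sbp, dbp_mmHg=dbp, lv_edd_mm=edd, lv_esd_mm=esd,
                measured_viscosity_cp=mu_measured))
            truths.append((r6, mu_true, group))
            n_accepted += 1
            if len(records) == spec.n:
                break
        if n_drawn >= 1000 and n_accepted / n_drawn < 0.01:
            raise GenerationError(
                f"rejection rate {1 - n_accepted / n_drawn:.3f} exceeds 0.99; "
                "spec constraints appear infeasible"
            )
    return records, PlantedTruth(
        subject_ids=tuple(r.subject_id for r in records),
        true_r6=tuple(t[0] for t in truths),
        true_mu_cp=tuple(t[1] for t in truths),
        group_indicator=tuple(t[2] for t in truths),
    )


def _mean_validation_r(
    spec: CohortSpec,
    config: GeneratorConfig,
    r6_noise_sd: float,
    n_replicates: int,
    constants: ModelConstants,
) -> float:
    """Mean r(mu', measured mu) on validation splits over seeded replicates."""
    from .calibration import personalized_viscosity  # local import avoids cycle noise

    rs = []
    for rep in range(n_replicates):
        cfg = GeneratorConfig(
            seed=config.seed + 1000 * rep,
            r6_noise_sd=r6_noise_sd,
            viscosity_noise_sd=config.viscosity_noise_sd,
            planted_models=config.planted_models,
        )
        cohort, _ = generate(spec, cfg, constants)
        split = random_split(cohort, ratio=0.5, seed=cfg.seed)
        val_ids = set(split.validation_ids)
        models = cfg.models()
        mu_est, mu_meas = [], []
        for rec in cohort:
            if rec.subject_id not in val_ids:
                continue
            result = personalized_viscosity(rec, models, constants)
            if result.valid:
                mu_est.append(result.mu_cp)
                mu_meas.append(rec.measured_viscosity_cp)
        if len(mu_est) >= 3:
            rs.append(pearson(mu_est, mu_meas).r)
    if not rs:
        raise GenerationError("no replicate produced enough valid subjects")
    return float(np.mean(rs))


def calibrate_noise_for_target_r(
    spec: CohortSpec,
    config: GeneratorConfig,
    target_r: float,
    tol: float = 0.05,
    n_replicates: int = 50,
    min_noise_sd: float = 0.0,
    max_noise_sd: float = 2.0,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Find the R^6 noise SD at which mean r(mu', mu) hits ``target_r``.

    Bisection over the monotone noise -> correlation mapping with fixed
    replicate seeds, searched in [min_noise_sd, max_noise_sd].
    ``target_r`` of 1.0 returns the noiseless limit if the floor allows it.
    Raises with the achieved bracket when the target is unreachable.
    """
    if not 0.0 < target_r <= 1.0:
        raise DomainError(f"target_r must be in (0, 1], got {target_r!r}")
    if not 0.0 <= min_noise_sd < max_noise_sd:
        raise DomainError("need 0 <= min_noise_sd < max_noise_sd")
    if target_r == 1.0 and min_noise_sd == 0.0:
        return 0.0
    lo, hi = min_noise_sd, max_noise_sd
    r_lo = _mean_validation_r(spec, config, lo, n_replicates, constants)
    r_hi = _mean_validation_r(spec, config, hi, n_replicates, constants)
    if not (r_hi <= target_r <= r_lo):
        raise GenerationError(
            f"target r={target_r} unreachable: achieved bracket "
            f"[{r_hi:.3f} at sd={hi}, {r_lo:.3f} at sd={lo}]"
        )
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        r_mid = _mean_validation_r(spec, config, mid, n_replicates, constants)
        if abs(r_mid - target_r) <= tol:
            return mid
        if r_mid > target_r:
            lo = mid
        else:
            hi = mid
    raise GenerationError(
        f"bisection did not converge to r={target_r} within tol={tol}; "
        f"final bracket sd=[{lo}, {hi}]"
    )
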