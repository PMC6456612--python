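"""Paired-eye cohort simulation with known effect sizes.

Each simulated participant is a treated hypertensive adult with demographic,
medication, ambulatory-BP and kidney covariates; each contributes one or two
eyes.  Per-eye flow-void outcomes (area %, mean void size in px, void count)
are generated from a linear model

    y_eye = baseline + sum_f beta_f * x_f + b_subject + e_eye,

with the subject-level random intercept ``b ~ N(0, subject_sd^2)`` shared by
both eyes and eye-level noise ``e ~ N(0, residual_sd^2)``.  The implied
inter-eye Pearson correlation is subject_sd^2 / (subject_sd^2 +
residual_sd^2); the defaults fix it at 0.65 for area and size and 0.49 for
count, the values reported for this measurement protocol.  Age and BP
effects are expressed per 10 units (years / mmHg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .covariates import bmi, classify_bp_control, egfr_ckd_epi, mcr_mg_mmol_to_mg_g

__all__ = [
    "OUTCOMES",
    "OUTCOME_COLUMNS",
    "PER10_FACTORS",
    "CovariateModel",
    "CohortSimConfig",
    "generate_cohort",
    "implied_inter_eye_r",
    "COHORT_DATA_DICTIONARY",
]

OUTCOMES = ("area", "size", "number")

#: Outcome name -> column in the eyes table.
OUTCOME_COLUMNS = {"area": "area_pct", "size": "size_px", "number": "n_voids"}

#: Factors whose regression coefficients are expressed per 10 units.
PER10_FACTORS = frozenset(
    {"age", "sbp_overall", "sbp_day", "sbp_night", "dbp_overall", "dbp_day", "dbp_night"}
)


@dataclass(frozen=True)
class CovariateModel:
    """Distributional parameters of the simulated covariates.

    Defaults reproduce a treated-hypertension cohort: age 56 +/- 11 y, 45 %
    women, 16 % diabetes, daytime systolic BP ~131 +/- 13 mmHg with a
    nocturnal dip, BMI ~26.5 kg/m^2, and log-normal creatinine and urine
    microalbumin/creatinine ratio.
    """

    age_mean: float = 56.0
    age_sd: float = 11.0
    female_frac: float = 0.45
    diabetes_frac: float = 0.16
    hyperlipidemia_frac: float = 0.47
    ckd_frac: float = 0.06
    smoking_fracs: tuple[float, float, float] = (0.92, 0.05, 0.03)  # never/past/current
    beta_blocker_frac: float = 0.36
    ccb_frac: float = 0.54
    acei_arb_frac: float = 0.55
    other_med_frac: float = 0.13
    sbp_day_mean: float = 131.0
    sbp_day_sd: float = 13.0
    sbp_dip_mean: float = 13.0
    sbp_dip_sd: float = 6.0
    dbp_day_mean: float = 80.0
    dbp_day_sd: float = 8.0
    dbp_dip_mean: float = 10.0
    dbp_dip_sd: float = 5.0
    bmi_mean: float = 26.5
    bmi_sd: float = 3.5
    height_mean_m: tuple[float, float] = (1.58, 1.70)  # (female, male)
    height_sd_m: float = 0.07
    creatinine_median_umol_l: tuple[float, float] = (62.0, 85.0)  # (female, male)
    creatinine_log_sd: float = 0.20
    mcr_median_mg_mmol: float = 1.0
    mcr_log_sd: float = 1.2


def _default_effects() -> dict[str, dict[str, float]]:
    # Ground-truth associations embedded by default: the study conditions the
    # statistics stage is asked to recover (per-10-unit scale for age/BP).
    return {
        "sbp_day": {"area": -0.13},
        "age": {"size": 0.21, "number": -21.21},
        "dbp_night": {"number": 13.89},
    }


def _default_subject_sd() -> dict[str, float]:
    # Between-subject SDs chosen with the residual SDs below so the implied
    # inter-eye correlations are 0.65 (area, size) and 0.49 (number).
    return {"area": math.sqrt(0.65), "size": math.sqrt(0.65), "number": 49.0}


def _default_residual_sd() -> dict[str, float]:
    return {"area": math.sqrt(0.35), "size": math.sqrt(0.35), "number": 50.0}


def _default_baselines() -> dict[str, float]:
    return {"area": 16.8, "size": 10.7, "number": 1190.0}


def _per_outcome(x: float | Mapping[str, float], what: str) -> dict[str, float]:
    if isinstance(x, Mapping):
        missing = set(OUTCOMES) - set(x)
        if missing:
            raise ValueError(f"{what} missing outcomes {sorted(missing)}")
        return {o: float(x[o]) for o in OUTCOMES}
    return {o: float(x) for o in OUTCOMES}


@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration of one simulated cohort draw."""

    n_subjects: int = 85
    p_second_eye: float = 0.93
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    #: factor -> outcome -> true coefficient (per-10 scale for age and BP).
    effects: Mapping[str, Mapping[str, float]] = field(default_factory=_default_effects)
    subject_sd: float | Mapping[str, float] = field(default_factory=_default_subject_sd)
    residual_sd: float | Mapping[str, float] = field(default_factory=_default_residual_sd)
    baselines: Mapping[str, float] = field(default_factory=_default_baselines)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError(f"n_subjects must be >= 2, got {self.n_subjects}")
        if not (0.0 <= self.p_second_eye <= 1.0):
            raise ValueError(f"p_second_eye must be in [0, 1], got {self.p_second_eye}")
        sb = _per_outcome(self.subject_sd, "subject_sd")
        se = _per_outcome(self.residual_sd, "residual_sd")
        for o in OUTCOMES:
            if sb[o] < 0:
                raise ValueError(f"subject_sd[{o}] must be >= 0")
            if se[o] <= 0:
                raise ValueError(f"residual_sd[{o}] must be > 0")

    def implied_r(self, outcome: str) -> float:
        """Implied inter-eye Pearson correlation for one outcome."""
        sb = _per_outcome(self.subject_sd, "subject_sd")[outcome]
        se = _per_outcome(self.residual_sd, "residual_sd")[outcome]
        return implied_inter_eye_r(sb, se)


def implied_inter_eye_r(subject_sd: float, residual_sd: float) -> float:
    """Inter-eye correlation implied by the variance components."""
    return subject_sd**2 / (subject_sd**2 + residual_sd**2)


def _factor_value(row: Mapping[str, object], factor: str) -> float:
    """Numeric value a true effect multiplies (per-10 scaling applied)."""
    if factor == "sex":
        return 1.0 if row["sex"] == "female" else 0.0
    val = row[factor]
    if isinstance(val, bool):
        val = float(val)
    val = float(val)
    if factor in PER10_FACTORS:
        val = val / 10.0
    return val


def generate_cohort(
    config: CohortSimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate a long-format cohort table, one row per eye.

    Covariates are drawn independently across subjects (and independently of
    each other, so univariate slopes are unconfounded by construction); both
    eyes of a subject share the covariates and the subject intercept.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    cm = config.covariate_model
    sb = _per_outcome(config.subject_sd, "subject_sd")
    se = _per_outcome(config.residual_sd, "residual_sd")
    rows = []
    for i in range(config.n_subjects):
        sid = f"S{i:04d}"
        sex = "female" if rng.random() < cm.female_frac else "male"
        age = float(np.clip(rng.normal(cm.age_mean, cm.age_sd), 25.0, 95.0))
        smoking = str(rng.choice(["never", "past", "current"], p=cm.smoking_fracs))
        diabetes = bool(rng.random() < cm.diabetes_frac)
        hyperlipidemia = bool(rng.random() < cm.hyperlipidemia_frac)
        ckd = bool(rng.random() < cm.ckd_frac)
        meds = {
            "beta_blocker": bool(rng.random() < cm.beta_blocker_frac),
            "ccb": bool(rng.random() < cm.ccb_frac),
            "acei_arb": bool(rng.random() < cm.acei_arb_frac),
            "other_med": bool(rng.random() < cm.other_med_frac),
        }
        if not any(meds.values()):  # everyone in the cohort is on treatment
            meds["acei_arb"] = True
        n_meds = sum(meds.values())
        n_meds_class = "1" if n_meds == 1 else ("2" if n_meds == 2 else "3+")
        sbp_day = rng.normal(cm.sbp_day_mean, cm.sbp_day_sd)
        sbp_night = sbp_day - rng.normal(cm.sbp_dip_mean, cm.sbp_dip_sd)
        dbp_day = rng.normal(cm.dbp_day_mean, cm.dbp_day_sd)
        dbp_night = dbp_day - rng.normal(cm.dbp_dip_mean, cm.dbp_dip_sd)
        # plain mean over all readings: day readings are sampled 3x as often
        sbp_overall = 0.75 * sbp_day + 0.25 * sbp_night
        dbp_overall = 0.75 * dbp_day + 0.25 * dbp_night
        height = rng.normal(cm.height_mean_m[sex == "male"], cm.height_sd_m)
        body_mass_index = max(rng.normal(cm.bmi_mean, cm.bmi_sd), 15.0)
        weight = body_mass_index * height**2
        crea = float(
            cm.creatinine_median_umol_l[sex == "male"]
            * np.exp(rng.normal(0.0, cm.creatinine_log_sd))
        )
        mcr = float(cm.mcr_median_mg_mmol * np.exp(rng.normal(0.0, cm.mcr_log_sd)))
        subject = {
            "subject_id": sid,
            "age": age,
            "sex": sex,
            "smoking": smoking,
            "diabetes": diabetes,
            "hyperlipidemia": hyperlipidemia,
            "ckd": ckd,
            **meds,
            "n_meds_class": n_meds_class,
            "sbp_day": float(sbp_day),
            "sbp_night": float(sbp_night),
            "sbp_overall": float(sbp_overall),
            "dbp_day": float(dbp_day),
            "dbp_night": float(dbp_night),
            "dbp_overall": float(dbp_overall),
            "bp_control": classify_bp_control(sbp_overall),
            "height_m": float(height),
            "weight_kg": float(weight),
            "bmi": bmi(weight, height),
            "creatinine_umol_l": crea,
            "urine_mcr_mg_mmol": mcr,
            "urine_mcr_mg_g": mcr_mg_mmol_to_mg_g(mcr),
            "egfr": egfr_ckd_epi(crea, age, sex),
        }
        lp = {}
        for o in OUTCOMES:
            lp[o] = float(config.baselines[o])
            for factor, per_outcome in config.effects.items():
                beta = per_outcome.get(o, 0.0)
                if beta:
                    lp[o] += beta * _factor_value(subject, factor)
        intercepts = {o: rng.normal(0.0, sb[o]) for o in OUTCOMES}
        n_eyes = 2 if rng.random() < config.p_second_eye else 1
        for eye in ("OD", "OS")[:n_eyes]:
            row = dict(subject)
            row["eye"] = eye
            for o in OUTCOMES:
                row[OUTCOME_COLUMNS[o]] = lp[o] + intercepts[o] + rng.normal(0.0, se[o])
            rows.append(row)
    return pd.DataFrame(rows)


COHORT_DATA_DICTIONARY = {
    "subject_id": "participant identifier; repeats across the two eye rows",
    "eye": "OD (right) or OS (left)",
    "age": "years",
    "sex": "female/male",
    "smoking": "never/past/current",
    "diabetes": "physician-diagnosed diabetes or glucose-lowering medication",
    "hyperlipidemia": "elevated cholesterol or lipid-lowering medication",
    "ckd": "chronic kidney disease flag",
    "beta_blocker": "on beta blockers",
    "ccb": "on calcium channel blockers",
    "acei_arb": "on ACE inhibitors / angiotensin-II receptor blockers",
    "other_med": "other antihypertensives (diuretics, alpha-2 agonists)",
    "n_meds_class": "number of antihypertensive classes: 1 / 2 / 3+",
    "sbp_day": "mean daytime (06:00-22:00) ambulatory systolic BP, mmHg",
    "sbp_night": "mean nighttime ambulatory systolic BP, mmHg",
    "sbp_overall": "mean of all ambulatory systolic readings, mmHg",
    "dbp_day": "mean daytime ambulatory diastolic BP, mmHg",
    "dbp_night": "mean nighttime ambulatory diastolic BP, mmHg",
    "dbp_overall": "mean of all ambulatory diastolic readings, mmHg",
    "bp_control": "systolic control stratum: intensive (<120) / standard / poor (>=140)",
    "height_m": "metres",
    "weight_kg": "kilograms",
    "bmi": "kg/m^2",
    "creatinine_umol_l": "serum creatinine, umol/L",
    "urine_mcr_mg_mmol": "urine microalbumin/creatinine ratio, mg/mmol",
    "urine_mcr_mg_g": "urine microalbumin/creatinine ratio, mg/g",
    "egfr": "estimated GFR (2009 CKD-EPI creatinine), mL/min/1.73 m^2",
    "area_pct": "flow-void area, % of analyzable scan area",
    "size_px": "mean flow-void component size, pixels",
    "n_voids": "number of flow-void components",
}
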