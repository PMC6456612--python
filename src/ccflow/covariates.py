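"""Derived clinical covariates: ambulatory BP summaries, SPRINT-style BP
control strata, CKD-EPI eGFR, BMI, and unit conversions."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "AbpmSummary",
    "summarize_abpm",
    "classify_bp_control",
    "egfr_ckd_epi",
    "bmi",
    "mcr_mg_mmol_to_mg_g",
    "DAY_WINDOW",
]

#: Daytime ambulatory-BP window, half-open local hours [06:00, 22:00);
#: everything else is night.
DAY_WINDOW = (6, 22)


@dataclass(frozen=True)
class AbpmSummary:
    """Window means of 24-h ambulatory blood pressure, mmHg.

    Missing windows are NaN (the monitor may fail overnight); downstream
    models treat them as missing values rather than errors.
    """

    sbp_overall: float
    dbp_overall: float
    sbp_day: float
    dbp_day: float
    sbp_night: float
    dbp_night: float


def _hour(ts: object) -> float:
    if isinstance(ts, (int, float)):
        return float(ts) % 24.0
    if isinstance(ts, str):
        ts = datetime.fromisoformat(ts)
    if isinstance(ts, datetime):
        return ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    raise TypeError(f"cannot interpret timestamp {ts!r}")


def summarize_abpm(
    readings: Iterable[tuple[object, float, float]]
) -> AbpmSummary:
    """Unweighted window means of (timestamp, systolic, diastolic) readings.

    Day is the half-open window [06:00, 22:00) by local clock time; a reading
    stamped exactly 22:00 is a night reading.  The overall summary is the
    plain mean over all readings (daytime readings, sampled more often,
    therefore weigh more — the convention of 24-h monitor reports).  An empty
    window yields NaN with a warning.
    """
    day_s, day_d, night_s, night_d = [], [], [], []
    for ts, sbp, dbp in readings:
        h = _hour(ts)
        if DAY_WINDOW[0] <= h < DAY_WINDOW[1]:
            day_s.append(sbp)
            day_d.append(dbp)
        else:
            night_s.append(sbp)
            night_d.append(dbp)
    if not day_s:
        warnings.warn("no daytime ambulatory-BP readings; day summary is NaN", stacklevel=2)
    if not night_s:
        warnings.warn("no nighttime ambulatory-BP readings; night summary is NaN", stacklevel=2)
    if not day_s and not night_s:
        warnings.warn("no ambulatory-BP readings at all", stacklevel=2)

    def m(vals: list[float]) -> float:
        return float(np.mean(vals)) if vals else float("nan")

    return AbpmSummary(
        sbp_overall=m(day_s + night_s),
        dbp_overall=m(day_d + night_d),
        sbp_day=m(day_s),
        dbp_day=m(day_d),
        sbp_night=m(night_s),
        dbp_night=m(night_d),
    )


def classify_bp_control(overall_sbp_mean: float) -> str:
    """SPRINT-style systolic control stratum.

    intensive < 120 mmHg <= standard < 140 mmHg <= poor.  Every positive
    input maps to exactly one stratum.
    """
    if not (overall_sbp_mean > 0):
        raise ValueError(f"systolic BP must be positive, got {overall_sbp_mean}")
    if overall_sbp_mean < 120:
        return "intensive"
    if overall_sbp_mean < 140:
        return "standard"
    return "poor"


def egfr_ckd_epi(
    creatinine_umol_l: float,
    age_years: float,
    sex: Literal["female", "male"],
    black: bool = False,
) -> float:
    """Estimated GFR (mL/min/1.73 m^2), 2009 CKD-EPI creatinine equation.

    Sex-stratified published form (the one clinical calculators implement):

        eGFR = base * min(Scr/kappa, 1)^alpha * max(Scr/kappa, 1)^-1.209
             * 0.993^age * 1.159 [black, off by default],

    with Scr in mg/dL (serum creatinine in umol/L divided by 88.4), and
    kappa = 0.7 / alpha = -0.329 / base = 144 (141 * 1.018 female factor,
    as printed) for women, kappa = 0.9 / alpha = -0.411 / base = 141 for
    men.  Continuous in creatinine (the two power branches meet at
    Scr = kappa) and strictly decreasing in creatinine.
    """
    if not (creatinine_umol_l > 0):
        raise ValueError(f"creatinine must be positive, got {creatinine_umol_l}")
    if not (age_years > 0):
        raise ValueError(f"age must be positive, got {age_years}")
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    scr = creatinine_umol_l / 88.4
    if sex == "female":
        kappa, alpha, base = 0.7, -0.329, 144.0
    else:
        kappa, alpha, base = 0.9, -0.411, 141.0
    ratio = scr / kappa
    egfr = (
        base
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** -1.209
        * 0.993**age_years
    )
    if black:
        egfr *= 1.159
    return float(egfr)


def bmi(weight_kg: float, height_m: float) -> float:
    """Body-mass index: weight (kg) / height (m)^2."""
    if not (weight_kg > 0):
        raise ValueError(f"weight must be positive, got {weight_kg}")
    if not (height_m > 0):
        raise ValueError(f"height must be positive, got {height_m}")
    return weight_kg / height_m**2


#: g of creatinine per mmol (molar mass 113.12 g/mol).
_CREATININE_G_PER_MMOL = 0.11312


def mcr_mg_mmol_to_mg_g(mcr_mg_mmol: float) -> float:
    """Urine microalbumin/creatinine ratio: mg/mmol creatinine -> mg/g."""
    return mcr_mg_mmol / _CREATININE_G_PER_MMOL
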