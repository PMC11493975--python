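"""Metabolic-phenotyping calculations.

Implements the glucose-homeostasis statistics used to phenotype diet
groups: the baseline-normalized meal-tolerance-test AUC, the insulin
tolerance test's constant rate of glucose disappearance (Kitt) from a
log-linear regression over 0-60 min, HOMA-IR, the caloric-restriction
ration rule (80% of ad libitum intake with a weekly ramp), and
digested-energy accounting from bomb calorimetry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import linregress

#: Metabolizable energy densities of the diets, kcal/g.
ENERGY_DENSITY_KCAL_PER_G = {"chow": 4.11, "hfd": 5.10}

#: HOMA-IR normalizing constant for glucose in mmol/L and insulin in mU/L.
HOMA_IR_DENOMINATOR = 22.5


@dataclass
class ToleranceCurve:
    """A timed glucose (and optionally insulin) series.

    timepoints in minutes (strictly increasing; the pre-bolus sample is
    negative or zero), glucose in mg/dL, insulin in ng/mL.
    ``baseline_index`` marks the pre-bolus sample.
    """

    timepoints: np.ndarray
    glucose: np.ndarray
    insulin: np.ndarray | None = None
    baseline_index: int = 0
    glucose_units: str = "mg/dL"
    time_units: str = "min"

    def __post_init__(self):
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        if self.timepoints.shape != self.glucose.shape:
            raise ValueError("timepoints and glucose must have equal length")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.glucose_units != "mg/dL":
            raise ValueError(f"glucose must be in mg/dL, got {self.glucose_units!r}")
        if self.time_units != "min":
            raise ValueError(f"time must be in minutes, got {self.time_units!r}")
        if not 0 <= self.baseline_index < self.timepoints.size:
            raise ValueError("baseline_index out of range")


@dataclass(frozen=True)
class FeedingLog:
    """Daily energy intake per cage, with optional fecal energy.

    ``daily_intake_kcal`` is per-animal kcal/day; grams are converted with
    an energy density before construction.
    """

    daily_intake_kcal: np.ndarray
    fecal_kcal_per_day: np.ndarray | None = None

    def __post_init__(self):
        intake = np.asarray(self.daily_intake_kcal, dtype=float)
        if intake.size == 0:
            raise ValueError("feeding log is empty")
        if (intake < 0).any():
            raise ValueError("intake must be >= 0")
        object.__setattr__(self, "daily_intake_kcal", intake)
        if self.fecal_kcal_per_day is not None:
            fecal = np.asarray(self.fecal_kcal_per_day, dtype=float)
            if (fecal < 0).any():
                raise ValueError("fecal energy must be >= 0")
            object.__setattr__(self, "fecal_kcal_per_day", fecal)


def mtt_auc(curve: ToleranceCurve) -> float:
    """Baseline-normalized meal-tolerance-test AUC (mg/dL x min).

    The pre-bolus glucose value is subtracted from every post-bolus point
    and the trapezoidal integral is taken over post-bolus timepoints only.
    Negative excursions are retained (net signed area), so the result is
    invariant to shifting the whole curve by a constant.
    """
    post = curve.timepoints > curve.timepoints[curve.baseline_index]
    if post.sum() < 2:
        raise ValueError("need at least 2 post-bolus points")
    baseline = curve.glucose[curve.baseline_index]
    return float(
        np.trapezoid(curve.glucose[post] - baseline, curve.timepoints[post])
    )


def kitt(curve: ToleranceCurve, window: tuple[float, float] = (0.0, 60.0)):
    """Constant rate of glucose disappearance, %/min.

    OLS slope of ln(glucose) against time over points within ``window``
    (default 0-60 min after the insulin bolus); Kitt = -slope x 100, so
    falling glucose gives a positive rate.  Returns ``(kitt, stderr)``
    with the regression standard error also on the %/min scale.
    """
    lo, hi = window
    sel = (curve.timepoints >= lo) & (curve.timepoints <= hi)
    if sel.sum() < 3:
        raise ValueError(f"need >= 3 points within [{lo}, {hi}] min")
    g = curve.glucose[sel]
    if (g <= 0).any():
        raise ValueError("glucose must be > 0 for the log transform")
    fit = linregress(curve.timepoints[sel], np.log(g))
    return -fit.slope * 100.0, fit.stderr * 100.0


def homa_ir(fasting_glucose_mmol_l: float, fasting_insulin_mu_l: float) -> float:
    """HOMA-IR = (fasting glucose [mmol/L] x fasting insulin [mU/L]) / 22.5."""
    if fasting_glucose_mmol_l <= 0 or fasting_insulin_mu_l <= 0:
        raise ValueError("fasting glucose and insulin must be > 0")
    return fasting_glucose_mmol_l * fasting_insulin_mu_l / HOMA_IR_DENOMINATOR


def cr_ration(
    al_log: FeedingLog, restriction: float = 0.20, ramp_weeks: int = 0
) -> np.ndarray:
    """Weekly caloric-restriction ration schedule (kcal/day).

    Steady state is (1 - restriction) x the mean ad libitum intake.  During
    the ramp the restriction steps from 0.10 toward the target by 0.10 per
    week, avoiding an abrupt drop in intake.  Returns one ration value per
    week for ``ramp_weeks`` weeks followed by the steady-state value.
    """
    if not 0.0 <= restriction < 1.0:
        raise ValueError("restriction must be in [0, 1)")
    al_mean = float(np.mean(al_log.daily_intake_kcal))
    if ramp_weeks <= 0:
        return np.array([(1.0 - restriction) * al_mean])
    fractions = []
    r = 0.10
    for _ in range(ramp_weeks):
        r = min(r, restriction)
        fractions.append(1.0 - r)
        r += 0.10
    fractions.append(1.0 - restriction)
    return al_mean * np.asarray(fractions)


def digested_energy(intake_kcal_per_day: float, fecal_kcal_per_day: float) -> float:
    """Energy available from digested food: intake minus fecal energy (kcal/day)."""
    if intake_kcal_per_day < 0 or fecal_kcal_per_day < 0:
        raise ValueError("energies must be >= 0")
    if fecal_kcal_per_day > intake_kcal_per_day:
        raise ValueError(
            "fecal energy exceeds intake: inconsistent calorimetry input"
        )
    return intake_kcal_per_day - fecal_kcal_per_day
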