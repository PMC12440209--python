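"""Pre-meal insulin dosing: standard bolus, sigmoid refinement, trend- and
prediction-gated final dose, IOB accounting, and the paired closed-loop
in-silico evaluation harness.

The standard meal bolus is

    MIB = CHO / CR + (CGM_meal - CGM_target) / CF .

When the dual-prediction system flags an upcoming excursion, the bolus is
refined multiplicatively,

    B_mod = MIB * (1 + adjustment_factor),

where the adjustment factor combines two logistic terms in pre-meal glucose
and in the correction factor. Taken verbatim (``sigmoid_mode="literal"``)
both logistics saturate for physiologic arguments and the factor pins near
+1, doubling every flagged dose; the default ``"normalized"`` mode therefore
centers and scales both arguments so the factor is zero at reference inputs
(glucose at target, CF at the population reference), increases when glucose
runs above target, and lies strictly inside (-1, 1):

    af = sigmoid((CGM_meal - CGM_target)/s_g) + sigmoid((CF - CF_ref)/s_cf) - 1 .

The final dose follows the prediction/trend gate: hypoglycemia prediction
takes precedence over hyperglycemia; with a falling 60-minute CGM trend the
dose becomes ``alpha * B_mod - IOB`` (resp. ``gamma * B_mod - IOB``),
otherwise ``B_mod``; with no predicted event the untouched MIB is delivered.
Negative results clamp to zero. IOB uses a linear decay over the duration of
insulin action, counting only boluses delivered strictly before the meal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core_io import BolusEvent, GlucoseTrace, TherapyParams
from .errors import TrendError
from .features import features_from_pre
from .cohort import (
    MealContext, SimScenario, VirtualPatient,
    draw_patient, patient_seed, realize_scenario, simulate_patient,
    standard_policy,
)
from .report import GlycemicReport, postprandial_report, tir_report, wilcoxon_paired
from .core_io import PatientRecord, segment_meal_windows

logger = logging.getLogger(__name__)


@dataclass
class BolusConfig:
    """Tunables of the adjustment algorithm (defaults = study settings)."""

    alpha: float = 1.02          # uplift under predicted hypo + falling CGM
    gamma: float = 1.01          # uplift under predicted hyper + falling CGM
    sigmoid_mode: str = "normalized"   # or "literal"
    s_g: float = 50.0            # mg/dL scale of the glucose logistic
    s_cf: float = 45.0           # CF logistic scale ~ population CF spread
    cf_ref: float = 105.0        # population-median correction factor
    trend_window_min: int = 60
    dia_hours: float = 4.0
    clamp_nonnegative: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 1.0 or self.gamma < 1.0:
            raise ValueError("alpha and gamma must be >= 1")
        if self.s_g <= 0 or self.s_cf <= 0:
            raise ValueError("normalization scales must be positive")
        if self.sigmoid_mode not in ("normalized", "literal"):
            raise ValueError("sigmoid_mode must be 'normalized' or 'literal'")


class Branch(str, Enum):
    NO_EVENT = "no_event"
    HYPO_DOWN = "hypo_trend_down"
    HYPO_UP = "hypo_trend_up"
    HYPER_DOWN = "hyper_trend_down"
    HYPER_UP = "hyper_trend_up"
    FALLBACK = "fallback_standard"


@dataclass
class BolusRecommendation:
    """Full provenance of one dosing decision."""

    mib: float
    adjustment_factor: float
    b_mod: float
    trend_slope: float
    iob: float
    s1_vote: int
    s2_vote: int
    b_final: float
    branch: Branch


def standard_bolus(cho: float, therapy: TherapyParams, cgm_meal: float) -> float:
    """Standard bolus-calculator dose (may be negative before clamping)."""
    return cho / therapy.cr + (cgm_meal - therapy.cgm_target) / therapy.cf


def sigmoid(x: float | np.ndarray):
    """Overflow-safe logistic 1 / (1 + exp(-x))."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return float(out) if out.ndim == 0 else out


def adjustment_factor(
    cgm_meal: float, therapy: TherapyParams, config: BolusConfig | None = None
) -> float:
    """Sigmoid dose-scaling factor (see module docstring for both modes)."""
    config = config or BolusConfig()
    if config.sigmoid_mode == "literal":
        return float(sigmoid(cgm_meal) + sigmoid(therapy.cf) - 1.0)
    return float(
        sigmoid((cgm_meal - therapy.cgm_target) / config.s_g)
        + sigmoid((therapy.cf - config.cf_ref) / config.s_cf)
        - 1.0
    )


def modified_bolus(mib: float, af: float) -> float:
    """B_mod = MIB * (1 + adjustment_factor)."""
    return mib * (1.0 + af)


def cgm_trend(pre: GlucoseTrace, window_min: int = 60) -> float:
    """OLS slope (mg/dL per minute) over the last ``window_min`` of a trace."""
    n_slots = window_min // pre.step_min
    vals = pre.values[-n_slots:]
    miss = pre.missing[-n_slots:]
    t = np.arange(len(vals)) * pre.step_min
    t, vals = t[~miss], vals[~miss]
    if len(vals) < 2:
        raise TrendError("CGM trend needs at least 2 samples in the window")
    slope = np.polyfit(t, vals, 1)[0]
    return float(slope)


def insulin_on_board(
    boluses: Sequence[BolusEvent], t: pd.Timestamp, dia_hours: float = 4.0
) -> float:
    """Linearly decaying IOB of boluses delivered strictly before ``t``."""
    if dia_hours <= 0:
        raise ValueError("dia_hours must be positive")
    t = pd.Timestamp(t)
    dia_min = dia_hours * 60.0
    iob = 0.0
    for b in boluses:
        dt_min = (t - b.time).total_seconds() / 60.0
        if dt_min > 0:
            iob += b.units * max(0.0, 1.0 - dt_min / dia_min)
        elif dt_min == 0:
            iob += b.units  # a bolus delivered exactly now is still on board
    return iob


def final_bolus(
    b_mod: float,
    mib: float,
    s1_vote: int,
    s2_vote: int,
    slope: float,
    iob: float,
    config: BolusConfig | None = None,
) -> BolusRecommendation:
    """Prediction/trend-gated final dose (hypo prediction takes precedence)."""
    config = config or BolusConfig()
    if s1_vote:
        if slope < 0:
            b_final, branch = config.alpha * b_mod - iob, Branch.HYPO_DOWN
        else:
            b_final, branch = b_mod, Branch.HYPO_UP
    elif s2_vote:
        if slope < 0:
            b_final, branch = config.gamma * b_mod - iob, Branch.HYPER_DOWN
        else:
            b_final, branch = b_mod, Branch.HYPER_UP
    else:
        b_final, branch = mib, Branch.NO_EVENT
    if config.clamp_nonnegative:
        b_final = max(0.0, b_final)
    return BolusRecommendation(
        mib=mib, adjustment_factor=(b_mod / mib - 1.0) if mib else 0.0,
        b_mod=b_mod, trend_slope=slope, iob=iob,
        s1_vote=int(s1_vote), s2_vote=int(s2_vote),
        b_final=float(b_final), branch=branch,
    )


def recommend(
    pre: GlucoseTrace,
    meal_time: pd.Timestamp,
    cho_announced: float,
    therapy: TherapyParams,
    predictor: Callable[[np.ndarray], tuple[int, int]],
    prior_boluses: Sequence[BolusEvent] = (),
    config: BolusConfig | None = None,
) -> BolusRecommendation:
    """End-to-end single-meal recommendation from a 72-sample pre-trace.

    ``predictor`` maps the 13-entry feature array to the (S1, S2) binary
    votes of the dual-prediction system.
    """
    config = config or BolusConfig()
    meal_time = pd.Timestamp(meal_time)
    cgm_meal = float(pre.values[-1])
    mib = standard_bolus(cho_announced, therapy, cgm_meal)
    fv = features_from_pre(pre, meal_hour=meal_time.hour, cho=cho_announced, mib=mib)
    s1_vote, s2_vote = predictor(fv.to_array())
    if not s1_vote and not s2_vote:
        rec = final_bolus(mib, mib, 0, 0, 0.0, 0.0, config)
        return rec
    af = adjustment_factor(cgm_meal, therapy, config)
    b_mod = modified_bolus(mib, af)
    slope = cgm_trend(pre, config.trend_window_min)
    iob = insulin_on_board(prior_boluses, meal_time, config.dia_hours)
    return final_bolus(b_mod, mib, s1_vote, s2_vote, slope, iob, config)


# ---------------------------------------------------------------------------
# closed-loop evaluation
# ---------------------------------------------------------------------------

def make_adjusted_policy(
    predictor: Callable[[np.ndarray], tuple[int, int]],
    config: BolusConfig | None = None,
    min_coverage: float = 0.9,
) -> Callable[[MealContext], float]:
    """Dosing policy that runs the full adjustment pipeline at each meal.

    Falls back to the plain standard bolus whenever the retrospective CGM
    window is too short or too sparse to featurize (e.g., the first meals
    of a simulation).
    """
    config = config or BolusConfig()

    def policy(ctx: MealContext) -> float:
        hist = ctx.cgm_history
        if len(hist) < 72:
            return standard_policy(ctx)
        pre = hist.slice(len(hist) - 72, len(hist))
        if pre.coverage() < min_coverage or pre.missing[-1] or pre.missing[-13]:
            return standard_policy(ctx)
        try:
            rec = recommend(
                pre, ctx.time, ctx.cho_announced, ctx.therapy,
                predictor, prior_boluses=ctx.bolus_history, config=config,
            )
        except Exception:  # noqa: BLE001 - dosing must never crash the plant
            logger.exception("adjusted policy failed; delivering standard bolus")
            return standard_policy(ctx)
        return rec.b_final

    return policy


@dataclass
class ClosedLoopResult:
    """Paired before/after glycemic outcomes of a cohort run."""

    before_overall: list[GlycemicReport]
    after_overall: list[GlycemicReport]
    before_post: list[GlycemicReport]
    after_post: list[GlycemicReport]
    patient_ids: list[str]

    def paired_metric(self, metric: str, mode: str = "post") -> tuple[np.ndarray, np.ndarray]:
        """Per-patient paired values of one report field."""
        b = self.before_post if mode == "post" else self.before_overall
        a = self.after_post if mode == "post" else self.after_overall
        return (np.array([getattr(r, metric) for r in b]),
                np.array([getattr(r, metric) for r in a]))

    def summary_table(self) -> pd.DataFrame:
        """Median [IQR] before/after plus Wilcoxon p per metric."""
        rows = []
        metric_modes = (
            [(m, "overall") for m in
             ("median_bg", "mean_bg", "sd_bg", "cv_pct",
              "pct_below_54", "pct_54_70", "pct_70_180",
              "pct_above_180", "pct_above_250")]
            + [(m, "post") for m in
               ("min_bg", "max_bg", "mean_bg", "median_bg", "initial_bg",
                "excursion", "time_to_peak_min",
                "pct_below_54", "pct_54_70", "pct_70_180",
                "pct_above_180", "pct_above_250")]
        )
        for metric, mode in metric_modes:
            b, a = self.paired_metric(metric, mode)
            try:
                _, p = wilcoxon_paired(b, a)
            except Exception:  # fewer than 5 patients
                p = float("nan")
            rows.append({
                "window": mode, "metric": metric,
                "before_median": float(np.median(b)),
                "before_q1": float(np.percentile(b, 25)),
                "before_q3": float(np.percentile(b, 75)),
                "after_median": float(np.median(a)),
                "after_q1": float(np.percentile(a, 25)),
                "after_q3": float(np.percentile(a, 75)),
                "wilcoxon_p": p,
            })
        return pd.DataFrame(rows)


def _patient_reports(record: PatientRecord) -> tuple[GlycemicReport, GlycemicReport]:
    overall = tir_report(record.trace)
    post = postprandial_report(segment_meal_windows(record))
    return overall, post


def closed_loop_evaluate(
    scenario: SimScenario,
    predictor: Callable[[np.ndarray], tuple[int, int]],
    config: BolusConfig | None = None,
    seed: int = 0,
    patients: list[VirtualPatient] | None = None,
) -> ClosedLoopResult:
    """Paired cohort simulation: standard dosing vs. the adjustment pipeline.

    Both arms replay identical per-patient realizations (meal times, carb
    draws, misestimations, sensor noise); only the dosing policy differs.
    """
    config = config or BolusConfig()
    result = ClosedLoopResult([], [], [], [], [])
    adjusted = make_adjusted_policy(predictor, config)
    for i in range(scenario.n_patients):
        p_seed = patient_seed(seed, i)
        patient = (patients[i] if patients is not None
                   else draw_patient(f"cl{i + 1:03d}", np.random.default_rng(p_seed)))
        real = realize_scenario(scenario, p_seed + 1)
        before = simulate_patient(patient, scenario, seed=0,
                                  policy=standard_policy, realization=real)
        after = simulate_patient(patient, scenario, seed=0,
                                 policy=adjusted, realization=real)
        bo, bp = _patient_reports(before)
        ao, ap = _patient_reports(after)
        result.before_overall.append(bo)
        result.after_overall.append(ao)
        result.before_post.append(bp)
        result.after_post.append(ap)
        result.patient_ids.append(patient.patient_id)
    return result


__all__ = [
    "BolusConfig", "BolusRecommendation", "Branch", "ClosedLoopResult",
    "standard_bolus", "sigmoid", "adjustment_factor", "modified_bolus",
    "cgm_trend", "insulin_on_board", "final_bolus", "recommend",
    "make_adjusted_policy", "closed_loop_evaluate",
]
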