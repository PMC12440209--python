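"""Per-meal feature extraction and postprandial event labeling.

Thirteen time-domain features are computed from the 6-hour retrospective CGM
window, the meal announcement and the meal bolus:

* CGM at meal onset (the reading at slot m0);
* six hourly CGM means over the hours preceding the meal, most recent first;
* LBGI and HBGI risk indices over the full 6-hour window (Kovatchev risk
  transform, mg/dL parameterization);
* 60-minute glucose excursion, BG(m0) - BG(m0 - 60 min);
* announced carbohydrates (g), meal hour of day (0-23), and meal insulin
  bolus (U).

Outcome labels cover the 4-hour postprandial horizon. Hypoglycemia = glucose
<= 70 mg/dL sustained for at least 15 minutes (three consecutive 5-minute
samples). Hyperglycemia uses a two-phase rule: >= 250 mg/dL sustained within
the first two hours, or >= 180 mg/dL sustained within the following two
hours; the sample at exactly 120 min opens the second phase. The same
15-minute sustain rule applies to both phases so that the two event
definitions stay symmetric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import GlucoseTrace, MealWindow, PatientRecord, segment_meal_windows
from .errors import FeatureError

logger = logging.getLogger(__name__)

FEATURE_NAMES = [
    "cgm_at_meal",
    "cgm_mean_0_1h", "cgm_mean_1_2h", "cgm_mean_2_3h",
    "cgm_mean_3_4h", "cgm_mean_4_5h", "cgm_mean_5_6h",
    "lbgi_6h", "hbgi_6h",
    "excursion_60min",
    "cho_g", "meal_hour", "bolus_u",
]
N_FEATURES = len(FEATURE_NAMES)

# Kovatchev symmetrization constants for BG in mg/dL
_RISK_A, _RISK_B, _RISK_C = 1.509, 1.084, 5.381

HYPO_THRESHOLD = 70.0
HYPER_EARLY_THRESHOLD = 250.0
HYPER_LATE_THRESHOLD = 180.0
SUSTAIN_SAMPLES = 3           # 15 min at 5-min cadence
PHASE_SPLIT_MIN = 120         # the 120-min sample opens the late phase


@dataclass
class FeatureVector:
    """The 13-entry per-meal feature vector (see module docstring)."""

    cgm_at_meal: float
    hourly_means: tuple[float, ...]   # 6 entries, most recent first
    lbgi_6h: float
    hbgi_6h: float
    excursion_60: float
    cho: float
    meal_hour: int
    mib: float

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.cgm_at_meal, *self.hourly_means, self.lbgi_6h, self.hbgi_6h,
             self.excursion_60, self.cho, float(self.meal_hour), self.mib]
        )


@dataclass
class MealInstance:
    """One meal with its features, outcome labels and (optional) cluster ids."""

    patient_id: str
    features: FeatureVector
    label_hypo: int
    label_hyper: int
    cluster_id_s1: int | None = None
    cluster_id_s2: int | None = None
    meal_time: object = None


def risk_space(bg: np.ndarray) -> np.ndarray:
    """Kovatchev symmetrized glucose scale f(BG) (zero at ~112.5 mg/dL)."""
    bg = np.asarray(bg, dtype=float)
    if np.any(bg <= 0):
        raise FeatureError("risk transform requires positive glucose")
    return _RISK_A * (np.log(bg) ** _RISK_B - _RISK_C)


def risk_indices(pre: GlucoseTrace) -> tuple[float, float]:
    """(LBGI, HBGI) over the non-missing samples of a retrospective window."""
    bg = pre.valid_values()
    if bg.size == 0:
        raise FeatureError("risk indices undefined on an all-missing window")
    f = risk_space(bg)
    rl = np.where(f < 0, 10.0 * f * f, 0.0)
    rh = np.where(f > 0, 10.0 * f * f, 0.0)
    return float(rl.mean()), float(rh.mean())


def features_from_pre(
    pre: GlucoseTrace, meal_hour: int, cho: float, mib: float
) -> FeatureVector:
    """Feature vector from a 72-sample retrospective trace ending at m0.

    Used both for training-set extraction and at dosing time, when the
    postprandial window does not exist yet.
    """
    n = len(pre)
    if n != 72:
        raise FeatureError("retrospective window must have 72 samples")
    if pre.missing[-1]:
        raise FeatureError("CGM reading at meal onset is missing")
    cgm_at_meal = float(pre.values[-1])

    hourly = []
    for j in range(6):
        block_vals = pre.values[n - 12 * (j + 1): n - 12 * j]
        block_miss = pre.missing[n - 12 * (j + 1): n - 12 * j]
        good = block_vals[~block_miss]
        if good.size == 0:
            raise FeatureError(f"hourly block {j} fully missing")
        hourly.append(float(good.mean()))

    if pre.missing[-13]:
        raise FeatureError("CGM reading 60 min before meal is missing")
    excursion = cgm_at_meal - float(pre.values[-13])

    lbgi, hbgi = risk_indices(pre)
    return FeatureVector(
        cgm_at_meal=cgm_at_meal,
        hourly_means=tuple(hourly),
        lbgi_6h=lbgi,
        hbgi_6h=hbgi,
        excursion_60=excursion,
        cho=float(cho),
        meal_hour=int(meal_hour),
        mib=float(mib),
    )


def extract_features(window: MealWindow) -> FeatureVector:
    """Compute the 13-feature vector for one meal window."""
    return features_from_pre(
        window.pre,
        meal_hour=int(window.meal.time.hour),
        cho=float(window.meal.cho_announced),
        mib=float(window.bolus_units),
    )


def _sustained(mask: np.ndarray, run: int = SUSTAIN_SAMPLES) -> bool:
    """True if ``mask`` contains ``run`` consecutive True values."""
    count = 0
    for m in mask:
        count = count + 1 if m else 0
        if count >= run:
            return True
    return False


def label_hypo(post: GlucoseTrace) -> int:
    """1 iff glucose <= 70 mg/dL sustained >= 15 min anywhere in the 4 h."""
    hit = (~post.missing) & (post.values <= HYPO_THRESHOLD)
    return int(_sustained(hit))


def label_hyper(post: GlucoseTrace) -> int:
    """Two-phase postprandial hyperglycemia label (>=250 early / >=180 late)."""
    # post sample i sits at (i+1)*step minutes after meal onset
    minutes = (np.arange(len(post)) + 1) * post.step_min
    early = minutes < PHASE_SPLIT_MIN
    valid = ~post.missing
    hit_early = valid & early & (post.values >= HYPER_EARLY_THRESHOLD)
    hit_late = valid & ~early & (post.values >= HYPER_LATE_THRESHOLD)
    return int(_sustained(hit_early[early]) or _sustained(hit_late[~early]))


def build_dataset(records: list[PatientRecord]) -> list[MealInstance]:
    """Segment, featurize and label every valid meal window of a cohort."""
    instances: list[MealInstance] = []
    n_dropped = 0
    for rec in records:
        for window in segment_meal_windows(rec):
            try:
                fv = extract_features(window)
            except FeatureError as exc:
                logger.info("patient %s: window at %s dropped (%s)",
                            rec.patient_id, window.meal.time, exc)
                n_dropped += 1
                continue
            instances.append(
                MealInstance(
                    patient_id=rec.patient_id,
                    features=fv,
                    label_hypo=label_hypo(window.post),
                    label_hyper=label_hyper(window.post),
                    meal_time=window.meal.time,
                )
            )
    if instances:
        hypo = sum(i.label_hypo for i in instances) / len(instances)
        hyper = sum(i.label_hyper for i in instances) / len(instances)
        logger.info(
            "dataset: %d instances (%d dropped), hypo prevalence %.3f, hyper %.3f",
            len(instances), n_dropped, hypo, hyper,
        )
    return instances


def dataset_to_arrays(instances: list[MealInstance]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack a dataset into (X [n,13], y_hypo, y_hyper) arrays."""
    X = np.vstack([i.features.to_array() for i in instances])
    y1 = np.array([i.label_hypo for i in instances], dtype=int)
    y2 = np.array([i.label_hyper for i in instances], dtype=int)
    return X, y1, y2


__all__ = [
    "FEATURE_NAMES", "N_FEATURES", "FeatureVector", "MealInstance",
    "risk_space", "risk_indices", "extract_features",
    "label_hypo", "label_hyper", "build_dataset", "dataset_to_arrays",
]
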