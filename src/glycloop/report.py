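"""Evaluation metrics: classification, glycemic time-in-range, postprandial
summaries and the paired Wilcoxon signed-rank test.

Band conventions for the time-in-range report: "below 54" is strict (<54),
"54-70" is closed on both sides, "70-180" is (70, 180], "above 180" and
"above 250" are strict and deliberately overlap (the >180 fraction contains
the >250 fraction, as these figures are conventionally printed). The five
disjoint bands <54, [54,70], (70,180], (180,250], >250 partition exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .core_io import GlucoseTrace, MealWindow
from .errors import MetricError


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class ClassMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float      # percent
    sensitivity: float   # percent
    specificity: float   # percent
    mcc: float
    auc: float | None = None


def mcc_score(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def confusion_metrics(y: np.ndarray, yhat: np.ndarray) -> ClassMetrics:
    """Confusion-matrix metrics for binary labels/predictions."""
    y = np.asarray(y, dtype=int)
    yhat = np.asarray(yhat, dtype=int)
    if y.shape != yhat.shape:
        raise MetricError("labels and predictions differ in length")
    if y.size == 0:
        raise MetricError("empty evaluation set")
    tp = int(np.sum((y == 1) & (yhat == 1)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return ClassMetrics(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=100.0 * (tp + tn) / y.size,
        sensitivity=sens, specificity=spec,
        mcc=mcc_score(tp, tn, fp, fn),
    )


def roc_auc(scores: np.ndarray, y: np.ndarray) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray], float]:
    """ROC curve and AUC.

    The AUC is computed as the normalized Mann-Whitney U statistic with
    rank-averaged ties, which equals the trapezoidal area under the ROC
    curve swept over all score thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos, n_neg = int(np.sum(y == 1)), int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise MetricError("ROC requires both classes present")
    ranks = stats.rankdata(scores)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(y, scores)
    return (fpr, tpr, thr), float(auc)


def _threshold_candidates(scores: np.ndarray) -> np.ndarray:
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate(([u[0] - 1.0], mids, [u[-1] + 1.0]))


def youden_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the midpoints between consecutive distinct scores (plus
    sentinels outside the score range), so on perfectly separated scores the
    midpoint of the separating gap is returned.
    """
    return _scan_threshold(scores, y, _youden_of)


def mcc_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """Threshold on the score grid maximizing the MCC."""
    return _scan_threshold(scores, y, _mcc_of)


def _youden_of(y: np.ndarray, yhat: np.ndarray) -> float:
    tp = np.sum((y == 1) & (yhat == 1))
    tn = np.sum((y == 0) & (yhat == 0))
    fp = np.sum((y == 0) & (yhat == 1))
    fn = np.sum((y == 1) & (yhat == 0))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return float(sens + spec - 1.0)


def _mcc_of(y: np.ndarray, yhat: np.ndarray) -> float:
    tp = int(np.sum((y == 1) & (yhat == 1)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    return mcc_score(tp, tn, fp, fn)


def _scan_threshold(scores, y, objective) -> float:
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    if scores.size == 0:
        raise MetricError("cannot pick a threshold on an empty score set")
    best_thr, best_obj = None, -np.inf
    for thr in _threshold_candidates(scores):
        obj = objective(y, (scores >= thr).astype(int))
        if obj > best_obj + 1e-12:
            best_obj, best_thr = obj, float(thr)
    return best_thr


# ---------------------------------------------------------------------------
# glycemic reports
# ---------------------------------------------------------------------------

@dataclass
class GlycemicReport:
    """Time-in-range fractions (percent) and summary glucose statistics."""

    pct_below_54: float
    pct_54_70: float
    pct_70_180: float
    pct_180_250: float
    pct_above_180: float   # includes >250
    pct_above_250: float
    mean_bg: float
    median_bg: float
    sd_bg: float
    cv_pct: float
    # postprandial-mode extras
    min_bg: float | None = None
    max_bg: float | None = None
    initial_bg: float | None = None
    excursion: float | None = None
    time_to_peak_min: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def tir_report(trace: GlucoseTrace | np.ndarray) -> GlycemicReport:
    """Time-in-range and variability statistics over non-missing samples."""
    if isinstance(trace, GlucoseTrace):
        bg = trace.valid_values()
    else:
        bg = np.asarray(trace, dtype=float)
        bg = bg[np.isfinite(bg)]
    if bg.size == 0:
        raise MetricError("time-in-range report on an all-missing trace")
    n = bg.size
    pct = lambda mask: 100.0 * np.sum(mask) / n  # noqa: E731
    mean = float(bg.mean())
    sd = float(bg.std(ddof=1)) if n > 1 else 0.0
    return GlycemicReport(
        pct_below_54=pct(bg < 54),
        pct_54_70=pct((bg >= 54) & (bg <= 70)),
        pct_70_180=pct((bg > 70) & (bg <= 180)),
        pct_180_250=pct((bg > 180) & (bg <= 250)),
        pct_above_180=pct(bg > 180),
        pct_above_250=pct(bg > 250),
        mean_bg=mean,
        median_bg=float(np.median(bg)),
        sd_bg=sd,
        cv_pct=100.0 * sd / mean if mean else float("nan"),
    )


def postprandial_report(windows: list[MealWindow]) -> GlycemicReport:
    """Patient-level postprandial report.

    Per meal: initial BG is the reading at meal onset; min/max/mean/median
    are taken over the 4-hour window; time-to-peak is the minutes from onset
    to the first postprandial maximum; excursion is mean postprandial BG
    minus initial BG. These continuous summaries are aggregated as the
    median across meals. The time-in-band percentages (and sd/cv) instead
    pool every in-window sample of the patient: the fraction of postprandial
    exposure in each band, not the median of mostly-zero per-meal fractions.
    """
    if not windows:
        raise MetricError("postprandial report requires at least one window")
    per_meal: list[dict] = []
    pooled: list[np.ndarray] = []
    for w in windows:
        bg = w.post.valid_values()
        if bg.size == 0 or w.pre.missing[-1]:
            continue
        initial = float(w.pre.values[-1])
        vals = w.post.values.copy()
        vals[w.post.missing] = -np.inf
        peak_idx = int(np.argmax(vals))  # first occurrence of the max
        pooled.append(bg)
        per_meal.append({
            "min_bg": float(bg.min()), "max_bg": float(bg.max()),
            "mean_bg": float(bg.mean()), "median_bg": float(np.median(bg)),
            "initial_bg": initial,
            "excursion": float(bg.mean()) - initial,
            "time_to_peak_min": (peak_idx + 1) * w.post.step_min,
        })
    if not per_meal:
        raise MetricError("no meal window had usable postprandial data")
    med = {k: float(np.median([m[k] for m in per_meal])) for k in per_meal[0]}
    bands = tir_report(np.concatenate(pooled))
    return GlycemicReport(
        pct_below_54=bands.pct_below_54, pct_54_70=bands.pct_54_70,
        pct_70_180=bands.pct_70_180, pct_180_250=bands.pct_180_250,
        pct_above_180=bands.pct_above_180, pct_above_250=bands.pct_above_250,
        mean_bg=med["mean_bg"], median_bg=med["median_bg"],
        sd_bg=bands.sd_bg, cv_pct=bands.cv_pct,
        min_bg=med["min_bg"], max_bg=med["max_bg"],
        initial_bg=med["initial_bg"], excursion=med["excursion"],
        time_to_peak_min=med["time_to_peak_min"],
    )


def cohort_summary(values: np.ndarray) -> tuple[float, float, float]:
    """Median and IQR bounds across patients: (median, q1, q3)."""
    v = np.asarray(values, dtype=float)
    return float(np.median(v)), float(np.percentile(v, 25)), float(np.percentile(v, 75))


# ---------------------------------------------------------------------------
# paired Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def wilcoxon_paired(before: np.ndarray, after: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped; tied |differences| get averaged ranks.
    The null distribution is enumerated exactly (dynamic program over the
    doubled integer ranks) for up to 25 nonzero pairs, and approximated
    normally (with tie correction and continuity correction) above that.
    Returns (W, p) with W = min(W+, W-). All-zero differences give p = 1.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise MetricError("paired samples differ in length")
    if before.size < 5:
        raise MetricError("Wilcoxon test requires at least 5 pairs")
    d = after - before
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    if n <= 25:
        p = _exact_signed_rank_p(ranks, w_pos)
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w_pos - mu - 0.5 * np.sign(w_pos - mu)) / sigma if sigma > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
    return w, float(min(p, 1.0))


def _exact_signed_rank_p(ranks: np.ndarray, w_pos: float) -> float:
    """Exact two-sided p for W+ under the sign-flip null.

    Works on doubled ranks so tie-averaged half-integer ranks become
    integers; the distribution of the doubled W+ is built by convolution.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2.0 * w_pos))
    mu2 = total / 2.0
    if w2 <= mu2:
        p = 2.0 * counts[: w2 + 1].sum()
    else:
        p = 2.0 * counts[w2:].sum()
    return float(min(p, 1.0))


__all__ = [
    "ClassMetrics", "GlycemicReport", "confusion_metrics", "mcc_score",
    "roc_auc", "youden_threshold", "mcc_threshold", "tir_report",
    "postprandial_report", "cohort_summary", "wilcoxon_paired",
]
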