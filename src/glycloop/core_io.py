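"""Patient-log data model, CSV readers/writers and meal-window segmentation.

The on-disk dialect is a long-format CSV with columns
``patient_id,timestamp,cgm_mg_dl,cho_g,bolus_u`` (empty cells meaning "no
event on this row") plus an optional JSON sidecar ``<stem>.therapy.json``
holding the therapy parameters of each patient. Timestamps are ISO-8601,
timezone-naive local time; the hour-of-day feature downstream is taken from
this local clock.

CGM traces are represented on a uniform grid (default 5-minute cadence).
Raw readings are snapped to the nearest grid slot; gaps of at most 15 minutes
are linearly interpolated, longer gaps stay missing. Glucose readings outside
the physiologically plausible (20, 600) mg/dL band are flagged missing rather
than kept.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import LoadError

logger = logging.getLogger(__name__)

#: default CGM cadence in minutes
DEFAULT_STEP_MIN = 5
#: plausible sensor range; values outside are treated as artifacts
GLUCOSE_MIN, GLUCOSE_MAX = 20.0, 600.0
#: maximum gap (minutes) bridged by linear interpolation
MAX_FILL_GAP_MIN = 15
#: retrospective / postprandial window lengths in samples at 5-min cadence
PRE_SAMPLES = 72   # 6 h
POST_SAMPLES = 48  # 4 h
#: boluses within this many minutes of a meal are attributed to it
BOLUS_MATCH_MIN = 15

CSV_COLUMNS = ["patient_id", "timestamp", "cgm_mg_dl", "cho_g", "bolus_u"]


@dataclass
class GlucoseTrace:
    """A uniformly gridded CGM series in mg/dL."""

    start_time: pd.Timestamp
    values: np.ndarray
    missing: np.ndarray
    step_min: int = DEFAULT_STEP_MIN

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.step_min <= 0:
            raise ValueError("step_min must be positive")
        if self.values.shape != self.missing.shape:
            raise ValueError("values and missing mask must have equal length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_time, periods=len(self.values), freq=f"{self.step_min}min"
        )

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + pd.Timedelta(minutes=self.step_min * (len(self) - 1))

    def valid_values(self) -> np.ndarray:
        return self.values[~self.missing]

    def coverage(self) -> float:
        """Fraction of non-missing samples."""
        return float(np.mean(~self.missing)) if len(self) else 0.0

    def index_of(self, t: pd.Timestamp) -> int:
        """Grid slot nearest to ``t`` (may fall outside the trace)."""
        delta = (pd.Timestamp(t) - self.start_time).total_seconds() / 60.0
        return int(round(delta / self.step_min))

    def slice(self, start: int, stop: int) -> "GlucoseTrace":
        """Sub-trace over slots [start, stop); bounds must be inside the trace."""
        if start < 0 or stop > len(self):
            raise IndexError(f"slice [{start}, {stop}) outside trace of {len(self)}")
        return GlucoseTrace(
            start_time=self.start_time + pd.Timedelta(minutes=start * self.step_min),
            values=self.values[start:stop].copy(),
            missing=self.missing[start:stop].copy(),
            step_min=self.step_min,
        )

    def validate_range(self) -> "GlucoseTrace":
        """Flag out-of-range glucose values as missing (returns self)."""
        bad = (~self.missing) & (
            (self.values <= GLUCOSE_MIN) | (self.values >= GLUCOSE_MAX)
        )
        if bad.any():
            logger.warning(
                "%d glucose sample(s) outside (%g, %g) mg/dL flagged missing",
                int(bad.sum()), GLUCOSE_MIN, GLUCOSE_MAX,
            )
            self.missing = self.missing | bad
            self.values = np.where(bad, np.nan, self.values)
        return self


@dataclass
class MealEvent:
    time: pd.Timestamp
    cho_announced: float
    #: ground-truth grams; equals announced for real logs
    cho_actual: float | None = None

    def __post_init__(self) -> None:
        self.time = pd.Timestamp(self.time)
        if self.cho_announced < 0:
            raise ValueError("cho_announced must be non-negative")
        if self.cho_actual is None:
            self.cho_actual = self.cho_announced


@dataclass
class BolusEvent:
    time: pd.Timestamp
    units: float

    def __post_init__(self) -> None:
        self.time = pd.Timestamp(self.time)
        if self.units < 0:
            raise ValueError("bolus units must be non-negative")


@dataclass
class TherapyParams:
    """Open-loop therapy settings used by the bolus calculator.

    cr : carbohydrate-to-insulin ratio, g/U
    cf : correction factor, mg/dL per U
    cgm_target : correction target, mg/dL
    dia_hours : duration of insulin action, h (IOB decay horizon)
    """

    cr: float
    cf: float
    cgm_target: float = 150.0
    dia_hours: float = 4.0

    def __post_init__(self) -> None:
        if self.cr <= 0 or self.cf <= 0:
            raise ValueError("cr and cf must be positive")
        if not 80.0 <= self.cgm_target <= 200.0:
            raise ValueError("cgm_target must lie in [80, 200] mg/dL")


@dataclass
class PatientRecord:
    patient_id: str
    trace: GlucoseTrace
    meals: list[MealEvent] = field(default_factory=list)
    boluses: list[BolusEvent] = field(default_factory=list)
    therapy: TherapyParams = field(default_factory=lambda: TherapyParams(cr=10.0, cf=40.0))

    def __post_init__(self) -> None:
        self.meals = sorted(self.meals, key=lambda m: m.time)
        self.boluses = sorted(self.boluses, key=lambda b: b.time)


@dataclass
class MealWindow:
    """A meal with its 6-hour retrospective and 4-hour postprandial traces.

    ``pre`` holds exactly 72 samples ending at the meal-onset slot m0 (so
    ``pre.values[-1]`` is the CGM-at-meal reading); ``post`` holds the 48
    samples strictly after m0.
    """

    meal: MealEvent
    pre: GlucoseTrace
    post: GlucoseTrace
    bolus_units: float
    patient_id: str = ""

    def __post_init__(self) -> None:
        if len(self.pre) != PRE_SAMPLES:
            raise ValueError(f"pre window must have {PRE_SAMPLES} samples")
        if len(self.post) != POST_SAMPLES:
            raise ValueError(f"post window must have {POST_SAMPLES} samples")


# ---------------------------------------------------------------------------
# grid alignment
# ---------------------------------------------------------------------------

def align_to_grid(
    raw: Sequence[tuple[pd.Timestamp, float]] | pd.DataFrame,
    step_min: int = DEFAULT_STEP_MIN,
    max_fill_gap_min: int = MAX_FILL_GAP_MIN,
) -> GlucoseTrace:
    """Snap raw (timestamp, glucose) readings onto a uniform grid.

    The grid is anchored at midnight of the first reading's day so that grid
    slots coincide with wall-clock multiples of ``step_min``. Duplicate hits
    on one slot keep the last reading (warned). Interior gaps spanning at most
    ``max_fill_gap_min`` minutes are linearly interpolated; longer gaps remain
    missing.
    """
    if isinstance(raw, pd.DataFrame):
        pairs = list(zip(pd.to_datetime(raw.iloc[:, 0]), raw.iloc[:, 1].astype(float)))
    else:
        pairs = [(pd.Timestamp(t), float(v)) for t, v in raw]
    if not pairs:
        raise LoadError("cannot align an empty reading list")
    times = [t for t, _ in pairs]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise LoadError("timestamps must be strictly increasing")

    anchor = times[0].normalize()
    slots = [int(round((t - anchor).total_seconds() / 60.0 / step_min)) for t in times]
    first, last = slots[0], slots[-1]
    n = last - first + 1
    values = np.full(n, np.nan)
    missing = np.ones(n, dtype=bool)
    seen: set[int] = set()
    for slot, (_, v) in zip(slots, pairs):
        idx = slot - first
        if slot in seen:
            logger.warning("duplicate reading for grid slot %d; keeping last", slot)
        seen.add(slot)
        values[idx] = v
        missing[idx] = False

    _fill_short_gaps(values, missing, step_min, max_fill_gap_min)
    start = anchor + pd.Timedelta(minutes=first * step_min)
    return GlucoseTrace(start_time=start, values=values, missing=missing, step_min=step_min)


def _fill_short_gaps(
    values: np.ndarray, missing: np.ndarray, step_min: int, max_fill_gap_min: int
) -> None:
    """Linearly interpolate interior missing runs of <= max gap, in place."""
    max_run = max_fill_gap_min // step_min - 1  # missing slots bridgeable
    n = len(values)
    i = 0
    while i < n:
        if missing[i]:
            j = i
            while j < n and missing[j]:
                j += 1
            run = j - i
            if 0 < i and j < n and run <= max_run:
                left, right = values[i - 1], values[j]
                for k in range(run):
                    frac = (k + 1) / (run + 1)
                    values[i + k] = left + frac * (right - left)
                    missing[i + k] = False
            i = j
        else:
            i += 1


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def load_patient_records(
    path: str | Path, schema: dict[str, str] | None = None
) -> list[PatientRecord]:
    """Load one CSV file or every ``*.csv`` under a directory.

    ``schema`` optionally maps the canonical column names
    (``patient_id, timestamp, cgm_mg_dl, cho_g, bolus_u``) to the file's own
    column names.
    """
    path = Path(path)
    files = sorted(path.glob("*.csv")) if path.is_dir() else [path]
    if not files:
        raise LoadError(f"no CSV files found under {path}")
    records: list[PatientRecord] = []
    for f in files:
        records.extend(_load_one_csv(f, schema))
    return records


def _load_one_csv(path: Path, schema: dict[str, str] | None) -> list[PatientRecord]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise LoadError(f"{path}: {exc}") from exc
    if df.empty:
        raise LoadError(f"{path}: file contains no rows")
    colmap = {k: k for k in CSV_COLUMNS}
    if schema:
        colmap.update(schema)
    for canonical, actual in colmap.items():
        if actual not in df.columns:
            raise LoadError(f"{path}: missing column {actual!r} (for {canonical})")
    try:
        df["_ts"] = pd.to_datetime(df[colmap["timestamp"]], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise LoadError(f"{path}: unparseable timestamp ({exc})") from exc

    sidecar = _load_sidecar(path)
    records = []
    for pid, g in df.groupby(colmap["patient_id"], sort=True):
        pid = str(pid)
        g = g.sort_values("_ts")
        cgm = g[g[colmap["cgm_mg_dl"]].notna()]
        if cgm.empty:
            raise LoadError(f"{path}: patient {pid} has no CGM rows")
        trace = align_to_grid(
            list(zip(cgm["_ts"], cgm[colmap["cgm_mg_dl"]].astype(float)))
        ).validate_range()
        actual_map = sidecar.get(pid, {}).get("cho_actual", {})
        meals = []
        for ts, cho in zip(g["_ts"], g[colmap["cho_g"]]):
            if pd.notna(cho):
                meals.append(
                    MealEvent(
                        time=ts,
                        cho_announced=float(cho),
                        cho_actual=actual_map.get(ts.isoformat()),
                    )
                )
        boluses = [
            BolusEvent(time=ts, units=float(u))
            for ts, u in zip(g["_ts"], g[colmap["bolus_u"]])
            if pd.notna(u)
        ]
        therapy = sidecar.get(pid, {}).get("therapy", TherapyParams(cr=10.0, cf=40.0))
        records.append(
            PatientRecord(
                patient_id=pid, trace=trace, meals=meals, boluses=boluses, therapy=therapy
            )
        )
    return records


def _load_sidecar(csv_path: Path) -> dict[str, dict]:
    sidecar = csv_path.with_suffix(".therapy.json")
    if not sidecar.exists():
        return {}
    data = json.loads(sidecar.read_text())
    out: dict[str, dict] = {}
    for pid, p in data.items():
        out[pid] = {
            "therapy": TherapyParams(
                cr=p["cr"], cf=p["cf"],
                cgm_target=p.get("cgm_target", 150.0),
                dia_hours=p.get("dia_hours", 4.0),
            ),
            "cho_actual": p.get("cho_actual", {}),
        }
    return out


def save_patient_records(records: Iterable[PatientRecord], path: str | Path) -> Path:
    """Write records to one long-format CSV plus a therapy sidecar."""
    path = Path(path)
    rows = []
    therapy = {}
    for rec in records:
        tr = rec.trace
        for t, v, miss in zip(tr.times, tr.values, tr.missing):
            if not miss:
                rows.append((rec.patient_id, t.isoformat(), repr(float(v)), "", ""))
        for m in rec.meals:
            rows.append((rec.patient_id, m.time.isoformat(), "", repr(float(m.cho_announced)), ""))
        for b in rec.boluses:
            rows.append((rec.patient_id, b.time.isoformat(), "", "", repr(float(b.units))))
        therapy[rec.patient_id] = {
            "cr": rec.therapy.cr, "cf": rec.therapy.cf,
            "cgm_target": rec.therapy.cgm_target, "dia_hours": rec.therapy.dia_hours,
            "cho_actual": {
                m.time.isoformat(): m.cho_actual
                for m in rec.meals
                if m.cho_actual != m.cho_announced
            },
        }
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False)
    path.with_suffix(".therapy.json").write_text(json.dumps(therapy, indent=1))
    return path


# ---------------------------------------------------------------------------
# meal-window segmentation
# ---------------------------------------------------------------------------

def segment_meal_windows(
    record: PatientRecord,
    min_coverage: float = 0.9,
    bolus_match_min: int = BOLUS_MATCH_MIN,
) -> list[MealWindow]:
    """Cut one (pre, post) window pair per meal; drop under-covered windows.

    A window is kept only if both the 72-sample retrospective trace and the
    48-sample postprandial trace have at least ``min_coverage`` non-missing
    samples. Boluses within ±``bolus_match_min`` minutes of meal onset are
    summed into ``bolus_units``. Drops are logged, never raised.
    """
    tr = record.trace
    windows: list[MealWindow] = []
    for meal in record.meals:
        m0 = tr.index_of(meal.time)
        lo, hi = m0 - (PRE_SAMPLES - 1), m0 + POST_SAMPLES + 1
        if lo < 0 or hi > len(tr):
            logger.info(
                "patient %s: meal at %s dropped (window outside trace)",
                record.patient_id, meal.time,
            )
            continue
        pre = tr.slice(lo, m0 + 1)
        post = tr.slice(m0 + 1, hi)
        if pre.coverage() < min_coverage or post.coverage() < min_coverage:
            logger.info(
                "patient %s: meal at %s dropped (coverage pre=%.2f post=%.2f)",
                record.patient_id, meal.time, pre.coverage(), post.coverage(),
            )
            continue
        tol = pd.Timedelta(minutes=bolus_match_min)
        units = sum(
            b.units for b in record.boluses if abs(b.time - meal.time) <= tol
        )
        windows.append(
            MealWindow(meal=meal, pre=pre, post=post, bolus_units=float(units),
                       patient_id=record.patient_id)
        )
    return windows


__all__ = [
    "GlucoseTrace", "MealEvent", "BolusEvent", "TherapyParams", "PatientRecord",
    "MealWindow", "align_to_grid", "load_patient_records", "save_patient_records",
    "segment_meal_windows", "DEFAULT_STEP_MIN", "PRE_SAMPLES", "POST_SAMPLES",
]
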