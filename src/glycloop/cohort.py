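"""Virtual type-1-diabetes cohort generator and closed-loop plant.

The plant is a deliberately minimal six-state glucose-insulin model
(Bergman-style remote insulin action, two-compartment gut absorption,
two-compartment subcutaneous insulin kinetics) with a sinusoidal circadian
multiplier on insulin sensitivity and on the meal-absorption rate:

    dG/dt  = -p1 (G - G_b) - m(t) X G + f k_m(t) Q2 / V
    dX/dt  = -p2 X + p2 S_I I2 / tau_i
    dQ1/dt = carb_in - k_m(t) Q1          (gut, mg)
    dQ2/dt = k_m(t) (Q1 - Q2)
    dI1/dt = insulin_in - I1 / tau_i      (subcutaneous depot, U)
    dI2/dt = (I1 - I2) / tau_i

with m(t) = 1 + a_c sin(2 pi (h(t) - phi_c) / 24) and k_m(t) = m(t)/tau_m.
Fasting with no insulin on board is a steady state at G = G_b (basal insulin
is implicit in this construction). Total meal glucose appearance integrates
to f * cho * 1000 / V mg/dL regardless of the circadian modulation, because
the appearance flux equals the outflow of the second gut compartment.

The default scenario matches the study conditions: 10 adults, 120 days,
three meals per day, meal-time jitter of +-20 minutes, meal content varied
by +-20%, carbohydrate misestimation ~ Normal(0, 0.2) truncated at +-0.4,
5-minute CGM sampling with additive Gaussian sensor noise. Open-loop meals
are dosed with the standard bolus formula on the announced carbohydrates.

Integration is fixed-step RK4 at a 1-minute internal step; meal and bolus
inputs enter as state impulses at whole-minute event times.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from ._compat import njit
from .core_io import (
    BolusEvent, GlucoseTrace, MealEvent, PatientRecord, TherapyParams,
)
from .errors import SimulationError

logger = logging.getLogger(__name__)

SENSOR_MIN, SENSOR_MAX = 20.0, 600.0


@dataclass
class VirtualPatient:
    """Parameter set of one virtual adult with T1D."""

    patient_id: str
    g_b: float        # basal glucose, mg/dL
    s_i: float        # insulin sensitivity, 1/U (integrated remote action per unit)
    p1: float         # glucose effectiveness, 1/min
    p2: float         # remote insulin action decay, 1/min
    f: float          # carbohydrate bioavailability, dimensionless
    tau_m: float      # meal absorption time constant, min
    tau_i: float      # subcutaneous insulin time constant, min
    v: float          # glucose distribution volume, dL
    a_c: float        # circadian amplitude, fraction
    phi_c: float      # circadian phase, hours
    therapy: TherapyParams

    def __post_init__(self) -> None:
        for name in ("s_i", "p1", "p2", "f", "tau_m", "tau_i", "v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.a_c <= 0.5:
            raise ValueError("a_c must lie in [0, 0.5]")


@dataclass
class SimScenario:
    """Study conditions for the in-silico cohort."""

    n_patients: int = 10
    n_days: int = 120
    meal_times_h: tuple[float, ...] = (8.0, 13.0, 19.0)
    meal_carbs_g: tuple[float, ...] = (50.0, 70.0, 60.0)
    meal_jitter_min: float = 20.0        # uniform +- jitter
    meal_content_var: float = 0.2        # uniform +-20% of nominal grams
    carb_misest_sd: float = 0.2          # announced = actual*(1+eps)
    carb_misest_max: float = 0.4         # truncation of eps
    sensor_noise_sd: float = 5.0         # mg/dL
    step_min: int = 5                    # CGM cadence
    seed: int = 0

    @property
    def meals_per_day(self) -> int:
        return len(self.meal_times_h)


#: per-patient parameter ranges (low, high, log-uniform?) used by
#: generate_cohort; tuned once so that the open-loop cohort statistics
#: bracket the reference simulated-cohort summary (see docs/methods.md).
PARAM_RANGES: dict[str, tuple[float, float, bool]] = {
    "g_b": (120.0, 152.0, False),
    "s_i": (0.35, 0.9, True),
    "p1": (0.002, 0.0035, True),
    "p2": (0.012, 0.02, True),
    "f": (0.85, 0.95, False),
    "tau_m": (65.0, 95.0, True),
    "tau_i": (80.0, 110.0, True),
    "v": (95.0, 130.0, False),
    "a_c": (0.2, 0.4, False),
    "phi_c": (0.0, 24.0, False),
}

#: calibration constants linking therapy parameters to the plant (chosen with
#: the parameter ranges above; see docs/methods.md)
CR_GLUCOSE_REF = 120.0     # mg/dL operating point for the CR derivation
CR_AGGRESSIVENESS = 1.12   # >1 = larger boluses (smaller CR)
CF_HORIZON_MIN = 240.0     # horizon over which 1 U is amortized for CF


def draw_patient(pid: str, rng: np.random.Generator) -> VirtualPatient:
    """One seeded draw from the documented parameter ranges."""
    params = {}
    for name, (lo, hi, log) in PARAM_RANGES.items():
        u = rng.uniform()
        params[name] = math.exp(math.log(lo) + u * (math.log(hi) - math.log(lo))) if log \
            else lo + u * (hi - lo)
    # Therapy derived from the plant: CR balances the integrated glucose
    # appearance of a meal against the integrated insulin action of its
    # bolus; CF amortizes one unit's action over the insulin-action horizon.
    cr = params["v"] * CR_GLUCOSE_REF * params["s_i"] / (params["f"] * 1000.0)
    cr /= CR_AGGRESSIVENESS
    cf = CR_GLUCOSE_REF * params["s_i"] / (params["p1"] * CF_HORIZON_MIN)
    therapy = TherapyParams(cr=cr, cf=cf, cgm_target=150.0, dia_hours=4.0)
    return VirtualPatient(patient_id=pid, therapy=therapy, **params)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

@dataclass
class SimState:
    """Plant state: glucose, remote insulin action, gut and insulin chains."""

    g: float   # mg/dL
    x: float   # 1/min
    q1: float  # mg
    q2: float  # mg
    i1: float  # U
    i2: float  # U

    def to_array(self) -> np.ndarray:
        return np.array([self.g, self.x, self.q1, self.q2, self.i1, self.i2])

    @classmethod
    def fasting(cls, patient: VirtualPatient) -> "SimState":
        return cls(g=patient.g_b, x=0.0, q1=0.0, q2=0.0, i1=0.0, i2=0.0)


def derivatives(
    state: SimState,
    patient: VirtualPatient,
    t_min: float,
    carb_in: float = 0.0,      # g/min
    insulin_in: float = 0.0,   # U/min
) -> SimState:
    """Instantaneous state rates; raises on non-finite state."""
    y = state.to_array()
    if not np.all(np.isfinite(y)):
        raise SimulationError(f"non-finite state at t={t_min:.1f} min")
    rates = _rates(
        y, t_min, carb_in * 1000.0, insulin_in,
        patient.g_b, patient.s_i, patient.p1, patient.p2, patient.f,
        patient.tau_m, patient.tau_i, patient.v, patient.a_c, patient.phi_c,
    )
    return SimState(*rates)


@njit
def _rates(y, t_min, carb_mg_per_min, insulin_in,
           gb, si, p1, p2, f, tau_m, tau_i, v, ac, phic):
    g, x, q1, q2, i1, i2 = y[0], y[1], y[2], y[3], y[4], y[5]
    h = (t_min / 60.0) % 24.0
    m = 1.0 + ac * math.sin(2.0 * math.pi * (h - phic) / 24.0)
    km = m / tau_m
    dg = -p1 * (g - gb) - m * x * g + f * km * q2 / v
    dx = -p2 * x + p2 * si * i2 / tau_i
    dq1 = carb_mg_per_min - km * q1
    dq2 = km * (q1 - q2)
    di1 = insulin_in - i1 / tau_i
    di2 = (i1 - i2) / tau_i
    return np.array([dg, dx, dq1, dq2, di1, di2])


@njit
def _integrate(y, t0, n_min, substeps,
               gb, si, p1, p2, f, tau_m, tau_i, v, ac, phic):
    """RK4 from t0 over n_min minutes; returns (y_end, G at each minute end)."""
    g_out = np.empty(n_min)
    dt = 1.0 / substeps
    t = t0
    for i in range(n_min):
        for _ in range(substeps):
            k1 = _rates(y, t, 0.0, 0.0, gb, si, p1, p2, f, tau_m, tau_i, v, ac, phic)
            k2 = _rates(y + 0.5 * dt * k1, t + 0.5 * dt, 0.0, 0.0,
                        gb, si, p1, p2, f, tau_m, tau_i, v, ac, phic)
            k3 = _rates(y + 0.5 * dt * k2, t + 0.5 * dt, 0.0, 0.0,
                        gb, si, p1, p2, f, tau_m, tau_i, v, ac, phic)
            k4 = _rates(y + dt * k3, t + dt, 0.0, 0.0,
                        gb, si, p1, p2, f, tau_m, tau_i, v, ac, phic)
            y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            t += dt
        g_out[i] = y[0]
    return y, g_out


# ---------------------------------------------------------------------------
# scenario realization (all randomness drawn up front, for paired designs)
# ---------------------------------------------------------------------------

@dataclass
class ScenarioRealization:
    """Every random draw of one patient-run, frozen for reuse.

    Reusing a realization with a different dosing policy yields a paired
    simulation: identical meals, misestimations and sensor noise.
    """

    meal_minutes: np.ndarray      # minute-of-simulation of each meal
    cho_actual: np.ndarray        # g
    cho_announced: np.ndarray     # g
    sensor_noise: np.ndarray      # mg/dL, one per CGM sample
    seed: int
    scenario: SimScenario


def realize_scenario(scenario: SimScenario, seed: int) -> ScenarioRealization:
    rng = np.random.default_rng(seed)
    jit = scenario.meal_jitter_min
    times, actual, announced = [], [], []
    trunc = stats.truncnorm(
        -scenario.carb_misest_max / scenario.carb_misest_sd,
        scenario.carb_misest_max / scenario.carb_misest_sd,
        loc=0.0, scale=scenario.carb_misest_sd,
    )
    for day in range(scenario.n_days):
        for nominal_h, nominal_g in zip(scenario.meal_times_h, scenario.meal_carbs_g):
            t = day * 1440 + nominal_h * 60.0 + rng.uniform(-jit, jit)
            cho = nominal_g * (1.0 + rng.uniform(-scenario.meal_content_var,
                                                 scenario.meal_content_var))
            eps = float(trunc.ppf(rng.uniform()))
            times.append(round(t))
            actual.append(cho)
            announced.append(cho * (1.0 + eps))
    n_samples = scenario.n_days * 1440 // scenario.step_min + 1
    noise = rng.normal(0.0, scenario.sensor_noise_sd, size=n_samples)
    return ScenarioRealization(
        meal_minutes=np.array(times, dtype=int),
        cho_actual=np.array(actual),
        cho_announced=np.array(announced),
        sensor_noise=noise,
        seed=seed,
        scenario=scenario,
    )


@dataclass
class MealContext:
    """What a dosing policy may see when a meal is announced."""

    patient_id: str
    time: pd.Timestamp
    minute: int
    cho_announced: float
    therapy: TherapyParams
    cgm_history: GlucoseTrace        # samples up to and including meal time
    bolus_history: list[BolusEvent]


DosingPolicy = Callable[[MealContext], float]


def standard_policy(ctx: MealContext) -> float:
    """Open-loop baseline: the standard bolus on announced carbohydrates."""
    from .bolus import standard_bolus  # local import avoids a cycle

    cgm_meal = _last_valid(ctx.cgm_history)
    return max(0.0, standard_bolus(ctx.cho_announced, ctx.therapy, cgm_meal))


def _last_valid(trace: GlucoseTrace) -> float:
    vals = trace.values[~trace.missing]
    if vals.size == 0:
        raise SimulationError("no CGM sample available at meal time")
    return float(vals[-1])


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------

START_TIME = pd.Timestamp("2024-01-01 00:00")


def simulate_patient(
    patient: VirtualPatient,
    scenario: SimScenario,
    seed: int,
    policy: DosingPolicy | None = None,
    realization: ScenarioRealization | None = None,
    substeps: int = 1,
) -> PatientRecord:
    """Run one patient through the scenario under a dosing policy.

    All randomness comes from ``seed`` (or an explicit pre-drawn
    ``realization``); the same (patient, realization) pair under two
    policies yields a paired comparison.
    """
    if policy is None:
        policy = standard_policy
    real = realization or realize_scenario(scenario, seed)
    step = scenario.step_min
    total_min = scenario.n_days * 1440
    n_samples = total_min // step + 1

    p = (patient.g_b, patient.s_i, patient.p1, patient.p2, patient.f,
         patient.tau_m, patient.tau_i, patient.v, patient.a_c, patient.phi_c)
    y = SimState.fasting(patient).to_array()
    g_minutes = np.empty(total_min + 1)
    g_minutes[0] = y[0]

    samples = np.full(n_samples, np.nan)
    missing = np.ones(n_samples, dtype=bool)

    def record_sample(idx: int, g: float) -> None:
        samples[idx] = float(np.clip(g + real.sensor_noise[idx], SENSOR_MIN, SENSOR_MAX))
        missing[idx] = False

    record_sample(0, y[0])

    meals: list[MealEvent] = []
    boluses: list[BolusEvent] = []
    order = np.argsort(real.meal_minutes, kind="stable")
    event_list = [(int(real.meal_minutes[i]), float(real.cho_actual[i]),
                   float(real.cho_announced[i])) for i in order]

    t = 0
    for minute, cho_act, cho_ann in event_list + [(total_min, None, None)]:
        minute = min(minute, total_min)
        if minute > t:
            y, g_seg = _integrate(y, float(t), minute - t, substeps, *p)
            if not np.all(np.isfinite(y)):
                raise SimulationError(f"non-finite state at t={minute} min")
            g_minutes[t + 1: minute + 1] = g_seg
            for m in range(t + 1, minute + 1):
                if m % step == 0:
                    record_sample(m // step, g_minutes[m])
            t = minute
        if cho_act is None:
            break
        ts = START_TIME + pd.Timedelta(minutes=minute)
        hist_n = t // step + 1
        history = GlucoseTrace(
            start_time=START_TIME,
            values=samples[:hist_n].copy(),
            missing=missing[:hist_n].copy(),
            step_min=step,
        )
        ctx = MealContext(
            patient_id=patient.patient_id, time=ts, minute=minute,
            cho_announced=cho_ann, therapy=patient.therapy,
            cgm_history=history, bolus_history=list(boluses),
        )
        units = max(0.0, float(policy(ctx)))
        y[2] += cho_act * 1000.0    # gut compartment, mg
        y[4] += units               # subcutaneous depot, U
        meals.append(MealEvent(time=ts, cho_announced=cho_ann, cho_actual=cho_act))
        boluses.append(BolusEvent(time=ts, units=units))

    trace = GlucoseTrace(start_time=START_TIME, values=samples, missing=missing,
                         step_min=step)
    return PatientRecord(
        patient_id=patient.patient_id, trace=trace, meals=meals,
        boluses=boluses, therapy=patient.therapy,
    )


def patient_seed(master_seed: int, index: int) -> int:
    """Deterministic, well-separated per-patient stream seed (< 2^31)."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def generate_cohort(
    scenario: SimScenario,
    policy: DosingPolicy | None = None,
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Simulate the full cohort; returns (records, parameter manifest)."""
    records, rows = [], []
    for i in range(scenario.n_patients):
        pid = f"sim{i + 1:03d}"
        p_seed = patient_seed(scenario.seed, i)
        patient = draw_patient(pid, np.random.default_rng(p_seed))
        rec = simulate_patient(patient, scenario, seed=p_seed + 1, policy=policy)
        records.append(rec)
        row = {k: v for k, v in asdict(patient).items() if k != "therapy"}
        row.update(cr=patient.therapy.cr, cf=patient.therapy.cf, seed=p_seed)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    logger.info("generated cohort of %d patients (master seed %d)",
                scenario.n_patients, scenario.seed)
    return records, manifest


def save_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_json(path, orient="records", indent=1)


__all__ = [
    "VirtualPatient", "SimScenario", "SimState", "ScenarioRealization",
    "MealContext", "DosingPolicy", "PARAM_RANGES",
    "derivatives", "draw_patient", "realize_scenario", "simulate_patient",
    "standard_policy", "generate_cohort", "patient_seed", "save_manifest",
]
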