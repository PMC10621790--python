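"""Trial protocols: the three pre-MIPD phases and the MIPD trial loop.

Phase I monitors single-dose pharmacokinetics in a small cohort; phase II
monitors the INR response under a fixed induction plus a linear dose-
adjustment heuristic; phase III repeats the phase-II design in a larger
cohort for eight weeks, recording only the end-of-trial INR and maintenance
dose.  The MIPD trial treats a cohort daily for a fixed horizon, delegating
every dose decision to a pluggable dosing agent.

Dose ``j`` is administered at nominal ``t = 24 (j - 1)`` h; the INR "taken
just before" a dose shares its nominal time and, through the execution
model, its actual (delayed) time.  Datasets record nominal schedules unless
``trials.report_actual_times`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .config import CTConfig
from .dataset import TrialDataset
from .dynamics import DosingRegimen
from .engine import CohortEngine, ParameterArrays
from .population import (CovariateProfile, Demographics, PopulationParameters,
                         covariates_frame, sample_cohort)
from .stochastic import occasion_matrix, sample_measurement


class ProtocolError(RuntimeError):
    """An agent or protocol violated its contract."""


@dataclass(frozen=True)
class MonitoringRecord:
    """Monitoring data available to an agent up to the current day."""

    measurements: tuple = ()          # ((value, time_h), ...)
    regimen_so_far: DosingRegimen = DosingRegimen()

    def __post_init__(self):
        times = [t for _, t in self.measurements]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("measurement times must be strictly increasing")

    @property
    def latest_inr(self) -> float | None:
        return self.measurements[-1][0] if self.measurements else None


@runtime_checkable
class DosingAgent(Protocol):
    """Dose-decision interface; must not consult the virtual patient's psi."""

    name: str

    def propose_dose(self, chi: CovariateProfile, record: MonitoringRecord,
                     y_star: float, day: int, patient_id: int) -> float:
        ...


def round_dose(dose, step: float = 0.5, dose_max: float = 30.0):
    """Tablet-like rounding to the nearest step, capped at the daily maximum."""
    dose = np.clip(np.round(np.asarray(dose, dtype=float) / step) * step,
                   0.0, dose_max)
    return float(dose) if dose.shape == () else dose


def heuristic_dose(d_prev: float, y_star: float, y_j: float,
                   step: float = 0.5, dose_max: float = 30.0) -> float:
    """Linear dose adjustment ``d_j = d_{j-1} y* / y_j``, rounded and capped."""
    if y_j <= 0:
        raise ValueError("measured INR must be > 0")
    if y_star <= 0 or d_prev < 0:
        raise ValueError("require y_star > 0 and d_prev >= 0")
    return round_dose(d_prev * y_star / y_j, step, dose_max)


def safety_stop(inr_history) -> bool:
    """True iff any three consecutive INR measurements all exceed 5."""
    h = list(inr_history)
    return any(h[i] > 5 and h[i + 1] > 5 and h[i + 2] > 5
               for i in range(len(h) - 2))


# ---------------------------------------------------------------------------
# shared machinery


def _streams(seed, n: int):
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def _setup_cohort(config: CTConfig, n: int, rng):
    theta = PopulationParameters.from_config(config.mechanistic,
                                             config.population)
    demo = Demographics.from_config(config.demographics)
    cohort = sample_cohort(theta, demo, n, rng)
    return cohort


def _delays(rng, shape, tau_min: float) -> np.ndarray:
    tau_h = tau_min / 60.0
    if tau_h == 0:
        return np.zeros(shape)
    # clip far tail to keep daily events ordered
    return np.minimum(rng.exponential(tau_h, size=shape), 23.0)


def _metadata(config: CTConfig, trial: str, seed, stopped=()) -> dict:
    return {"trial": trial, "seed": int(seed),
            "config_hash": config.config_hash(),
            "stopped_patients": sorted(int(i) for i in stopped)}


# ---------------------------------------------------------------------------
# phase I


def run_phase1(config: CTConfig, seed) -> TrialDataset:
    """Single 10 mg dose; concentrations sampled at 10, 35 and 60 h."""
    n = config.trials.phase1_n
    rng_cohort, rng_iov, rng_exec, rng_meas = _streams(seed, 4)
    cohort = _setup_cohort(config, n, rng_cohort)
    chis = [c for c, _ in cohort]
    params = ParameterArrays([p for _, p in cohort])

    dose_mg, meas_nominal = 10.0, np.array([10.0, 35.0, 60.0])
    eta = occasion_matrix(n, 4, config.iov, rng_iov)
    # the dose and the three measurements have distinct nominal times
    delays = _delays(rng_exec, (n, 4), config.execution.tau_min)
    dose_actual = 0.0 + delays[:, 0]
    meas_actual = meas_nominal[None, :] + delays[:, 1:]

    eng = CohortEngine(params, step_h=config.mechanistic.rk4_step_h)
    eng.advance_through_days(dose_actual, eta)
    eng.apply_dose(dose_mg)
    conc = np.empty((n, 3))
    for m in range(3):
        eng.advance_through_days(meas_actual[:, m], eta)
        conc[:, m] = eng.conc()
    measured = sample_measurement(conc, config.measurement, rng_meas)

    report_actual = config.trials.report_actual_times
    ids = np.repeat(np.arange(1, n + 1), 3)
    times = (meas_actual if report_actual
             else np.tile(meas_nominal, (n, 1))).ravel()
    measurements = pd.DataFrame({
        "ID": ids, "Observable": "warfarin_conc_mg_per_L",
        "Time_h": times, "Value": measured.ravel()})
    doses = pd.DataFrame({
        "ID": np.arange(1, n + 1),
        "Time_h": dose_actual if report_actual else np.zeros(n),
        "Dose_mg": np.full(n, dose_mg)})
    return TrialDataset(covariates_frame(chis), measurements, doses,
                        _metadata(config, "phase1", seed))


# ---------------------------------------------------------------------------
# phases II and III


def _run_adjustment_trial(config: CTConfig, seed, n: int, n_days: int,
                          measurement_days, adjustment_days):
    """Fixed induction + heuristic adjustments; returns the full trace.

    Doses on days 0-2 are 10/7.5/5 mg for everyone; on each adjustment day
    the dose is reset by the linear heuristic from the same-day measurement;
    otherwise the previous day's dose repeats.  Measurements happen just
    before the dose (shared delay).  Three consecutive measurements above
    INR 5 stop a patient's trial.
    """
    trials = config.trials
    rng_cohort, rng_iov, rng_exec, rng_meas = _streams(seed, 4)
    cohort = _setup_cohort(config, n, rng_cohort)
    chis = [c for c, _ in cohort]
    params = ParameterArrays([p for _, p in cohort])
    measurement_days = sorted(measurement_days)
    adjustment_days = set(adjustment_days)

    eta = occasion_matrix(n, n_days, config.iov, rng_iov)
    delays = _delays(rng_exec, (n, n_days), config.execution.tau_min)

    eng = CohortEngine(params, step_h=config.mechanistic.rk4_step_h)
    active = np.ones(n, dtype=bool)
    history = [[] for _ in range(n)]
    current_dose = np.zeros(n)
    induction = {0: 10.0, 1: 7.5, 2: 5.0}

    meas_rows, dose_rows = [], []
    report_actual = trials.report_actual_times
    for day in range(n_days):
        event_time = 24.0 * day + delays[:, day]
        eng.advance_through_days(event_time, eta)
        if day in measurement_days:
            inr_true = np.maximum(eng.inr(), 1e-6)
            inr_meas = sample_measurement(inr_true, config.measurement,
                                          rng_meas)
            for i in np.where(active)[0]:
                history[i].append(float(inr_meas[i]))
                meas_rows.append((i + 1, "INR",
                                  float(event_time[i]) if report_actual
                                  else 24.0 * day, float(inr_meas[i])))
            newly_stopped = [i for i in np.where(active)[0]
                             if safety_stop(history[i])]
            active[newly_stopped] = False
        if day in induction:
            current_dose[:] = induction[day]
        elif day in adjustment_days:
            for i in np.where(active)[0]:
                current_dose[i] = heuristic_dose(
                    current_dose[i], trials.y_star, history[i][-1],
                    trials.dose_step, trials.dose_max)
        administered = np.where(active, current_dose, 0.0)
        eng.apply_dose(administered)
        for i in np.where(active)[0]:
            dose_rows.append((i + 1,
                              float(event_time[i]) if report_actual
                              else 24.0 * day, float(administered[i])))

    measurements = pd.DataFrame(
        meas_rows, columns=["ID", "Observable", "Time_h", "Value"])
    doses = pd.DataFrame(dose_rows, columns=["ID", "Time_h", "Dose_mg"])
    stopped = [i + 1 for i in range(n) if not active[i]]
    return chis, measurements, doses, stopped


PHASE2_MEASUREMENT_DAYS = (0, 1, 2, 3, 5, 7, 13, 20)
PHASE2_ADJUSTMENT_DAYS = (3, 5, 7, 13)
PHASE3_MEASUREMENT_DAYS = (0, 1, 2, 3, 5, 7, 13, 20, 27, 34, 55)
PHASE3_ADJUSTMENT_DAYS = (3, 5, 7, 13, 27, 34)


def run_phase2(config: CTConfig, seed, n: int | None = None) -> TrialDataset:
    """Three-week INR monitoring trial with heuristic dose adjustments."""
    n = config.trials.phase2_n if n is None else n
    chis, measurements, doses, stopped = _run_adjustment_trial(
        config, seed, n, n_days=21,
        measurement_days=PHASE2_MEASUREMENT_DAYS,
        adjustment_days=PHASE2_ADJUSTMENT_DAYS)
    return TrialDataset(covariates_frame(chis), measurements, doses,
                        _metadata(config, "phase2", seed, stopped))


def run_phase3(config: CTConfig, seed, n: int | None = None) -> TrialDataset:
    """Eight-week maintenance-dose trial.

    The recorded dataset keeps, per surviving patient, only the day-55 INR
    measurement and the final (maintenance) dose.
    """
    n = config.trials.phase3_n if n is None else n
    chis, measurements, doses, stopped = _run_adjustment_trial(
        config, seed, n, n_days=56,
        measurement_days=PHASE3_MEASUREMENT_DAYS,
        adjustment_days=PHASE3_ADJUSTMENT_DAYS)
    final_inr = measurements[measurements["Time_h"] >= 24.0 * 55 - 12.0]
    final_dose = doses.sort_values("Time_h").groupby("ID").tail(1)
    keep = set(final_inr["ID"])
    final_dose = final_dose[final_dose["ID"].isin(keep)]
    return TrialDataset(covariates_frame(chis),
                        final_inr.reset_index(drop=True),
                        final_dose.reset_index(drop=True),
                        _metadata(config, "phase3", seed, stopped))


# ---------------------------------------------------------------------------
# MIPD trial


def run_mipd_trial(config: CTConfig, agent: DosingAgent, cohort,
                   seed) -> TrialDataset:
    """Daily agent-guided dosing for the configured horizon (no stop rule).

    The cohort is passed in so that competing agents can be evaluated on the
    same virtual patients.  Each day the INR is measured just before the dose
    (shared execution delay); the agent sees the recorded (nominal-time)
    monitoring data plus covariates, never the patient's true parameters.
    """
    trials = config.trials
    n, n_days = len(cohort), trials.mipd_days
    _, rng_iov, rng_exec, rng_meas = _streams(seed, 4)
    chis = [c for c, _ in cohort]
    params = ParameterArrays([p for _, p in cohort])

    eta = occasion_matrix(n, n_days, config.iov, rng_iov)
    delays = _delays(rng_exec, (n, n_days), config.execution.tau_min)
    eng = CohortEngine(params, step_h=config.mechanistic.rk4_step_h)

    measured = [[] for _ in range(n)]   # (value, nominal time)
    dosed = [[] for _ in range(n)]      # (dose, nominal time)
    meas_rows, dose_rows = [], []
    report_actual = trials.report_actual_times
    for day in range(n_days):
        event_time = 24.0 * day + delays[:, day]
        eng.advance_through_days(event_time, eta)
        inr_true = np.maximum(eng.inr(), 1e-6)
        inr_meas = sample_measurement(inr_true, config.measurement, rng_meas)
        doses_today = np.empty(n)
        for i in range(n):
            measured[i].append((float(inr_meas[i]), 24.0 * day))
            record = MonitoringRecord(
                tuple(measured[i]),
                DosingRegimen(tuple((d, t) for d, t in dosed[i])))
            dose = agent.propose_dose(chis[i], record, trials.y_star, day,
                                      patient_id=i + 1)
            if dose is None or not np.isfinite(dose) or dose < 0:
                raise ProtocolError(
                    f"agent {getattr(agent, 'name', agent)!r} returned "
                    f"invalid dose {dose!r} on day {day}")
            dose = round_dose(dose, trials.dose_step, trials.dose_max)
            doses_today[i] = dose
            dosed[i].append((dose, 24.0 * day))
            t_rec = float(event_time[i]) if report_actual else 24.0 * day
            meas_rows.append((i + 1, "INR", t_rec, float(inr_meas[i])))
            dose_rows.append((i + 1, t_rec, dose))
        eng.apply_dose(doses_today)

    measurements = pd.DataFrame(
        meas_rows, columns=["ID", "Observable", "Time_h", "Value"])
    doses = pd.DataFrame(dose_rows, columns=["ID", "Time_h", "Dose_mg"])
    meta = _metadata(config, f"mipd-{getattr(agent, 'name', 'agent')}", seed)
    return TrialDataset(covariates_frame(chis), measurements, doses, meta)
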