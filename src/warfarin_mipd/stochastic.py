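"""Stochastic layers of the clinical-trial model.

Three independent noise sources sit between the mechanistic model and the
recorded data:

* inter-occasion variability — a fresh Normal(mu_eta, sigma_eta^2) vitamin-K
  input multiplier per simulation day;
* execution variability — exponentially distributed delays of dose
  administrations and monitoring measurements (a dose and a measurement
  sharing a nominal time share one delay);
* measurement noise — lognormal with median equal to the model output, so
  the error scales with the measured quantity (~10% at the default sigma).
"""

from __future__ import annotations

import numpy as np

from .config import ExecutionConfig, IOVConfig, MeasurementConfig
from .dynamics import DosingRegimen, OccasionSeries

ETA_FLOOR = 0.05  # keeps the vitamin-K input multiplier positive


def sample_occasions(n_days: int, cfg: IOVConfig, rng) -> OccasionSeries:
    """One independent daily multiplier, floored at a small positive value."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(rng)
    draws = rng.normal(cfg.mu_eta, cfg.sigma_eta, size=n_days)
    draws = np.maximum(draws, ETA_FLOOR)
    return OccasionSeries({day: float(e) for day, e in enumerate(draws)})


def occasion_matrix(n_patients: int, n_days: int, cfg: IOVConfig,
                    rng) -> np.ndarray:
    """(n_patients, n_days) matrix of daily multipliers for a cohort."""
    rng = np.random.default_rng(rng)
    draws = rng.normal(cfg.mu_eta, cfg.sigma_eta, size=(n_patients, n_days))
    return np.maximum(draws, ETA_FLOOR)


def perturb_schedule(nominal: DosingRegimen, nominal_measurement_times,
                     cfg: ExecutionConfig, rng):
    """Delay nominal dose and measurement times by exponential deviations.

    Returns ``(actual_regimen, actual_measurement_times)``.  Events sharing a
    nominal time receive one shared delay; dose amounts are unchanged.
    """
    rng = np.random.default_rng(rng)
    meas_times = np.asarray(nominal_measurement_times, dtype=float)
    if np.any(np.diff(meas_times) < 0):
        raise ValueError("nominal measurement times must be sorted")
    tau_h = cfg.tau_min / 60.0

    def delay():
        return float(rng.exponential(tau_h)) if tau_h > 0 else 0.0

    delays_by_time: dict[float, float] = {}
    actual_events = []
    for dose, t in nominal.events:
        d = delays_by_time.setdefault(float(t), delay())
        actual_events.append((dose, t + d))
    actual_meas = np.array(
        [t + delays_by_time.setdefault(float(t), delay())
         for t in meas_times])
    # exponential delays are non-negative, but enforce ordering defensively
    actual_events.sort(key=lambda e: e[1])
    return (DosingRegimen(tuple(actual_events), kind="actual"),
            np.sort(actual_meas))


def sample_measurement(y_bar, cfg: MeasurementConfig, rng):
    """Lognormal measurement with median ``y_bar`` and log-scale sigma.

    Accepts scalars or arrays; applies the lower limit of quantification as a
    floor when configured.
    """
    y_bar = np.asarray(y_bar, dtype=float)
    if np.any(y_bar <= 0):
        raise ValueError("y_bar must be > 0 (lognormal median)")
    rng = np.random.default_rng(rng)
    draws = y_bar * np.exp(cfg.sigma * rng.standard_normal(y_bar.shape))
    if cfg.lloq is not None:
        draws = np.maximum(draws, cfg.lloq)
    return draws if draws.shape else float(draws)
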