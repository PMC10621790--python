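"""Mechanistic warfarin PKPD core.

The model is a reduced stand-in for a full coagulation-network description,
keeping the interface and the qualitative behaviour (nonlinearity, multi-day
response delay, vitamin-K coupling) while being fully self-contained:

* PK: one-compartment disposition with first-order absorption,
  ``da_d/dt = -ka a_d + r(t)``, ``da_c/dt = ka a_d - ke a_c``; the monitored
  concentration is ``C = a_c / V``.
* PD: the central concentration inhibits the production of a clotting-activity
  transit chain via an inhibitory Hill function
  ``E(C) = 1 - C^gamma / (EC50^gamma + C^gamma)``,
  ``dA_1/dt = ktr (eta_day E(C) - A_1)``,
  ``dA_i/dt = ktr (A_{i-1} - A_i)``, with ``ktr = n_transit / MTT``.
  The daily multiplier ``eta_day`` models varying vitamin-K intake.
* INR readout: ``INR(t) = inr_base + inr_max * max(0, 1 - A_n)^lam``.

Doses are instantaneous bolus additions to the dose compartment.  Time is in
hours throughout; day ``k`` spans ``[24k, 24(k+1))`` hours (0-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp


class IntegrationFailure(RuntimeError):
    """Raised when the ODE solution is non-finite or the solver fails."""


@dataclass(frozen=True)
class IndividualParameters:
    """Mechanistic parameters of one virtual patient."""

    ka: float          # absorption rate, 1/h
    ke: float          # elimination rate, 1/h
    V: float           # volume of distribution, L
    EC50: float        # half-maximal inhibitory concentration, mg/L
    gamma: float       # Hill coefficient
    MTT: float         # mean transit time of the response chain, h
    n_transit: int     # number of transit compartments
    inr_base: float    # drug-free INR
    inr_max: float     # maximal INR increment
    lam: float         # response-shape exponent

    def __post_init__(self):
        for name in ("ka", "ke", "V", "EC50", "MTT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.inr_base < 0.8:
            raise ValueError("inr_base must be >= 0.8")
        if self.n_transit < 1:
            raise ValueError("n_transit must be >= 1")
        if self.inr_max < 0 or self.lam <= 0 or self.gamma <= 0:
            raise ValueError("inr_max must be >= 0; lam, gamma > 0")

    @property
    def ktr(self) -> float:
        return self.n_transit / self.MTT

    def with_(self, **kwargs) -> "IndividualParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DosingRegimen:
    """Ordered sequence of (dose_mg, time_h) events; nominal or actual."""

    events: tuple = ()
    kind: str = "nominal"

    def __post_init__(self):
        events = tuple((float(d), float(t)) for d, t in self.events)
        object.__setattr__(self, "events", events)
        times = [t for _, t in events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose times must be non-decreasing")
        if any(d < 0 for d, _ in events):
            raise ValueError("doses must be >= 0")
        if self.kind not in ("nominal", "actual"):
            raise ValueError("kind must be 'nominal' or 'actual'")

    @property
    def doses(self) -> np.ndarray:
        return np.array([d for d, _ in self.events])

    @property
    def times(self) -> np.ndarray:
        return np.array([t for _, t in self.events])

    @staticmethod
    def daily(doses_mg: Sequence[float], start_h: float = 0.0,
              kind: str = "nominal") -> "DosingRegimen":
        """Daily regimen: dose j at ``start_h + 24 j``."""
        return DosingRegimen(
            tuple((d, start_h + 24.0 * j) for j, d in enumerate(doses_mg)),
            kind=kind)


@dataclass(frozen=True)
class OccasionSeries:
    """Daily vitamin-K input multipliers, keyed by 0-based day index."""

    eta_by_day: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if any(v <= 0 for v in self.eta_by_day.values()):
            raise ValueError("all eta must be > 0")

    def eta(self, day: int) -> float:
        return float(self.eta_by_day.get(int(day), 1.0))


@dataclass(frozen=True)
class ResponseTrajectory:
    times_h: np.ndarray
    conc_mg_per_L: np.ndarray
    inr: np.ndarray

    def __post_init__(self):
        if not (len(self.times_h) == len(self.conc_mg_per_L) == len(self.inr)):
            raise ValueError("trajectory vectors must share a length")


def inr_from_activity(a_n, psi: IndividualParameters):
    """Map the terminal chain activity to an INR value."""
    depletion = np.maximum(0.0, 1.0 - np.asarray(a_n))
    return psi.inr_base + psi.inr_max * depletion ** psi.lam


def _rhs(t, y, psi: IndividualParameters, eta: float):
    ka, ke, ktr = psi.ka, psi.ke, psi.ktr
    a_d, a_c = y[0], y[1]
    conc = max(a_c, 0.0) / psi.V
    hill = conc ** psi.gamma / (psi.EC50 ** psi.gamma + conc ** psi.gamma)
    effect = 1.0 - hill
    dy = np.empty_like(y)
    dy[0] = -ka * a_d
    dy[1] = ka * a_d - ke * a_c
    dy[2] = ktr * (eta * effect - y[2])
    for i in range(3, len(y)):
        dy[i] = ktr * (y[i - 1] - y[i])
    return dy


def simulate_response(regimen: DosingRegimen,
                      psi: IndividualParameters,
                      times,
                      occasions: OccasionSeries | None = None,
                      rtol: float = 1e-6,
                      atol: float = 1e-8) -> ResponseTrajectory:
    """Simulate concentration and noise-free INR on a requested time grid.

    The ODE system is integrated piecewise between dose events and day
    boundaries (where the occasion multiplier may change), with doses applied
    as instantaneous additions to the dose compartment.

    Parameters
    ----------
    regimen
        Dosing events; events before the first grid time still contribute.
    psi
        Individual mechanistic parameters.
    times
        Sorted evaluation grid in hours; must be non-empty.
    occasions
        Optional daily multipliers; absent days default to 1.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("time grid must be non-empty")
    if np.any(np.diff(times) < 0):
        raise ValueError("time grid must be sorted")
    occ = occasions or OccasionSeries()

    t0 = min(float(times[0]), regimen.times[0] if len(regimen.events) else
             float(times[0]))
    t_end = float(times[-1])

    # breakpoints: dose events and day boundaries
    breaks = {t0, t_end}
    breaks.update(float(t) for t in regimen.times if t0 <= t <= t_end)
    day0, day1 = int(np.floor(t0 / 24.0)), int(np.ceil(t_end / 24.0))
    breaks.update(24.0 * k for k in range(day0, day1 + 1)
                  if t0 <= 24.0 * k <= t_end)
    breaks = sorted(breaks)

    dose_at = {}
    for d, t in regimen.events:
        if t0 <= t <= t_end:
            dose_at[float(t)] = dose_at.get(float(t), 0.0) + d

    n_states = 2 + psi.n_transit
    y = np.zeros(n_states)
    y[2:] = 1.0  # drug-free steady state of the activity chain

    out = np.full((len(times), n_states), np.nan)
    done = np.zeros(len(times), dtype=bool)

    def record(t_lo, t_hi, sol):
        mask = (~done) & (times >= t_lo - 1e-12) & (times <= t_hi + 1e-12)
        if np.any(mask):
            out[mask] = sol.sol(times[mask]).T
            done[mask] = True

    for t_lo, t_hi in zip(breaks[:-1], breaks[1:]):
        if t_lo in dose_at:
            y[0] += dose_at[t_lo]
        exact = (~done) & (np.abs(times - t_lo) <= 1e-12)
        out[exact] = y
        done[exact] = True
        if t_hi <= t_lo:
            continue
        eta = occ.eta(int(np.floor((t_lo + 1e-9) / 24.0)))
        sol = solve_ivp(_rhs, (t_lo, t_hi), y, args=(psi, eta),
                        method="LSODA", rtol=rtol, atol=atol,
                        dense_output=True)
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise IntegrationFailure(
                f"integration failed on [{t_lo}, {t_hi}] for psi={psi}")
        record(t_lo, t_hi, sol)
        y = sol.y[:, -1]
    if breaks[-1] in dose_at:
        y[0] += dose_at[breaks[-1]]
    exact = (~done) & (np.abs(times - breaks[-1]) <= 1e-12)
    out[exact] = y
    done[exact] = True
    if not np.all(done):
        raise IntegrationFailure("time grid extends beyond integrated span")

    conc = np.maximum(out[:, 1], 0.0) / psi.V
    inr = inr_from_activity(out[:, -1], psi)
    return ResponseTrajectory(times, conc, inr)


def steady_state_inr(daily_dose_mg: float, psi: IndividualParameters,
                     n_days: int = 35) -> float:
    """Approximate steady-state trough INR under constant daily dosing.

    Simulates ``n_days`` (>= 30) of daily dosing and returns the INR at the
    end of the final day, i.e. just before the next dose.
    """
    if daily_dose_mg < 0:
        raise ValueError("daily_dose_mg must be >= 0")
    if n_days < 30:
        raise ValueError("steady state requires at least 30 days")
    if daily_dose_mg == 0:
        return psi.inr_base
    regimen = DosingRegimen.daily([daily_dose_mg] * n_days)
    traj = simulate_response(regimen, psi, times=[24.0 * n_days])
    return float(traj.inr[-1])


def steady_state_inr_closed_form(daily_dose_mg: float,
                                 psi: IndividualParameters) -> float:
    """Closed-form steady-state INR at the average concentration.

    At steady state the chain relaxes to E(C); evaluating E at the average
    concentration ``C_ss = dose rate / (ke V)`` gives a fast analytic
    approximation used for calibration cross-checks and toy oracles.
    """
    if daily_dose_mg == 0:
        return psi.inr_base
    c_ss = daily_dose_mg / (24.0 * psi.ke * psi.V)
    hill = c_ss ** psi.gamma / (psi.EC50 ** psi.gamma + c_ss ** psi.gamma)
    return float(psi.inr_base + psi.inr_max * hill ** psi.lam)


def calibrate_ec50(psi: IndividualParameters, daily_dose_mg: float = 5.0,
                   target_inr: float = 2.5,
                   bracket=(0.5, 50.0)) -> float:
    """Solve for the EC50 putting the reference patient on target.

    One-dimensional root solve of ``steady_state_inr(dose; EC50) = target``.
    """
    from scipy.optimize import brentq

    def f(ec50):
        return steady_state_inr(daily_dose_mg, psi.with_(EC50=ec50)) \
            - target_inr

    return float(brentq(f, *bracket, xtol=1e-4))


def load_sbml_model(path):
    """Optional hook: load an SBML mechanistic model with the same interface.

    Requires ``python-libsbml``; disabled by default.  The loader returns an
    object exposing ``simulate_response`` with the contract above, so a full
    coagulation-network model can be plugged into the trial protocols later.
    """
    try:
        import libsbml  # noqa: F401
    except ImportError as err:
        raise ImportError(
            "SBML import requires the optional dependency 'python-libsbml'"
        ) from err
    raise NotImplementedError(
        "SBML-backed mechanistic models are not implemented yet")
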