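"""Bayesian PKPD dosing: hierarchical fit, MAP individualisation, regimen
optimisation.

The MIPD-internal model shares the reduced mechanistic structure of the
clinical-trial model (an optional ``misspecify`` switch degrades it for
robustness studies).  Three stages:

1. ``fit_population`` — hierarchical Bayesian fit of the population typical
   values, random-effect SDs and measurement scale to pre-MIPD trial data,
   using a blocked adaptive-Metropolis sampler: an adaptive-covariance
   Metropolis update on the population block alternates with vectorised
   per-patient random-effect updates.  Covariate multipliers and the
   remaining structural parameters are held at their configured values.
2. ``fit_individual_map`` — maximum a posteriori estimate of one patient's
   random effects given the fitted population model, the covariates and the
   monitoring data (grid initialisation + Nelder-Mead polish).
3. ``optimise_regimen`` — CMA-ES minimisation of the squared distance
   between predicted daily INR and the target over the remaining horizon.

``PKPDAgent`` chains 2 and 3 each trial day, warm-starting from the previous
day's solution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._cmaes import cma_es_minimise
from .config import REFERENCE_AGE, CTConfig
from .dataset import TrialDataset
from .dynamics import DosingRegimen, IndividualParameters
from .engine import CohortEngine, ParameterArrays, simulate_cohort_inr
from .population import (CovariateProfile, PopulationParameters,
                         typical_parameters)
from .protocols import MonitoringRecord, round_dose

PARAM_NAMES = ("tv_ke", "tv_EC50", "omega_ke", "omega_EC50", "sigma")
_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# data blocks


class _Block:
    """Lockstep view of one trial dataset for the fit likelihood."""

    def __init__(self, dataset: TrialDataset, config: CTConfig):
        mech, pop = config.mechanistic, config.population
        # the MIPD-internal model never carries IOV ('drop_iov' is inherent);
        # 'coarse_transit' additionally collapses the response chain
        self.n_transit = (1 if config.pkpd.misspecify == "coarse_transit"
                          else mech.n_transit)
        cov = dataset.covariates
        self.n = len(cov)
        self.ke_mult = np.array([
            pop.cyp2c9_ke_mult[c] *
            (1.0 + pop.age_slope * (a - REFERENCE_AGE))
            for c, a in zip(cov["CYP2C9"], cov["Age"])])
        self.ec50_mult = np.array(
            [pop.vkorc1_ec50_mult[v] for v in cov["VKORC1"]])

        ids = cov["ID"].to_numpy()
        id_pos = {pid: k for k, pid in enumerate(ids)}
        meas = dataset.measurements
        self.observable = ("inr" if (meas["Observable"] == "INR").all()
                           else "conc")
        self.obs_times = np.sort(meas["Time_h"].unique())
        t_pos = {t: m for m, t in enumerate(self.obs_times)}
        self.log_obs = np.full((self.n, len(self.obs_times)), np.nan)
        for pid, t, v in zip(meas["ID"], meas["Time_h"], meas["Value"]):
            self.log_obs[id_pos[pid], t_pos[t]] = np.log(v)
        self.mask = ~np.isnan(self.log_obs)

        if dataset.metadata.get("trial") == "phase3":
            # recorded as (maintenance dose, day-55 INR): emulate 56 days of
            # constant maintenance dosing
            self.dose_times = 24.0 * np.arange(56)
            amounts = np.zeros(self.n)
            for pid, d in zip(dataset.doses["ID"], dataset.doses["Dose_mg"]):
                amounts[id_pos[pid]] = d
            self.doses = np.tile(amounts[:, None], (1, 56))
        else:
            self.dose_times = np.sort(dataset.doses["Time_h"].unique())
            d_pos = {t: k for k, t in enumerate(self.dose_times)}
            self.doses = np.zeros((self.n, len(self.dose_times)))
            for pid, t, d in zip(dataset.doses["ID"],
                                 dataset.doses["Time_h"],
                                 dataset.doses["Dose_mg"]):
                self.doses[id_pos[pid], d_pos[t]] = d

    def residual_ss(self, tv_ke, tv_ec50, om_ke, om_ec50, z,
                    mech, step_h) -> np.ndarray:
        """Per-patient sum of squared log residuals.

        The lognormal log-likelihood decomposes as
        ``-ss / (2 sigma^2) - n_obs log(sigma) + const``, so caching ``ss``
        makes sigma updates free of simulations.
        """
        ke = tv_ke * self.ke_mult * np.exp(om_ke * z[:, 0])
        ec50 = tv_ec50 * self.ec50_mult * np.exp(om_ec50 * z[:, 1])
        params = ParameterArrays(
            ka=np.full(self.n, mech.ka), ke=ke,
            V=np.full(self.n, mech.V), EC50=ec50,
            gamma=np.full(self.n, mech.gamma),
            ktr=np.full(self.n, self.n_transit / mech.MTT),
            n_transit=self.n_transit,
            inr_base=np.full(self.n, mech.inr_base),
            inr_max=np.full(self.n, mech.inr_max),
            lam=np.full(self.n, mech.lam))
        pred = simulate_cohort_inr(params, self.dose_times, self.doses,
                                   self.obs_times, step_h=step_h,
                                   observable=self.observable)
        log_pred = np.log(np.maximum(pred, 1e-10))
        res2 = (self.log_obs - log_pred) ** 2
        return np.where(self.mask, res2, 0.0).sum(axis=1)


# ---------------------------------------------------------------------------
# hierarchical posterior


@dataclass
class HierarchicalPosterior:
    """Population-level posterior draws plus convergence diagnostics."""

    param_names: tuple
    draws: np.ndarray            # (chains, draws, 5), natural scale
    rhat: dict
    ess: dict
    config: CTConfig
    converged: bool = True
    accept_rates: dict = field(default_factory=dict)

    def posterior_mean(self) -> dict:
        flat = self.draws.reshape(-1, self.draws.shape[-1])
        return dict(zip(self.param_names, flat.mean(axis=0)))

    def credible_interval(self, name: str, level: float = 0.90):
        j = self.param_names.index(name)
        flat = self.draws[:, :, j].ravel()
        a = 100 * (1 - level) / 2
        return tuple(np.percentile(flat, [a, 100 - a]))

    @property
    def sigma_hat(self) -> float:
        return self.posterior_mean()["sigma"]

    def point_estimate(self) -> PopulationParameters:
        """Posterior-mean population model for downstream individualisation.

        Fitted typical values and omegas replace the configured ones; the
        structural parameters and covariate multipliers the fit conditioned
        on are carried over unchanged.
        """
        mean = self.posterior_mean()
        base = PopulationParameters.from_config(self.config.mechanistic,
                                                self.config.population)
        typical = base.typical.with_(ke=mean["tv_ke"], EC50=mean["tv_EC50"])
        if self.config.pkpd.misspecify == "coarse_transit":
            typical = typical.with_(n_transit=1)
        omegas = dict(base.omegas)
        omegas["ke"] = mean["omega_ke"]
        omegas["EC50"] = mean["omega_EC50"]
        return PopulationParameters(
            typical=typical, cyp2c9_ke_mult=base.cyp2c9_ke_mult,
            vkorc1_ec50_mult=base.vkorc1_ec50_mult,
            age_slope=base.age_slope, omegas=omegas)

    def save(self, path) -> None:
        payload = {
            "param_names": list(self.param_names),
            "draws": self.draws.tolist(),
            "rhat": self.rhat, "ess": self.ess,
            "converged": self.converged,
            "accept_rates": self.accept_rates,
            "config": self.config.to_dict(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "HierarchicalPosterior":
        payload = json.loads(Path(path).read_text())
        return cls(param_names=tuple(payload["param_names"]),
                   draws=np.array(payload["draws"]),
                   rhat=payload["rhat"], ess=payload["ess"],
                   config=CTConfig.from_dict(payload["config"]),
                   converged=payload["converged"],
                   accept_rates=payload["accept_rates"])


def _default_prior(config: CTConfig):
    """Weakly informative lognormal priors centred on the config values."""
    mech, fit = config.mechanistic, config.pkpd
    centres = np.log([mech.ke, mech.EC50, 0.2, 0.2, 0.1])
    sds = np.full(5, fit.prior_log_sd)
    return centres, sds


def fit_population(datasets, config: CTConfig, rng_seed,
                   priors=None, n_chains: int | None = None,
                   n_warmup: int | None = None,
                   n_draws: int | None = None,
                   step_h: float = 1.0) -> HierarchicalPosterior:
    """Hierarchical Bayesian fit of the population model to trial data.

    Sampling alternates an adaptive-covariance Metropolis update of the
    population block ``(tv_ke, tv_EC50, omega_ke, omega_EC50, sigma)`` (on
    the log scale) with elementwise Metropolis updates of the per-patient
    standard-normal random effects, vectorised across patients.  Split-chain
    R-hat and effective sample sizes are computed with arviz; non-convergence
    produces a flagged posterior and a warning, never a silent success.
    """
    import arviz as az

    fit_cfg = config.pkpd
    n_chains = n_chains or fit_cfg.n_chains
    n_warmup = n_warmup if n_warmup is not None else fit_cfg.n_warmup
    n_draws = n_draws or fit_cfg.n_draws
    centres, prior_sds = priors if priors is not None \
        else _default_prior(config)
    mech = config.mechanistic

    blocks = [_Block(ds, config) for ds in datasets]
    n_pats = [b.n for b in blocks]
    n_total = sum(n_pats)
    n_obs = np.concatenate([b.mask.sum(axis=1) for b in blocks])
    ll_const = np.concatenate(
        [-(np.where(b.mask, b.log_obs, 0.0).sum(axis=1))
         - 0.5 * b.mask.sum(axis=1) * _LOG2PI for b in blocks])

    def ss_vector(theta_log, z):
        tv_ke, tv_ec50, om_ke, om_ec50 = np.exp(theta_log[:4])
        out, start = np.empty(n_total), 0
        for b in blocks:
            out[start:start + b.n] = b.residual_ss(
                tv_ke, tv_ec50, om_ke, om_ec50,
                z[start:start + b.n], mech, step_h)
            start += b.n
        return out

    def ll_from_ss(ss, log_sigma):
        return (-0.5 * ss * np.exp(-2.0 * log_sigma)
                - n_obs * log_sigma + ll_const)

    def log_prior_theta(theta_log):
        return float(-0.5 * (((theta_log - centres) / prior_sds) ** 2).sum())

    total = n_warmup + n_draws
    all_draws = np.empty((n_chains, n_draws, 5))
    accept = {"theta": [], "z": []}
    master = np.random.SeedSequence(rng_seed)
    for chain, chain_seed in enumerate(master.spawn(n_chains)):
        rng = np.random.default_rng(chain_seed)
        theta_log = centres + 0.1 * rng.standard_normal(5)
        z = np.zeros((n_total, 2))
        ss_res = ss_vector(theta_log, z)
        lp_theta = log_prior_theta(theta_log)

        hist = np.empty((total, 5))
        scale = 0.05
        cov = np.eye(4) * scale ** 2
        acc_t = acc_z = 0
        for sweep in range(total):
            # structural population block (typical values and omegas)
            prop = theta_log.copy()
            prop[:4] = rng.multivariate_normal(theta_log[:4], cov)
            ss_prop = ss_vector(prop, z)
            lp_prop = log_prior_theta(prop)
            delta = (ll_from_ss(ss_prop, theta_log[4]).sum() + lp_prop
                     - ll_from_ss(ss_res, theta_log[4]).sum() - lp_theta)
            if np.log(rng.random()) < delta:
                theta_log, ss_res, lp_theta = prop, ss_prop, lp_prop
                acc_t += 1
            hist[sweep] = theta_log
            if sweep >= 100:
                emp = np.cov(hist[max(0, sweep - 800):sweep + 1, :4].T)
                cov = (2.38 ** 2 / 4) * emp + 1e-8 * np.eye(4)

            # random-effects block (elementwise accept across patients)
            z_prop = z + 0.4 * rng.standard_normal(z.shape)
            ss_prop = ss_vector(theta_log, z_prop)
            delta = (ll_from_ss(ss_prop, theta_log[4])
                     - ll_from_ss(ss_res, theta_log[4])
                     - 0.5 * (z_prop ** 2).sum(axis=1)
                     + 0.5 * (z ** 2).sum(axis=1))
            take = np.log(rng.random(n_total)) < delta
            z[take] = z_prop[take]
            ss_res[take] = ss_prop[take]
            acc_z += take.mean()

            # sigma updates reuse the cached residuals (no simulation)
            for _ in range(5):
                prop_s = theta_log[4] + 0.2 * rng.standard_normal()
                delta = (ll_from_ss(ss_res, prop_s).sum()
                         - ll_from_ss(ss_res, theta_log[4]).sum()
                         - ((prop_s - centres[4]) ** 2
                            - (theta_log[4] - centres[4]) ** 2)
                         / (2 * prior_sds[4] ** 2))
                if np.log(rng.random()) < delta:
                    theta_log[4] = prop_s

            # interweaving moves: reparameterisation updates that leave every
            # individual's parameters (hence the likelihood) unchanged, which
            # breaks the funnel-shaped correlation between the population
            # block and the random effects
            for j, col in ((0, 0), (1, 1)):  # (typical value, its z column)
                om = np.exp(theta_log[2 + col])
                # translate the typical value, shifting z to compensate
                eps = 0.2 * rng.standard_normal()
                z_new = z[:, col] - eps / om
                delta = (-((theta_log[j] + eps - centres[j]) ** 2
                           - (theta_log[j] - centres[j]) ** 2)
                         / (2 * prior_sds[j] ** 2)
                         - 0.5 * (z_new ** 2 - z[:, col] ** 2).sum())
                if np.log(rng.random()) < delta:
                    theta_log[j] += eps
                    z[:, col] = z_new
                # rescale omega, scaling z to keep psi fixed (the Jacobian
                # of the deterministic z map enters the ratio)
                eps = 0.2 * rng.standard_normal()
                new_log_om = theta_log[2 + col] + eps
                ratio = np.exp(theta_log[2 + col] - new_log_om)
                z_new = z[:, col] * ratio
                delta = (-((new_log_om - centres[2 + col]) ** 2
                           - (theta_log[2 + col] - centres[2 + col]) ** 2)
                         / (2 * prior_sds[2 + col] ** 2)
                         - 0.5 * (z_new ** 2 - z[:, col] ** 2).sum()
                         + n_total * np.log(ratio))
                if np.log(rng.random()) < delta:
                    theta_log[2 + col] = new_log_om
                    z[:, col] = z_new
            lp_theta = log_prior_theta(theta_log)

            if sweep >= n_warmup:
                all_draws[chain, sweep - n_warmup] = np.exp(theta_log)
        accept["theta"].append(acc_t / total)
        accept["z"].append(acc_z / total)

    idata = az.from_dict(posterior={
        name: all_draws[:, :, j] for j, name in enumerate(PARAM_NAMES)})
    rhat = {k: float(v.values) for k, v in az.rhat(idata).items()}
    ess = {k: float(v.values) for k, v in az.ess(idata).items()}
    converged = all(v < 1.05 for v in rhat.values())
    posterior = HierarchicalPosterior(
        param_names=PARAM_NAMES, draws=all_draws, rhat=rhat, ess=ess,
        config=config, converged=converged, accept_rates={
            k: float(np.mean(v)) for k, v in accept.items()})
    if not converged:
        warnings.warn(
            f"population fit not converged (max R-hat "
            f"{max(rhat.values()):.3f}); posterior flagged", stacklevel=2)
    return posterior


# ---------------------------------------------------------------------------
# individual MAP fit


@dataclass
class IndividualPosterior:
    psi_hat: IndividualParameters
    z_hat: np.ndarray
    chi: CovariateProfile
    record: MonitoringRecord
    sigma: float
    neg_log_posterior: float
    theta: PopulationParameters


def _predict_inr(psis_typical: IndividualParameters, omegas, z_matrix,
                 dose_times, doses, obs_times, step_h) -> np.ndarray:
    """INR predictions for a batch of random-effect vectors (one patient)."""
    n = len(z_matrix)
    t = psis_typical
    ke = t.ke * np.exp(omegas[0] * z_matrix[:, 0])
    ec50 = t.EC50 * np.exp(omegas[1] * z_matrix[:, 1])
    params = ParameterArrays(
        ka=np.full(n, t.ka), ke=ke, V=np.full(n, t.V), EC50=ec50,
        gamma=np.full(n, t.gamma), ktr=np.full(n, t.ktr),
        n_transit=t.n_transit, inr_base=np.full(n, t.inr_base),
        inr_max=np.full(n, t.inr_max), lam=np.full(n, t.lam))
    return simulate_cohort_inr(params, dose_times, np.tile(doses, (n, 1)),
                               obs_times, step_h=step_h)


def fit_individual_map(posterior: HierarchicalPosterior,
                       chi: CovariateProfile, record: MonitoringRecord,
                       step_h: float = 1.0, z_start=None,
                       refine_rounds: int = 3) -> IndividualPosterior:
    """MAP estimate of one patient's random effects from monitoring data.

    With no monitoring data the MAP equals the subpopulation typical value.
    Otherwise the objective (lognormal likelihood plus standard-normal prior
    on the random effects) is minimised gradient-free: a coarse multi-start
    grid over the random-effect plane followed by iterated shrinking-grid
    refinement, every round evaluated as one vectorised batch.  A warm start
    (``z_start``) skips the coarse stage.
    """
    theta = posterior.point_estimate()
    typical = typical_parameters(theta, chi)
    omegas = np.array([theta.omegas.get("ke", 0.0),
                       theta.omegas.get("EC50", 0.0)])
    sigma = posterior.sigma_hat
    if not record.measurements:
        return IndividualPosterior(typical, np.zeros(2), chi, record,
                                   sigma, 0.0, theta)

    obs = np.array([v for v, _ in record.measurements])
    obs_times = np.array([t for _, t in record.measurements])
    regimen = record.regimen_so_far
    dose_times = regimen.times if len(regimen.events) else np.array([0.0])
    doses = regimen.doses if len(regimen.events) else np.array([0.0])
    log_obs = np.log(obs)

    def neg_log_post_batch(z_matrix):
        pred = _predict_inr(typical, omegas, z_matrix, dose_times, doses,
                            obs_times, step_h)
        res = (log_obs[None, :] - np.log(np.maximum(pred, 1e-10))) / sigma
        nll = 0.5 * (res ** 2).sum(axis=1) + len(obs) * np.log(sigma)
        return nll + 0.5 * (z_matrix ** 2).sum(axis=1)

    if z_start is not None:
        best_z = np.asarray(z_start, dtype=float)
        best_val = float(neg_log_post_batch(best_z[None, :])[0])
        spans = (0.3, 0.1)[:refine_rounds]  # warm: local refinement only
    else:
        g = np.linspace(-1.5, 1.5, 7)
        starts = np.array(np.meshgrid(g, g)).reshape(2, -1).T
        vals = neg_log_post_batch(starts)
        k = int(np.argmin(vals))
        best_z, best_val = starts[k], float(vals[k])
        spans = (0.5, 0.15, 0.05)[:refine_rounds]
    for span in spans:
        g = np.linspace(-span, span, 5)
        local = best_z + np.array(np.meshgrid(g, g)).reshape(2, -1).T
        vals = neg_log_post_batch(local)
        k = int(np.argmin(vals))
        if vals[k] < best_val:
            best_z, best_val = local[k], float(vals[k])
    psi_hat = typical.with_(ke=typical.ke * np.exp(omegas[0] * best_z[0]),
                            EC50=typical.EC50 * np.exp(omegas[1] * best_z[1]))
    return IndividualPosterior(psi_hat, best_z, chi, record, sigma,
                               best_val, theta)


# ---------------------------------------------------------------------------
# regimen optimisation


def optimise_regimen(individual: IndividualPosterior, y_star: float,
                     horizon_days: int, dose_bounds=(0.0, 30.0),
                     past_regimen: DosingRegimen | None = None,
                     start_day: int = 0, popsize: int = 8,
                     n_iter: int = 200, rng=None, warm_start=None,
                     dose_step: float = 0.5,
                     step_h: float = 1.0) -> DosingRegimen:
    """CMA-ES daily doses minimising squared INR-target error.

    Simulates the individual's predicted response from treatment start (the
    already-administered regimen is fixed) and optimises the remaining daily
    doses against daily INR predictions.  A flat objective (no drug effect)
    falls back to an all-zero regimen.
    """
    if horizon_days < 1:
        raise ValueError("horizon_days must be >= 1")
    psi = individual.psi_hat
    past_regimen = past_regimen or DosingRegimen()
    future_times = 24.0 * (start_day + np.arange(horizon_days))

    # integrate through the administered regimen once; candidate regimens
    # only differ in the future, so they all restart from this state
    pre = CohortEngine(ParameterArrays([psi]), step_h=step_h)
    for dose, t in past_regimen.events:
        if t < future_times[0]:
            pre.advance(np.array([t]))
            pre.apply_dose(np.array([dose]))
    pre.advance(np.array([future_times[0]]))
    state0, t0 = pre.state[0], float(pre.t[0])

    def _batch_params(n):
        return ParameterArrays(
            ka=np.full(n, psi.ka), ke=np.full(n, psi.ke),
            V=np.full(n, psi.V), EC50=np.full(n, psi.EC50),
            gamma=np.full(n, psi.gamma), ktr=np.full(n, psi.ktr),
            n_transit=psi.n_transit,
            inr_base=np.full(n, psi.inr_base),
            inr_max=np.full(n, psi.inr_max), lam=np.full(n, psi.lam))

    def objective(x):
        n = len(x)
        eng = CohortEngine(_batch_params(n), step_h=step_h)
        eng.state = np.tile(state0, (n, 1))
        eng.t = np.full(n, t0)
        sq_err = np.zeros(n)
        for k in range(horizon_days):
            eng.apply_dose(x[:, k])
            eng.advance(eng.t + 24.0)
            sq_err += (eng.inr() - y_star) ** 2
        return sq_err

    # degenerate objective: no achievable drug effect
    probe = np.vstack([np.zeros(horizon_days),
                       np.full(horizon_days, dose_bounds[1])])
    probe_vals = objective(probe)
    if abs(probe_vals[1] - probe_vals[0]) < 1e-9:
        zeros = tuple((0.0, t) for t in future_times)
        return DosingRegimen(zeros)

    x0 = np.asarray(warm_start, dtype=float) if warm_start is not None \
        else np.full(horizon_days, 5.0)
    sigma0 = 1.5 if warm_start is not None else 4.0
    f0 = float(objective(x0[None, :])[0])
    x_best, f_best, history = cma_es_minimise(
        objective, x0, sigma0, dose_bounds, n_iter=n_iter,
        popsize=popsize, rng=rng)
    if f_best >= f0:  # never return worse than the starting regimen
        x_best, f_best = x0, f0
        if n_iter >= 50:
            warnings.warn("regimen optimiser made no improvement over "
                          "budget; returning best found", stacklevel=2)
    doses = round_dose(x_best, dose_step, dose_bounds[1])
    return DosingRegimen(tuple(zip(np.atleast_1d(doses), future_times)))


def pkpd_agent_step(posterior: HierarchicalPosterior, chi: CovariateProfile,
                    record: MonitoringRecord, y_star: float, day: int,
                    horizon_total: int = 19, rng=None,
                    n_iter: int | None = None, warm_z=None,
                    warm_regimen=None, step_h: float = 1.0):
    """One day of PKPD-guided dosing: MAP fit, regimen optimisation.

    Returns ``(dose_mg, individual, regimen)`` where ``regimen`` is the full
    predicted future regimen (logged for dosing-strategy diagnostics).
    """
    fit_cfg = posterior.config.pkpd
    individual = fit_individual_map(posterior, chi, record, step_h=step_h,
                                    z_start=warm_z)
    horizon = max(1, horizon_total - day)
    regimen = optimise_regimen(
        individual, y_star, horizon,
        dose_bounds=(0.0, posterior.config.trials.dose_max),
        past_regimen=record.regimen_so_far, start_day=day,
        popsize=fit_cfg.cma_popsize,
        n_iter=n_iter if n_iter is not None else fit_cfg.cma_iters,
        rng=rng, warm_start=warm_regimen,
        dose_step=posterior.config.trials.dose_step, step_h=step_h)
    return float(regimen.doses[0]), individual, regimen


class PKPDAgent:
    """Daily MAP-individualised, regimen-optimising dosing agent.

    Warm-starts each day's MAP fit and CMA-ES run from the previous day's
    solution for the same patient; keeps a per-patient log of predicted
    regimens for dosing-strategy diagnostics.
    """

    name = "pkpd"

    def __init__(self, posterior: HierarchicalPosterior, rng_seed=0,
                 n_iter: int | None = None, step_h: float = 2.0):
        self.posterior = posterior
        self.rng = np.random.default_rng(rng_seed)
        self.n_iter = (n_iter if n_iter is not None
                       else posterior.config.pkpd.cma_iters_trial)
        self.step_h = step_h
        self._warm: dict = {}
        self.regimen_log: dict = {}

    def propose_dose(self, chi, record, y_star, day, patient_id):
        warm_z, warm_regimen = self._warm.get(patient_id, (None, None))
        if warm_regimen is not None and len(warm_regimen) > 1:
            warm_regimen = warm_regimen[1:]
        else:
            warm_regimen = None
        n_iter = self.n_iter if warm_regimen is not None \
            else max(40, self.n_iter)
        dose, individual, regimen = pkpd_agent_step(
            self.posterior, chi, record, y_star, day,
            horizon_total=self.posterior.config.trials.mipd_days,
            rng=self.rng.integers(2 ** 31), n_iter=n_iter,
            warm_z=warm_z, warm_regimen=warm_regimen, step_h=self.step_h)
        self._warm[patient_id] = (individual.z_hat, regimen.doses)
        self.regimen_log[(patient_id, day)] = regimen
        return dose
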