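"""Configuration for the warfarin clinical-trial model and the MIPD agents.

All tunable quantities live here so that a single YAML file fully determines a
simulated trial.  Sections mirror the five components of the clinical-trial
model (mechanistic / population / iov / execution / measurement) plus trial
designs and agent hyperparameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

CYP2C9_GENOTYPES = ("*1*1", "*1*2", "*1*3", "*2*2", "*2*3", "*3*3")
VKORC1_GENOTYPES = ("GG", "GA", "AA")

REFERENCE_AGE = 71


@dataclass
class MechanisticConfig:
    """Typical-individual parameters of the reduced warfarin PKPD core.

    One-compartment PK with first-order absorption feeds an inhibitory Hill
    effect on the production input of a transit-compartment clotting-activity
    chain; INR rises as the chain activity falls.  EC50 is calibrated so the
    (GG, *1*1, 71) reference patient reaches INR 2.5 at 5 mg/day.
    """

    ka: float = 1.0          # absorption rate, 1/h
    ke: float = 0.018        # elimination rate, 1/h
    V: float = 14.0          # volume of distribution, L
    EC50: float = 1.8083     # half-maximal inhibitory concentration, mg/L
    gamma: float = 1.2       # Hill coefficient
    MTT: float = 40.0        # mean transit time of the response chain, h
    n_transit: int = 3       # transit compartments
    inr_base: float = 1.0    # drug-free INR
    inr_max: float = 19.0    # maximal INR increment
    lam: float = 2.0         # response-shape exponent
    rtol: float = 1e-6       # adaptive-solver relative tolerance
    atol: float = 1e-8       # adaptive-solver absolute tolerance
    rk4_step_h: float = 0.5  # fixed step of the vectorised cohort engine, h


@dataclass
class PopulationConfig:
    """Covariate model and lognormal inter-individual variability.

    CYP2C9 scales the elimination rate, VKORC1 scales EC50 and age modulates
    elimination linearly around the reference age of 71 years.
    """

    cyp2c9_ke_mult: dict = field(default_factory=lambda: {
        "*1*1": 1.0, "*1*2": 0.73, "*1*3": 0.40,
        "*2*2": 0.55, "*2*3": 0.35, "*3*3": 0.20,
    })
    vkorc1_ec50_mult: dict = field(default_factory=lambda: {
        "GG": 1.0, "GA": 0.60, "AA": 0.35,
    })
    age_slope: float = -0.01   # fractional change of ke per year vs age 71
    omegas: dict = field(default_factory=lambda: {
        "ke": 0.25, "EC50": 0.30, "MTT": 0.20, "V": 0.10,
    })


@dataclass
class DemographicsConfig:
    cyp2c9_freqs: dict = field(default_factory=lambda: {
        "*1*1": 0.65, "*1*2": 0.17, "*1*3": 0.10,
        "*2*2": 0.03, "*2*3": 0.03, "*3*3": 0.02,
    })
    vkorc1_freqs: dict = field(default_factory=lambda: {
        "GG": 0.36, "GA": 0.48, "AA": 0.16,
    })
    age_mean: float = 65.0
    age_sd: float = 10.0
    age_min: int = 18
    age_max: int = 100


@dataclass
class IOVConfig:
    """Day-to-day variation of the vitamin-K input multiplier eta."""

    mu_eta: float = 1.0
    sigma_eta: float = 0.1

    def __post_init__(self):
        if self.mu_eta <= 0:
            raise ValueError("mu_eta must be positive")
        if self.sigma_eta < 0:
            raise ValueError("sigma_eta must be non-negative")


@dataclass
class ExecutionConfig:
    """Exponentially distributed delays of dosing/monitoring events."""

    tau_min: float = 30.0  # mean delay in minutes

    def __post_init__(self):
        if self.tau_min < 0:
            raise ValueError("tau_min must be non-negative")


@dataclass
class MeasurementConfig:
    """Lognormal measurement noise with median equal to the model output."""

    sigma: float = 0.1
    lloq: float | None = None

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass
class TrialConfig:
    phase1_n: int = 60
    phase2_n: int = 100
    phase3_n: int = 1000
    mipd_n: int = 1000
    mipd_days: int = 19
    y_star: float = 2.5
    dose_max: float = 30.0     # mg/day cap
    dose_step: float = 0.5     # rounding granularity, mg
    report_actual_times: bool = False


@dataclass
class RegressionConfig:
    hidden_width: int = 1024
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 500
    val_fraction: float = 0.1
    patience: int = 50


@dataclass
class DeepRLConfig:
    hidden_widths: tuple = (256, 128, 64)
    n_actions: int = 58
    discount: float = 0.99
    n_step: int = 3       # multi-step returns bridge the INR response delay
    n_members: int = 3    # independent runs averaged into the final policy
    episodes: int = 6000
    horizon_days: int = 19
    epsilon_start: float = 1.0
    epsilon_end: float = 0.05
    epsilon_decay_fraction: float = 0.8
    buffer_size: int = 50_000
    batch_size: int = 64
    target_sync_every: int = 500
    learning_rate: float = 1e-4
    env_batch: int = 32
    updates_per_env_step: int = 8


@dataclass
class PKPDFitConfig:
    n_chains: int = 3
    n_warmup: int = 500
    n_draws: int = 1000
    prior_log_sd: float = 0.5      # lognormal prior SD on typical values
    omega_prior_sd: float = 0.3    # half-normal prior SD on omegas
    map_starts: int = 5
    cma_popsize: int = 8
    cma_iters: int = 200
    cma_iters_trial: int = 15      # reduced budget inside the daily trial loop
                                   # (warm-started from the previous day)
    misspecify: str | None = None  # None | 'drop_iov' | 'coarse_transit'


@dataclass
class CTConfig:
    """Top-level configuration bundling all components."""

    mechanistic: MechanisticConfig = field(default_factory=MechanisticConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    demographics: DemographicsConfig = field(default_factory=DemographicsConfig)
    iov: IOVConfig = field(default_factory=IOVConfig)
    execution: ExecutionConfig = field(default_factory=ExecutionConfig)
    measurement: MeasurementConfig = field(default_factory=MeasurementConfig)
    trials: TrialConfig = field(default_factory=TrialConfig)
    regression: RegressionConfig = field(default_factory=RegressionConfig)
    deeprl: DeepRLConfig = field(default_factory=DeepRLConfig)
    pkpd: PKPDFitConfig = field(default_factory=PKPDFitConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "CTConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "CTConfig":
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                section = raw[f.name]
                sub_cls = f.default_factory  # type: ignore[misc]
                if isinstance(section, dict):
                    sub_fields = {
                        sf.name for sf in dataclasses.fields(sub_cls())}
                    unknown = set(section) - sub_fields
                    if unknown:
                        raise ValueError(
                            f"unknown keys in config section "
                            f"'{f.name}': {sorted(unknown)}")
                    if "hidden_widths" in section:
                        section["hidden_widths"] = tuple(
                            section["hidden_widths"])
                    kwargs[f.name] = type(sub_cls())(**section)
                else:
                    kwargs[f.name] = section
        return cls(**kwargs)


def default_config() -> CTConfig:
    return CTConfig()
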