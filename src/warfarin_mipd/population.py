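"""Population model: covariates, subpopulation typical values and IIV.

Inter-individual variability follows a nonlinear mixed-effects structure:
covariates shift the typical mechanistic parameters (CYP2C9 and age act on
the elimination rate, VKORC1 acts on EC50) and lognormal random effects add
the variability not explained by covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (CYP2C9_GENOTYPES, REFERENCE_AGE, VKORC1_GENOTYPES,
                     DemographicsConfig, MechanisticConfig, PopulationConfig)
from .dynamics import IndividualParameters

# parameters that may carry a lognormal random effect
RANDOM_EFFECT_FIELDS = ("ka", "ke", "V", "EC50", "gamma", "MTT")


@dataclass(frozen=True)
class CovariateProfile:
    """Observable patient characteristics: genotypes and age."""

    cyp2c9: str
    vkorc1: str
    age: int

    def __post_init__(self):
        if self.cyp2c9 not in CYP2C9_GENOTYPES:
            raise ValueError(f"unknown CYP2C9 genotype {self.cyp2c9!r}; "
                             f"expected one of {CYP2C9_GENOTYPES}")
        if self.vkorc1 not in VKORC1_GENOTYPES:
            raise ValueError(f"unknown VKORC1 genotype {self.vkorc1!r}; "
                             f"expected one of {VKORC1_GENOTYPES}")
        if not 18 <= int(self.age):
            raise ValueError("age must be an integer >= 18")


REFERENCE_COVARIATES = CovariateProfile("*1*1", "GG", REFERENCE_AGE)


@dataclass(frozen=True)
class PopulationParameters:
    """Typical reference parameters plus covariate effects and omegas."""

    typical: IndividualParameters
    cyp2c9_ke_mult: dict
    vkorc1_ec50_mult: dict
    age_slope: float
    omegas: dict = field(default_factory=dict)

    def __post_init__(self):
        for table, ref in ((self.cyp2c9_ke_mult, "*1*1"),
                           (self.vkorc1_ec50_mult, "GG")):
            if any(v <= 0 for v in table.values()):
                raise ValueError("multipliers must be > 0")
            if abs(table[ref] - 1.0) > 1e-12:
                raise ValueError(f"reference multiplier for {ref} must be 1")
        if any(w < 0 for w in self.omegas.values()):
            raise ValueError("omegas must be >= 0")
        unknown = set(self.omegas) - set(RANDOM_EFFECT_FIELDS)
        if unknown:
            raise ValueError(f"omegas refer to unknown parameters {unknown}")

    @classmethod
    def from_config(cls, mech: MechanisticConfig,
                    pop: PopulationConfig) -> "PopulationParameters":
        typical = IndividualParameters(
            ka=mech.ka, ke=mech.ke, V=mech.V, EC50=mech.EC50,
            gamma=mech.gamma, MTT=mech.MTT, n_transit=mech.n_transit,
            inr_base=mech.inr_base, inr_max=mech.inr_max, lam=mech.lam)
        return cls(typical=typical,
                   cyp2c9_ke_mult=dict(pop.cyp2c9_ke_mult),
                   vkorc1_ec50_mult=dict(pop.vkorc1_ec50_mult),
                   age_slope=pop.age_slope,
                   omegas=dict(pop.omegas))


@dataclass(frozen=True)
class Demographics:
    """Sampling distributions of the covariates in a cohort."""

    cyp2c9_freqs: dict
    vkorc1_freqs: dict
    age_mean: float = 65.0
    age_sd: float = 10.0
    age_min: int = 18
    age_max: int = 100

    def __post_init__(self):
        for name, table, labels in (
                ("cyp2c9_freqs", self.cyp2c9_freqs, CYP2C9_GENOTYPES),
                ("vkorc1_freqs", self.vkorc1_freqs, VKORC1_GENOTYPES)):
            if set(table) != set(labels):
                raise ValueError(f"{name} must cover exactly {labels}")
            if abs(sum(table.values()) - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1")

    @classmethod
    def from_config(cls, cfg: DemographicsConfig) -> "Demographics":
        return cls(cyp2c9_freqs=dict(cfg.cyp2c9_freqs),
                   vkorc1_freqs=dict(cfg.vkorc1_freqs),
                   age_mean=cfg.age_mean, age_sd=cfg.age_sd,
                   age_min=cfg.age_min, age_max=cfg.age_max)

    def sample_covariates(self, n: int, rng: np.random.Generator):
        cyp = rng.choice(list(self.cyp2c9_freqs),
                         p=list(self.cyp2c9_freqs.values()), size=n)
        vko = rng.choice(list(self.vkorc1_freqs),
                         p=list(self.vkorc1_freqs.values()), size=n)
        ages = np.empty(n, dtype=int)
        todo = np.arange(n)
        while todo.size:  # rejection sampling for the truncation
            draw = np.rint(rng.normal(self.age_mean, self.age_sd,
                                      size=todo.size)).astype(int)
            ok = (draw >= self.age_min) & (draw <= self.age_max)
            ages[todo[ok]] = draw[ok]
            todo = todo[~ok]
        return [CovariateProfile(str(c), str(v), int(a))
                for c, v, a in zip(cyp, vko, ages)]


def typical_parameters(theta: PopulationParameters,
                       chi: CovariateProfile) -> IndividualParameters:
    """Subpopulation-typical parameters for a covariate profile.

    ke is scaled by the CYP2C9 multiplier and linearly by age around the
    reference age; EC50 is scaled by the VKORC1 multiplier.
    """
    try:
        ke_mult = theta.cyp2c9_ke_mult[chi.cyp2c9]
        ec50_mult = theta.vkorc1_ec50_mult[chi.vkorc1]
    except KeyError as err:
        raise ValueError(f"unknown genotype label {err.args[0]!r}") from err
    age_factor = 1.0 + theta.age_slope * (chi.age - REFERENCE_AGE)
    if age_factor <= 0:
        raise ValueError("age effect drives ke non-positive")
    return theta.typical.with_(
        ke=theta.typical.ke * ke_mult * age_factor,
        EC50=theta.typical.EC50 * ec50_mult)


def sample_individual(theta: PopulationParameters, chi: CovariateProfile,
                      rng) -> IndividualParameters:
    """Draw one individual: typical value times lognormal random effects."""
    rng = np.random.default_rng(rng)
    typ = typical_parameters(theta, chi)
    updates = {}
    for name in RANDOM_EFFECT_FIELDS:
        omega = theta.omegas.get(name, 0.0)
        if omega > 0:
            updates[name] = getattr(typ, name) * float(
                np.exp(omega * rng.standard_normal()))
    return typ.with_(**updates) if updates else typ


def sample_cohort(theta: PopulationParameters, demographics: Demographics,
                  n: int, rng):
    """Sample covariates and parameters for ``n`` virtual patients."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    chis = demographics.sample_covariates(n, rng)
    return [(chi, sample_individual(theta, chi, rng)) for chi in chis]


def covariates_frame(chis) -> pd.DataFrame:
    """Tidy covariates table (ID, CYP2C9, VKORC1, Age)."""
    return pd.DataFrame({
        "ID": np.arange(1, len(chis) + 1),
        "CYP2C9": [c.cyp2c9 for c in chis],
        "VKORC1": [c.vkorc1 for c in chis],
        "Age": [c.age for c in chis],
    })
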