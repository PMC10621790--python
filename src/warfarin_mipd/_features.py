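"""Shared covariate/INR feature encoding for the learned agents."""

from __future__ import annotations

import numpy as np

from .config import CYP2C9_GENOTYPES, VKORC1_GENOTYPES

N_FEATURES = len(CYP2C9_GENOTYPES) + len(VKORC1_GENOTYPES) + 2


def encode_features(cyp2c9, vkorc1, age, inr, age_loc: float,
                    age_scale: float) -> np.ndarray:
    """(n, 11) design matrix: one-hot CYP2C9, one-hot VKORC1, z-age, INR."""
    cyp2c9 = np.atleast_1d(np.asarray(cyp2c9))
    vkorc1 = np.atleast_1d(np.asarray(vkorc1))
    age = np.atleast_1d(np.asarray(age, dtype=float))
    inr = np.atleast_1d(np.asarray(inr, dtype=float))
    n = len(cyp2c9)
    x = np.zeros((n, N_FEATURES))
    for j, g in enumerate(CYP2C9_GENOTYPES):
        x[:, j] = cyp2c9 == g
    if not np.all(x[:, :len(CYP2C9_GENOTYPES)].sum(axis=1) == 1):
        raise ValueError("unknown CYP2C9 genotype label")
    off = len(CYP2C9_GENOTYPES)
    for j, g in enumerate(VKORC1_GENOTYPES):
        x[:, off + j] = vkorc1 == g
    if not np.all(x[:, off:off + len(VKORC1_GENOTYPES)].sum(axis=1) == 1):
        raise ValueError("unknown VKORC1 genotype label")
    x[:, -2] = (age - age_loc) / age_scale
    x[:, -1] = inr
    return x
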