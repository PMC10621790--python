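"""Neural-network regression of the daily maintenance dose.

The model learns ``d* = d*(chi, y)`` from phase-III data: covariates plus the
achieved end-of-trial INR map to the maintenance dose that produced it.  At
prediction time the desired response ``y*`` is substituted for the achieved
INR, yielding a covariate-based maintenance-dose recommendation that never
updates during treatment.

Architecture: three fully connected layers; two hidden layers of width 1024
with ReLU activations and a sigmoid output scaled to [0, dose_max].
Training minimises mean squared error with Adam.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._features import N_FEATURES, encode_features
from ._nn import MLP, Adam
from .config import RegressionConfig
from .dataset import TrialDataset, maintenance_table
from .population import CovariateProfile
from .protocols import round_dose

MIN_TRAINING_ROWS = 50


class NotTrainedError(RuntimeError):
    pass


@dataclass
class RegressionModel:
    net: MLP
    age_loc: float
    age_scale: float
    dose_max: float
    seed: int
    loss_history: list = field(default_factory=list)
    trained: bool = False

    def predict(self, cyp2c9, vkorc1, age, inr) -> np.ndarray:
        if not self.trained:
            raise NotTrainedError("model must be trained before prediction")
        x = encode_features(cyp2c9, vkorc1, age, inr,
                            self.age_loc, self.age_scale)
        # the network regresses dose / dose_max through a unit sigmoid
        return self.net.forward(x)[:, 0] * self.dose_max

    def save(self, path) -> None:
        path = Path(path)
        payload = {
            "widths": self.net.widths,
            "age_loc": self.age_loc, "age_scale": self.age_scale,
            "dose_max": self.dose_max, "seed": self.seed,
            "loss_history": self.loss_history, "trained": self.trained,
            "W": [w.tolist() for w in self.net.W],
            "b": [b.tolist() for b in self.net.b],
        }
        path.write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "RegressionModel":
        payload = json.loads(Path(path).read_text())
        net = MLP(payload["widths"], head="sigmoid", head_scale=1.0, rng=0)
        net.W = [np.array(w) for w in payload["W"]]
        net.b = [np.array(b) for b in payload["b"]]
        model = cls(net=net, age_loc=payload["age_loc"],
                    age_scale=payload["age_scale"],
                    dose_max=payload["dose_max"], seed=payload["seed"],
                    loss_history=payload["loss_history"])
        model.trained = payload["trained"]
        return model


def train_regression(phase3: TrialDataset, config: RegressionConfig,
                     rng_seed, dose_max: float = 30.0) -> RegressionModel:
    """Fit the maintenance-dose network to phase-III data.

    Uses a train/validation split with early stopping on the validation MSE;
    the best-validation weights are restored.  Deterministic given the seed.
    """
    table = maintenance_table(phase3)
    if len(table) < MIN_TRAINING_ROWS:
        raise ValueError(
            f"need >= {MIN_TRAINING_ROWS} training rows, got {len(table)}")
    rng = np.random.default_rng(rng_seed)
    age = table["Age"].to_numpy(dtype=float)
    age_loc, age_scale = float(age.mean()), float(age.std() or 1.0)
    x = encode_features(table["CYP2C9"], table["VKORC1"], age,
                        table["INR"], age_loc, age_scale)
    y = table["MaintenanceDose"].to_numpy(dtype=float)[:, None] / dose_max

    perm = rng.permutation(len(x))
    n_val = max(1, int(round(config.val_fraction * len(x))))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    x_tr, y_tr, x_val, y_val = x[tr_idx], y[tr_idx], x[val_idx], y[val_idx]

    net = MLP((N_FEATURES, config.hidden_width, config.hidden_width, 1),
              head="sigmoid", head_scale=1.0, rng=rng)
    # start the sigmoid head near the mean normalised dose with small output
    # weights; a wide He-initialised head saturates the sigmoid and dies
    net.W[-1] *= 0.01
    m = float(np.clip(y_tr.mean(), 1e-3, 1 - 1e-3))
    net.b[-1][...] = np.log(m / (1.0 - m))
    opt = Adam(net.params, lr=config.learning_rate)
    best = [np.copy(p) for p in net.params]
    best_val, since_best = np.inf, 0
    losses = []
    for _ in range(config.epochs):
        order = rng.permutation(len(x_tr))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            cache: list = []
            pred = net.forward(x_tr[idx], cache)
            err = pred - y_tr[idx]
            epoch_loss += float((err ** 2).sum())
            opt.step(net.backward(cache, 2.0 * err / len(idx)))
        losses.append(epoch_loss / len(x_tr))
        val_mse = float(((net.forward(x_val) - y_val) ** 2).mean())
        if val_mse < best_val - 1e-10:
            best_val, since_best = val_mse, 0
            for dst, src in zip(best, net.params):
                dst[...] = src
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    for dst, src in zip(net.params, best):
        dst[...] = src
    model = RegressionModel(net=net, age_loc=age_loc, age_scale=age_scale,
                            dose_max=dose_max, seed=int(rng_seed),
                            loss_history=losses)
    model.trained = True
    return model


def predict_maintenance_dose(model: RegressionModel, chi: CovariateProfile,
                             y_star: float, dose_step: float = 0.5) -> float:
    """Covariate-based maintenance dose at the target response."""
    dose = float(model.predict([chi.cyp2c9], [chi.vkorc1], [chi.age],
                               [y_star])[0])
    return round_dose(dose, dose_step, model.dose_max)


class RegressionAgent:
    """Static dosing policy: the predicted maintenance dose, every day."""

    name = "regression"

    def __init__(self, model: RegressionModel, dose_step: float = 0.5):
        self.model = model
        self.dose_step = dose_step
        self._cache: dict = {}

    def propose_dose(self, chi, record, y_star, day, patient_id):
        key = (chi.cyp2c9, chi.vkorc1, chi.age, y_star)
        if key not in self._cache:
            self._cache[key] = predict_maintenance_dose(
                self.model, chi, y_star, self.dose_step)
        return self._cache[key]
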