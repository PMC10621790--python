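"""Deep Q-learning dosing agent (Double DQN).

The agent maps a Markov state — the most recent INR measurement plus the
patient's covariates — to one of 58 discrete daily doses.  It is trained
online against a treatment-response emulator (the fitted population PKPD
model with measurement noise, but no execution delays), with an
epsilon-greedy behaviour policy, an experience-replay buffer and a periodically
synchronised target network.  Action selection and evaluation are decoupled
(Double Q-learning) to curb Q-value overestimation.

The reward is the negative absolute distance of the next-day INR from the
target, ``r_t = -|INR_{t+1} - y*|``, which is maximal (zero) exactly on
target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._features import N_FEATURES, encode_features
from ._nn import MLP, Adam
from .config import DeepRLConfig
from .engine import CohortEngine, ParameterArrays
from .population import Demographics, PopulationParameters, sample_cohort

Q_DIVERGENCE_LIMIT = 1e4


def default_dose_grid(n_actions: int = 58, step: float = 0.5) -> np.ndarray:
    """Doses 0, 0.5, ..., 28.5 mg (58 values)."""
    return np.arange(n_actions) * step


@dataclass
class QNetwork:
    net: MLP
    dose_grid: np.ndarray
    age_loc: float
    age_scale: float
    seed: int
    reward_curve: list = field(default_factory=list)

    def q_values(self, states: np.ndarray) -> np.ndarray:
        return self.net.forward(states)

    def encode(self, chis, inr) -> np.ndarray:
        return encode_features([c.cyp2c9 for c in chis],
                               [c.vkorc1 for c in chis],
                               [c.age for c in chis], inr,
                               self.age_loc, self.age_scale)

    def save(self, path) -> None:
        payload = {
            "widths": self.net.widths, "dose_grid": self.dose_grid.tolist(),
            "age_loc": self.age_loc, "age_scale": self.age_scale,
            "seed": self.seed, "reward_curve": self.reward_curve,
            "W": [w.tolist() for w in self.net.W],
            "b": [b.tolist() for b in self.net.b],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "QNetwork":
        payload = json.loads(Path(path).read_text())
        net = MLP(payload["widths"], rng=0)
        net.W = [np.array(w) for w in payload["W"]]
        net.b = [np.array(b) for b in payload["b"]]
        return cls(net=net, dose_grid=np.array(payload["dose_grid"]),
                   age_loc=payload["age_loc"],
                   age_scale=payload["age_scale"], seed=payload["seed"],
                   reward_curve=payload["reward_curve"])


def select_dose(qnet: QNetwork, state: np.ndarray, epsilon: float,
                rng) -> tuple[int, float]:
    """Epsilon-greedy action; greedy ties break towards the lowest dose."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must be a probability")
    rng = np.random.default_rng(rng)
    grid = qnet.dose_grid
    if rng.random() < epsilon:
        a = int(rng.integers(len(grid)))
    else:
        q = qnet.q_values(state.reshape(1, -1))[0]
        a = int(np.argmax(q))  # first (lowest-dose) maximiser
    return a, float(grid[a])


def td_target(rewards, next_states, terminal, online: MLP, target: MLP,
              discount: float) -> np.ndarray:
    """Double-DQN regression targets.

    The online network selects the argmax action in the next state; the
    target network evaluates it: ``y = r + g * Q_tgt(s', argmax Q_on(s'))``
    for non-terminal transitions and ``y = r`` for terminal ones.
    """
    rewards = np.asarray(rewards, dtype=float)
    terminal = np.asarray(terminal, dtype=bool)
    y = rewards.copy()
    live = ~terminal
    if np.any(live):
        nxt = np.atleast_2d(next_states)[live]
        best = np.argmax(online.forward(nxt), axis=1)
        q_eval = target.forward(nxt)[np.arange(len(best)), best]
        y[live] += discount * q_eval
    return y


class PKPDEmulator:
    """Treatment-response emulator for online RL training.

    Samples virtual patients from a population model (typically the fitted
    PKPD posterior point estimate) and steps them one day per action.  The
    agent observes lognormally noisy INR values; execution delays and
    inter-occasion variability are not part of the emulator — the full
    clinical-trial model is only used at evaluation time.
    """

    def __init__(self, theta: PopulationParameters,
                 demographics: Demographics, measurement_sigma: float = 0.1,
                 step_h: float = 0.5):
        self.theta = theta
        self.demographics = demographics
        self.sigma = measurement_sigma
        self.step_h = step_h
        self._eng: CohortEngine | None = None
        self.chis = []

    def reset(self, n: int, rng) -> np.ndarray:
        """Sample ``n`` fresh patients; returns their noisy baseline INR."""
        self._rng = np.random.default_rng(rng)
        cohort = sample_cohort(self.theta, self.demographics, n, self._rng)
        self.chis = [c for c, _ in cohort]
        self._eng = CohortEngine(ParameterArrays([p for _, p in cohort]),
                                 step_h=self.step_h)
        return self._measure()

    def _measure(self) -> np.ndarray:
        inr = np.maximum(self._eng.inr(), 1e-6)
        noise = np.exp(self.sigma * self._rng.standard_normal(len(inr)))
        return inr * noise

    def step(self, doses_mg: np.ndarray) -> np.ndarray:
        """Administer today's doses, advance 24 h, return tomorrow's INR."""
        if self._eng is None:
            raise RuntimeError("reset() must be called before step()")
        self._eng.apply_dose(np.asarray(doses_mg, dtype=float))
        self._eng.advance(self._eng.t + 24.0)
        return self._measure()


class _Replay:
    def __init__(self, capacity: int, state_dim: int):
        self.capacity = capacity
        self.s = np.zeros((capacity, state_dim), dtype=np.float32)
        self.a = np.zeros(capacity, dtype=np.int64)
        self.r = np.zeros(capacity, dtype=np.float32)
        self.s2 = np.zeros((capacity, state_dim), dtype=np.float32)
        self.term = np.zeros(capacity, dtype=bool)
        self.size = self.pos = 0

    def push(self, s, a, r, s2, term):
        n = len(a)
        idx = (self.pos + np.arange(n)) % self.capacity
        self.s[idx], self.a[idx], self.r[idx] = s, a, r
        self.s2[idx], self.term[idx] = s2, term
        self.pos = int((self.pos + n) % self.capacity)
        self.size = min(self.size + n, self.capacity)

    def sample(self, batch: int, rng):
        idx = rng.integers(self.size, size=batch)
        return (self.s[idx], self.a[idx], self.r[idx], self.s2[idx],
                self.term[idx])


def train_agent(emulator: PKPDEmulator, config: DeepRLConfig, rng_seed,
                y_star: float = 2.5) -> QNetwork:
    """Train the Double-DQN dose policy against the emulator.

    Episodes run in vectorised batches of patients; epsilon decays linearly
    over the first ``epsilon_decay_fraction`` of episodes.  Aborts if
    Q-values diverge.  Returns the greedy policy network with its
    mean-episode-reward curve.
    """
    rng = np.random.default_rng(rng_seed)
    grid = default_dose_grid(config.n_actions)
    n_step = max(1, int(getattr(config, "n_step", 1)))
    demo = emulator.demographics
    online = MLP((N_FEATURES,) + tuple(config.hidden_widths) +
                 (config.n_actions,), rng=rng)
    target = MLP(online.widths, rng=0)
    target.copy_from(online)
    # Polyak-averaged copy: the returned greedy policy reads this network,
    # which smooths the late-training oscillation of near-tied Q-values
    ema = MLP(online.widths, rng=0)
    ema.copy_from(online)
    ema_tau = 0.999
    qnet = QNetwork(net=online, dose_grid=grid, age_loc=demo.age_mean,
                    age_scale=demo.age_sd, seed=int(rng_seed))
    opt = Adam(online.params, lr=config.learning_rate)
    buffer = _Replay(config.buffer_size, N_FEATURES)

    episodes_done = updates = 0
    decay_until = max(1, int(config.episodes * config.epsilon_decay_fraction))
    while episodes_done < config.episodes:
        n_env = min(config.env_batch, config.episodes - episodes_done)
        inr = emulator.reset(n_env, rng.integers(2 ** 31))
        states = qnet.encode(emulator.chis, inr).astype(np.float32)
        frac = min(1.0, episodes_done / decay_until)
        eps = (config.epsilon_start +
               frac * (config.epsilon_end - config.epsilon_start))
        ep_states = [states]
        ep_actions, ep_rewards = [], []
        for day in range(config.horizon_days):
            q = online.forward(states)
            if np.max(np.abs(q)) > Q_DIVERGENCE_LIMIT:
                raise RuntimeError("Q-values diverged during training")
            actions = np.argmax(q, axis=1)
            explore = rng.random(n_env) < eps
            actions[explore] = rng.integers(len(grid),
                                            size=int(explore.sum()))
            inr = emulator.step(grid[actions])
            states = qnet.encode(emulator.chis, inr).astype(np.float32)
            ep_states.append(states)
            ep_actions.append(actions)
            ep_rewards.append(-np.abs(inr - y_star))
            if buffer.size >= config.batch_size:
                for _ in range(config.updates_per_env_step):
                    s, a, r, s2, term = buffer.sample(config.batch_size, rng)
                    targets = td_target(r, s2, term, online, target,
                                        config.discount ** n_step)
                    cache: list = []
                    q_pred = online.forward(s, cache)
                    grad = np.zeros_like(q_pred)
                    rows = np.arange(len(a))
                    grad[rows, a] = 2.0 * (q_pred[rows, a] - targets) / len(a)
                    opt.step(online.backward(cache, grad))
                    updates += 1
                    for p_ema, p_on in zip(ema.params, online.params):
                        p_ema *= ema_tau
                        p_ema += (1.0 - ema_tau) * p_on
                    if updates % config.target_sync_every == 0:
                        target.copy_from(online)
        # n-step returns: credit each dose with the discounted rewards of
        # the following days, bridging the delayed INR response
        horizon = config.horizon_days
        rewards_arr = np.stack(ep_rewards)            # (H, n_env)
        for t in range(horizon):
            last = min(t + n_step, horizon)
            ret = np.zeros(n_env)
            for k in range(last - 1, t - 1, -1):
                ret = rewards_arr[k] + config.discount * ret
            terminal = np.full(n_env, last == horizon)
            buffer.push(ep_states[t], ep_actions[t], ret,
                        ep_states[last], terminal)
        episodes_done += n_env
        qnet.reward_curve.append(float(rewards_arr.sum(axis=0).mean()))
    qnet.net = ema
    return qnet


class QEnsemble:
    """Q-value average of independently trained networks.

    Individual DQN runs leave small seed-dependent wiggles in regions where
    many doses have near-identical value (a consequence of the delayed INR
    response); averaging the Q-surfaces of a few independent runs cancels
    them, yielding a smoother greedy dose function.  Exposes the same
    read-only interface as :class:`QNetwork`.
    """

    def __init__(self, members):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = list(members)
        self.dose_grid = self.members[0].dose_grid

    def encode(self, chis, inr) -> np.ndarray:
        return self.members[0].encode(chis, inr)

    def q_values(self, states: np.ndarray) -> np.ndarray:
        return np.mean([m.q_values(states) for m in self.members], axis=0)

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(self.members):
            m.save(path / f"member_{i}.json")

    @classmethod
    def load(cls, path) -> "QEnsemble":
        files = sorted(Path(path).glob("member_*.json"))
        return cls([QNetwork.load(f) for f in files])


def train_ensemble(emulator: PKPDEmulator, config: DeepRLConfig, rng_seed,
                   y_star: float = 2.5, n_members: int = 3) -> QEnsemble:
    """Train ``n_members`` independent DQNs and average their Q-values."""
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(rng_seed).spawn(n_members)]
    return QEnsemble([train_agent(emulator, config, s, y_star=y_star)
                      for s in seeds])


def policy_slice(qnet, chi, inr_grid) -> np.ndarray:
    """Greedy dose for each INR value on a grid, for one covariate profile.

    The diagnostic behind dose-function plots: a sensible policy gives large
    doses below the therapeutic range and small doses above it.
    """
    inr_grid = np.asarray(inr_grid, dtype=float)
    states = qnet.encode([chi] * len(inr_grid), inr_grid)
    actions = np.argmax(qnet.q_values(states), axis=1)
    return qnet.dose_grid[actions]


class RLAgent:
    """Greedy DQN policy over the latest INR measurement."""

    name = "deeprl"

    def __init__(self, qnet):  # QNetwork or QEnsemble
        self.qnet = qnet

    def propose_dose(self, chi, record, y_star, day, patient_id):
        inr = record.latest_inr
        if inr is None:
            raise ValueError("RL agent requires at least one INR measurement")
        state = self.qnet.encode([chi], [inr])
        a = int(np.argmax(self.qnet.q_values(state)[0]))
        return float(self.qnet.dose_grid[a])
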