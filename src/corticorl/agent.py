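"""Temporal-difference actor-critic on logged ICU trajectories.

Two distinct networks: an actor mapping the daily state vector to softmax
probabilities over the five dose actions, and a critic estimating the state
value. Training is offline: transitions are replayed in shuffled batches;
the critic minimizes the squared one-step TD error
``delta = r + gamma * V(s') - V(s)`` (semi-gradient, V(terminal) = 0) and
the actor ascends ``delta * grad log pi(a|s)`` with a linearly decayed
entropy bonus. No importance correction is applied inside training; the
off-policy evaluation module quantifies the resulting policy instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._mlp import MLP, SGDMomentum, softmax

N_ACTIONS = 5


@dataclass
class TrainConfig:
    gamma: float = 0.99
    lr_actor: float = 1e-4
    lr_critic: float = 1e-3
    epochs: int = 300
    batch_size: int = 256
    seed: int = 0
    entropy_coef: float = 1e-2
    final_lr_fraction: float = 1.0   # <1 anneals learning rates linearly
    hidden: tuple = (64, 64)
    momentum: float = 0.9
    plateau_window: int = 25
    plateau_tol: float = 1e-3

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr_actor <= 0 or self.lr_critic <= 0:
            raise ValueError("learning rates must be positive")
        if self.entropy_coef < 0:
            raise ValueError("entropy_coef must be >= 0")


@dataclass
class ActorCriticModel:
    """Stochastic 5-action policy (actor) plus state-value estimator (critic)."""

    actor: MLP
    critic: MLP
    feature_names: list = field(default_factory=list)

    @classmethod
    def initialize(cls, n_features: int, hidden=(64, 64), seed: int = 0,
                   feature_names=None) -> "ActorCriticModel":
        actor = MLP(sizes=(n_features, *hidden, N_ACTIONS), seed=seed)
        critic = MLP(sizes=(n_features, *hidden, 1), seed=seed + 1)
        return cls(actor=actor, critic=critic,
                   feature_names=list(feature_names or []))

    def policy_probs(self, states: np.ndarray) -> np.ndarray:
        return softmax(self.actor(np.atleast_2d(states)))

    def value(self, states: np.ndarray) -> np.ndarray:
        return self.critic(np.atleast_2d(states))[:, 0]

    def to_json(self) -> str:
        return json.dumps({"actor": json.loads(self.actor.to_json()),
                           "critic": json.loads(self.critic.to_json()),
                           "feature_names": self.feature_names})

    @classmethod
    def from_json(cls, text: str) -> "ActorCriticModel":
        d = json.loads(text)
        return cls(actor=MLP.from_json(json.dumps(d["actor"])),
                   critic=MLP.from_json(json.dumps(d["critic"])),
                   feature_names=d.get("feature_names", []))

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "ActorCriticModel":
        return cls.from_json(Path(path).read_text())


def recommend(model: ActorCriticModel, state: np.ndarray):
    """Argmax action(s) of the policy; ties break toward the lower (more
    restrictive) action index."""
    probs = model.policy_probs(state)
    out = probs.argmax(axis=1)
    return int(out[0]) if np.asarray(state).ndim == 1 else out


def td_error(model: ActorCriticModel, state, reward, next_state, gamma: float) -> float:
    """One-step TD error delta = r + gamma V(s') - V(s); V(terminal) = 0."""
    v_s = float(model.value(state)[0])
    v_next = 0.0 if next_state is None else float(model.value(next_state)[0])
    return reward + gamma * v_next - v_s


@dataclass
class TrainingLog:
    relative_error: list = field(default_factory=list)
    td_loss: list = field(default_factory=list)
    action_counts: list = field(default_factory=list)
    concordance: list = field(default_factory=list)
    concordance_val: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        d = {"epoch": np.arange(1, len(self.td_loss) + 1),
             "relative_error": self.relative_error,
             "td_loss": self.td_loss,
             "concordance": self.concordance}
        for a in range(N_ACTIONS):
            d[f"action_{a}_count"] = [c[a] for c in self.action_counts]
        if self.concordance_val:
            d["concordance_val"] = self.concordance_val
        return pd.DataFrame(d)


def _flatten(trajectories):
    S, A, R, S_next, terminal = [], [], [], [], []
    for tr in trajectories:
        T = len(tr)
        for t in range(T):
            S.append(tr.states[t])
            A.append(tr.actions[t])
            R.append(tr.rewards[t])
            if t + 1 < T:
                S_next.append(tr.states[t + 1])
                terminal.append(False)
            else:
                S_next.append(np.zeros_like(tr.states[t]))
                terminal.append(True)
    return (np.asarray(S, dtype=float), np.asarray(A, dtype=int),
            np.asarray(R, dtype=float), np.asarray(S_next, dtype=float),
            np.asarray(terminal, dtype=bool))


def train(trajectories, config: TrainConfig | None = None,
          eval_trajectories=None, model: ActorCriticModel | None = None):
    """Train the actor-critic on logged trajectories.

    Returns (model, TrainingLog). Deterministic given config.seed. Logs per
    epoch: mean TD loss, relative error (mean critic loss divided by the
    first epoch's, so epoch 1 is 1.0 by definition), the action histogram
    of the argmax policy, and concordance with the logged actions. Stops
    early when the relative error plateaus. Raises RuntimeError on
    divergence (non-finite loss).
    """
    cfg = config or TrainConfig()
    if not trajectories:
        raise ValueError("training requires at least one trajectory")
    S, A, R, S_next, terminal = _flatten(trajectories)
    n, d = S.shape
    if model is None:
        names = getattr(trajectories[0], "feature_names", [])
        model = ActorCriticModel.initialize(d, hidden=cfg.hidden, seed=cfg.seed,
                                            feature_names=list(names))
    rng = np.random.default_rng(cfg.seed)
    opt_actor = SGDMomentum(model.actor, cfg.lr_actor, cfg.momentum)
    opt_critic = SGDMomentum(model.critic, cfg.lr_critic, cfg.momentum)
    log = TrainingLog()
    base_loss = None

    eval_states = None
    eval_actions = None
    if eval_trajectories:
        eval_states = np.concatenate([tr.states for tr in eval_trajectories])
        eval_actions = np.concatenate([tr.actions for tr in eval_trajectories])

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        frac = (epoch - 1) / max(cfg.epochs - 1, 1)
        beta = cfg.entropy_coef * max(0.0, 1.0 - frac)
        anneal = 1.0 + (cfg.final_lr_fraction - 1.0) * frac
        opt_actor.lr = cfg.lr_actor * anneal
        opt_critic.lr = cfg.lr_critic * anneal
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            s, a, r, sn, term = S[idx], A[idx], R[idx], S_next[idx], terminal[idx]
            B = len(idx)

            v_s, cache_c = model.critic.forward(s)
            v_next = model.critic(sn)[:, 0]
            v_next = np.where(term, 0.0, v_next)
            delta = r + cfg.gamma * v_next - v_s[:, 0]
            loss = float(np.mean(delta ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (non-finite TD loss); "
                    f"lr_critic={cfg.lr_critic}, lr_actor={cfg.lr_actor}")
            epoch_losses.append(loss)
            # semi-gradient: only V(s) receives gradient
            grad_v = (-2.0 * delta / B)[:, None]
            wg, bg = model.critic.backward(cache_c, grad_v)
            opt_critic.step(wg, bg)

            logits, cache_a = model.actor.forward(s)
            probs = softmax(logits)
            logp = np.log(np.clip(probs, 1e-12, None))
            entropy = -(probs * logp).sum(axis=1, keepdims=True)
            onehot = np.zeros_like(probs)
            onehot[np.arange(B), a] = 1.0
            # ascend delta*log pi(a|s) + beta*H  ->  descend the negative
            grad_logits = (-(delta[:, None]) * (onehot - probs)
                           + beta * probs * (logp + entropy)) / B
            wg, bg = model.actor.backward(cache_a, grad_logits)
            opt_actor.step(wg, bg)

        mean_loss = float(np.mean(epoch_losses))
        if base_loss is None:
            base_loss = mean_loss if mean_loss > 0 else 1.0
        log.td_loss.append(mean_loss)
        log.relative_error.append(mean_loss / base_loss)
        rec = model.policy_probs(S).argmax(axis=1)
        log.action_counts.append(np.bincount(rec, minlength=N_ACTIONS).tolist())
        log.concordance.append(float(np.mean(rec == A)))
        if eval_states is not None:
            rec_val = model.policy_probs(eval_states).argmax(axis=1)
            log.concordance_val.append(float(np.mean(rec_val == eval_actions)))
        w = cfg.plateau_window
        if epoch >= w:
            recent = log.relative_error[-w:]
            if max(recent) - min(recent) < cfg.plateau_tol:
                break
    return model, log


def concordance(model: ActorCriticModel, trajectories):
    """Fraction of day-states where the recommended action equals the
    logged one, plus the 5x5 confusion matrix (logged x recommended)."""
    if not trajectories:
        raise ValueError("concordance requires at least one trajectory")
    S = np.concatenate([tr.states for tr in trajectories])
    A = np.concatenate([tr.actions for tr in trajectories])
    rec = model.policy_probs(S).argmax(axis=1)
    confusion = np.zeros((N_ACTIONS, N_ACTIONS), dtype=int)
    np.add.at(confusion, (A, rec), 1)
    return float(np.mean(rec == A)), confusion
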