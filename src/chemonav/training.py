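"""Proximal policy optimization over vectorized episodes.

Episodes carry a single terminal reward (arrival speed, or a distance-based
shaping penalty on timeout).  Training alternates batched rollouts with
clipped-surrogate updates; recurrent variants replay entire episodes in
order from their zero initial hidden state (episodes are short at the
problem sizes used here, so no truncated backpropagation-through-time
windows are needed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import autodiff as F
from .autodiff import Tensor
from .environment import CellParams, EpisodeConfig, FieldParams
from .policies import NeuralPolicy, PolicySpec, forward_core, init_params
from .rollout import BatchResult, simulate_batch

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_ENTROPY_CONST = 0.5 * (1.0 + math.log(2.0 * math.pi))


class TrainingError(RuntimeError):
    """Non-finite loss or gradients; diagnostics attached."""


@dataclass(frozen=True)
class Transition:
    """One step of experience (terminal reward only on the last step)."""

    measurements: np.ndarray
    prev_action: float
    action: float
    log_prob: float
    value: float
    reward: float
    done: bool


@dataclass(frozen=True)
class PPOConfig:
    clip_epsilon: float = 0.2
    discount: float = 0.99
    gae_lambda: float = 0.95
    epochs_per_update: int = 4
    minibatch_size: int = 4096
    learning_rate: float = 3e-4
    lr_decay: bool = True
    entropy_coeff: float = 1e-3
    value_coeff: float = 0.5
    n_parallel_episodes: int = 256
    total_updates: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.clip_epsilon <= 0:
            raise ValueError("clip_epsilon must be positive")
        if not (0 < self.discount <= 1):
            raise ValueError("discount must be in (0, 1]")
        if not (0 <= self.gae_lambda <= 1):
            raise ValueError("gae_lambda must be in [0, 1]")


# ---------------------------------------------------------------------------
# Rollout collection
# ---------------------------------------------------------------------------


def collect_rollouts(
    policy: NeuralPolicy,
    config: EpisodeConfig,
    field_template: FieldParams,
    cell: CellParams,
    n_episodes: int,
    seed,
) -> BatchResult:
    """Run ``n_episodes`` stochastic episodes and record every transition.

    Per-episode random streams make the result independent of batching.
    """
    return simulate_batch(
        policy,
        config,
        field_template,
        cell,
        seed,
        n_episodes,
        deterministic=False,
        collect=True,
    )


def batch_transitions(batch: BatchResult, episode: int) -> list[Transition]:
    """Expand one recorded episode into Transition objects (terminal reward
    on the final step only)."""
    T = int(batch.lengths[episode])
    out = []
    for t in range(T):
        done = t == T - 1
        out.append(
            Transition(
                measurements=batch.measurements[episode, t].copy(),
                prev_action=float(batch.prev_actions[episode, t]),
                action=float(batch.actions[episode, t]),
                log_prob=float(batch.log_probs[episode, t]),
                value=float(batch.values[episode, t]),
                reward=float(batch.rewards[episode]) if done else 0.0,
                done=done,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Advantages
# ---------------------------------------------------------------------------


def compute_gae(
    values: np.ndarray,
    rewards: np.ndarray,
    discount: float,
    gae_lambda: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Generalized advantage estimation for one finished episode.

    Terminal bootstrap value is zero.  Returns ``(advantages, returns)``
    with ``returns = advantages + values``.
    """
    values = np.asarray(values, dtype=np.float64)
    rewards = np.asarray(rewards, dtype=np.float64)
    if values.shape != rewards.shape:
        raise ValueError("values and rewards must have equal length")
    T = len(values)
    adv = np.zeros(T)
    next_value = 0.0
    carry = 0.0
    for t in range(T - 1, -1, -1):
        delta = rewards[t] + discount * next_value - values[t]
        carry = delta + discount * gae_lambda * carry
        adv[t] = carry
        next_value = values[t]
    return adv, adv + values


def _batched_gae(batch: BatchResult, cfg: PPOConfig) -> tuple[np.ndarray, np.ndarray]:
    """Masked (B, T) advantages/returns across a padded batch."""
    B, T = batch.values.shape
    rewards = np.zeros((B, T))
    rewards[np.arange(B), batch.lengths - 1] = batch.rewards
    adv = np.zeros((B, T))
    carry = np.zeros(B)
    next_value = np.zeros(B)
    mask = batch.mask
    values = batch.values
    for t in range(T - 1, -1, -1):
        m = mask[:, t]
        delta = rewards[:, t] + cfg.discount * next_value - values[:, t]
        carry = np.where(m, delta + cfg.discount * cfg.gae_lambda * carry, carry)
        adv[:, t] = np.where(m, carry, 0.0)
        # seen from step t-1, the bootstrap value is V_t; padding (tail only)
        # leaves carry and next_value at their terminal-step zeros
        next_value = np.where(m, values[:, t], next_value)
    return adv, adv + np.where(mask, values, 0.0)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------


@dataclass
class AdamState:
    m: dict[str, np.ndarray]
    v: dict[str, np.ndarray]
    t: int = 0

    @classmethod
    def init(cls, params: dict[str, np.ndarray]) -> "AdamState":
        return cls(
            m={k: np.zeros_like(p) for k, p in params.items()},
            v={k: np.zeros_like(p) for k, p in params.items()},
        )


def adam_step(
    params: dict[str, np.ndarray],
    grads: dict[str, np.ndarray],
    state: AdamState,
    lr: float,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> dict[str, np.ndarray]:
    state.t += 1
    out = {}
    bc1 = 1.0 - beta1**state.t
    bc2 = 1.0 - beta2**state.t
    for k, p in params.items():
        g = grads[k]
        state.m[k] = beta1 * state.m[k] + (1 - beta1) * g
        state.v[k] = beta2 * state.v[k] + (1 - beta2) * g * g
        out[k] = p - lr * (state.m[k] / bc1) / (np.sqrt(state.v[k] / bc2) + eps)
    return out


# ---------------------------------------------------------------------------
# PPO loss and update
# ---------------------------------------------------------------------------


def _gaussian_logp(actions, mu, sigma):
    z = (Tensor(actions) - mu) / sigma
    return -0.5 * F.square(z) - F.log(sigma) - _LOG_SQRT_2PI


def _loss_terms(mu, sigma, value, actions, old_logp, adv, returns, weights, cfg: PPOConfig):
    """Weighted per-element PPO loss pieces; `weights` sums to 1."""
    logp = _gaussian_logp(actions, mu, sigma)
    ratio = F.exp(logp - old_logp)
    clipped = F.clip(ratio, 1.0 - cfg.clip_epsilon, 1.0 + cfg.clip_epsilon)
    surrogate = F.minimum(ratio * adv, clipped * adv)
    policy_loss = -(surrogate * weights).sum()
    value_loss = (F.square(value - returns) * weights).sum()
    entropy = ((F.log(sigma) + _ENTROPY_CONST) * weights).sum()
    return policy_loss, value_loss, entropy


def ppo_update(
    params: dict[str, np.ndarray],
    batch: BatchResult,
    spec: PolicySpec,
    cfg: PPOConfig,
    opt_state: Optional[AdamState] = None,
    rng: Optional[np.random.Generator] = None,
    lr: Optional[float] = None,
) -> tuple[dict[str, np.ndarray], dict]:
    """One PPO update over a collected batch.

    Advantages are normalized across the update.  Feedforward variants
    shuffle flattened transitions into minibatches; recurrent variants
    replay whole episodes (minibatched over episodes) from zero hidden
    state.  Returns the new parameters and diagnostics.
    """
    if batch.n_episodes == 0:
        raise ValueError("empty batch")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    opt_state = opt_state if opt_state is not None else AdamState.init(params)
    lr = cfg.learning_rate if lr is None else lr

    adv, returns = _batched_gae(batch, cfg)
    valid = batch.mask
    n_valid = int(valid.sum())
    a_mean = adv[valid].mean()
    a_std = adv[valid].std()
    adv = np.where(valid, (adv - a_mean) / (a_std + 1e-8), 0.0)

    diag = {"policy_loss": 0.0, "value_loss": 0.0, "entropy": 0.0, "n_minibatches": 0}
    current = params

    for _ in range(cfg.epochs_per_update):
        if spec.is_recurrent:
            ep_order = rng.permutation(batch.n_episodes)
            mb = max(1, min(cfg.minibatch_size, batch.n_episodes))
            slices = [ep_order[i : i + mb] for i in range(0, batch.n_episodes, mb)]
            for sel in slices:
                current, opt_state, d = _update_recurrent(
                    current, batch, spec, cfg, opt_state, sel, adv, returns, lr
                )
                for k in ("policy_loss", "value_loss", "entropy"):
                    diag[k] += d[k]
                diag["n_minibatches"] += 1
        else:
            flat_idx = np.argwhere(valid)
            order = rng.permutation(len(flat_idx))
            mb = max(1, min(cfg.minibatch_size, len(flat_idx)))
            for i in range(0, len(order), mb):
                sel = flat_idx[order[i : i + mb]]
                current, opt_state, d = _update_feedforward(
                    current, batch, spec, cfg, opt_state, sel, adv, returns, lr
                )
                for k in ("policy_loss", "value_loss", "entropy"):
                    diag[k] += d[k]
                diag["n_minibatches"] += 1

    n = max(diag["n_minibatches"], 1)
    diag = {k: (v / n if k != "n_minibatches" else v) for k, v in diag.items()}
    diag["mean_reward"] = float(batch.rewards.mean())
    diag["mean_length"] = float(batch.lengths.mean())
    diag["mean_sigma"] = _mean_sigma(current, batch, spec)
    return current, diag


def _wrap_params(params):
    return {k: Tensor(v, requires_grad=True) for k, v in params.items()}


def _extract_grads(wrapped):
    grads = {}
    for k, t in wrapped.items():
        g = t.grad if t.grad is not None else np.zeros_like(t.data)
        if not np.all(np.isfinite(g)):
            raise TrainingError(f"non-finite gradient in {k}")
        grads[k] = g
    return grads


def _update_feedforward(params, batch, spec, cfg, opt_state, sel, adv, returns, lr):
    rows = sel[:, 0]
    cols = sel[:, 1]
    m = batch.measurements[rows, cols]
    actions = batch.actions[rows, cols][:, None]
    old_logp = batch.log_probs[rows, cols][:, None]
    a = adv[rows, cols][:, None]
    ret = returns[rows, cols][:, None]
    w = np.full((len(rows), 1), 1.0 / len(rows))

    wrapped = _wrap_params(params)
    mu, sigma, value, _ = forward_core(spec, wrapped, m, None, None)
    pl, vl, ent = _loss_terms(mu, sigma, value, actions, old_logp, a, ret, w, cfg)
    loss = pl + cfg.value_coeff * vl - cfg.entropy_coeff * ent
    if not np.isfinite(loss.data):
        raise TrainingError(f"non-finite loss: policy={pl.data} value={vl.data}")
    loss.backward()
    grads = _extract_grads(wrapped)
    new_params = adam_step(params, grads, opt_state, lr)
    return new_params, opt_state, {
        "policy_loss": float(pl.data),
        "value_loss": float(vl.data),
        "entropy": float(ent.data),
    }


def _update_recurrent(params, batch, spec, cfg, opt_state, sel, adv, returns, lr):
    from .policies import _gru_step, input_vector, mlp_heads

    m = batch.measurements[sel]
    pa = batch.prev_actions[sel]
    mask = batch.mask[sel]
    Bm = mask.shape[0]
    T_eff = int(batch.lengths[sel].max())
    n_valid = mask.sum()

    wrapped = _wrap_params(params)
    # replay the whole sequence through the GRU (hidden starts at zero at
    # every episode start), then run the MLP/heads and the loss once over
    # the time-stacked features
    hidden = np.zeros((Bm, spec.hidden_size))
    feats = []
    for t in range(T_eff):
        x = input_vector(spec, m[:, t], pa[:, t][:, None])
        hidden = _gru_step(wrapped, x, hidden)
        feats.append(hidden)
    feat = F.concat(feats, axis=0)  # (T_eff * Bm, H), time-major
    mu, sigma, value = mlp_heads(spec, wrapped, feat)

    def tm(x):  # time-major flatten matching the feature stack
        return x[:, :T_eff].T.reshape(-1, 1)

    w = tm(mask.astype(np.float64)) / n_valid
    pl, vl, ent = _loss_terms(
        mu, sigma, value, tm(batch.actions[sel]), tm(batch.log_probs[sel]),
        tm(adv[sel]), tm(returns[sel]), w, cfg,
    )
    loss = pl + cfg.value_coeff * vl - cfg.entropy_coeff * ent
    if not np.isfinite(loss.data):
        raise TrainingError(f"non-finite loss: policy={pl.data} value={vl.data}")
    loss.backward()
    grads = _extract_grads(wrapped)
    new_params = adam_step(params, grads, opt_state, lr)
    return new_params, opt_state, {
        "policy_loss": float(pl.data),
        "value_loss": float(vl.data),
        "entropy": float(ent.data),
    }


def _mean_sigma(params, batch, spec):
    """Average exploration noise over the batch's visited states."""
    valid = np.argwhere(batch.mask)
    take = valid[:: max(1, len(valid) // 1024)]
    rows, cols = take[:, 0], take[:, 1]
    m = batch.measurements[rows, cols]
    if spec.is_recurrent:
        h = batch.hiddens[rows, cols]
        pa = batch.prev_actions[rows, cols][:, None]
    else:
        h, pa = None, None
    _, sigma, _, _ = forward_core(spec, params, m, h, pa)
    return float(np.mean(sigma))


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


def train(
    spec: PolicySpec,
    env_config: EpisodeConfig,
    field_template: FieldParams,
    cell: CellParams,
    ppo_config: PPOConfig,
    out_dir=None,
    checkpoint_every: int = 50,
    progress: Optional[Callable[[int, dict], None]] = None,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Full training run: alternate rollouts and PPO updates.

    Returns the final parameters and a per-update log (mean reward, mean
    episode length, mean sigma, loss terms).  With ``out_dir`` set, periodic
    and final checkpoints are written there; on an abort the last periodic
    checkpoint survives.
    """
    root = np.random.SeedSequence(ppo_config.seed)
    init_seq, update_seq, rollout_seq = root.spawn(3)
    params = init_params(spec, np.random.Generator(np.random.PCG64(init_seq)))
    opt_state = AdamState.init(params)
    update_rng = np.random.Generator(np.random.PCG64(update_seq))
    rollout_children = rollout_seq.spawn(ppo_config.total_updates)

    rows = []
    for u in range(ppo_config.total_updates):
        lr = ppo_config.learning_rate
        if ppo_config.lr_decay and ppo_config.total_updates > 1:
            lr *= 1.0 - u / ppo_config.total_updates
        batch = collect_rollouts(
            NeuralPolicy(spec, params),
            env_config,
            field_template,
            cell,
            ppo_config.n_parallel_episodes,
            rollout_children[u],
        )
        params, diag = ppo_update(
            params, batch, spec, ppo_config, opt_state, update_rng, lr=lr
        )
        diag["update"] = u
        diag["lr"] = lr
        rows.append(diag)
        if progress is not None:
            progress(u, diag)
        if out_dir is not None and (u + 1) % checkpoint_every == 0:
            _write_checkpoint(params, spec, out_dir, f"update_{u + 1:05d}")

    log = pd.DataFrame(rows)
    if out_dir is not None:
        _write_checkpoint(params, spec, out_dir, "final")
        log.to_csv(f"{out_dir}/training_log.csv", index=False)
    return params, log


def _write_checkpoint(params, spec, out_dir, tag):
    from .experiment_io import save_checkpoint

    save_checkpoint(f"{out_dir}/checkpoint_{tag}.json", params, spec)
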