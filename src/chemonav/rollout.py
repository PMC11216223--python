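"""Vectorized episode simulation.

Runs many independent episodes in lockstep.  Every episode owns its own
random bit-stream (spawned from one root seed sequence) and consumes it in
a fixed order — four initialisation draws, then blocks of Gaussian
increments and uniform variates — so results do not depend on how episodes
are grouped into batches: a batch of N episodes is, stream for stream, the
same as N one-episode batches with the corresponding child seeds.

Sensor counts are drawn by inverting the Poisson CDF at the pre-drawn
uniforms (:func:`poisson_icdf`), which vectorises across episodes with
state-dependent means while preserving the per-episode streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import special

from .environment import (
    CellParams,
    EpisodeConfig,
    FieldParams,
    compute_reward,
    concentration_profile,
)
from .policies import BlindPolicy, NeuralPolicy, forward_core

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_BLOCK = 512  # steps of noise pre-drawn per episode at a time


def poisson_icdf(u: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Exact Poisson quantile function, vectorized over elements.

    Returns the smallest k with CDF(k) = Q(k+1, lam) >= u (Q the regularized
    upper incomplete gamma function).  A Cornish–Fisher normal start point
    is corrected by stepping the CDF, so typical inputs converge in one or
    two vectorized passes.
    """
    shape = np.shape(u)
    lam = np.asarray(lam, dtype=np.float64).ravel()
    u = np.asarray(u, dtype=np.float64).ravel()
    with np.errstate(invalid="ignore"):
        z = special.ndtri(u)
        k = np.floor(lam + np.sqrt(lam) * z + (z * z - 1.0) / 6.0)
    k = np.where(np.isfinite(k), np.maximum(k, 0.0), 0.0)
    idx = np.flatnonzero(special.gammaincc(k + 1.0, lam) < u)
    while idx.size:
        k[idx] += 1.0
        c = special.gammaincc(k[idx] + 1.0, lam[idx])
        idx = idx[c < u[idx]]
    idx = np.flatnonzero(k > 0)
    while idx.size:
        c = special.gammaincc(k[idx], lam[idx])
        idx = idx[c >= u[idx]]
        k[idx] -= 1.0
        idx = idx[k[idx] > 0]
    return k.astype(np.int64).reshape(shape)


@dataclass
class BatchResult:
    """Per-episode outcomes, plus padded per-step records when collected."""

    taus: np.ndarray
    d_inits: np.ndarray
    d_finals: np.ndarray
    reached: np.ndarray
    rewards: np.ndarray
    lengths: np.ndarray
    conc_scales: np.ndarray
    # padded (B, T, ...) records; None unless collect=True
    measurements: Optional[np.ndarray] = None
    actions: Optional[np.ndarray] = None
    prev_actions: Optional[np.ndarray] = None
    log_probs: Optional[np.ndarray] = None
    values: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None
    distances: Optional[np.ndarray] = None
    hiddens: Optional[np.ndarray] = None

    @property
    def n_episodes(self) -> int:
        return len(self.taus)


_SCALARS = ("taus", "d_inits", "d_finals", "reached", "rewards", "lengths", "conc_scales")
_PADDED = ("measurements", "actions", "prev_actions", "log_probs", "values", "mask", "distances", "hiddens")


def _concat_results(parts: list[BatchResult]) -> BatchResult:
    if len(parts) == 1:
        return parts[0]
    scalars = {k: np.concatenate([getattr(p, k) for p in parts]) for k in _SCALARS}
    padded = {}
    for k in _PADDED:
        vals = [getattr(p, k) for p in parts]
        if vals[0] is None:
            padded[k] = None
            continue
        t_max = max(v.shape[1] for v in vals)
        out = []
        for v in vals:
            pad = [(0, 0), (0, t_max - v.shape[1])] + [(0, 0)] * (v.ndim - 2)
            out.append(np.pad(v, pad))
        padded[k] = np.concatenate(out, axis=0)
    return BatchResult(**scalars, **padded)


def simulate_batch(
    policy,
    config: EpisodeConfig,
    field_template: FieldParams,
    cell: CellParams,
    seed,
    n_episodes: int,
    deterministic: bool = False,
    horizon: Optional[float] = None,
    collect: bool = False,
    chunk_size: Optional[int] = None,
) -> BatchResult:
    """Simulate ``n_episodes`` independent episodes.

    ``seed`` may be an int or a ``np.random.SeedSequence``; one child stream
    is spawned per episode.  ``chunk_size`` bounds how many episodes run in
    lockstep at once without changing any result.
    """
    seed_seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = seed_seq.spawn(n_episodes)
    if chunk_size is None:
        chunk_size = n_episodes
    parts = []
    for lo in range(0, n_episodes, chunk_size):
        parts.append(
            _run_chunk(
                policy,
                config,
                field_template,
                cell,
                children[lo : lo + chunk_size],
                deterministic,
                horizon,
                collect,
            )
        )
    return _concat_results(parts)


def _run_chunk(
    policy,
    config: EpisodeConfig,
    field_template: FieldParams,
    cell: CellParams,
    children: list[np.random.SeedSequence],
    deterministic: bool,
    horizon: Optional[float],
    collect: bool,
) -> BatchResult:
    B = len(children)
    gens = [np.random.Generator(np.random.PCG64(c)) for c in children]
    t_end = config.t_max if horizon is None else horizon
    n_steps = int(round(t_end / config.dt))
    K = cell.n_sensors
    dt = config.dt

    if isinstance(policy, NeuralPolicy):
        spec = policy.spec
        params = policy.params
        is_neural = True
        H = spec.hidden_size if spec.is_recurrent else 0
    elif isinstance(policy, BlindPolicy):
        is_neural = False
        H = 0
    else:
        raise TypeError(
            "simulate_batch supports NeuralPolicy and BlindPolicy; use "
            "environment.run_episode for other policy types"
        )
    # the blind agent never reads its sensors: skip count sampling unless
    # the caller wants recorded observations
    need_counts = is_neural or collect

    # initial conditions, matching environment.reset draw-for-draw
    positions = np.empty((B, 2))
    headings = np.empty(B)
    conc = np.empty(B)
    lo, hi = config.d0_range
    clo, chi = config.conc_scale_range
    for j, g in enumerate(gens):
        d0 = g.uniform(lo, hi)
        phi = g.uniform(0.0, 2.0 * math.pi)
        headings[j] = g.uniform(0.0, 2.0 * math.pi)
        conc[j] = math.exp(g.uniform(math.log(clo), math.log(chi)))
        positions[j] = d0 * np.array([math.cos(phi), math.sin(phi)])
    d_inits = np.hypot(positions[:, 0], positions[:, 1])

    sector = 2.0 * math.pi * np.arange(K) / K
    area = math.pi * cell.sensor_radius**2
    base_profile = FieldParams(
        C0=1.0,
        lambda_decay=field_template.lambda_decay,
        profile_kind=field_template.profile_kind,
        match_radius=field_template.match_radius,
    )
    rot_std = math.sqrt(2.0 * cell.rot_diffusion * dt)

    hidden = np.zeros((B, H)) if H else None
    prev_action = np.zeros(B)
    active = np.ones(B, dtype=bool)
    taus = np.full(B, t_end)
    reached = np.zeros(B, dtype=bool)
    lengths = np.zeros(B, dtype=np.int64)

    normal_blocks = np.zeros((B, _BLOCK, 2))
    uniform_blocks = np.zeros((B, _BLOCK, K)) if need_counts else None

    if collect:
        rec_m = np.zeros((B, n_steps, K))
        rec_a = np.zeros((B, n_steps))
        rec_pa = np.zeros((B, n_steps))
        rec_lp = np.zeros((B, n_steps))
        rec_v = np.zeros((B, n_steps))
        rec_mask = np.zeros((B, n_steps), dtype=bool)
        rec_d = np.zeros((B, n_steps))
        rec_h = np.zeros((B, n_steps, H)) if H else None

    for t in range(n_steps):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        off = t % _BLOCK
        if off == 0:
            blk = min(_BLOCK, n_steps - t)
            for j in idx:
                normal_blocks[j, :blk] = gens[j].standard_normal((blk, 2))
                if need_counts:
                    uniform_blocks[j, :blk] = gens[j].random((blk, K))

        pos = positions[idx]
        if need_counts:
            ang = headings[idx, None] + sector[None, :]
            sx = pos[:, 0:1] + cell.radius * np.cos(ang)
            sy = pos[:, 1:2] + cell.radius * np.sin(ang)
            d_sens = np.hypot(sx, sy)
            lam = conc[idx, None] * np.asarray(
                concentration_profile(base_profile, d_sens)
            ) * area
            counts = poisson_icdf(uniform_blocks[idx, off], lam)
            m = np.log(counts + 1.0)
        else:
            m = None

        if is_neural:
            h_in = hidden[idx] if H else None
            mu, sigma, value, h_out = forward_core(
                spec, params, m, h_in, prev_action[idx, None]
            )
            mu = mu[:, 0]
            sigma = sigma[:, 0]
            value = value[:, 0]
        else:
            mu = np.zeros(idx.size)
            sigma = np.zeros(idx.size)
            value = np.zeros(idx.size)
            h_out = None

        if deterministic:
            actions = mu
        else:
            actions = mu + sigma * normal_blocks[idx, off, 0]
        noise = normal_blocks[idx, off, 1]

        if collect:
            with np.errstate(divide="ignore", invalid="ignore"):
                safe = np.where(sigma > 0, sigma, 1.0)
                logp = np.where(
                    sigma > 0,
                    -0.5 * ((actions - mu) / safe) ** 2 - np.log(safe) - _LOG_SQRT_2PI,
                    0.0,
                )
            rec_m[idx, t] = m if m is not None else 0.0
            rec_a[idx, t] = actions
            rec_pa[idx, t] = prev_action[idx]
            rec_lp[idx, t] = logp
            rec_v[idx, t] = value
            rec_mask[idx, t] = True
            rec_d[idx, t] = np.hypot(pos[:, 0], pos[:, 1])
            if H:
                rec_h[idx, t] = hidden[idx]

        new_heading = (headings[idx] + actions * dt + rot_std * noise) % (2.0 * math.pi)
        positions[idx, 0] = pos[:, 0] + cell.speed * dt * np.cos(new_heading)
        positions[idx, 1] = pos[:, 1] + cell.speed * dt * np.sin(new_heading)
        headings[idx] = new_heading
        prev_action[idx] = actions
        if H:
            hidden[idx] = h_out
        lengths[idx] += 1

        dist = np.hypot(positions[idx, 0], positions[idx, 1])
        arrived = dist <= config.delta
        if np.any(arrived):
            hit = idx[arrived]
            reached[hit] = True
            taus[hit] = (t + 1) * dt
            active[hit] = False

    d_finals = np.where(reached, config.delta, np.hypot(positions[:, 0], positions[:, 1]))
    rewards = np.array(
        [
            compute_reward(min(taus[j], config.t_max), d_finals[j], d_inits[j], config)
            for j in range(B)
        ]
    )

    t_used = int(lengths.max()) if B else 0
    return BatchResult(
        taus=taus,
        d_inits=d_inits,
        d_finals=d_finals,
        reached=reached,
        rewards=rewards,
        lengths=lengths,
        conc_scales=conc,
        measurements=rec_m[:, :t_used] if collect else None,
        actions=rec_a[:, :t_used] if collect else None,
        prev_actions=rec_pa[:, :t_used] if collect else None,
        log_probs=rec_lp[:, :t_used] if collect else None,
        values=rec_v[:, :t_used] if collect else None,
        mask=rec_mask[:, :t_used] if collect else None,
        distances=rec_d[:, :t_used] if collect else None,
        hiddens=(rec_h[:, :t_used] if H else None) if collect else None,
    )
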