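"""Integrated-gradients attribution of trained policies.

The importance of input ``x_i`` to the deterministic steering output
``pi(x) = mu`` is

    I_i = (x_i - x'_i) * integral_0^1  d pi(x' + a (x - x')) / d x_i  da,

approximated by a midpoint Riemann sum; the baseline ``x'`` is the zero
input.  Integrated gradients satisfy completeness — the attributions sum to
``pi(x) - pi(x')`` — which we report as a diagnostic for every record.

From the per-input importances we derive the memory-usage statistic

    U_h = sum_{i in hidden} |I_i| / (sum_{i in hidden} |I_i| + sum_{i in measurements} |I_i|),

the fraction of total absolute attribution carried by the recurrent hidden
state versus the instantaneous measurements (previous-action attributions
are excluded from both sums).  U_h = 1 means the decision rests entirely on
memory, U_h = 0 entirely on the current measurement.

For recurrent policies the current action is also a function of all past
measurements through the chain of hidden states; ``unrolled_attribution``
unrolls the recurrence over a trailing window and attributes the action to
every (lag, sensor) measurement individually, holding the recorded actions
and the window's initial hidden state fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .environment import CellParams, EpisodeConfig, FieldParams
from .policies import NeuralPolicy, PolicySpec, forward_core
from .rollout import simulate_batch

DEFAULT_N_STEPS = 512
COMPLETENESS_RTOL = 1e-3


class CompletenessWarning(UserWarning):
    pass


@dataclass(frozen=True)
class AttributionRecord:
    """Per-input importances for one evaluation point."""

    importances: np.ndarray
    baseline: np.ndarray
    n_steps: int
    completeness_error: float
    output: float
    baseline_output: float
    memory_usage: Optional[float] = None


def integrated_gradients(
    policy_fn: Callable[[Tensor], Tensor],
    x: np.ndarray,
    baseline: Optional[np.ndarray] = None,
    n_steps: int = DEFAULT_N_STEPS,
    rtol: float = COMPLETENESS_RTOL,
) -> AttributionRecord:
    """Midpoint-rule integrated gradients of a scalar differentiable map.

    ``policy_fn`` must accept a ``(B, D)`` Tensor batch and return a
    ``(B, 1)`` Tensor.  A completeness error above ``rtol`` (relative to the
    output span) triggers a warning suggesting a finer integration grid.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    x = np.asarray(x, dtype=np.float64)
    baseline = np.zeros_like(x) if baseline is None else np.asarray(baseline, dtype=np.float64)
    alphas = (np.arange(n_steps) + 0.5) / n_steps
    points = baseline[None, :] + alphas[:, None] * (x - baseline)[None, :]
    leaf = Tensor(points, requires_grad=True)
    out = policy_fn(leaf)
    out.sum().backward()
    avg_grad = leaf.grad.mean(axis=0)
    importances = (x - baseline) * avg_grad

    ends = policy_fn(Tensor(np.stack([x, baseline]))).data[:, 0]
    span = ends[0] - ends[1]
    err = abs(span - importances.sum())
    rel = err / max(abs(span), 1e-12)
    if rel > rtol:
        warnings.warn(
            f"completeness error {err:.3e} ({rel:.2e} relative) exceeds {rtol}; "
            "raise n_steps",
            CompletenessWarning,
            stacklevel=2,
        )
    return AttributionRecord(
        importances=importances,
        baseline=baseline,
        n_steps=n_steps,
        completeness_error=float(err),
        output=float(ends[0]),
        baseline_output=float(ends[1]),
    )


# ---------------------------------------------------------------------------
# Instantaneous attribution of a policy step
# ---------------------------------------------------------------------------


def input_partition(spec: PolicySpec) -> dict[str, np.ndarray]:
    """Index groups of the flat instantaneous input vector
    ``[measurements..., prev_action, hidden...]`` (prev_action and hidden
    only for recurrent variants)."""
    n_m = 1 if spec.variant == "temporal" else spec.n_sensors
    idx = {"measurements": np.arange(n_m)}
    if spec.is_recurrent:
        off = n_m
        if spec.feed_back_action:
            idx["prev_action"] = np.arange(off, off + 1)
            off += 1
        idx["hidden"] = np.arange(off, off + spec.hidden_size)
    else:
        idx["prev_action"] = np.arange(0)
        idx["hidden"] = np.arange(0)
    return idx


def action_fn(spec: PolicySpec, params) -> Callable[[Tensor], Tensor]:
    """The deterministic steering output mu as a function of the flat
    instantaneous input vector (see :func:`input_partition`)."""
    part = input_partition(spec)
    n_m = len(part["measurements"])

    def fn(z):
        m = z[:, :n_m]
        if spec.is_recurrent:
            off = n_m
            if spec.feed_back_action:
                pa = z[:, off : off + 1] * spec.action_scale
                off += 1
            else:
                pa = None
            h = z[:, off:]
            # measurements enter pre-averaged for the temporal variant, so
            # bypass the in-forward averaging by widening to a fake K=1 spec
            mu, _, _, _ = forward_core(_flat_spec(spec), params, m, h, pa)
        else:
            mu, _, _, _ = forward_core(spec, params, m, None, None)
        return mu

    return fn


def _flat_spec(spec: PolicySpec) -> PolicySpec:
    """For the temporal variant the flat input already holds <m>; reuse the
    combined forward path with a single 'sensor'."""
    if spec.variant != "temporal":
        return spec
    return PolicySpec(
        variant="combined",
        n_sensors=1,
        hidden_size=spec.hidden_size,
        mlp_widths=spec.mlp_widths,
        action_scale=spec.action_scale,
        feed_back_action=spec.feed_back_action,
        obs_loc=spec.obs_loc,
        obs_scale=spec.obs_scale,
    )


def flat_input(
    spec: PolicySpec,
    measurements: np.ndarray,
    prev_action: float = 0.0,
    hidden: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Pack an observation/state into the flat attribution input vector.
    The previous action is stored normalized by the action scale so all
    inputs live on comparable scales."""
    m = np.asarray(measurements, dtype=np.float64)
    if spec.variant == "temporal":
        m = np.atleast_1d(m.mean())
    if not spec.is_recurrent:
        return m
    parts = [m]
    if spec.feed_back_action:
        parts.append(np.array([prev_action / spec.action_scale]))
    parts.append(hidden if hidden is not None else np.zeros(spec.hidden_size))
    return np.concatenate(parts)


def attribute_step(
    spec: PolicySpec,
    params,
    measurements: np.ndarray,
    prev_action: float = 0.0,
    hidden: Optional[np.ndarray] = None,
    n_steps: int = DEFAULT_N_STEPS,
    baseline: Optional[np.ndarray] = None,
    rtol: Optional[float] = None,
) -> AttributionRecord:
    """Instantaneous attribution of one policy step, with memory usage.

    Coarse integration grids (n_steps < 256) relax the completeness warning
    threshold: ratio statistics such as U_h tolerate far larger quadrature
    error than the completeness identity itself.
    """
    if rtol is None:
        rtol = COMPLETENESS_RTOL if n_steps >= 256 else 0.05
    x = flat_input(spec, measurements, prev_action, hidden)
    rec = integrated_gradients(action_fn(spec, params), x, baseline, n_steps, rtol=rtol)
    u = memory_usage(rec, input_partition(spec))
    return AttributionRecord(
        importances=rec.importances,
        baseline=rec.baseline,
        n_steps=rec.n_steps,
        completeness_error=rec.completeness_error,
        output=rec.output,
        baseline_output=rec.baseline_output,
        memory_usage=u,
    )


def memory_usage(record: AttributionRecord, partition: dict[str, np.ndarray]) -> float:
    """U_h from an attribution record and an input partition.

    Previous-action attributions are excluded.  When both the hidden and
    the measurement groups carry zero attribution the statistic is
    undefined and NaN is returned as the missing-value flag.
    """
    covered = np.concatenate([partition[k] for k in ("hidden", "measurements", "prev_action")])
    if len(np.unique(covered)) != len(record.importances):
        raise ValueError("partition must cover every input exactly once")
    h_sum = np.abs(record.importances[partition["hidden"]]).sum()
    m_sum = np.abs(record.importances[partition["measurements"]]).sum()
    denom = h_sum + m_sum
    if denom == 0.0:
        return float("nan")
    return float(h_sum / denom)


# ---------------------------------------------------------------------------
# Through-time (unrolled) attribution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UnrolledAttribution:
    """(lag, sensor) importance matrix for one trajectory position.

    ``importances[l, i]`` is the contribution of sensor ``i`` at ``l`` steps
    in the past to the current action; lag 0 is the current measurement.
    """

    importances: np.ndarray
    completeness_error: float
    output: float
    baseline_output: float
    truncated: bool


def unrolled_attribution(
    policy: NeuralPolicy,
    measurements: np.ndarray,
    actions: np.ndarray,
    t_index: int,
    t_back: int = 300,
    n_steps: int = DEFAULT_N_STEPS,
    initial_hidden: Optional[np.ndarray] = None,
) -> UnrolledAttribution:
    """Attribute the action at ``t_index`` to the last ``t_back`` measurement
    vectors of a recorded trajectory.

    The recurrence is unrolled from the hidden state at the window start
    (recomputed by replay unless supplied); recorded actions feed the
    action-feedback input and are held fixed, so the attribution targets the
    measurements alone.  A window extending before the trajectory start is
    truncated and flagged.
    """
    spec, params = policy.spec, policy.params
    measurements = np.asarray(measurements, dtype=np.float64)
    actions = np.asarray(actions, dtype=np.float64)
    T, K = measurements.shape
    if not 0 <= t_index < T:
        raise ValueError("t_index outside trajectory")
    truncated = t_back > t_index + 1
    n_back = min(t_back, t_index + 1)
    start = t_index + 1 - n_back

    if spec.is_recurrent:
        if initial_hidden is not None and not truncated and start > 0:
            h0 = np.asarray(initial_hidden, dtype=np.float64)
        else:
            h0 = _replay_hidden(spec, params, measurements, actions, start)
    else:
        h0 = None

    window = measurements[start : t_index + 1]  # (n_back, K), oldest first
    prev_actions = np.concatenate([[0.0], actions])[start : t_index + 1]

    def fn(z):
        B = z.shape[0]
        h = np.zeros((B, spec.hidden_size)) if spec.is_recurrent else None
        mu = None
        for s in range(n_back):
            m_s = z[:, s * K : (s + 1) * K]
            if spec.is_recurrent:
                if s == 0 and h0 is not None:
                    h = np.broadcast_to(h0, (B, spec.hidden_size)).copy()
                pa = np.full((B, 1), prev_actions[s])
                mu, _, _, h = forward_core(spec, params, m_s, h, pa)
            else:
                mu, _, _, _ = forward_core(spec, params, m_s, None, None)
        return mu

    x = window.reshape(-1)
    rec = integrated_gradients(fn, x, None, n_steps)
    imp = rec.importances.reshape(n_back, K)[::-1]  # row 0 = lag 0 (current)
    return UnrolledAttribution(
        importances=imp,
        completeness_error=rec.completeness_error,
        output=rec.output,
        baseline_output=rec.baseline_output,
        truncated=truncated,
    )


def _replay_hidden(spec, params, measurements, actions, upto: int) -> np.ndarray:
    """Hidden state after replaying steps [0, upto) of a trajectory."""
    h = np.zeros((1, spec.hidden_size))
    prev = 0.0
    for t in range(upto):
        _, _, _, h = forward_core(
            spec, params, measurements[t][None, :], h, np.array([[prev]])
        )
        prev = actions[t]
    return np.asarray(h[0])


def mean_unrolled_attribution(
    policy: NeuralPolicy,
    config: EpisodeConfig,
    field_template: FieldParams,
    cell: CellParams,
    n_runs: int,
    seed,
    t_back: int = 300,
    n_steps: int = 64,
    positions_per_run: int = 4,
) -> pd.DataFrame:
    """Average (lag, sensor) attribution curves over evaluation trajectories
    (the through-time sensor-influence picture), as a long-format table."""
    res = simulate_batch(
        policy, config, field_template, cell, seed, n_runs,
        deterministic=True, collect=True,
    )
    acc = np.zeros((t_back, cell.n_sensors))
    n_acc = 0
    for ep in range(n_runs):
        L = int(res.lengths[ep])
        if L <= t_back:
            continue
        picks = np.linspace(t_back, L - 1, positions_per_run).astype(int)
        for t_idx in np.unique(picks):
            rec = unrolled_attribution(
                policy,
                res.measurements[ep, :L],
                res.actions[ep, :L],
                int(t_idx),
                t_back=t_back,
                n_steps=n_steps,
            )
            acc += rec.importances
            n_acc += 1
    mean_imp = acc / max(n_acc, 1)
    lags, sensors = np.meshgrid(np.arange(t_back), np.arange(cell.n_sensors), indexing="ij")
    return pd.DataFrame(
        {
            "lag": lags.ravel(),
            "sensor_index": sensors.ravel(),
            "mean_importance": mean_imp.ravel(),
            "n_positions": n_acc,
        }
    )


# ---------------------------------------------------------------------------
# Memory-usage maps
# ---------------------------------------------------------------------------


def instant_attributions(
    spec: PolicySpec,
    params,
    measurements: np.ndarray,
    prev_actions: np.ndarray,
    hiddens: Optional[np.ndarray],
    n_steps: int = 32,
) -> np.ndarray:
    """Vectorized instantaneous attributions for T policy steps at once.

    Returns a (T, D) importance array over the flat input vector.  A coarse
    integration grid is acceptable here because U_h is a ratio of absolute
    attributions, far less sensitive than completeness."""
    T = len(measurements)
    xs = np.stack(
        [
            flat_input(
                spec,
                measurements[t],
                float(prev_actions[t]),
                hiddens[t] if hiddens is not None else None,
            )
            for t in range(T)
        ]
    )
    D = xs.shape[1]
    alphas = (np.arange(n_steps) + 0.5) / n_steps
    pts = (alphas[None, :, None] * xs[:, None, :]).reshape(T * n_steps, D)
    leaf = Tensor(pts, requires_grad=True)
    out = action_fn(spec, params)(leaf)
    out.sum().backward()
    grads = leaf.grad.reshape(T, n_steps, D).mean(axis=1)
    return xs * grads


def memory_usage_trace(
    policy: NeuralPolicy, batch, episode: int, n_steps: int = 32
) -> np.ndarray:
    """U_h at every recorded step of one rollout episode."""
    spec, params = policy.spec, policy.params
    part = input_partition(spec)
    L = int(batch.lengths[episode])
    if not spec.is_recurrent:
        return np.zeros(L)
    imp = instant_attributions(
        spec,
        params,
        batch.measurements[episode, :L],
        batch.prev_actions[episode, :L],
        batch.hiddens[episode, :L],
        n_steps=n_steps,
    )
    h_sum = np.abs(imp[:, part["hidden"]]).sum(axis=1)
    m_sum = np.abs(imp[:, part["measurements"]]).sum(axis=1)
    denom = h_sum + m_sum
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, h_sum / denom, np.nan)


def memory_usage_map(
    policies,
    radii: Sequence[float],
    concentration_scales: Sequence[float],
    config: EpisodeConfig,
    cell_template: CellParams,
    field_template: FieldParams,
    n_runs: int,
    seed,
    n_distance_bins: int = 8,
    n_steps: int = 32,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean memory usage per (radius, concentration scale), plus a
    distance-resolved U_h profile pooled over the grid.

    ``policies`` is either one policy used everywhere or a mapping from
    radius to the policy trained at that radius.
    """
    from dataclasses import replace as dc_replace

    table_rows = []
    dist_values: list[np.ndarray] = []
    dist_uh: list[np.ndarray] = []
    seed_seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    cells = seed_seq.spawn(len(radii) * len(concentration_scales))
    for i, radius in enumerate(radii):
        policy = policies[radius] if isinstance(policies, dict) else policies
        cell = dc_replace(cell_template, radius=radius, sensor_radius=None)
        for j, scale in enumerate(concentration_scales):
            cfg = dc_replace(config, conc_scale_range=(scale, scale))
            res = simulate_batch(
                policy, cfg, field_template, cell, cells[i * len(concentration_scales) + j],
                n_runs, deterministic=True, collect=True,
            )
            uh_all = []
            for ep in range(n_runs):
                L = int(res.lengths[ep])
                trace = memory_usage_trace(policy, res, ep, n_steps=n_steps)
                uh_all.append(trace)
                dist_values.append(res.distances[ep, :L])
                dist_uh.append(trace)
            pooled = np.concatenate(uh_all)
            table_rows.append(
                {
                    "radius": radius,
                    "conc_scale": scale,
                    "mean_Uh": float(np.nanmean(pooled)) if pooled.size else np.nan,
                    "n_steps_pooled": int(pooled.size),
                }
            )
    d = np.concatenate(dist_values)
    u = np.concatenate(dist_uh)
    edges = np.linspace(config.delta, config.d0_range[1], n_distance_bins + 1)
    which = np.digitize(d, edges) - 1
    prof_rows = []
    for b in range(n_distance_bins):
        sel = (which == b) & np.isfinite(u)
        prof_rows.append(
            {
                "distance_lo": edges[b],
                "distance_hi": edges[b + 1],
                "mean_Uh": float(u[sel].mean()) if sel.any() else np.nan,
                "n": int(sel.sum()),
            }
        )
    return pd.DataFrame(table_rows), pd.DataFrame(prof_rows)
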