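"""Chemotactic performance statistics.

The central figure of merit is the chemotactic efficiency

    eta = < (d0 - delta) / (v * tau) >,

the straight-line travel time from the start distance ``d0`` to the arrival
threshold ``delta`` divided by the realized arrival time ``tau``, averaged
over episodes.  ``eta = 1`` is a perfect beeline; a blind (non-sensing)
swimmer scores a few percent.  Policies are evaluated in deterministic mode
(mean action), at a horizon longer than the training horizon so that slow
but successful strategies are not truncated; episodes that still fail are
assigned ``tau`` equal to the evaluation horizon and kept in the average
(an explicit flag restricts the average to arrivals instead).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .environment import CellParams, EpisodeConfig, FieldParams, run_episode
from .policies import BlindPolicy, NeuralPolicy, Policy, PolicySpec
from .rollout import simulate_batch
from .training import PPOConfig, train

DEFAULT_HORIZON_FACTOR = 4.0


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Mean efficiency with a bootstrap standard error."""

    eta_mean: float
    stderr: float
    n_runs: int
    failure_fraction: float


@dataclass(frozen=True)
class ArrivalSummary:
    """Arrival-time statistics over successful runs, failures counted apart."""

    times: np.ndarray
    n_failures: int
    n_runs: int
    mean: float
    median: float
    skewness: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray

    @property
    def empty(self) -> bool:
        return self.times.size == 0


def _run_many(
    policy: Policy,
    config: EpisodeConfig,
    field_template: FieldParams,
    cell: CellParams,
    n_runs: int,
    seed,
    horizon: float,
    chunk_size: Optional[int] = None,
):
    """(taus, d_inits, reached) over n_runs deterministic episodes."""
    if isinstance(policy, (NeuralPolicy, BlindPolicy)):
        res = simulate_batch(
            policy,
            config,
            field_template,
            cell,
            seed,
            n_runs,
            deterministic=True,
            horizon=horizon,
            chunk_size=chunk_size,
        )
        return res.taus, res.d_inits, res.reached
    seed_seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    taus = np.empty(n_runs)
    d_inits = np.empty(n_runs)
    reached = np.zeros(n_runs, dtype=bool)
    for i, child in enumerate(seed_seq.spawn(n_runs)):
        rng = np.random.Generator(np.random.PCG64(child))
        r = run_episode(
            policy, config, field_template, cell, rng, deterministic=True, horizon=horizon
        )
        taus[i], d_inits[i], reached[i] = r.tau, r.d_init, r.reached
    return taus, d_inits, reached


def chemotactic_efficiency(
    policy: Policy,
    config: EpisodeConfig,
    field_template: FieldParams,
    cell: CellParams,
    n_runs: int,
    seed,
    horizon_factor: float = DEFAULT_HORIZON_FACTOR,
    condition_on_arrival: bool = False,
    n_bootstrap: int = 200,
    chunk_size: Optional[int] = None,
) -> EfficiencyEstimate:
    """Estimate eta over ``n_runs`` independent deterministic episodes.

    Failed episodes enter the mean with ``tau`` set to the evaluation
    horizon (``horizon_factor * t_max``) unless ``condition_on_arrival``.
    """
    horizon = horizon_factor * config.t_max
    taus, d_inits, reached = _run_many(
        policy, config, field_template, cell, n_runs, seed, horizon, chunk_size
    )
    tau_eff = np.where(reached, taus, horizon)
    eta_runs = (d_inits - config.delta) / (cell.speed * tau_eff)
    if condition_on_arrival:
        eta_runs = eta_runs[reached]
    if eta_runs.size == 0:
        return EfficiencyEstimate(np.nan, np.nan, n_runs, 1.0)
    seed_seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    boot_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed_seq.entropy, spawn_key=(*seed_seq.spawn_key, 0xB007))
    )
    means = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        means[b] = eta_runs[boot_rng.integers(0, eta_runs.size, eta_runs.size)].mean()
    return EfficiencyEstimate(
        eta_mean=float(eta_runs.mean()),
        stderr=float(means.std(ddof=1)),
        n_runs=n_runs,
        failure_fraction=float(1.0 - reached.mean()),
    )


def arrival_time_distribution(
    policy: Policy,
    config: EpisodeConfig,
    field_template: FieldParams,
    cell: CellParams,
    n_runs: int,
    seed,
    horizon_factor: float = DEFAULT_HORIZON_FACTOR,
    n_bins: int = 30,
    chunk_size: Optional[int] = None,
) -> ArrivalSummary:
    """Arrival times of successful runs; failures are counted separately."""
    horizon = horizon_factor * config.t_max
    taus, _, reached = _run_many(
        policy, config, field_template, cell, n_runs, seed, horizon, chunk_size
    )
    times = np.sort(taus[reached])
    n_fail = int(n_runs - reached.sum())
    if times.size:
        counts, edges = np.histogram(times, bins=n_bins)
        return ArrivalSummary(
            times=times,
            n_failures=n_fail,
            n_runs=n_runs,
            mean=float(times.mean()),
            median=float(np.median(times)),
            skewness=float(stats.skew(times)) if times.size > 2 else np.nan,
            hist_counts=counts,
            hist_edges=edges,
        )
    return ArrivalSummary(
        times=times,
        n_failures=n_fail,
        n_runs=n_runs,
        mean=np.nan,
        median=np.nan,
        skewness=np.nan,
        hist_counts=np.zeros(n_bins, dtype=np.int64),
        hist_edges=np.linspace(0.0, horizon, n_bins + 1),
    )


def size_sweep(
    variants: Sequence[str],
    radii: Sequence[float],
    env_config: EpisodeConfig,
    field_template: FieldParams,
    cell_template: CellParams,
    train_budget: PPOConfig,
    n_eval: int,
    seed: int,
    spec_template: Optional[PolicySpec] = None,
) -> pd.DataFrame:
    """Train fresh policies per (variant, radius) under identical budgets and
    evaluate their efficiencies.  Returns a long-format table; a failed
    training run yields a row with NaN efficiency and the error message
    rather than aborting the sweep."""
    rows = []
    for radius in radii:
        cell = replace(cell_template, radius=radius, sensor_radius=None)
        for variant in variants:
            if spec_template is None:
                spec = PolicySpec(variant=variant, n_sensors=cell.n_sensors)
            else:
                spec = replace(spec_template, variant=variant, n_sensors=cell.n_sensors)
            row = {
                "variant": variant,
                "radius": radius,
                "n_eval": n_eval,
                "train_updates": train_budget.total_updates,
                "train_episodes": train_budget.n_parallel_episodes,
                "seed": seed,
                "t_max": env_config.t_max,
                "d0_lo": env_config.d0_range[0],
                "d0_hi": env_config.d0_range[1],
                "conc_lo": env_config.conc_scale_range[0],
                "conc_hi": env_config.conc_scale_range[1],
                "error": "",
            }
            try:
                budget = replace(train_budget, seed=seed)
                params, _ = train(spec, env_config, field_template, cell, budget)
                est = chemotactic_efficiency(
                    NeuralPolicy(spec, params),
                    env_config,
                    field_template,
                    cell,
                    n_eval,
                    seed=seed + 1,
                )
                row.update(
                    eta_mean=est.eta_mean,
                    stderr=est.stderr,
                    failure_fraction=est.failure_fraction,
                )
            except Exception as exc:  # noqa: BLE001 - sweep must survive cells
                row.update(eta_mean=np.nan, stderr=np.nan, failure_fraction=np.nan, error=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)
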