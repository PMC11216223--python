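"""Stochastic 2D chemotaxis world.

A circular model cell of radius ``R`` swims at constant speed ``v`` through a
static, radially symmetric chemoattractant field centred on the origin.  Its
heading evolves under its own steering action plus rotational diffusion
(Euler–Maruyama).  ``K`` sensors sit on the cell perimeter, co-rotating with
the body; each counts the particles inside a disk of radius
``r_s = R sin(pi/K)`` as an independent Poisson draw per step (the
perfect-instrument model), and counts are compressed through the
Weber–Fechner transform ``m = log(M + 1)``.

Episodes start at a random distance ``d0`` from the source with random
orientation and end when the cell comes within ``delta`` of the source or the
horizon ``t_max`` elapses.  The terminal reward rewards fast arrival and,
on timeout, penalises ending farther from the source:

    R = (t_max - tau)/t_max + max(-1, (delta - d)/(d0 - delta))

with ``d = delta`` on arrival and ``tau = t_max`` on timeout, so exactly one
term is nonzero and the reward lies in [-1, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import k0 as bessel_k0


class ConfigurationError(ValueError):
    """An invalid or inconsistent simulation configuration."""


class SimulationError(RuntimeError):
    """A numerical failure during a simulation step."""


class InvalidEpisodeError(ValueError):
    """Episode geometry violates d0 > delta."""


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

PROFILE_KINDS = ("exponential", "algebraic", "bessel")


@dataclass(frozen=True)
class FieldParams:
    """Chemoattractant concentration profile.

    Parameters
    ----------
    C0
        Peak concentration amplitude (particles/um^2).
    lambda_decay
        Inverse decay length lambda (1/um).  If the microscopic parameters
        ``D`` (particle diffusion, um^2/s) and ``kappa`` (decay rate, 1/s)
        are supplied, they must satisfy ``lambda = sqrt(kappa / D)``.
    profile_kind
        One of ``exponential`` (C0 exp(-lambda r)), ``algebraic``
        (C0 / (1 + lambda r)^2) or ``bessel`` (the radially symmetric
        steady state of diffusion with decay and a point source at the
        origin, K0(lambda r), scaled to match the exponential profile at
        ``match_radius``).
    rho
        Particle release rate at the source (particles/s); retained for
        bookkeeping only.
    match_radius
        Radius (um) at which the Bessel profile is pinned to the
        exponential one, making the two comparable at the cell scale.
    """

    C0: float
    lambda_decay: float
    profile_kind: str = "exponential"
    D: Optional[float] = None
    kappa: Optional[float] = None
    rho: Optional[float] = None
    match_radius: float = 1.0

    def __post_init__(self):
        if self.C0 <= 0:
            raise ConfigurationError("C0 must be positive")
        if self.lambda_decay <= 0:
            raise ConfigurationError("lambda_decay must be positive")
        if self.profile_kind not in PROFILE_KINDS:
            raise ConfigurationError(
                f"unknown profile_kind {self.profile_kind!r}; "
                f"expected one of {PROFILE_KINDS}"
            )
        if self.D is not None and self.kappa is not None:
            lam = math.sqrt(self.kappa / self.D)
            if abs(lam - self.lambda_decay) > 1e-12 * lam:
                raise ConfigurationError(
                    f"lambda_decay={self.lambda_decay} inconsistent with "
                    f"sqrt(kappa/D)={lam}"
                )


def decay_length_scale(D: float, kappa: float) -> float:
    """Inverse length scale lambda = sqrt(kappa/D) of a diffusion-decay field."""
    return math.sqrt(kappa / D)


@dataclass(frozen=True)
class CellParams:
    """Cell geometry and motility.

    ``sensor_radius`` defaults to ``R sin(pi/K)`` so the K perimeter sensors
    jointly cover the cell surface; a supplied value must match that relation.
    """

    radius: float = 2.0
    n_sensors: int = 5
    speed: float = 5.0
    rot_diffusion: float = 0.025
    sensor_radius: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.radius <= 0:
            raise ConfigurationError("radius must be positive")
        if self.n_sensors < 1:
            raise ConfigurationError("n_sensors must be >= 1")
        if self.speed <= 0:
            raise ConfigurationError("speed must be positive")
        if self.rot_diffusion < 0:
            raise ConfigurationError("rot_diffusion must be >= 0")
        rs = self.radius * math.sin(math.pi / self.n_sensors)
        if self.sensor_radius is None:
            object.__setattr__(self, "sensor_radius", rs)
        elif abs(self.sensor_radius - rs) > 1e-12 * rs:
            raise ConfigurationError(
                f"sensor_radius={self.sensor_radius} != R sin(pi/K)={rs}"
            )


@dataclass(frozen=True)
class CellState:
    """Position (um), heading (rad, wrapped to [0, 2pi)) and time (s)."""

    position: np.ndarray
    heading: float
    time: float = 0.0

    def __post_init__(self):
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=np.float64)
        )
        object.__setattr__(self, "heading", float(self.heading) % (2 * math.pi))

    @property
    def distance(self) -> float:
        return float(np.hypot(self.position[0], self.position[1]))


@dataclass(frozen=True)
class Observation:
    """Per-sensor Poisson counts and their Weber–Fechner transforms."""

    counts: np.ndarray
    measurements: np.ndarray
    mean_measurement: float

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "Observation":
        counts = np.asarray(counts, dtype=np.int64)
        m = np.log(counts + 1.0)
        return cls(counts=counts, measurements=m, mean_measurement=float(m.mean()))


@dataclass(frozen=True)
class EpisodeConfig:
    """Episode geometry, horizon and per-episode concentration sampling.

    ``d0_range`` and ``t_max`` are not tied to a single biological system;
    the defaults place the source well outside the arrival threshold while
    leaving ample slack over the straight-line travel time.
    ``conc_scale_range`` is the interval from which each episode's peak
    concentration ``C0`` is drawn log-uniformly (both bounds equal pins it).
    """

    d0_range: tuple[float, float] = (100.0, 500.0)
    delta: float = 10.0
    t_max: float = 2000.0
    dt: float = 0.1
    conc_scale_range: tuple[float, float] = (16.0, 160.0)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.d0_range
        if not (lo <= hi):
            raise ConfigurationError("d0_range must be ordered")
        if lo <= self.delta:
            raise ConfigurationError("d0_range lower bound must exceed delta")
        if self.delta <= 0:
            raise ConfigurationError("delta must be positive")
        if not (self.t_max >= self.dt > 0):
            raise ConfigurationError("need t_max >= dt > 0")
        clo, chi = self.conc_scale_range
        if not (0 < clo <= chi):
            raise ConfigurationError("conc_scale_range must be positive and ordered")

    @property
    def max_steps(self) -> int:
        return int(round(self.t_max / self.dt))


@dataclass(frozen=True)
class EpisodeResult:
    """Outcome of one simulated episode."""

    tau: float
    d_final: float
    d_init: float
    reached: bool
    reward: float
    trajectory: Optional[list] = None


# ---------------------------------------------------------------------------
# Fields
# ---------------------------------------------------------------------------


def _bessel_amplitude(f: FieldParams) -> float:
    r0 = f.match_radius
    return f.C0 * math.exp(-f.lambda_decay * r0) / float(bessel_k0(f.lambda_decay * r0))


def concentration_profile(f: FieldParams, r) -> np.ndarray | float:
    """Concentration at radial distance ``r`` (um) from the source."""
    r = np.asarray(r, dtype=np.float64)
    lam = f.lambda_decay
    if f.profile_kind == "exponential":
        out = f.C0 * np.exp(-lam * r)
    elif f.profile_kind == "algebraic":
        out = f.C0 / (1.0 + lam * r) ** 2
    elif f.profile_kind == "bessel":
        with np.errstate(divide="ignore"):
            out = _bessel_amplitude(f) * bessel_k0(lam * r)
    else:  # pragma: no cover - guarded in FieldParams
        raise ConfigurationError(f"unknown profile_kind {f.profile_kind!r}")
    return out if out.ndim else float(out)


def concentration_at(f: FieldParams, point: Sequence[float]) -> float:
    """Concentration at a 2D point (um)."""
    p = np.asarray(point, dtype=np.float64)
    return float(concentration_profile(f, np.hypot(p[..., 0], p[..., 1])))


# ---------------------------------------------------------------------------
# Sensing
# ---------------------------------------------------------------------------


def sensor_positions(cell: CellParams, state: CellState) -> np.ndarray:
    """(K, 2) sensor centres; sensor 0 faces along the heading, the rest
    follow counterclockwise.  The array co-rotates with the body frame."""
    k = np.arange(cell.n_sensors)
    ang = state.heading + 2.0 * math.pi * k / cell.n_sensors
    return state.position[None, :] + cell.radius * np.stack(
        [np.cos(ang), np.sin(ang)], axis=1
    )


def expected_counts(f: FieldParams, cell: CellParams, state: CellState) -> np.ndarray:
    """E(M_i) = C(d_i) * pi * r_s^2, d_i the sensor centre's distance to the
    source (the concentration is nearly constant over a sensor's disk)."""
    pos = sensor_positions(cell, state)
    d = np.hypot(pos[:, 0], pos[:, 1])
    return np.asarray(concentration_profile(f, d)) * math.pi * cell.sensor_radius**2


def sample_observation(
    f: FieldParams, cell: CellParams, state: CellState, rng: np.random.Generator
) -> Observation:
    """Independent Poisson counts per sensor (perfect-instrument model)."""
    lam = expected_counts(f, cell, state)
    return Observation.from_counts(rng.poisson(lam))


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------


def step(
    state: CellState,
    action: float,
    cell: CellParams,
    dt: float,
    rng: np.random.Generator,
) -> CellState:
    """One Euler–Maruyama step: heading updated first (action + rotational
    noise), then translation at speed v along the new heading.  Positive
    action turns counterclockwise (left)."""
    if not math.isfinite(action):
        raise SimulationError(f"non-finite action {action!r} at t={state.time}")
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    noise = math.sqrt(2.0 * cell.rot_diffusion * dt) * rng.standard_normal()
    theta = (state.heading + action * dt + noise) % (2.0 * math.pi)
    pos = state.position + cell.speed * dt * np.array(
        [math.cos(theta), math.sin(theta)]
    )
    return CellState(position=pos, heading=theta, time=state.time + dt)


def reset(
    config: EpisodeConfig,
    field_template: FieldParams,
    rng: np.random.Generator,
) -> tuple[CellState, FieldParams]:
    """Draw the initial state and the per-episode field.

    d0 is uniform over ``d0_range``, the start direction and heading are
    uniform on the circle, and the episode's C0 is log-uniform over
    ``conc_scale_range`` (so each decade of signal-to-noise is equally
    represented).
    """
    lo, hi = config.d0_range
    d0 = rng.uniform(lo, hi)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    clo, chi = config.conc_scale_range
    c0 = math.exp(rng.uniform(math.log(clo), math.log(chi)))
    f = replace(field_template, C0=c0)
    state = CellState(
        position=d0 * np.array([math.cos(phi), math.sin(phi)]),
        heading=theta0,
        time=0.0,
    )
    return state, f


# ---------------------------------------------------------------------------
# Reward and episode loop
# ---------------------------------------------------------------------------


def compute_reward(
    tau: float, d_final: float, d_init: float, config: EpisodeConfig
) -> float:
    """Terminal episode reward in [-1, 1].

    On arrival (``d_final`` clamps to ``delta``) only the time term
    ``(t_max - tau)/t_max`` is nonzero; on timeout (``tau = t_max``) only the
    distance term ``max(-1, (delta - d)/(d0 - delta))`` is.
    """
    if d_init <= config.delta:
        raise InvalidEpisodeError(
            f"initial distance {d_init} must exceed delta={config.delta}"
        )
    if tau > config.t_max + 1e-9:
        raise InvalidEpisodeError(f"tau={tau} exceeds t_max={config.t_max}")
    time_term = (config.t_max - tau) / config.t_max
    dist_term = max(-1.0, (config.delta - d_final) / (d_init - config.delta))
    return time_term + dist_term


def run_episode(
    policy,
    config: EpisodeConfig,
    field_template: FieldParams,
    cell: CellParams,
    rng: np.random.Generator,
    record: bool = False,
    deterministic: bool = True,
    horizon: Optional[float] = None,
) -> EpisodeResult:
    """Simulate one episode: observe -> act -> step until arrival or timeout.

    ``horizon`` overrides ``config.t_max`` for evaluation at longer horizons;
    the reward is always computed against ``config.t_max`` semantics with
    ``tau`` capped there.
    """
    state, f = reset(config, field_template, rng)
    t_end = config.t_max if horizon is None else horizon
    n_steps = int(round(t_end / config.dt))
    d_init = state.distance
    pol_state = policy.init_state()
    trajectory = [] if record else None

    reached = False
    tau = t_end
    for _ in range(n_steps):
        obs = sample_observation(f, cell, state, rng)
        action, pol_state = policy.act(
            obs, pol_state, rng, deterministic=deterministic, cell_state=state
        )
        if record:
            trajectory.append((state, obs, float(action)))
        state = step(state, float(action), cell, config.dt, rng)
        if state.distance <= config.delta:
            reached = True
            tau = state.time
            break

    d_final = config.delta if reached else state.distance
    reward = compute_reward(min(tau, config.t_max), d_final, d_init, config)
    return EpisodeResult(
        tau=tau,
        d_final=d_final,
        d_init=d_init,
        reached=reached,
        reward=reward,
        trajectory=trajectory,
    )
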