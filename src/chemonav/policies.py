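"""Navigation policies.

Three trainable neural variants share one architecture family (Fig-style
"mu / sigma / V" heads on top of an MLP, optionally fed by a gated
recurrent unit):

* ``spatial`` — a stateless feedforward network mapping the K instantaneous
  per-sensor measurements to an action: pure gradient sensing across the
  body, no memory.
* ``temporal`` — receives only the sensor average ``<m>`` (plus its own
  previous action) through a GRU: it must build gradient information over
  time, like a bacterium.
* ``combined`` — receives all K measurements plus the previous action
  through a GRU: it can express any mixture of spatial and temporal
  strategies.

All variants emit an action mean ``mu`` (bounded by ``action_scale`` via a
tanh squash), a state-dependent standard deviation ``sigma`` (softplus) and
a value estimate ``V``.  Positive actions turn the cell counterclockwise
(left).

Hand-coded baselines (blind, memory-kernel comparator, temporal-to-spatial
switching, and a perfect-aim oracle for tests) implement the same
``Policy`` interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import autodiff as F
from .environment import Observation

__all__ = [
    "PolicySpec",
    "HiddenState",
    "PolicyOutput",
    "init_params",
    "policy_forward",
    "forward_core",
    "sample_action",
    "NeuralPolicy",
    "BlindPolicy",
    "OraclePolicy",
    "ScriptedPolicy",
    "KernelPolicy",
    "SwitchingPolicy",
    "blind_policy",
    "kernel_policy",
    "switching_policy",
]

NEURAL_VARIANTS = ("spatial", "temporal", "combined")


class InterfaceError(ValueError):
    """Spec/observation dimension mismatch."""


@dataclass(frozen=True)
class PolicySpec:
    """Architecture description of a neural policy.

    ``obs_loc``/``obs_scale`` define a fixed affine rescaling of the
    Weber–Fechner measurements before they enter the network: over the
    concentration range studied, ``m = log(M + 1)`` spans roughly 0-9, so
    centering and shrinking to O(1) keeps tanh/sigmoid units away from
    saturation at initialisation.
    """

    variant: str
    n_sensors: int = 5
    hidden_size: int = 32
    mlp_widths: tuple[int, ...] = (64, 64)
    action_scale: float = math.pi
    feed_back_action: bool = True
    obs_loc: float = 4.0
    obs_scale: float = 3.0

    def __post_init__(self):
        if self.variant not in NEURAL_VARIANTS:
            raise InterfaceError(f"unknown neural variant {self.variant!r}")
        if self.action_scale <= 0:
            raise InterfaceError("action_scale must be positive")
        if self.is_recurrent and self.hidden_size < 1:
            raise InterfaceError("recurrent variants need hidden_size >= 1")

    @property
    def is_recurrent(self) -> bool:
        return self.variant in ("temporal", "combined")

    @property
    def input_size(self) -> int:
        """Width of the network input vector."""
        base = 1 if self.variant == "temporal" else self.n_sensors
        if self.is_recurrent and self.feed_back_action:
            base += 1
        return base


@dataclass(frozen=True)
class HiddenState:
    """Recurrent state; the zero vector at episode start."""

    values: np.ndarray

    @classmethod
    def zeros(cls, size: int) -> "HiddenState":
        return cls(values=np.zeros(size))


@dataclass(frozen=True)
class PolicyOutput:
    mu: float
    sigma: float
    value: float
    next_hidden: Optional[HiddenState]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    lim = math.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-lim, lim, size=(n_in, n_out))


def init_params(spec: PolicySpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Glorot-initialised parameter dictionary.

    The mu and value heads start near zero so untrained cells swim roughly
    straight; the sigma head bias puts the initial exploration noise at
    half the action scale.
    """
    p: dict[str, np.ndarray] = {}
    n_in = spec.input_size
    feat = n_in
    if spec.is_recurrent:
        H = spec.hidden_size
        for gate in ("z", "r", "n"):
            p[f"gru/W{gate}"] = _glorot(rng, n_in, H)
            p[f"gru/U{gate}"] = _glorot(rng, H, H)
            p[f"gru/b{gate}"] = np.zeros(H)
        p["gru/bhn"] = np.zeros(H)
        feat = H
    for i, w in enumerate(spec.mlp_widths):
        p[f"mlp/W{i}"] = _glorot(rng, feat, w)
        p[f"mlp/b{i}"] = np.zeros(w)
        feat = w
    for head in ("mu", "v"):
        p[f"{head}/W"] = 0.01 * _glorot(rng, feat, 1)
        p[f"{head}/b"] = np.zeros(1)
    p["sigma/W"] = 0.01 * _glorot(rng, feat, 1)
    # softplus(b) = 0.5 * action_scale
    target = 0.5 * spec.action_scale
    p["sigma/b"] = np.full(1, math.log(math.expm1(target)))
    return p


# ---------------------------------------------------------------------------
# Forward pass (numpy or autodiff Tensors, batched)
# ---------------------------------------------------------------------------


def _gru_step(params, x, h):
    mm = F.matmul
    z = F.sigmoid(mm(x, params["gru/Wz"]) + mm(h, params["gru/Uz"]) + params["gru/bz"])
    r = F.sigmoid(mm(x, params["gru/Wr"]) + mm(h, params["gru/Ur"]) + params["gru/br"])
    n = F.tanh(
        mm(x, params["gru/Wn"])
        + params["gru/bn"]
        + r * (mm(h, params["gru/Un"]) + params["gru/bhn"])
    )
    return (1.0 - z) * n + z * h


def input_vector(spec: PolicySpec, measurements, prev_action):
    """Assemble the network input from measurements (and fed-back action)."""
    if spec.variant == "temporal":
        x = F.mean(measurements, axis=1, keepdims=True)
    else:
        x = measurements
    x = (x - spec.obs_loc) * (1.0 / spec.obs_scale)
    if spec.is_recurrent and spec.feed_back_action:
        x = F.concat([x, prev_action * (1.0 / spec.action_scale)], axis=1)
    return x


def mlp_heads(spec: PolicySpec, params, feat):
    """MLP trunk plus the (mu, sigma, V) output heads."""
    i = 0
    while f"mlp/W{i}" in params:
        feat = F.tanh(F.matmul(feat, params[f"mlp/W{i}"]) + params[f"mlp/b{i}"])
        i += 1
    mu = spec.action_scale * F.tanh(F.matmul(feat, params["mu/W"]) + params["mu/b"])
    sigma = F.softplus(F.matmul(feat, params["sigma/W"]) + params["sigma/b"])
    value = F.matmul(feat, params["v/W"]) + params["v/b"]
    return mu, sigma, value


def forward_core(spec: PolicySpec, params, measurements, hidden, prev_action):
    """Batched forward pass.

    Parameters
    ----------
    measurements : (B, K) array or Tensor of Weber–Fechner measurements.
    hidden : (B, H) array or Tensor; ignored for the spatial variant.
    prev_action : (B, 1) array or Tensor (rad/s); used only by recurrent
        variants with action feedback.

    Returns ``(mu, sigma, value, next_hidden)`` with shapes (B, 1) each and
    (B, H) for the hidden state (``None`` for spatial).
    """
    x = input_vector(spec, measurements, prev_action)
    next_hidden = None
    if spec.is_recurrent:
        next_hidden = _gru_step(params, x, hidden)
        feat = next_hidden
    else:
        feat = x
    mu, sigma, value = mlp_heads(spec, params, feat)
    return mu, sigma, value, next_hidden


def policy_forward(
    spec: PolicySpec,
    params: dict[str, np.ndarray],
    obs: Observation,
    hidden: Optional[HiddenState],
    prev_action: float = 0.0,
) -> PolicyOutput:
    """Single-observation forward pass (deterministic given params/inputs)."""
    m = np.asarray(obs.measurements, dtype=np.float64)
    if spec.variant != "temporal" and m.shape[-1] != spec.n_sensors:
        raise InterfaceError(
            f"observation has {m.shape[-1]} sensors, spec expects {spec.n_sensors}"
        )
    h = None
    if spec.is_recurrent:
        hv = hidden.values if hidden is not None else np.zeros(spec.hidden_size)
        if hv.shape[-1] != spec.hidden_size:
            raise InterfaceError("hidden state width mismatch")
        h = hv[None, :]
    mu, sigma, value, nh = forward_core(
        spec, params, m[None, :], h, np.array([[prev_action]])
    )
    return PolicyOutput(
        mu=float(mu[0, 0]),
        sigma=float(sigma[0, 0]),
        value=float(value[0, 0]),
        next_hidden=HiddenState(nh[0]) if nh is not None else None,
    )


def sample_action(
    output: PolicyOutput, rng: np.random.Generator, deterministic: bool = False
) -> float:
    """Draw from Normal(mu, sigma); deterministic mode returns mu (exploration
    noise collapses by the end of training, so mu is the evaluation action)."""
    if deterministic or output.sigma == 0.0:
        return output.mu
    return output.mu + output.sigma * float(rng.standard_normal())


# ---------------------------------------------------------------------------
# Policy interface
# ---------------------------------------------------------------------------


class Policy:
    """Minimal interface: ``init_state`` and ``act``.

    ``act`` receives the policy's carried state and returns
    ``(action, new_state)``.  ``cell_state`` is supplied by the episode loop
    for oracle/test policies only; sensing policies must not use it.
    """

    def init_state(self):
        return None

    def act(self, obs, state, rng, deterministic=True, cell_state=None):
        raise NotImplementedError


@dataclass
class _NeuralState:
    hidden: Optional[np.ndarray]
    prev_action: float


class NeuralPolicy(Policy):
    """A (spec, params) pair behind the common policy interface."""

    def __init__(self, spec: PolicySpec, params: dict[str, np.ndarray]):
        self.spec = spec
        self.params = params

    def init_state(self) -> _NeuralState:
        h = np.zeros(self.spec.hidden_size) if self.spec.is_recurrent else None
        return _NeuralState(hidden=h, prev_action=0.0)

    def act(self, obs, state, rng, deterministic=True, cell_state=None):
        hidden = HiddenState(state.hidden) if state.hidden is not None else None
        out = policy_forward(self.spec, self.params, obs, hidden, state.prev_action)
        a = sample_action(out, rng, deterministic=deterministic)
        nh = out.next_hidden.values if out.next_hidden is not None else None
        return a, _NeuralState(hidden=nh, prev_action=a)


class BlindPolicy(Policy):
    """Never steers: pure ballistic motion randomised by rotational noise."""

    def act(self, obs, state, rng, deterministic=True, cell_state=None):
        return 0.0, None


def blind_policy() -> BlindPolicy:
    return BlindPolicy()


class OraclePolicy(Policy):
    """Turns straight toward the source each step (uses the true cell state;
    a kinematic reference for tests and efficiency normalisation checks)."""

    def __init__(self, dt: float):
        self.dt = dt

    def act(self, obs, state, rng, deterministic=True, cell_state=None):
        if cell_state is None:
            raise InterfaceError("OraclePolicy needs the true cell state")
        x, y = cell_state.position
        target = math.atan2(-y, -x)
        delta = (target - cell_state.heading + math.pi) % (2 * math.pi) - math.pi
        return delta / self.dt, None


class ScriptedPolicy(Policy):
    """Plays a fixed time-indexed schedule of actions (test aid)."""

    def __init__(self, fn):
        self.fn = fn  # fn(step_index, cell_state) -> action

    def init_state(self):
        return 0

    def act(self, obs, state, rng, deterministic=True, cell_state=None):
        return float(self.fn(state, cell_state)), state + 1


@dataclass
class _KernelState:
    window: np.ndarray  # (L, K), most recent row first
    filled: int


class KernelPolicy(Policy):
    """Memory-kernel comparator baseline.

    Keeps the last ``len(kernel_weights)`` measurement vectors and steers by

        a_t = gain * sum_l kernel[l] * sum_i sin(2 pi i / K) m_i(t - l)

    The sine weighting contrasts the left sensors (positive) against the
    right (negative), with the front sensor weighted zero; a delta kernel
    reduces to an instantaneous left-right comparison.  Steps before the
    window fills are padded with zeros.
    """

    def __init__(self, kernel_weights: Sequence[float], gain: float, n_sensors: int = 5):
        self.kernel = np.asarray(kernel_weights, dtype=np.float64)
        if not np.all(np.isfinite(self.kernel)):
            raise InterfaceError("kernel weights must be finite")
        self.gain = float(gain)
        self.n_sensors = n_sensors
        self.side_weights = np.sin(2.0 * math.pi * np.arange(n_sensors) / n_sensors)

    def init_state(self) -> _KernelState:
        return _KernelState(
            window=np.zeros((len(self.kernel), self.n_sensors)), filled=0
        )

    def act(self, obs, state, rng, deterministic=True, cell_state=None):
        window = np.roll(state.window, 1, axis=0)
        window[0] = obs.measurements
        contrast = window @ self.side_weights
        a = self.gain * float(self.kernel @ contrast)
        return a, _KernelState(window=window, filled=min(state.filled + 1, len(self.kernel)))


def kernel_policy(kernel_weights: Sequence[float], gain: float, n_sensors: int = 5) -> KernelPolicy:
    return KernelPolicy(kernel_weights, gain, n_sensors)


@dataclass
class _SwitchState:
    switched: bool
    inner_temporal: object
    inner_spatial: object


class SwitchingPolicy(Policy):
    """Noise-robust temporal strategy far out, reactive spatial strategy near
    the source: delegates to the temporal sub-policy until the mean
    measurement first crosses ``threshold``, then latches onto the spatial
    sub-policy for the rest of the episode."""

    def __init__(self, temporal_policy: Policy, spatial_policy: Policy, threshold: float):
        self.temporal = temporal_policy
        self.spatial = spatial_policy
        self.threshold = threshold

    def init_state(self) -> _SwitchState:
        return _SwitchState(
            switched=False,
            inner_temporal=self.temporal.init_state(),
            inner_spatial=self.spatial.init_state(),
        )

    def act(self, obs, state, rng, deterministic=True, cell_state=None):
        switched = state.switched or obs.mean_measurement >= self.threshold
        if switched:
            a, inner = self.spatial.act(
                obs, state.inner_spatial, rng, deterministic, cell_state
            )
            return a, _SwitchState(True, state.inner_temporal, inner)
        a, inner = self.temporal.act(
            obs, state.inner_temporal, rng, deterministic, cell_state
        )
        return a, _SwitchState(False, inner, state.inner_spatial)


def switching_policy(temporal_policy: Policy, spatial_policy: Policy, threshold: float) -> SwitchingPolicy:
    return SwitchingPolicy(temporal_policy, spatial_policy, threshold)
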