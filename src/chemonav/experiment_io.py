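"""Configuration, fixtures, checkpoints, trajectory output and manifests.

Checkpoints are a single JSON document: a metadata block (format version,
policy spec, optional run info) plus every parameter array stored losslessly
as base64-encoded raw bytes with dtype and shape.  The encoding is
deterministic, so save -> load -> save reproduces the file byte for byte.
"""

from __future__ import annotations

import base64
import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .environment import (
    CellParams,
    EpisodeConfig,
    EpisodeResult,
    FieldParams,
)
from .policies import PolicySpec
from .training import PPOConfig

CHECKPOINT_VERSION = 1


class CheckpointError(RuntimeError):
    """Unreadable, corrupted, or incompatible checkpoint file."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_SECTIONS = {
    "field": (FieldParams, {"C0": 16.0, "lambda_decay": 0.032}),
    "cell": (CellParams, {}),
    "episode": (EpisodeConfig, {}),
    "ppo": (PPOConfig, {}),
}


def default_config() -> dict:
    """All defaults, as a plain nested dict (the `config --dump` payload)."""
    out = {}
    for name, (cls, overrides) in _SECTIONS.items():
        kwargs = dict(overrides)
        obj = cls(**kwargs)
        out[name] = _to_plain(dataclasses.asdict(obj))
    out["policy"] = {
        "hidden_size": 32,
        "mlp_widths": [64, 64],
        "action_scale": math.pi,
        "feed_back_action": True,
    }
    return out


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def load_config(path=None, overrides: Optional[dict] = None) -> dict:
    """Layered config: package defaults < file < explicit overrides."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, vals in user.items():
            if section not in cfg:
                raise KeyError(f"unknown config section {section!r}")
            cfg[section].update(vals or {})
    for section, vals in (overrides or {}).items():
        cfg[section].update(vals)
    return cfg


def dump_config(cfg: dict) -> str:
    return yaml.safe_dump(cfg, sort_keys=True)


def _tupled(d, keys):
    d = dict(d)
    for k in keys:
        if k in d and d[k] is not None:
            d[k] = tuple(d[k])
    return d


def build_objects(cfg: dict, variant: str = "combined"):
    """Instantiate (field, cell, episode, ppo, spec) from a config dict."""
    f = FieldParams(**cfg["field"])
    cell_kwargs = dict(cfg["cell"])
    cell_kwargs.pop("sensor_radius", None)
    cell = CellParams(**cell_kwargs)
    episode = EpisodeConfig(**_tupled(cfg["episode"], ("d0_range", "conc_scale_range")))
    ppo = PPOConfig(**cfg["ppo"])
    pol = cfg["policy"]
    spec = PolicySpec(
        variant=variant,
        n_sensors=cell.n_sensors,
        hidden_size=pol["hidden_size"],
        mlp_widths=tuple(pol["mlp_widths"]),
        action_scale=pol["action_scale"],
        feed_back_action=pol["feed_back_action"],
    )
    return f, cell, episode, ppo, spec


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def _encode_array(a: np.ndarray) -> dict:
    a = np.ascontiguousarray(a)
    return {
        "dtype": a.dtype.str,
        "shape": list(a.shape),
        "data": base64.b64encode(a.tobytes()).decode("ascii"),
    }


def _decode_array(d: dict) -> np.ndarray:
    raw = base64.b64decode(d["data"])
    a = np.frombuffer(raw, dtype=np.dtype(d["dtype"])).reshape(d["shape"])
    return a.copy()


def save_checkpoint(
    path,
    params: dict[str, np.ndarray],
    spec: PolicySpec,
    manifest: Optional[dict] = None,
) -> None:
    """Serialize named parameter arrays plus spec metadata (lossless)."""
    doc = {
        "version": CHECKPOINT_VERSION,
        "code_version": __version__,
        "spec": _to_plain(dataclasses.asdict(spec)),
        "manifest": _to_plain(manifest or {}),
        "params": {k: _encode_array(v) for k, v in sorted(params.items())},
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, separators=(",", ":")))


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], PolicySpec]:
    try:
        doc = json.loads(Path(path).read_text())
        version = doc["version"]
    except (json.JSONDecodeError, UnicodeDecodeError, KeyError) as exc:
        raise CheckpointError(f"unreadable checkpoint {path}: {exc}") from exc
    if version != CHECKPOINT_VERSION:
        raise CheckpointError(
            f"checkpoint format version {version} != supported {CHECKPOINT_VERSION}; "
            "explicit migration required"
        )
    try:
        params = {k: _decode_array(v) for k, v in doc["params"].items()}
        spec_d = doc["spec"]
        spec = PolicySpec(
            variant=spec_d["variant"],
            n_sensors=spec_d["n_sensors"],
            hidden_size=spec_d["hidden_size"],
            mlp_widths=tuple(spec_d["mlp_widths"]),
            action_scale=spec_d["action_scale"],
            feed_back_action=spec_d["feed_back_action"],
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise CheckpointError(f"corrupted checkpoint {path}: {exc}") from exc
    return params, spec


# ---------------------------------------------------------------------------
# Trajectory output
# ---------------------------------------------------------------------------


def trajectory_frame(result: EpisodeResult, episode_id: int = 0, manifest_ref: str = ""):
    """Long-format trajectory table: t, x, y, theta, action, M_i..., m_i...."""
    import pandas as pd

    if result.trajectory is None:
        raise ValueError("episode was run without record=True")
    rows = []
    for state, obs, action in result.trajectory:
        row = {
            "episode_id": episode_id,
            "t": state.time,
            "x": state.position[0],
            "y": state.position[1],
            "theta": state.heading,
            "action": action,
        }
        for i, (M, m) in enumerate(zip(obs.counts, obs.measurements)):
            row[f"M_{i}"] = int(M)
            row[f"m_{i}"] = float(m)
        row["manifest"] = manifest_ref
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Reproducibility record written by every CLI run."""

    command: str
    config: dict
    seed: int
    code_version: str = __version__
    timestamp: str = ""
    outputs: dict = field(default_factory=dict)

    def add_output(self, path) -> None:
        p = Path(path)
        self.outputs[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()

    def write(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["config"] = _to_plain(doc["config"])
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("straight_run", "linear_policy", "poisson_batch")


def generate_fixture(name: str, seed: int, out_dir=None):
    """Deterministic tiny test assets.

    ``straight_run``: a 50-step noiseless episode driven by the perfect-aim
    oracle (distance to source strictly decreasing).
    ``linear_policy``: a 6-weight linear map for closed-form attribution
    checks (integrated gradients of w.x from a zero baseline are w_i x_i).
    ``poisson_batch``: 3 episodes x 100 steps of sensor counts at one frozen
    state, for Poisson moment tests.

    With ``out_dir`` the asset is also written to disk (CSV/JSON); identical
    seeds produce byte-identical files.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 0xF1C5])))
    if name == "straight_run":
        from .environment import run_episode
        from .policies import OraclePolicy

        config = EpisodeConfig(d0_range=(260.0, 260.0), delta=10.0, t_max=5.0, dt=0.1)
        f = FieldParams(C0=160.0, lambda_decay=0.032)
        cell = CellParams(rot_diffusion=0.0)
        result = run_episode(
            OraclePolicy(config.dt), config, f, cell, rng, record=True, deterministic=True
        )
        asset = trajectory_frame(result, episode_id=0, manifest_ref=f"fixture:{name}:{seed}")
        if out_dir is not None:
            asset.to_csv(Path(out_dir) / f"{name}.csv", index=False, float_format="%.12g")
        return asset
    if name == "linear_policy":
        w = np.round(rng.uniform(-1.0, 1.0, size=6), 6)
        asset = {"weights": w, "description": "linear policy pi(x) = w . x"}
        if out_dir is not None:
            Path(Path(out_dir) / f"{name}.json").write_text(
                json.dumps({"weights": w.tolist()}, sort_keys=True)
            )
        return asset
    # poisson_batch
    f = FieldParams(C0=160.0, lambda_decay=0.032)
    cell = CellParams()
    from .environment import CellState, expected_counts

    state = CellState(position=np.array([60.0, 25.0]), heading=0.7)
    lam = expected_counts(f, cell, state)
    counts = rng.poisson(lam, size=(3, 100, cell.n_sensors))
    asset = {"expected": lam, "counts": counts, "state": state}
    if out_dir is not None:
        import pandas as pd

        e, t, k = np.meshgrid(np.arange(3), np.arange(100), np.arange(cell.n_sensors), indexing="ij")
        pd.DataFrame(
            {"episode": e.ravel(), "step": t.ravel(), "sensor": k.ravel(), "count": counts.ravel()}
        ).to_csv(Path(out_dir) / f"{name}.csv", index=False)
    return asset
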