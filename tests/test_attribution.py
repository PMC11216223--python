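"""Integrated gradients, memory usage, and through-time attributions."""

import numpy as np
import pytest

from chemonav import (
    CellParams,
    EpisodeConfig,
    FieldParams,
    NeuralPolicy,
    PolicySpec,
    init_params,
    integrated_gradients,
    memory_usage,
)
from chemonav.attribution import (
    AttributionRecord,
    attribute_step,
    input_partition,
    instant_attributions,
    memory_usage_map,
    memory_usage_trace,
    unrolled_attribution,
)
from chemonav.autodiff import Tensor
from chemonav.rollout import simulate_batch


def linear_fn(w):
    w = np.asarray(w, float)

    def fn(x):
        return x @ w[:, None]

    return fn


class TestIntegratedGradients:
    def test_linear_map_closed_form(self):
        """For pi(x) = w.x with zero baseline, I_i = w_i x_i exactly."""
        rng = np.random.default_rng(0)
        w = rng.normal(size=6)
        x = rng.normal(size=6)
        rec = integrated_gradients(linear_fn(w), x, n_steps=8)
        np.testing.assert_allclose(rec.importances, w * x, rtol=1e-12)
        assert rec.completeness_error < 1e-12

    def test_input_at_baseline_gets_zero_attribution(self):
        rng = np.random.default_rng(1)
        w = rng.normal(size=4)
        x = np.array([1.0, 0.0, -2.0, 0.0])
        rec = integrated_gradients(linear_fn(w), x, n_steps=4)
        assert rec.importances[1] == 0.0
        assert rec.importances[3] == 0.0

    def test_completeness_on_random_recurrent_policies(self):
        """|pi(x) - pi(0) - sum I_i| within 1e-3 relative at 512 grid points,
        across 20 random networks and inputs."""
        from chemonav.attribution import action_fn, flat_input

        rng = np.random.default_rng(42)
        for trial in range(20):
            spec = PolicySpec(
                "combined", n_sensors=5, hidden_size=6, mlp_widths=(12,)
            )
            params = init_params(spec, rng)
            # exaggerate weights so the map is decidedly nonlinear
            params = {k: v * 3.0 for k, v in params.items()}
            m = rng.uniform(0.0, 8.0, size=5)
            h = rng.normal(size=6)
            x = flat_input(spec, m, rng.normal() * 2.0, h)
            rec = integrated_gradients(action_fn(spec, params), x, n_steps=512)
            span = abs(rec.output - rec.baseline_output)
            assert rec.completeness_error <= 1e-3 * max(span, 1e-12)

    @pytest.mark.filterwarnings("ignore::chemonav.attribution.CompletenessWarning")
    def test_halving_grid_spacing_does_not_worsen_completeness(self):
        """Midpoint-rule convergence on smooth tanh policies: doubling
        n_steps never increases the completeness error."""
        from chemonav.attribution import action_fn, flat_input

        rng = np.random.default_rng(9)
        spec = PolicySpec("combined", n_sensors=5, hidden_size=4, mlp_widths=(8,))
        params = {k: v * 3.0 for k, v in init_params(spec, rng).items()}
        x = flat_input(spec, rng.uniform(0, 8, 5), 0.5, rng.normal(size=4))
        fn = action_fn(spec, params)
        errors = [
            integrated_gradients(fn, x, n_steps=n).completeness_error
            for n in (16, 32, 64, 128, 256)
        ]
        assert all(e2 <= e1 + 1e-15 for e1, e2 in zip(errors, errors[1:]))

    def test_warning_when_grid_too_coarse(self):
        """A strongly curved map on two grid points cannot satisfy the
        completeness tolerance; a warning suggests refining."""
        def fn(x):
            from chemonav import autodiff as F

            return F.tanh(x * 4.0).sum(axis=1, keepdims=True)

        from chemonav.attribution import CompletenessWarning

        with pytest.warns(CompletenessWarning):
            integrated_gradients(fn, np.array([2.0]), n_steps=2)


class TestMemoryUsage:
    def _record(self, importances):
        return AttributionRecord(
            importances=np.asarray(importances, float),
            baseline=np.zeros(len(importances)),
            n_steps=8,
            completeness_error=0.0,
            output=1.0,
            baseline_output=0.0,
        )

    def test_degenerate_cases(self):
        part = {
            "measurements": np.arange(0, 2),
            "prev_action": np.arange(2, 3),
            "hidden": np.arange(3, 5),
        }
        only_hidden = self._record([0.0, 0.0, 9.0, 0.4, -0.6])
        assert memory_usage(only_hidden, part) == 1.0
        only_meas = self._record([0.3, -0.2, 9.0, 0.0, 0.0])
        assert memory_usage(only_meas, part) == 0.0
        neither = self._record([0.0, 0.0, 9.0, 0.0, 0.0])
        assert np.isnan(memory_usage(neither, part))

    def test_bounded_and_scale_invariant(self):
        rng = np.random.default_rng(3)
        part = {
            "measurements": np.arange(0, 5),
            "prev_action": np.arange(5, 6),
            "hidden": np.arange(6, 14),
        }
        for _ in range(50):
            imp = rng.normal(size=14)
            u = memory_usage(self._record(imp), part)
            assert 0.0 <= u <= 1.0
            u_scaled = memory_usage(self._record(imp * 37.5), part)
            assert u_scaled == pytest.approx(u)

    def test_partition_must_cover_inputs(self):
        part = {
            "measurements": np.arange(0, 2),
            "prev_action": np.arange(0),
            "hidden": np.arange(2, 3),
        }
        with pytest.raises(ValueError):
            memory_usage(self._record([1.0, 2.0, 3.0, 4.0]), part)

    def test_spatial_policy_memory_usage_is_zero(self, rng):
        spec = PolicySpec("spatial", n_sensors=5, mlp_widths=(16,))
        params = init_params(spec, rng)
        for _ in range(5):
            m = rng.uniform(0.0, 8.0, size=5)
            rec = attribute_step(spec, params, m, n_steps=32)
            assert rec.memory_usage == 0.0

    def test_hidden_only_toy_policy_memory_usage_is_one(self):
        """A recurrent policy whose measurement and action input weights are
        all zero acts on memory alone: U_h = 1."""
        spec = PolicySpec("combined", n_sensors=5, hidden_size=4, mlp_widths=(8,))
        params = init_params(spec, np.random.default_rng(4))
        for gate in ("z", "r", "n"):
            params[f"gru/W{gate}"] = np.zeros_like(params[f"gru/W{gate}"])
        rec = attribute_step(
            spec, params, np.array([1.0, 2.0, 3.0, 2.0, 1.0]),
            prev_action=0.4, hidden=np.array([0.5, -0.3, 0.2, 0.1]), n_steps=64,
        )
        assert rec.memory_usage == pytest.approx(1.0)


class TestUnrolledAttribution:
    @pytest.fixture
    def short_trajectory(self, rng):
        T, K = 12, 5
        return rng.uniform(0, 6, size=(T, K)), rng.normal(size=12) * 0.5

    def test_spatial_policy_has_no_past_attribution(self, rng, short_trajectory):
        m, a = short_trajectory
        spec = PolicySpec("spatial", n_sensors=5, mlp_widths=(16,))
        policy = NeuralPolicy(spec, init_params(spec, rng))
        rec = unrolled_attribution(policy, m, a, t_index=9, t_back=6, n_steps=32)
        assert rec.importances.shape == (6, 5)
        np.testing.assert_array_equal(rec.importances[1:], 0.0)
        assert np.any(rec.importances[0] != 0.0)

    def test_temporal_policy_attributions_sensor_symmetric(self, rng, short_trajectory):
        m, a = short_trajectory
        spec = PolicySpec("temporal", n_sensors=5, hidden_size=6, mlp_widths=(12,))
        policy = NeuralPolicy(spec, init_params(spec, rng))
        rec = unrolled_attribution(policy, m, a, t_index=9, t_back=6, n_steps=64)
        # each lag: equal attribution per unit measurement across sensors
        sens = rec.importances / np.where(m[4:10][::-1] == 0, 1.0, m[4:10][::-1])
        for lag in range(6):
            np.testing.assert_allclose(sens[lag], sens[lag, 0], rtol=1e-9, atol=1e-12)

    def test_unrolled_completeness(self, rng, short_trajectory):
        m, a = short_trajectory
        spec = PolicySpec("combined", n_sensors=5, hidden_size=6, mlp_widths=(12,))
        policy = NeuralPolicy(spec, init_params(spec, rng))
        rec = unrolled_attribution(policy, m, a, t_index=9, t_back=6, n_steps=512)
        span = abs(rec.output - rec.baseline_output)
        assert rec.completeness_error <= 1e-3 * max(span, 1e-12)
        assert not rec.truncated

    def test_short_trajectory_is_truncated_and_flagged(self, rng, short_trajectory):
        m, a = short_trajectory
        spec = PolicySpec("combined", n_sensors=5, hidden_size=6, mlp_widths=(12,))
        policy = NeuralPolicy(spec, init_params(spec, rng))
        rec = unrolled_attribution(policy, m, a, t_index=3, t_back=10, n_steps=16)
        assert rec.truncated
        assert rec.importances.shape == (4, 5)


class TestMemoryUsageMap:
    FIELD = FieldParams(C0=1600.0, lambda_decay=0.032)
    EPISODE = EpisodeConfig(
        d0_range=(40.0, 70.0), delta=10.0, t_max=4.0, dt=0.1,
        conc_scale_range=(1600.0, 1600.0),
    )

    def test_table_dimensions_and_range(self, rng):
        spec = PolicySpec("combined", n_sensors=5, hidden_size=6, mlp_widths=(12,))
        policy = NeuralPolicy(spec, init_params(spec, rng))
        radii = [1.0, 2.0]
        scales = [160.0, 1600.0]
        table, profile = memory_usage_map(
            policy, radii, scales, self.EPISODE, CellParams(radius=2.0),
            self.FIELD, n_runs=3, seed=0, n_distance_bins=4,
        )
        assert len(table) == len(radii) * len(scales)
        vals = table["mean_Uh"].dropna()
        assert ((vals >= 0) & (vals <= 1)).all()
        assert len(profile) == 4
        pv = profile["mean_Uh"].dropna()
        assert ((pv >= 0) & (pv <= 1)).all()

    def test_memory_heavy_temporal_policy_scores_above_half(self):
        """A temporal-variant network built to lean on its hidden state
        (strong recurrent weights, weak instantaneous path) shows U_h > 0.5
        along a trajectory."""
        spec = PolicySpec("temporal", n_sensors=5, hidden_size=6, mlp_widths=(12,))
        params = init_params(spec, np.random.default_rng(5))
        for gate in ("z", "r", "n"):
            params[f"gru/W{gate}"] = params[f"gru/W{gate}"] * 0.05
            params[f"gru/U{gate}"] = params[f"gru/U{gate}"] * 4.0
        policy = NeuralPolicy(spec, params)
        cell = CellParams(radius=2.0)
        res = simulate_batch(
            policy, self.EPISODE, self.FIELD, cell, 11, 2,
            deterministic=True, collect=True,
        )
        trace = memory_usage_trace(policy, res, 0, n_steps=32)
        # skip the first few steps while the hidden state spins up from zero
        assert np.nanmean(trace[5:]) > 0.5

    def test_spatial_trace_is_identically_zero(self, rng):
        spec = PolicySpec("spatial", n_sensors=5, mlp_widths=(16,))
        policy = NeuralPolicy(spec, init_params(spec, rng))
        res = simulate_batch(
            policy, self.EPISODE, self.FIELD, CellParams(radius=2.0), 12, 2,
            deterministic=True, collect=True,
        )
        trace = memory_usage_trace(policy, res, 0)
        np.testing.assert_array_equal(trace, 0.0)


CELL = CellParams(radius=2.0)


def test_instant_attributions_match_single_step(rng):
    """The vectorized many-step path agrees with attribute_step."""
    spec = PolicySpec("combined", n_sensors=5, hidden_size=4, mlp_widths=(8,))
    params = init_params(spec, rng)
    m = rng.uniform(0, 6, size=(3, 5))
    pa = rng.normal(size=3) * 0.5
    h = rng.normal(size=(3, 4)) * 0.3
    imp = instant_attributions(spec, params, m, pa, h, n_steps=16)
    for t in range(3):
        rec = attribute_step(spec, params, m[t], float(pa[t]), h[t], n_steps=16)
        np.testing.assert_allclose(imp[t], rec.importances, rtol=1e-10, atol=1e-12)
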