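"""Geometry, connectivity kernel, normalization maps and dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from avcausal.network import (
    ConnectivityParams,
    build_connectivity,
    build_geometry,
    net_input,
    normalize_linear,
    normalize_squared,
    run_dynamics,
)
from avcausal.readout import detect_bumps
from avcausal.stimulus import StimulusConfig, mean_input


class TestGeometry:
    def test_default_grid_matches_angle_formula(self, geom):
        # theta_i = 0.1 * i - 50 on the default 1000-neuron strip
        i = np.arange(1000)
        np.testing.assert_allclose(geom.preferred_angles, 0.1 * i - 50.0, atol=1e-12)
        assert geom.spacing == pytest.approx(0.1)
        assert geom.preferred_angles[500] == pytest.approx(0.0)

    def test_two_point_grid(self):
        g = build_geometry(2, 0.0, 1.0)
        np.testing.assert_allclose(g.preferred_angles, [0.0, 0.5])

    @pytest.mark.parametrize("n,lo,hi", [(1, 0, 1), (0, 0, 1), (10, 5, 5), (10, 5, -5)])
    def test_invalid_arguments_rejected(self, n, lo, hi):
        with pytest.raises(ValueError):
            build_geometry(n, lo, hi)

    def test_angles_strictly_increasing(self, geom):
        assert np.all(np.diff(geom.preferred_angles) > 0)


class TestConnectivity:
    def test_self_coupling_value(self, geom, weights):
        # hand-evaluated difference of Gaussians at zero distance:
        # 28/(1.5 sqrt(2 pi)) - 10/(3 sqrt(2 pi)) = 7.44721... - 1.32981...
        expected = 28 / (1.5 * math.sqrt(2 * math.pi)) - 10 / (3 * math.sqrt(2 * math.pi))
        assert expected == pytest.approx(6.1171, abs=1e-4)
        np.testing.assert_allclose(np.diag(weights), expected)

    def test_symmetric_and_distance_dependent(self, weights):
        np.testing.assert_allclose(weights, weights.T)
        # same |angle difference| -> same weight, regardless of location
        assert weights[100, 130] == pytest.approx(weights[600, 630])

    def test_net_inhibition_at_distance(self, geom, weights):
        # 6 deg apart = 60 grid steps: excitation (sigma1=1.5) has decayed
        # faster than inhibition (sigma2=3), leaving net suppression
        assert weights[500, 560] < 0
        assert weights[500, 500] > 0

    def test_equal_gaussians_cancel(self, small_geom):
        j = build_connectivity(small_geom, ConnectivityParams(m1=5, m2=5, sigma1=2, sigma2=2))
        np.testing.assert_allclose(j, 0.0, atol=1e-14)

    @pytest.mark.parametrize(
        "kwargs", [dict(m1=-1), dict(m1=0), dict(m2=-0.5), dict(sigma1=0), dict(sigma2=-1)]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ConnectivityParams(**kwargs)


class TestNormalization:
    def test_linear_uniform_input(self):
        c = 3.0
        a = np.full(50, c)
        np.testing.assert_allclose(normalize_linear(a), c / (1 + c))

    def test_linear_kills_nonpositive(self):
        assert np.all(normalize_linear(np.array([-2.0, 0.0, -0.1])) == 0.0)
        assert np.all(normalize_linear(np.zeros(10)) == 0.0)

    def test_squared_uniform_input(self):
        c = 3.0
        np.testing.assert_allclose(normalize_squared(np.full(50, c)), c**2 / (1 + c**2))

    def test_squared_two_neuron_example(self):
        # denominator 1 + (1 + 4)/2 = 3.5
        u = normalize_squared(np.array([1.0, 2.0]))
        np.testing.assert_allclose(u, [1 / 3.5, 4 / 3.5])

    @given(a=arrays(float, 40, elements=st.floats(-50, 50)))
    @settings(max_examples=50, deadline=None)
    def test_outputs_nonnegative_and_bounded(self, a):
        ul, us = normalize_linear(a), normalize_squared(a)
        assert np.all(ul >= 0) and np.all(us >= 0)
        # mean of [a]+/(1+mean[a]+) is mean/(1+mean) < 1, same algebra squared
        assert ul.mean() < 1.0 and us.mean() < 1.0


class TestNetInput:
    def test_zero_rates_pass_external_through(self, small_weights):
        h = np.linspace(0, 1, 64)
        np.testing.assert_allclose(net_input(np.zeros(64), small_weights, h), h)

    def test_no_input_no_rates(self, small_weights):
        np.testing.assert_allclose(net_input(np.zeros(64), small_weights), 0.0)

    def test_single_unit_reads_weight_column(self, small_weights):
        u = np.zeros(64)
        u[10] = 1.0
        np.testing.assert_allclose(net_input(u, small_weights), small_weights[:, 10])

    def test_dimension_mismatch(self, small_weights):
        with pytest.raises(ValueError):
            net_input(np.zeros(65), small_weights)
        with pytest.raises(ValueError):
            net_input(np.zeros(64), small_weights, h=np.zeros(63))


def _noiseless_input(geom, x_v, x_a):
    cfg = StimulusConfig(s_v=x_v, s_a=x_a)
    return mean_input(x_v, x_a, cfg, geom)


class TestDynamics:
    def test_zero_input_stays_at_zero(self, small_weights):
        res = run_dynamics(np.zeros(64), small_weights)
        assert res.converged
        np.testing.assert_allclose(res.state.u, 0.0)

    def test_coincident_cues_form_single_bump_at_zero(self, geom, weights):
        res = run_dynamics(_noiseless_input(geom, 0.0, 0.0), weights)
        bumps = detect_bumps(res.state.u, geom)
        assert bumps.count == 1
        assert bumps.peaks[0].position == pytest.approx(0.0, abs=0.2)

    def test_far_cues_form_two_bumps(self, geom, weights):
        res = run_dynamics(_noiseless_input(geom, -15.0, 15.0), weights)
        assert detect_bumps(res.state.u, geom).count == 2

    def test_rates_nonnegative_under_noisy_drive(self, small_weights, rng):
        h = rng.normal(0, 3, size=64)
        for mode in ("linear", "squared"):
            res = run_dynamics(h, small_weights, mode=mode, record_trajectory=True)
            assert np.all(res.trajectory >= 0)

    def test_mean_rate_bounded_under_linear_normalization(self, geom, weights, rng):
        h = _noiseless_input(geom, -5.0, 5.0) + rng.normal(0, 1, 1000)
        res = run_dynamics(h, weights, record_trajectory=True)
        assert np.all(res.trajectory[1:].mean(axis=1) < 1.0)

    def test_translation_equivariance(self, geom, weights):
        delta = 7.0
        res0 = run_dynamics(_noiseless_input(geom, -10.0, 5.0), weights)
        res1 = run_dynamics(_noiseless_input(geom, -10.0 + delta, 5.0 + delta), weights)
        p0 = [b.position for b in detect_bumps(res0.state.u, geom).peaks]
        p1 = [b.position for b in detect_bumps(res1.state.u, geom).peaks]
        assert len(p0) == len(p1)
        for a, b in zip(p0, p1):
            assert b - a == pytest.approx(delta, abs=geom.spacing)

    @pytest.mark.parametrize("d", [5.0, 10.0, 15.0, 20.0, 25.0, 30.0])
    def test_squared_normalization_winner_take_all(self, geom, weights, d):
        # strong (exponent-2) normalization fuses cues at any disparity
        res = run_dynamics(_noiseless_input(geom, -d / 2, d / 2), weights, mode="squared")
        assert detect_bumps(res.state.u, geom).count == 1

    def test_converged_state_is_a_fixed_point(self, geom, weights):
        h = _noiseless_input(geom, 0.0, 0.0)
        res = run_dynamics(h, weights, max_steps=500, tol=1e-10)
        assert res.converged
        u_next = normalize_linear(weights @ res.state.u)
        assert np.max(np.abs(u_next - res.state.u)) < 1e-9

    def test_nonconvergence_is_flagged_not_raised(self, geom, weights):
        res = run_dynamics(_noiseless_input(geom, -10.0, 10.0), weights, max_steps=20)
        assert not res.converged
        assert res.n_steps == 20

    def test_trajectory_export_schema(self, small_geom, small_weights):
        from avcausal.network import trajectory_frame

        h = _noiseless_input(small_geom, 0.0, 0.0)
        res = run_dynamics(h, small_weights, record_trajectory=True)
        df = trajectory_frame(res, small_geom)
        assert list(df.columns) == ["t", "theta", "u"]
        assert len(df) == (res.n_steps + 1) * small_geom.n
        with pytest.raises(ValueError):
            trajectory_frame(run_dynamics(h, small_weights), small_geom)

    def test_invalid_step_counts_rejected(self, small_weights):
        with pytest.raises(ValueError):
            run_dynamics(np.zeros(64), small_weights, input_steps=0)
        with pytest.raises(ValueError):
            run_dynamics(np.zeros(64), small_weights, input_steps=5, max_steps=5)
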