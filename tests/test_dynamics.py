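"""Right-hand-side assembly: neural inputs, muscles, friction, body forces.

The mechanical block is checked against an independently written free-body
oracle that loops over every spring, damper, muscle and friction contact
one at a time.
"""

import numpy as np
import pytest

import larvacrawl as lc
from larvacrawl import _kernels
from larvacrawl.dynamics import (assemble_rhs, body_rhs,
                                 elastic_damping_muscle_forces,
                                 friction_forces, muscle_rhs, neural_inputs,
                                 neural_rhs, pack_state, packed_rhs,
                                 proprio_switch)
from conftest import random_valid_state


def contracted_state(params, segment, contraction):
    """Rest state with one segment contracted (rod-consistent: the lost
    length is recovered by stretching the diametrically placed segment)."""
    s = lc.rest_state(params)
    other = 1 if segment != 1 else 2
    delta = contraction * params.L
    if segment > other:
        for j in range(other, segment):
            s.x[j] -= delta
    else:
        for j in range(segment, other):
            s.x[j] += delta
    s.x[-1] = s.x[0] - params.n_units * params.L
    return s


class TestProprioSwitch:
    def test_rest_is_off(self, params):
        assert np.max(proprio_switch(lc.rest_state(params), params)) < 1e-12

    def test_contracted_segment_fires(self, params):
        s = contracted_state(params, segment=2, contraction=0.3)
        sw = proprio_switch(s, params)
        assert sw[1] > 1 - 1e-12  # segment 2 (0-based index 1)

    def test_midpoint_at_threshold(self, params):
        s = contracted_state(params, segment=3, contraction=1.0 / 18.0)
        assert proprio_switch(s, params)[2] == pytest.approx(0.5, abs=1e-9)


class TestNeuralInputs:
    def test_posterior_neighbor_coupling(self, params):
        s = lc.rest_state(params)
        s.E[1] = 0.8  # unit 2
        inp = neural_inputs(s, params)
        assert inp.h_E[0] == pytest.approx(params.w_En * 0.8, abs=1e-12)

    def test_quiescent_inputs_vanish(self, params):
        inp = neural_inputs(lc.rest_state(params), params)
        assert np.max(np.abs(inp.h_E)) < 1e-9
        assert np.max(np.abs(inp.h_I)) < 1e-9

    def test_long_range_tail_reinitiation(self, params):
        # segment 1 contracted by 0.2 L: its stretch receptor saturates and
        # feeds both the tail E unit (T2->A8 route) and its own I unit
        s = contracted_state(params, segment=1, contraction=0.2)
        inp = neural_inputs(s, params)
        assert inp.h_E[9] == pytest.approx(params.w_Ep, abs=1e-9)
        assert inp.h_I[0] == pytest.approx(params.w_Ip, abs=1e-9)

    def test_silencing_is_exact(self, params):
        """With w_Ep = w_Ip = 0 the body configuration cannot reach the VNC."""
        silenced = params.with_overrides(w_Ep=0.0, w_Ip=0.0)
        rng = np.random.default_rng(7)
        for _ in range(5):
            s = random_valid_state(silenced, rng, scale=0.3)
            inp = neural_inputs(s, silenced)
            expected_hE = np.empty(10)
            expected_hE[:9] = silenced.w_En * s.E[1:]
            expected_hE[9] = silenced.w_En * s.E[0]
            np.testing.assert_allclose(inp.h_E, expected_hE, atol=0)
            assert np.all(inp.h_I == 0.0)


class TestNeuralMuscleRhs:
    def test_saturated_drive(self, params):
        s = lc.rest_state(params)
        inp = neural_inputs(s, params)
        inp.h_E[:] = 1.0  # supra-threshold drive on every unit
        dE, dI = neural_rhs(s, inp, params)
        np.testing.assert_allclose(dE, 1.0 / params.tau_E, atol=1e-9)
        assert np.max(np.abs(dI)) < 1e-9  # I stays off: h_I = 0

    @pytest.mark.parametrize("E, f, expected", [
        (1.0, 0.0, "rise"),    # sigma_f saturated: df = f_max/tau_f
        (0.0, 0.3, "decay"),   # pure decay toward 0
    ])
    def test_muscle_limits(self, params, E, f, expected):
        df = muscle_rhs(np.full(10, f), np.full(10, E), params)
        if expected == "rise":
            np.testing.assert_allclose(df, params.f_max / params.tau_f,
                                       rtol=1e-9)
        else:
            np.testing.assert_allclose(df, -f / params.tau_f, rtol=1e-9)

    def test_muscle_midpoint_steady_state(self, params):
        """At E = E_hat the fixed point is f = f_max / 2."""
        df = muscle_rhs(np.full(10, params.f_max / 2.0),
                        np.full(10, params.E_hat), params)
        assert np.max(np.abs(df)) < 1e-12


class TestFriction:
    def test_lifted_segment_loses_friction(self, params):
        s = lc.rest_state(params)
        s.f[:] = params.f_max  # all segments lifted (f > f_hat)
        s.v[:] = 0.1
        s.v[-1] = s.v[0]
        F = friction_forces(s, params)
        assert np.max(np.abs(F)) < 1e-9

    def test_grounded_moving_mass_feels_max_friction(self, params):
        s = lc.rest_state(params)
        s.v[:] = 0.1
        s.v[-1] = s.v[0]
        F = friction_forces(s, params)
        np.testing.assert_allclose(F, params.F_max, rtol=1e-9)

    def test_static_mass_feels_none(self, params):
        F = friction_forces(lc.rest_state(params), params)
        assert np.all(F == 0.0)

    def test_gate_monotone_in_muscle_force(self, params):
        s = lc.rest_state(params)
        s.v[:] = 0.05
        s.v[-1] = s.v[0]
        mags = []
        for fval in np.linspace(0, params.f_max, 30):
            s.f[:] = fval
            mags.append(np.abs(friction_forces(s, params)).max())
        assert np.all(np.diff(mags) <= 1e-12)


def oracle_body_rhs(state, f, params):
    """Free-body-diagram oracle: per-spring scalar loops, no vectorization.

    Independent re-derivation of the mechanics used only for testing.
    """
    n = params.n_masses
    force = [0.0] * n
    for i in range(1, n):  # spring/damper/muscle i spans masses i-1, i
        ell = state.x[i - 1] - state.x[i]
        dell = state.v[i - 1] - state.v[i]
        pull = params.k * (ell - params.L) + params.c_damping * dell + f[i - 1]
        force[i - 1] -= pull
        force[i] += pull
    for j in range(n):
        f_gate = f[9] if j == 0 else f[j - 1]
        gate = 0.5 + 0.5 * np.tanh(params.g_F * (params.f_hat - f_gate)
                                   / (params.k * params.L))
        force[j] -= params.F_max * np.tanh(state.v[j] / params.v_eps) * gate
    dv = [0.0] * n
    for j in range(1, n - 1):
        dv[j] = force[j] / params.m_reg
    dv[0] = dv[n - 1] = (force[0] + force[n - 1]) / (2 * params.m_reg)
    return np.array(state.v), np.array(dv)


class TestBodyMechanics:
    def test_rest_equilibrium(self, params):
        s = lc.rest_state(params)
        dx, dv = body_rhs(s, s.f, friction_forces(s, params), params)
        assert np.max(np.abs(dv)) < 1e-12 and np.max(np.abs(dx)) < 1e-12

    def test_translation_invariance(self, params):
        rng = np.random.default_rng(3)
        s = random_valid_state(params, rng)
        F = friction_forces(s, params)
        _, dv1 = body_rhs(s, s.f, F, params)
        s2 = s.copy()
        s2.x += 2.5
        _, dv2 = body_rhs(s2, s2.f, F, params)
        np.testing.assert_allclose(dv1, dv2, atol=1e-9)

    def test_single_stretched_spring_action_reaction(self, params):
        """One stretched spring exerts equal and opposite forces k*e."""
        s = lc.rest_state(params)
        e = 0.1
        s.x[4] += e  # stretches segment 5 (masses 4,5), compresses segment 4
        force = elastic_damping_muscle_forces(s, s.f, params)
        # mass 3 feels only segment-4 compression; mass 5 only segment-5 pull
        assert force[5] == pytest.approx(params.k * e, rel=1e-12)
        assert force[3] == pytest.approx(params.k * e, rel=1e-12)
        assert force[4] == pytest.approx(-2 * params.k * e, rel=1e-12)
        assert np.max(np.abs(force[[0, 1, 2, 6, 7, 8, 9, 10]])) < 1e-12

    def test_internal_forces_sum_to_zero(self, params):
        rng = np.random.default_rng(11)
        for _ in range(10):
            s = random_valid_state(params, rng, scale=0.2)
            force = elastic_damping_muscle_forces(s, s.f, params)
            assert abs(force.sum()) < 1e-9

    def test_matches_free_body_oracle(self, params):
        rng = np.random.default_rng(5)
        for _ in range(20):
            s = random_valid_state(params, rng, scale=0.15)
            F = friction_forces(s, params)
            dx, dv = body_rhs(s, s.f, F, params)
            odx, odv = oracle_body_rhs(s, s.f, params)
            np.testing.assert_allclose(dx, odx, atol=1e-12)
            np.testing.assert_allclose(dv, odv, atol=1e-12 * max(1, np.abs(odv).max()))

    def test_rejects_broken_rod(self, params):
        s = lc.rest_state(params)
        s.x[-1] -= 0.1
        with pytest.raises(RuntimeError, match="rod constraint"):
            body_rhs(s, s.f, np.zeros(11), params)


class TestAssembly:
    def test_rest_rhs_is_zero(self, params):
        d = assemble_rhs(lc.rest_state(params), params)
        for arr in (d.E, d.I, d.f, d.x, d.v):
            assert np.max(np.abs(arr)) < 1e-9

    def test_pulse_targets_only_one_unit(self, params):
        pulse = np.zeros(10)
        pulse[9] = 0.61
        d = assemble_rhs(lc.rest_state(params), params, pulse)
        assert d.E[9] > 0.1
        assert np.max(np.abs(d.E[:9])) < 1e-9
        assert np.max(np.abs(d.I)) < 1e-9

    def test_component_shapes(self, params):
        d = assemble_rhs(lc.rest_state(params), params)
        assert (len(d.E), len(d.I), len(d.f), len(d.x), len(d.v)) \
            == (10, 10, 10, 11, 11)


class TestCompiledKernels:
    """The numba hot path must agree with the plain-numpy reference."""

    def test_rhs_matches_reference(self, params):
        pv = _kernels.pack_params(params)
        rng = np.random.default_rng(21)
        pulse = np.zeros(10)
        pulse[4] = 0.61
        for _ in range(10):
            s = random_valid_state(params, rng, scale=0.2)
            y = pack_state(s)
            np.testing.assert_allclose(
                _kernels.rhs(0.0, y, pv, pulse),
                packed_rhs(0.0, y, params, pulse), rtol=1e-13, atol=1e-13)

    def test_jacobian_matches_finite_differences(self, params):
        # moderate gains: the analytic expressions are gain-generic and the
        # production gains are too steep for central differences to resolve
        smooth = params.with_overrides(g_n=10.0, g_f=5.0, g_p=8.0, g_F=7.0,
                                       v_eps=0.1)
        pv = _kernels.pack_params(smooth)
        rng = np.random.default_rng(22)
        pulse = np.zeros(10)
        pulse[2] = 0.3
        for _ in range(3):
            s = random_valid_state(smooth, rng, scale=0.1)
            y = pack_state(s)
            J = _kernels.jac(0.0, y, pv, pulse)
            h = 1e-6
            for col in range(50):
                yp, ym = y.copy(), y.copy()
                yp[col] += h
                ym[col] -= h
                fd = (_kernels.rhs(0.0, yp, pv, pulse)
                      - _kernels.rhs(0.0, ym, pv, pulse)) / (2 * h)
                scale = max(1.0, np.abs(fd).max())
                np.testing.assert_allclose(J[:, col], fd, atol=1e-6 * scale)
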