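"""Right-hand side of the coupled neural / muscular / mechanical system.

Composition, per segment i = 1..10 and mass j = 0..10:

* Wilson-Cowan rate equations for excitatory and inhibitory populations,
  driven by intra-segment weights, the posterior->anterior neural coupling
  w_En, and proprioceptive input gated on segment contraction.
* First-order muscle dynamics relaxing toward f_max * sigma_f[E_i - E_hat].
* Gated dry friction on every mass: friction vanishes once the segment's
  muscle force exceeds the lift-off threshold f_hat (the segment lifts off
  the substrate); sign(xdot) is smoothed as tanh(xdot / v_eps).
* Overdamped force balance on the mass chain, regularized with a small
  inertia m_reg so explicit/adaptive integrators apply.  Head (mass 0) and
  tail (mass 10) are linked by a rigid rod (the gut acting as a "visceral
  piston"), enforced by reduction: the pair moves as one composite of
  inertia 2*m_reg driven by the sum of forces on both ends, so the
  constraint x_0 - x_10 = 10 L holds exactly.

Muscle sign convention: f_i is contractile, pulling masses i-1 and i toward
each other (+f_i on mass i, -f_i on mass i-1), which reproduces the
f_i - f_{i+1} pattern in the interior force balance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Params, SystemState, sigmoid

ROD_TOL = 1e-7  # relative rod-constraint tolerance accepted on input states


@dataclass
class Inputs:
    """External drives entering the Wilson-Cowan sigmoids for each unit."""

    h_E: np.ndarray  # excitatory drives, shape (10,)
    h_I: np.ndarray  # inhibitory-population drives, shape (10,)
    s: np.ndarray    # proprioceptive switch values in (0,1), shape (10,)


def proprio_switch(state: SystemState, params: Params) -> np.ndarray:
    """Stretch-receptor output s_i per segment: ~0 relaxed, ~1 contracted.

    s_i = sigma_p[(c_i - c_hat)/L] with c_i the segment contraction and
    c_hat = L/18 under default parameters; the steep gain g_p makes this an
    effectively binary "mission accomplished" signal.
    """
    c = state.contractions(params)
    return sigmoid((c - params.c_hat) / params.L, params.g_p)


def neural_inputs(state: SystemState, params: Params,
                  pulse_drive: np.ndarray | None = None) -> Inputs:
    """Assemble h_E and h_I from neural coupling, proprioception and pulses.

    Unit i < 10 listens to its posterior neighbor i+1 (activity and stretch
    receptor); unit 10 (tail) closes the loop via the long-range thoracic
    T2 -> A8 pathway, listening to unit 1.  Inhibitory populations receive
    only their own segment's proprioceptive signal.
    """
    s = proprio_switch(state, params)
    E = state.E
    h_E = np.empty(params.n_units)
    # anterior units listen posterior: h_E_i = w_En*E_{i+1} + w_Ep*s_{i+1}
    h_E[:-1] = params.w_En * E[1:] + params.w_Ep * s[1:]
    # tail unit re-initiates from the front: h_E_10 = w_En*E_1 + w_Ep*s_1
    h_E[-1] = params.w_En * E[0] + params.w_Ep * s[0]
    if pulse_drive is not None:
        h_E = h_E + pulse_drive
    h_I = params.w_Ip * s
    return Inputs(h_E=h_E, h_I=h_I, s=s)


def neural_rhs(state: SystemState, inputs: Inputs,
               params: Params) -> tuple[np.ndarray, np.ndarray]:
    """Wilson-Cowan derivatives (dE, dI) for all 10 units."""
    E, I = state.E, state.I
    arg_E = params.w_EE * E + params.w_EI * I + inputs.h_E - params.theta_E
    arg_I = params.w_IE * E + params.w_II * I + inputs.h_I - params.theta_I
    dE = (-E + sigmoid(arg_E, params.g_n)) / params.tau_E
    dI = (-I + sigmoid(arg_I, params.g_n)) / params.tau_I
    return dE, dI


def muscle_rhs(f: np.ndarray, E: np.ndarray, params: Params) -> np.ndarray:
    """First-order muscle dynamics: relax toward f_max*sigma_f[E - E_hat]."""
    return (-f + params.f_max * sigmoid(E - params.E_hat, params.g_f)) / params.tau_f


def friction_forces(state: SystemState, params: Params) -> np.ndarray:
    """Frictional force magnitude-with-sign per mass, shape (11,).

    F_j acts against the motion of mass j (it enters the force balance with
    a minus sign) and is gated off when the controlling muscle force exceeds
    f_hat: masses 1..10 are gated by their own segment's muscle f_j, while
    the head (mass 0) lifts with the tail segment's muscle f_10 -- head and
    tail share the rod, so they share ground contact state.
    """
    f_gate = np.concatenate(([state.f[-1]], state.f))  # mass 0 gated by f_10
    gate = sigmoid((params.f_hat - f_gate) / (params.k * params.L), params.g_F)
    return params.F_max * np.tanh(state.v / params.v_eps) * gate


def elastic_damping_muscle_forces(state: SystemState, f: np.ndarray,
                                  params: Params) -> np.ndarray:
    """Net internal (spring + damper + muscle) force on each mass, shape (11,).

    Springs carry explicit rest length L; because every mass sees one spring
    on each side (the rod-closed chain), the rest lengths cancel and the
    elastic terms reduce to second differences of position.
    """
    ell = state.segment_lengths()          # (10,) segment i = masses i-1,i
    dell = state.v[:-1] - state.v[1:]      # d(ell_i)/dt
    # spring i tension-like force: positive pulls its two masses together
    pull = params.k * (ell - params.L) + params.c_damping * dell + f
    force = np.zeros(params.n_masses)
    force[:-1] -= pull   # mass i-1 (anterior end) pulled in -x
    force[1:] += pull    # mass i (posterior end) pulled in +x
    return force


def body_rhs(state: SystemState, f: np.ndarray, F: np.ndarray,
             params: Params) -> tuple[np.ndarray, np.ndarray]:
    """Mechanical derivatives (dx, dv) under the head-tail rod reduction."""
    gap = state.x[0] - state.x[-1] - params.n_units * params.L
    if abs(gap) > ROD_TOL * params.L:
        raise RuntimeError(
            f"rod constraint violated by {gap:.3e} L on input to body_rhs")
    net = elastic_damping_muscle_forces(state, f, params) - F
    dv = np.empty(params.n_masses)
    dv[1:-1] = net[1:-1] / params.m_reg
    # head+tail composite: inertia 2*m_reg, summed forces, common acceleration
    a_rod = (net[0] + net[-1]) / (2.0 * params.m_reg)
    dv[0] = dv[-1] = a_rod
    dx = state.v.copy()
    dx[-1] = dx[0]  # rod: v_10 == v_0 by construction
    return dx, dv


def assemble_rhs(state: SystemState, params: Params,
                 pulse_drive: np.ndarray | None = None) -> SystemState:
    """Full time derivative of the system as a SystemState-shaped container."""
    inputs = neural_inputs(state, params, pulse_drive)
    dE, dI = neural_rhs(state, inputs, params)
    df = muscle_rhs(state.f, state.E, params)
    F = friction_forces(state, params)
    dx, dv = body_rhs(state, state.f, F, params)
    return SystemState(t=1.0, E=dE, I=dI, f=df, x=dx, v=dv)


# ---------------------------------------------------------------------------
# Packed right-hand side for the integrator.
#
# The rod removes one position and one velocity degree of freedom, so the
# integrator works on a 50-vector: [E(10), I(10), f(10), x_0..x_9 (10),
# v_0..v_9 (10)] with x_10 = x_0 - 10 L and v_10 = v_0 reconstructed.

N_PACKED = 50
_sE, _sI, _sf = slice(0, 10), slice(10, 20), slice(20, 30)
_sx, _sv = slice(30, 40), slice(40, 50)


def pack_state(state: SystemState) -> np.ndarray:
    return np.concatenate([state.E, state.I, state.f, state.x[:-1], state.v[:-1]])


def unpack_state(t: float, y: np.ndarray, params: Params) -> SystemState:
    x = np.empty(params.n_masses)
    v = np.empty(params.n_masses)
    x[:-1] = y[_sx]
    x[-1] = y[_sx][0] - params.n_units * params.L
    v[:-1] = y[_sv]
    v[-1] = y[_sv][0]
    return SystemState(t=t, E=y[_sE].copy(), I=y[_sI].copy(), f=y[_sf].copy(),
                       x=x, v=v)


def packed_rhs(t: float, y: np.ndarray, params: Params,
               pulse_drive: np.ndarray | None = None) -> np.ndarray:
    """Flat RHS on the reduced 50-vector; hot path, kept allocation-light."""
    E = y[_sE]
    I = y[_sI]
    f = y[_sf]
    xr = y[_sx]
    vr = y[_sv]
    p = params
    L, k = p.L, p.k

    # segment lengths/contractions; segment 10 spans mass 9 and tail(=x0-10L)
    ell = np.empty(10)
    ell[:9] = xr[:-1] - xr[1:]
    ell[9] = xr[9] - (xr[0] - p.n_units * L)
    c = L - ell
    s = 0.5 + 0.5 * np.tanh(p.g_p * (c - p.c_hat) / L)

    h_E = np.empty(10)
    h_E[:9] = p.w_En * E[1:] + p.w_Ep * s[1:]
    h_E[9] = p.w_En * E[0] + p.w_Ep * s[0]
    if pulse_drive is not None:
        h_E += pulse_drive
    h_I = p.w_Ip * s

    dE = (-E + 0.5 + 0.5 * np.tanh(
        p.g_n * (p.w_EE * E + p.w_EI * I + h_E - p.theta_E))) / p.tau_E
    dI = (-I + 0.5 + 0.5 * np.tanh(
        p.g_n * (p.w_IE * E + p.w_II * I + h_I - p.theta_I))) / p.tau_I
    df = (-f + p.f_max * (0.5 + 0.5 * np.tanh(p.g_f * (E - p.E_hat)))) / p.tau_f

    # velocities incl. tail
    v10 = vr[0]
    dell = np.empty(10)
    dell[:9] = vr[:-1] - vr[1:]
    dell[9] = vr[9] - v10

    pull = k * (ell - L) + p.c_damping * dell + f
    net = np.zeros(11)
    net[:10] -= pull
    net[1:] += pull

    # friction: mass j gated by f_j (j>=1), mass 0 gated by f_10
    gate_arg = (p.f_hat - f) / (k * L)
    gate = 0.5 + 0.5 * np.tanh(p.g_F * gate_arg)
    vfull = np.empty(11)
    vfull[:10] = vr
    vfull[10] = v10
    gate_full = np.empty(11)
    gate_full[0] = gate[9]
    gate_full[1:] = gate
    net -= p.F_max * np.tanh(vfull / p.v_eps) * gate_full

    dv = np.empty(10)
    dv[1:] = net[1:10] / p.m_reg
    dv[0] = (net[0] + net[10]) / (2.0 * p.m_reg)

    dy = np.empty(N_PACKED)
    dy[_sE] = dE
    dy[_sI] = dI
    dy[_sf] = df
    dy[_sx] = vr
    dy[_sv] = dv
    return dy
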