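"""Numba-compiled right-hand side and Jacobian of the packed 50-state system.

These kernels mirror :mod:`larvacrawl.dynamics` exactly (the test suite
asserts agreement to machine precision) but take the parameter set as a
flat float array so they can be JIT-compiled.  The analytic Jacobian is
what makes implicit stiff stepping fast: the smoothed dry-friction law has
local stiffness of order F_max / (v_eps * m_reg) ~ 1e6, so practical
integration requires an implicit method with an exact Jacobian.

Packed layout: y = [E(0:10), I(10:20), f(20:30), x_0..x_9 (30:40),
v_0..v_9 (40:50)]; the tail mass is reconstructed from the head via the
rigid head-tail rod (x_10 = x_0 - 10 L, v_10 = v_0).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# parameter-vector layout (order matters; see pack_params)
PARAM_NAMES = (
    "tau_E", "tau_I", "tau_f", "k", "L", "c_damping", "f_max", "F_max",
    "f_hat", "c_hat", "E_hat", "theta_E", "theta_I",
    "w_EE", "w_EI", "w_IE", "w_II", "w_En", "w_Ep", "w_Ip",
    "g_n", "g_f", "g_p", "g_F", "m_reg", "v_eps",
)
(_TAU_E, _TAU_I, _TAU_F, _K, _LL, _C, _FMAX, _FFMAX, _FHAT, _CHAT, _EHAT,
 _THE, _THI, _WEE, _WEI, _WIE, _WII, _WEN, _WEP, _WIP,
 _GN, _GF, _GP, _GFR, _MREG, _VEPS) = range(len(PARAM_NAMES))


def pack_params(params) -> np.ndarray:
    """Flatten a Params dataclass into the kernel parameter vector."""
    return np.array([
        params.tau_E, params.tau_I, params.tau_f, params.k, params.L,
        params.c_damping, params.f_max, params.F_max, params.f_hat,
        params.c_hat, params.E_hat, params.theta_E, params.theta_I,
        params.w_EE, params.w_EI, params.w_IE, params.w_II,
        params.w_En, params.w_Ep, params.w_Ip,
        params.g_n, params.g_f, params.g_p, params.g_F,
        params.m_reg, params.v_eps,
    ])


@njit(cache=True)
def rhs(t, y, pv, pulse):
    """dy/dt of the packed system; ``pulse`` is the length-10 h_E addition."""
    E = y[0:10]
    I = y[10:20]
    f = y[20:30]
    xr = y[30:40]
    vr = y[40:50]
    L = pv[_LL]
    k = pv[_K]

    ell = np.empty(10)
    for a in range(9):
        ell[a] = xr[a] - xr[a + 1]
    ell[9] = xr[9] - xr[0] + 10.0 * L

    s = np.empty(10)
    for a in range(10):
        s[a] = 0.5 + 0.5 * np.tanh(pv[_GP] * ((L - ell[a]) - pv[_CHAT]) / L)

    dy = np.empty(50)
    for a in range(10):
        if a < 9:
            hE = pv[_WEN] * E[a + 1] + pv[_WEP] * s[a + 1] + pulse[a]
        else:
            hE = pv[_WEN] * E[0] + pv[_WEP] * s[0] + pulse[9]
        hI = pv[_WIP] * s[a]
        argE = pv[_WEE] * E[a] + pv[_WEI] * I[a] + hE - pv[_THE]
        argI = pv[_WIE] * E[a] + pv[_WII] * I[a] + hI - pv[_THI]
        dy[a] = (-E[a] + 0.5 + 0.5 * np.tanh(pv[_GN] * argE)) / pv[_TAU_E]
        dy[10 + a] = (-I[a] + 0.5 + 0.5 * np.tanh(pv[_GN] * argI)) / pv[_TAU_I]
        dy[20 + a] = (-f[a] + pv[_FMAX] *
                      (0.5 + 0.5 * np.tanh(pv[_GF] * (E[a] - pv[_EHAT])))) / pv[_TAU_F]

    dell = np.empty(10)
    for a in range(9):
        dell[a] = vr[a] - vr[a + 1]
    dell[9] = vr[9] - vr[0]

    pull = np.empty(10)
    for a in range(10):
        pull[a] = k * (ell[a] - L) + pv[_C] * dell[a] + f[a]

    gate = np.empty(10)
    for a in range(10):
        gate[a] = 0.5 + 0.5 * np.tanh(pv[_GFR] * (pv[_FHAT] - f[a]) / (k * L))

    for j in range(10):
        dy[30 + j] = vr[j]

    # interior masses 1..9
    for j in range(1, 10):
        fric = pv[_FFMAX] * np.tanh(vr[j] / pv[_VEPS]) * gate[j - 1]
        dy[40 + j] = (pull[j - 1] - pull[j] - fric) / pv[_MREG]
    # head+tail composite (friction on both masses, gated by tail muscle f_10)
    fric0 = 2.0 * pv[_FFMAX] * np.tanh(vr[0] / pv[_VEPS]) * gate[9]
    dy[40] = (pull[9] - pull[0] - fric0) / (2.0 * pv[_MREG])
    return dy


@njit(cache=True)
def jac(t, y, pv, pulse):
    """Dense analytic Jacobian d(rhs)/dy, shape (50, 50)."""
    E = y[0:10]
    I = y[10:20]
    f = y[20:30]
    xr = y[30:40]
    vr = y[40:50]
    L = pv[_LL]
    k = pv[_K]
    J = np.zeros((50, 50))

    ell = np.empty(10)
    for a in range(9):
        ell[a] = xr[a] - xr[a + 1]
    ell[9] = xr[9] - xr[0] + 10.0 * L

    # proprioceptive switch and its derivative wrt segment length
    s = np.empty(10)
    ds_dell = np.empty(10)
    for a in range(10):
        th = np.tanh(pv[_GP] * ((L - ell[a]) - pv[_CHAT]) / L)
        s[a] = 0.5 + 0.5 * th
        ds_dell[a] = -0.5 * pv[_GP] * (1.0 - th * th) / L

    # segment-length dependence on packed x: cols (ca, cb) with (+1, -1)
    ell_ca = np.empty(10, dtype=np.int64)
    ell_cb = np.empty(10, dtype=np.int64)
    for a in range(9):
        ell_ca[a] = 30 + a
        ell_cb[a] = 30 + a + 1
    ell_ca[9] = 30 + 9
    ell_cb[9] = 30 + 0

    for a in range(10):
        if a < 9:
            b = a + 1
            hE = pv[_WEN] * E[b] + pv[_WEP] * s[b] + pulse[a]
        else:
            b = 0
            hE = pv[_WEN] * E[0] + pv[_WEP] * s[0] + pulse[9]
        hI = pv[_WIP] * s[a]

        argE = pv[_WEE] * E[a] + pv[_WEI] * I[a] + hE - pv[_THE]
        thE = np.tanh(pv[_GN] * argE)
        gnE = 0.5 * pv[_GN] * (1.0 - thE * thE)          # dsigma_n/darg
        argI = pv[_WIE] * E[a] + pv[_WII] * I[a] + hI - pv[_THI]
        thI = np.tanh(pv[_GN] * argI)
        gnI = 0.5 * pv[_GN] * (1.0 - thI * thI)

        # row a: dE_a
        J[a, a] += (-1.0 + gnE * pv[_WEE]) / pv[_TAU_E]
        J[a, 10 + a] += gnE * pv[_WEI] / pv[_TAU_E]
        J[a, b] += gnE * pv[_WEN] / pv[_TAU_E]
        coef = gnE * pv[_WEP] * ds_dell[b] / pv[_TAU_E]
        J[a, ell_ca[b]] += coef
        J[a, ell_cb[b]] -= coef

        # row 10+a: dI_a
        J[10 + a, a] += gnI * pv[_WIE] / pv[_TAU_I]
        J[10 + a, 10 + a] += (-1.0 + gnI * pv[_WII]) / pv[_TAU_I]
        coef = gnI * pv[_WIP] * ds_dell[a] / pv[_TAU_I]
        J[10 + a, ell_ca[a]] += coef
        J[10 + a, ell_cb[a]] -= coef

        # row 20+a: df_a
        thf = np.tanh(pv[_GF] * (E[a] - pv[_EHAT]))
        J[20 + a, 20 + a] = -1.0 / pv[_TAU_F]
        J[20 + a, a] = pv[_FMAX] * 0.5 * pv[_GF] * (1.0 - thf * thf) / pv[_TAU_F]

    # dx_j = v_j
    for j in range(10):
        J[30 + j, 40 + j] = 1.0

    # pull[a] = k*(ell[a]-L) + c*dell[a] + f[a]
    # dell[a]: a<9 -> +vr[a] - vr[a+1]; a=9 -> +vr[9] - vr[0]
    gate = np.empty(10)
    dgate_df = np.empty(10)
    for a in range(10):
        thF = np.tanh(pv[_GFR] * (pv[_FHAT] - f[a]) / (k * L))
        gate[a] = 0.5 + 0.5 * thF
        dgate_df[a] = -0.5 * pv[_GFR] * (1.0 - thF * thF) / (k * L)

    def_rows = np.empty(0)  # placate lint; unused

    for j in range(10):
        if j == 0:
            inv_m = 1.0 / (2.0 * pv[_MREG])
            a_plus = 9   # +pull[9]
            a_minus = 0  # -pull[0]
        else:
            inv_m = 1.0 / pv[_MREG]
            a_plus = j - 1
            a_minus = j
        row = 40 + j
        for sgn, a in ((1.0, a_plus), (-1.0, a_minus)):
            J[row, ell_ca[a]] += sgn * k * inv_m
            J[row, ell_cb[a]] -= sgn * k * inv_m
            # dell pattern shares the index pattern of ell (x -> v columns)
            J[row, ell_ca[a] + 10] += sgn * pv[_C] * inv_m
            J[row, ell_cb[a] + 10] -= sgn * pv[_C] * inv_m
            J[row, 20 + a] += sgn * inv_m

        # friction
        th = np.tanh(vr[j] / pv[_VEPS])
        if j == 0:
            ga = 9
            mult = 2.0
        else:
            ga = j - 1
            mult = 1.0
        J[row, 40 + j] += -mult * pv[_FFMAX] * (1.0 - th * th) / pv[_VEPS] \
            * gate[ga] * inv_m
        J[row, 20 + ga] += -mult * pv[_FFMAX] * th * dgate_df[ga] * inv_m
    return J
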