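"""Dimensionless parameterization and state containers for the crawler model.

The larva body is a chain of 11 point masses (indices 0..10, head first)
connected by 10 damped linear springs; each segment i (between masses i-1
and i) carries one contractile muscle and one excitatory/inhibitory
Wilson-Cowan neural unit.  Everything is expressed in simulation units:
segment rest length L, spring stiffness k and excitatory relaxation time
tau_E are all 1.

Coordinate convention: mass 0 (head) sits at the largest coordinate and the
animal crawls in +x.  Segment length is ell_i = x_{i-1} - x_i (rest value L)
and segment contraction is c_i = L - ell_i, so the proprioceptive stretch
receptors switch on once c_i exceeds c_hat = L + u_hat*L = L/18 (about 5.6%
contraction) -- the "mission accomplished" signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from fractions import Fraction

import numpy as np

N_UNITS = 10   # neural units / muscles / segments, indexed 1..10
N_MASSES = 11  # point masses, indexed 0..10 (0 = head, 10 = tail)


def sigmoid(arg, gain):
    """Switching sigmoid sigma[z] = 0.5 + 0.5*tanh(gain*z), range (0, 1).

    Used for every switching nonlinearity in the model (neural activation
    sigma_n, proprioceptive switch sigma_p, muscle activation sigma_f and
    friction gate sigma_F); callers scale the argument into the appropriate
    dimensionless form before passing it in.

    Parameters
    ----------
    arg : float or array
        Dimensionless argument; must be finite.
    gain : float
        Sigmoid gain, > 0.

    Returns
    -------
    float or array in the open interval (0, 1), strictly increasing in arg.
    """
    arg = np.asarray(arg, dtype=float)
    if not np.all(np.isfinite(arg)):
        raise ValueError("sigmoid argument must be finite")
    if gain <= 0:
        raise ValueError("sigmoid gain must be > 0")
    out = 0.5 + 0.5 * np.tanh(gain * arg)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Params:
    """Dimensionless model constants plus numerical regularization knobs.

    Defaults are the values used for every headline simulation; fractions
    are stored exactly (computed from integer ratios, never from rounded
    decimals).  ``m_reg`` and ``v_eps`` are numerical devices, not
    biophysical parameters: a small segment inertia that regularizes the
    otherwise first-order (overdamped) force balance, and a velocity scale
    that smooths sign(xdot) in the dry-friction law.
    """

    tau_E: float = 1.0                    # excitatory relaxation time (time unit)
    tau_I_over_tau_E: float = 3.0         # inhibitory time-scale ratio
    tau_f_over_tau_E: float = 0.4         # muscle relaxation ratio
    k: float = 1.0                        # segment spring stiffness (force unit / L)
    L: float = 1.0                        # rest segment length (length unit)
    c_damping: float = 3.5                # scaled damping c*tau_E/k
    f_max: float = float(Fraction(5, 6))  # scaled max muscle force fmax/kL
    F_max: float = float(Fraction(25, 3)) # scaled max friction Fmax/kL
    f_hat: float = float(Fraction(5, 12)) # scaled lift-off force threshold
    u_hat: float = float(Fraction(-17, 18))  # scaled contraction threshold (signed)
    E_hat: float = 0.4                    # muscle activation threshold
    theta_E: float = 0.6                  # excitatory activation threshold
    theta_I: float = 0.6                  # inhibitory activation threshold
    w_EE: float = 1.0
    w_EI: float = -2.0
    w_IE: float = 0.6
    w_II: float = 0.0
    w_En: float = 0.6                     # posterior->anterior neural coupling
    w_Ep: float = 1.95                    # proprioceptive drive to E populations
    w_Ip: float = 1.95                    # proprioceptive drive to I populations
    g_n: float = 40000.0                  # neural sigmoid gain
    g_f: float = 1000.0                   # muscle sigmoid gain
    g_p: float = 1000.0                   # proprioceptive sigmoid gain
    g_F: float = 1000.0                   # friction-gate sigmoid gain
    m_reg: float = 0.01                   # regularization inertia (k*tau_E^2)
    v_eps: float = 1e-3                   # velocity scale smoothing sign(xdot) (L/tau_E)
    n_masses: int = N_MASSES
    n_units: int = N_UNITS

    def __post_init__(self):
        for name in ("tau_E", "tau_I_over_tau_E", "tau_f_over_tau_E", "k", "L",
                     "F_max", "g_n", "g_f", "g_p", "g_F", "m_reg", "v_eps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        if self.f_hat < 0:
            raise ValueError("f_hat must be >= 0")
        if self.n_masses != self.n_units + 1:
            raise ValueError("n_masses must equal n_units + 1")
        if not (0.0 < self.c_hat < self.L):
            raise ValueError("contraction threshold c_hat = L + u_hat*L must lie in (0, L)")

    # Derived quantities ----------------------------------------------------
    @property
    def tau_I(self) -> float:
        return self.tau_I_over_tau_E * self.tau_E

    @property
    def tau_f(self) -> float:
        return self.tau_f_over_tau_E * self.tau_E

    @property
    def c_hat(self) -> float:
        """Contraction threshold: segments "report done" past this contraction."""
        return self.L + self.u_hat * self.L

    def with_overrides(self, **overrides) -> "Params":
        """Return a copy with the named fields replaced (unknown names error)."""
        valid = {f.name for f in fields(self)}
        for key in overrides:
            if key not in valid:
                raise KeyError(f"unknown parameter {key!r}; valid names: {sorted(valid)}")
        return replace(self, **overrides)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def default_params() -> Params:
    """The default dimensionless parameter set used in all baseline runs."""
    return Params()


@dataclass
class SystemState:
    """Full instantaneous state of the coupled neuromechanical system.

    Arrays use 0-based storage: ``E[i-1]`` holds unit i for E, I, f
    (units 1..10) while ``x[j]``/``v[j]`` hold mass j directly (0..10).
    """

    t: float
    E: np.ndarray  # excitatory activities, shape (10,)
    I: np.ndarray  # inhibitory activities, shape (10,)
    f: np.ndarray  # muscle forces, shape (10,), in kL units
    x: np.ndarray  # mass positions, shape (11,), in L units
    v: np.ndarray  # mass velocities, shape (11,), in L/tau_E units

    def copy(self) -> "SystemState":
        return SystemState(self.t, self.E.copy(), self.I.copy(), self.f.copy(),
                           self.x.copy(), self.v.copy())

    def segment_lengths(self) -> np.ndarray:
        """ell_i = x_{i-1} - x_i for i = 1..10 (index 0 of result = segment 1)."""
        return self.x[:-1] - self.x[1:]

    def contractions(self, params: Params) -> np.ndarray:
        """c_i = L - ell_i for i = 1..10."""
        return params.L - self.segment_lengths()

    def check_rod(self, params: Params, tol: float = 1e-9) -> None:
        gap = self.x[0] - self.x[-1] - params.n_units * params.L
        if abs(gap) > tol * params.L:
            raise RuntimeError(
                f"head-tail rod constraint violated by {gap:.3e} L at t={self.t:g}")


def rest_state(params: Params) -> SystemState:
    """Quiescent stationary larva: zero activity and forces, undeformed body.

    Mass j sits at x_j = (n_units - j) * L so the head leads in +x; this is a
    fixed point of the full dynamics (the neural sigmoid is saturated off at
    -theta below threshold).
    """
    n = params.n_units
    x = (n - np.arange(params.n_masses, dtype=float)) * params.L
    return SystemState(
        t=0.0,
        E=np.zeros(n), I=np.zeros(n), f=np.zeros(n),
        x=x, v=np.zeros(params.n_masses),
    )
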