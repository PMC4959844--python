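"""Time integration of the crawler under experiment protocols.

A :class:`Protocol` bundles everything that defines one in-silico
experiment: the crawl-initiation pulse (a rectangular excitatory drive to
one segment's E population), optional activity clamps that emulate acute
optogenetic interventions (holding E or I of one unit at a fixed value
during a time window), parameter overrides (e.g. silencing proprioception
by zeroing w_Ep and w_Ip), the total simulated duration and the output
sampling interval.

Integration uses an implicit, adaptive, stiffness-capable method (LSODA by
default) with an analytic Jacobian: the steep switching sigmoids and the
smoothed dry-friction law make the system strongly stiff.  Runs are
deterministic -- identical parameters and protocol give bitwise-identical
trajectories for a fixed integrator configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels
from .model import N_UNITS, Params, SystemState, rest_state
from .dynamics import pack_state, unpack_state

DEFAULT_V_MOVE = 0.01  # |v| threshold (L/tau_E) classifying a mass as moving


class SimulationError(RuntimeError):
    """Raised when the integrator fails or the rod constraint drifts."""


@dataclass(frozen=True)
class IntegratorConfig:
    """Stepper settings; exposed in config files, stable across platforms."""

    method: str = "LSODA"
    rtol: float = 1e-6
    atol: float = 1e-9

    def to_dict(self) -> dict:
        return {"method": self.method, "rtol": self.rtol, "atol": self.atol}


@dataclass(frozen=True)
class Pulse:
    """Rectangular excitatory drive initiating crawling (added to h_E)."""

    unit: int = 10          # target neural unit, 1..10 (10 = most posterior)
    height: float = 0.61    # drive amplitude (dimensionless)
    start: float = 0.0      # onset time (tau_E)
    duration: float = 10.0  # pulse length (tau_E)

    def __post_init__(self):
        if not 1 <= self.unit <= N_UNITS:
            raise ValueError(f"pulse unit must be 1..{N_UNITS}, got {self.unit}")
        if self.height < 0:
            raise ValueError("pulse height must be >= 0")


@dataclass(frozen=True)
class Clamp:
    """Hold one neural population at a fixed value during [t0, t1].

    Models acute optogenetic perturbation: the clamped variable equals
    ``value`` with zero derivative throughout the window and is released to
    its normal dynamics afterwards.
    """

    population: str  # "E" or "I"
    unit: int        # 1..10
    t0: float
    t1: float
    value: float

    def __post_init__(self):
        if self.population not in ("E", "I"):
            raise ValueError("clamp population must be 'E' or 'I'")
        if not 1 <= self.unit <= N_UNITS:
            raise ValueError(f"clamp unit must be 1..{N_UNITS}, got {self.unit}")
        if not self.t0 < self.t1:
            raise ValueError("clamp window must satisfy t0 < t1")
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("clamp value must lie in [0, 1]")

    @property
    def packed_index(self) -> int:
        return (self.unit - 1) + (0 if self.population == "E" else N_UNITS)


@dataclass(frozen=True)
class Protocol:
    """One reproducible experiment: pulse + clamps + overrides + duration."""

    pulse: Pulse = field(default_factory=Pulse)
    clamps: tuple[Clamp, ...] = ()
    overrides: dict = field(default_factory=dict)
    duration: float = 500.0
    dt_sample: float = 0.1

    def __post_init__(self):
        for cl in self.clamps:
            if cl.t1 > self.duration:
                raise ValueError("clamp window extends beyond protocol duration")
        if self.dt_sample <= 0:
            raise ValueError("dt_sample must be > 0")

    def apply_overrides(self, params: Params) -> Params:
        return params.with_overrides(**self.overrides) if self.overrides else params

    def to_dict(self) -> dict:
        return {
            "pulse": {"unit": self.pulse.unit, "height": self.pulse.height,
                      "start": self.pulse.start, "duration": self.pulse.duration},
            "clamps": [{"population": c.population, "unit": c.unit,
                        "t0": c.t0, "t1": c.t1, "value": c.value}
                       for c in self.clamps],
            "overrides": dict(self.overrides),
            "duration": self.duration,
            "dt_sample": self.dt_sample,
        }


@dataclass
class Trajectory:
    """Sampled system history plus derived per-sample flags.

    Arrays are sample-major: ``E[n, i]`` is unit i+1 at sample n; ``x`` and
    ``v`` carry all 11 masses (tail reconstructed from the rod constraint).
    ``off_ground[n, i]`` marks segments whose muscle force exceeds the
    lift-off threshold; ``moving[n, j]`` marks masses with |v| > v_move.
    """

    t: np.ndarray
    E: np.ndarray
    I: np.ndarray
    f: np.ndarray
    x: np.ndarray
    v: np.ndarray
    off_ground: np.ndarray
    moving: np.ndarray
    params: Params
    protocol: Protocol
    v_move: float = DEFAULT_V_MOVE

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def state_at(self, n: int) -> SystemState:
        return SystemState(t=float(self.t[n]), E=self.E[n].copy(),
                           I=self.I[n].copy(), f=self.f[n].copy(),
                           x=self.x[n].copy(), v=self.v[n].copy())

    def segment_lengths(self) -> np.ndarray:
        """ell_i(t) for i = 1..10, shape (n_samples, 10)."""
        return self.x[:, :-1] - self.x[:, 1:]

    def contractions(self) -> np.ndarray:
        """c_i(t) = L - ell_i(t), shape (n_samples, 10)."""
        return self.params.L - self.segment_lengths()

    def to_dataframe(self):
        """53-column table: t, E1..E10, I1..I10, f1..f10, x0..x10, v0..v10."""
        import pandas as pd

        cols = {"t": self.t}
        for i in range(N_UNITS):
            cols[f"E{i + 1}"] = self.E[:, i]
        for i in range(N_UNITS):
            cols[f"I{i + 1}"] = self.I[:, i]
        for i in range(N_UNITS):
            cols[f"f{i + 1}"] = self.f[:, i]
        for j in range(self.params.n_masses):
            cols[f"x{j}"] = self.x[:, j]
        for j in range(self.params.n_masses):
            cols[f"v{j}"] = self.v[:, j]
        return pd.DataFrame(cols)


def _breakpoints(protocol: Protocol) -> list[float]:
    """Times where the RHS definition changes (pulse edges, clamp edges)."""
    pts = {0.0, protocol.duration,
           protocol.pulse.start, protocol.pulse.start + protocol.pulse.duration}
    for cl in protocol.clamps:
        pts.update((cl.t0, cl.t1))
    return sorted(t for t in pts if 0.0 <= t <= protocol.duration)


def simulate(params: Params, protocol: Protocol,
             integrator: IntegratorConfig | None = None,
             initial_state: SystemState | None = None) -> Trajectory:
    """Integrate the full model from rest under the given protocol.

    The time axis is split at pulse and clamp edges so that within each
    piece the right-hand side is a fixed smooth function; clamped variables
    are pinned to their clamp value (zero derivative) inside their window,
    which makes the clamp exact at every sample.
    """
    integrator = integrator or IntegratorConfig()
    params = protocol.apply_overrides(params)
    pv = _kernels.pack_params(params)
    state0 = initial_state if initial_state is not None else rest_state(params)
    y = pack_state(state0)

    n_samp = int(math.floor(protocol.duration / protocol.dt_sample + 1e-9)) + 1
    t_grid = np.arange(n_samp) * protocol.dt_sample
    samples = np.empty((n_samp, _kernels_n_packed()))
    samples[0] = y
    filled = 1

    zero_pulse = np.zeros(N_UNITS)
    edges = _breakpoints(protocol)
    for t0, t1 in zip(edges[:-1], edges[1:]):
        if t1 <= t0:
            continue
        tm = 0.5 * (t0 + t1)
        pulse_vec = zero_pulse
        if (protocol.pulse.height > 0 and
                protocol.pulse.start <= tm < protocol.pulse.start + protocol.pulse.duration):
            pulse_vec = np.zeros(N_UNITS)
            pulse_vec[protocol.pulse.unit - 1] = protocol.pulse.height
        active = [cl for cl in protocol.clamps if cl.t0 <= tm < cl.t1]
        idx = np.array([cl.packed_index for cl in active], dtype=int)
        vals = np.array([cl.value for cl in active])
        for i, vv in zip(idx, vals):  # clamp takes effect at window start
            y[i] = vv
            if filled and abs(t_grid[filled - 1] - t0) < 1e-9:
                samples[filled - 1, i] = vv  # boundary sample shows the clamp

        def rhs(t, yy, _idx=idx, _vals=vals, _p=pulse_vec):
            if _idx.size:
                yy = yy.copy()
                yy[_idx] = _vals
            dy = _kernels.rhs(t, yy, pv, _p)
            if _idx.size:
                dy[_idx] = 0.0
            return dy

        def jac(t, yy, _idx=idx, _vals=vals, _p=pulse_vec):
            if _idx.size:
                yy = yy.copy()
                yy[_idx] = _vals
            J = _kernels.jac(t, yy, pv, _p)
            if _idx.size:
                J[_idx, :] = 0.0
                J[:, _idx] = 0.0
            return J

        in_piece = (t_grid > t0 + 1e-12) & (t_grid <= t1 + 1e-12)
        t_eval = t_grid[in_piece]
        n_grid = t_eval.size
        if n_grid == 0 or t_eval[-1] < t1 - 1e-12:
            # piece end is off the sampling grid: evaluate it anyway so the
            # next piece continues from exactly t1
            t_eval = np.append(t_eval, t1)
        sol = solve_ivp(rhs, (t0, t1), y, method=integrator.method, jac=jac,
                        rtol=integrator.rtol, atol=integrator.atol,
                        t_eval=t_eval, dense_output=False)
        if not sol.success:
            raise SimulationError(
                f"integration failed in [{t0:g}, {t1:g}]: {sol.message}")
        y = sol.y[:, -1].copy()
        if n_grid:
            samples[filled:filled + n_grid] = sol.y[:, :n_grid].T
            filled += n_grid

    samples = samples[:filled]
    t = t_grid[:filled]
    return _build_trajectory(t, samples, params, protocol)


def _kernels_n_packed() -> int:
    from .dynamics import N_PACKED
    return N_PACKED


def _build_trajectory(t: np.ndarray, ys: np.ndarray, params: Params,
                      protocol: Protocol,
                      v_move: float = DEFAULT_V_MOVE) -> Trajectory:
    n = len(t)
    E = ys[:, 0:10]
    I = ys[:, 10:20]
    f = ys[:, 20:30]
    x = np.empty((n, params.n_masses))
    v = np.empty((n, params.n_masses))
    x[:, :-1] = ys[:, 30:40]
    x[:, -1] = ys[:, 30] - params.n_units * params.L
    v[:, :-1] = ys[:, 40:50]
    v[:, -1] = ys[:, 40]
    return Trajectory(
        t=t, E=E, I=I, f=f, x=x, v=v,
        off_ground=f > params.f_hat,
        moving=np.abs(v) > v_move,
        params=params, protocol=protocol, v_move=v_move,
    )


# ---------------------------------------------------------------------------
# Experiment presets

# sweep grids used by the corresponding preset experiments
WEN_GRID = tuple(np.round(np.arange(0.30, 1.0001, 0.05), 10))
FRICTION_GRID = tuple(np.round(np.geomspace(0.005, 25.0 / 3.0, 15), 10))

_SILENCE = {"w_Ep": 0.0, "w_Ip": 0.0}

PRESETS = ("fig2_baseline", "fig3_E_clamp", "fig3_I_clamp", "fig4_no_proprio",
           "fig5_wEn_sweep", "fig6_friction_sweep", "pure_proprio")


def preset_protocol(name: str) -> Protocol:
    """Protocols of the standard experiments.

    * ``fig2_baseline`` -- pulse to the most posterior unit (E10), 500 tau_E.
    * ``fig3_E_clamp`` / ``fig3_I_clamp`` -- crawl started at A4 (pulse to
      E6); segment A6's excitatory unit held at 0 (resp. inhibitory unit
      held at 1) for t in [65, 95].
    * ``fig4_no_proprio`` -- baseline with proprioception silenced
      (w_Ep = w_Ip = 0).
    * ``fig5_wEn_sweep`` / ``fig6_friction_sweep`` -- the base protocol the
      corresponding parameter sweep runs at each grid point (grids in
      ``WEN_GRID`` / ``FRICTION_GRID``).
    * ``pure_proprio`` -- no neural coupling (w_En = 0), proprioception only.
    """
    if name == "fig2_baseline":
        return Protocol()
    if name == "fig3_E_clamp":
        return Protocol(pulse=Pulse(unit=6),
                        clamps=(Clamp("E", 8, 65.0, 95.0, 0.0),),
                        duration=250.0)
    if name == "fig3_I_clamp":
        return Protocol(pulse=Pulse(unit=6),
                        clamps=(Clamp("I", 8, 65.0, 95.0, 1.0),),
                        duration=250.0)
    if name == "fig4_no_proprio":
        return Protocol(overrides=dict(_SILENCE))
    if name == "fig5_wEn_sweep":
        return Protocol(duration=400.0)
    if name == "fig6_friction_sweep":
        return Protocol(duration=400.0)
    if name == "pure_proprio":
        return Protocol(overrides={"w_En": 0.0})
    raise ValueError(f"unknown preset {name!r}; valid presets: {PRESETS}")


# ---------------------------------------------------------------------------
# Parameter sweeps and the delay-curve crossover

@dataclass
class SweepPoint:
    """Result of one sweep grid point; ``error`` set if that run failed."""

    value: float
    trajectory: Trajectory | None = None
    metrics: object | None = None
    error: str | None = None


def sweep(params: Params, protocol: Protocol, parameter_name: str, grid,
          integrator: IntegratorConfig | None = None,
          metric_fn=None, keep_trajectories: bool = True) -> list[SweepPoint]:
    """Run one independent simulation from rest per grid value.

    ``metric_fn(trajectory, params) -> object`` is evaluated per point when
    given (typically :func:`larvacrawl.metrics.compute_metrics`).  A failure
    at one grid point is recorded on its :class:`SweepPoint` and does not
    abort the sweep.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("sweep grid must be non-empty")
    params.with_overrides(**{parameter_name: grid[0]})  # validate name early
    out = []
    for value in grid:
        point = SweepPoint(value=float(value))
        try:
            p = params.with_overrides(**{parameter_name: float(value)})
            traj = simulate(p, protocol, integrator=integrator)
            if metric_fn is not None:
                point.metrics = metric_fn(traj, p)
            if keep_trajectories:
                point.trajectory = traj
        except Exception as exc:  # noqa: BLE001 - recorded per point by contract
            point.error = f"{type(exc).__name__}: {exc}"
        out.append(point)
    return out


def find_slippage_onset(params: Params, protocol: Protocol, grid=FRICTION_GRID,
                        integrator: IntegratorConfig | None = None,
                        t_discard: float = 100.0, v_move: float = DEFAULT_V_MOVE,
                        rel_tol: float = 0.05, max_iter: int = 8) -> float:
    """Scaled friction F_max/kL below which grounded segments start to slip.

    Slippage is flagged when the median number of moving masses exceeds the
    median number of off-ground segments.  The grid scan finds the largest
    slipping value; the boundary to the next (non-slipping) grid point is
    then refined by bisection.  Returns NaN if no grid point slips, and the
    largest grid value if all slip.
    """
    from .metrics import offground_stats  # local import to avoid a cycle

    def slips(F_max: float) -> bool:
        p = params.with_overrides(F_max=float(F_max))
        traj = simulate(p, protocol, integrator=integrator)
        off_med, mov_med = offground_stats(traj, p, t_discard, v_move)
        return mov_med > off_med

    grid = sorted(float(g) for g in grid)
    flags = [slips(g) for g in grid]
    slipping = [g for g, fl in zip(grid, flags) if fl]
    if not slipping:
        return float("nan")
    lo = max(slipping)
    above = [g for g, fl in zip(grid, flags) if g > lo and not fl]
    if not above:
        return lo
    hi = min(above)
    for _ in range(max_iter):
        if (hi - lo) / hi < rel_tol:
            break
        mid = math.sqrt(lo * hi)  # log-spaced grid, log-midpoint bisection
        if slips(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class CrossoverResult:
    w_star: float | None
    degenerate: bool = False

    @property
    def found(self) -> bool:
        return self.w_star is not None


def channel_delay_curves(params: Params, protocol: Protocol, grid=WEN_GRID,
                         integrator: IntegratorConfig | None = None
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Propagation-delay curves of the two wave-propagation channels vs w_En.

    For each coupling strength the proprioception-silenced model gives the
    neural-channel delay (neighbor E_hat-crossing lag, NaN where the
    silenced model produces no waves) and the full model gives the
    proprioceptive-channel delay (E_hat crossing to stretch-receptor
    switch-on).  Returns (grid, delay_neural, delay_proprio).
    """
    from .metrics import compute_metrics  # local import to avoid a cycle

    def metric_fn(traj, p):
        return compute_metrics(traj, p)

    silenced = params.with_overrides(w_Ep=0.0, w_Ip=0.0)
    pts_np = sweep(silenced, protocol, "w_En", grid, integrator=integrator,
                   metric_fn=metric_fn, keep_trajectories=False)
    pts_full = sweep(params, protocol, "w_En", grid, integrator=integrator,
                     metric_fn=metric_fn, keep_trajectories=False)
    d_neural = np.array([
        pt.metrics.delay_nn if pt.metrics is not None and
        len(pt.metrics.wave_times) > 0 else np.nan
        for pt in pts_np])
    d_proprio = np.array([
        pt.metrics.delay_np if pt.metrics is not None else np.nan
        for pt in pts_full])
    return np.asarray(grid, dtype=float), d_neural, d_proprio


def find_crossover(grid, delay_neural, delay_proprio) -> CrossoverResult:
    """Interpolated coupling strength where two delay curves intersect.

    ``delay_neural`` and ``delay_proprio`` are the neural-channel and
    proprioceptive-channel propagation delays sampled on ``grid``; NaN
    entries (e.g. below the onset of neural-only crawling) are ignored.
    Returns the linearly interpolated abscissa of the first sign change of
    their difference; identical curves yield the first usable grid point,
    flagged degenerate; no sign change yields ``w_star=None``.
    """
    g = np.asarray(grid, dtype=float)
    d = np.asarray(delay_neural, dtype=float) - np.asarray(delay_proprio, dtype=float)
    ok = np.isfinite(d)
    g, d = g[ok], d[ok]
    if len(g) < 2:
        return CrossoverResult(None)
    if np.all(d == 0.0):
        return CrossoverResult(float(g[0]), degenerate=True)
    for a in range(len(g) - 1):
        if d[a] == 0.0:
            return CrossoverResult(float(g[a]))
        if d[a] * d[a + 1] < 0.0:
            w = g[a] + (g[a + 1] - g[a]) * (0.0 - d[a]) / (d[a + 1] - d[a])
            return CrossoverResult(float(w))
    if d[-1] == 0.0:
        return CrossoverResult(float(g[-1]))
    return CrossoverResult(None)
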