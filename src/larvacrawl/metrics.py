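"""Crawling metrics extracted from simulated trajectories.

A peristaltic wave is counted when the tail lifts off the substrate, i.e.
when the tail segment's muscle force f_10 crosses the lift-off threshold
f_hat upward.  Summary statistics (frequency, speed, step size, peak
contraction, off-ground counts, propagation delays, phases) are computed on
a post-transient analysis window; by default the first 100 tau_E of a run
are discarded.

Two signal-propagation delays characterize the two routes a wave can take
from one segment to the next:

* ``delay_nn`` (neuron-to-neuron): lag between the excitatory populations
  of neighboring segments crossing the muscle-activation threshold E_hat.
* ``delay_np`` (neuron-to-proprioceptor): time from a unit's E_hat crossing
  to the switch-on of its own segment's stretch receptor (s crossing 0.5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .model import N_UNITS, Params
from .simulation import Trajectory

DEFAULT_T_DISCARD = 100.0  # transient discarded before summary metrics (tau_E)


class MetricError(ValueError):
    """Raised when a metric is requested on an unusable window."""


# ---------------------------------------------------------------------------
# crossing detection

def upward_crossings(t: np.ndarray, signal: np.ndarray,
                     threshold: float) -> np.ndarray:
    """Times where ``signal`` crosses ``threshold`` upward (linear interp)."""
    below = signal[:-1] <= threshold
    above = signal[1:] > threshold
    idx = np.where(below & above)[0]
    if idx.size == 0:
        return np.empty(0)
    frac = (threshold - signal[idx]) / (signal[idx + 1] - signal[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def detect_waves(traj: Trajectory, params: Params,
                 t_min: float | None = None,
                 require_completion: bool = False) -> np.ndarray:
    """Tail lift-off times: upward crossings of f_10 through f_hat.

    Events inside the initiation-pulse window (or before ``t_min`` when
    given) are discarded -- the pulse itself briefly lifts the tail.
    A wave is counted at its initiation (the tail lifting off); with
    ``require_completion`` only initiations whose wave reaches the most
    anterior segment (E_1 crossing E_hat before the next initiation) are
    kept.
    """
    if t_min is None:
        pulse = traj.protocol.pulse
        t_min = pulse.start + pulse.duration
    times = upward_crossings(traj.t, traj.f[:, N_UNITS - 1], params.f_hat)
    times = times[times >= t_min]
    if require_completion and times.size:
        head = upward_crossings(traj.t, traj.E[:, 0], params.E_hat)
        completed = []
        for n, t0 in enumerate(times):
            t1 = times[n + 1] if n + 1 < times.size else np.inf
            if np.any((head > t0) & (head < t1)):
                completed.append(t0)
        times = np.array(completed)
    return times


# ---------------------------------------------------------------------------
# speed / step size / contraction / counts

def gait_speed(traj: Trajectory, t_start: float = DEFAULT_T_DISCARD) -> float:
    """Mean mass displacement over [t_start, end] divided by its length (L/tau_E)."""
    if traj.n_samples < 2:
        raise MetricError("speed needs at least two samples")
    com = traj.x.mean(axis=1)
    c0 = np.interp(t_start, traj.t, com)
    window = traj.t[-1] - t_start
    if window <= 0:
        raise MetricError("analysis window is empty")
    return float((com[-1] - c0) / window)


def step_size(traj: Trajectory, wave_times: np.ndarray,
              t_start: float = DEFAULT_T_DISCARD) -> float:
    """Tail net displacement per wave over the analysis window (L).

    Returns NaN (undefined-metric marker) when no wave falls in the window.
    """
    wt = wave_times[wave_times >= t_start]
    if wt.size == 0:
        return float("nan")
    tail = traj.x[:, -1]
    t0 = np.interp(t_start, traj.t, tail)
    return float((tail[-1] - t0) / wt.size)


def peak_contraction(traj: Trajectory, wave_times: np.ndarray, params: Params,
                     segments=None) -> float:
    """Per-wave maximum contraction fraction, averaged over waves then segments.

    ``segments`` selects 1-based segment indices (segment i spans masses
    i-1 and i); e.g. ``[6]`` restricts to the A3-A4 inter-mass distance.
    Waves only partially inside the trajectory are excluded.  Returns 0 for
    a trajectory with no waves (undeformed body).
    """
    if segments is None:
        segments = range(1, N_UNITS + 1)
    segments = list(segments)
    if not segments:
        raise MetricError("empty segment subset")
    c = traj.contractions() / params.L
    if len(wave_times) < 2:
        return 0.0 if len(wave_times) == 0 else float(
            np.mean([c[traj.t >= wave_times[0], s - 1].max() for s in segments]))
    per_segment = []
    for s in segments:
        ci = c[:, s - 1]
        per_wave = []
        for w0, w1 in zip(wave_times[:-1], wave_times[1:]):
            m = (traj.t >= w0) & (traj.t < w1)
            if m.any():
                per_wave.append(ci[m].max())
        per_segment.append(np.mean(per_wave))
    return float(np.mean(per_segment))


def offground_stats(traj: Trajectory, params: Params,
                    t_start: float = DEFAULT_T_DISCARD,
                    v_move: float | None = None) -> tuple[int, float]:
    """Medians over post-transient samples of the off-ground and moving counts.

    Off-ground: segments with f_i > f_hat.  Moving: masses with
    |v_j| > v_move (default the trajectory's own threshold).
    """
    m = traj.t >= t_start
    if not m.any():
        raise MetricError("analysis window holds no samples")
    off = (traj.f[m] > params.f_hat).sum(axis=1)
    if v_move is None:
        moving = traj.moving[m].sum(axis=1)
    else:
        moving = (np.abs(traj.v[m]) > v_move).sum(axis=1)
    return int(np.median(off)), float(np.median(moving))


# ---------------------------------------------------------------------------
# propagation delays

def _paired_delays(t_src: np.ndarray, t_dst: np.ndarray) -> list[float]:
    """For each source event, lag to the next destination event before the
    following source event (skipping pairs with no such destination)."""
    out = []
    for n, ts in enumerate(t_src):
        limit = t_src[n + 1] if n + 1 < len(t_src) else np.inf
        after = t_dst[(t_dst > ts) & (t_dst < limit)]
        if after.size:
            out.append(float(after[0] - ts))
    return out


def propagation_delays(traj: Trajectory, params: Params,
                       t_start: float = DEFAULT_T_DISCARD
                       ) -> tuple[float, float]:
    """(delay_nn, delay_np) averaged over waves and units, in tau_E.

    Crossing times use linear interpolation; unit pairs with no measurable
    crossing are excluded, and a delay is NaN when nothing was measurable
    on its channel.
    """
    m = traj.t >= t_start
    t = traj.t[m]
    e_cross = [upward_crossings(t, traj.E[m, i], params.E_hat)
               for i in range(N_UNITS)]

    nn = []
    for i in range(N_UNITS - 1):  # posterior unit i+2 fires, then unit i+1
        nn.extend(_paired_delays(e_cross[i + 1], e_cross[i]))

    c = traj.contractions()[m]
    s = 0.5 + 0.5 * np.tanh(params.g_p * (c - params.c_hat) / params.L)
    np_delays = []
    for i in range(N_UNITS):
        s_cross = upward_crossings(t, s[:, i], 0.5)
        np_delays.extend(_paired_delays(e_cross[i], s_cross))

    delay_nn = float(np.mean(nn)) if nn else float("nan")
    delay_np = float(np.mean(np_delays)) if np_delays else float("nan")
    if not nn and not np_delays:
        raise MetricError("no threshold crossings measurable in the window")
    return delay_nn, delay_np


# ---------------------------------------------------------------------------
# DFT phases

def phase_analysis(traj: Trajectory, params: Params,
                   wave_freq: float | None = None,
                   t_start: float = DEFAULT_T_DISCARD,
                   min_periods: int = 3) -> dict[str, np.ndarray]:
    """Per-segment phases of E, f and contraction relative to tail E activity.

    Each signal is mean-removed (contraction additionally linearly
    detrended, since the body drifts forward), the DFT is taken over an
    integer number of wave periods at the end of the run, and the phase is
    the negative complex phase at the fundamental (the DFT bin nearest the
    measured wave frequency).  Larger phase means later in the cycle.
    """
    if wave_freq is None:
        waves = detect_waves(traj, params, t_min=t_start)
        window = traj.t[-1] - t_start
        wave_freq = len(waves) / window if window > 0 else 0.0
    if wave_freq <= 0:
        raise MetricError("phase analysis needs a nonzero wave frequency")
    period = 1.0 / wave_freq
    avail = traj.t[-1] - t_start
    n_per = int(np.floor(avail / period))
    if n_per < min_periods:
        raise MetricError(
            f"window holds {n_per} wave periods; need >= {min_periods}")
    dt = traj.t[1] - traj.t[0]
    n_keep = int(round(n_per * period / dt))
    sl = slice(traj.n_samples - n_keep, traj.n_samples)
    t_win = traj.t[sl]

    freqs = np.fft.rfftfreq(n_keep, d=dt)
    fundamental = int(np.argmin(np.abs(freqs - wave_freq)))
    if fundamental == 0:
        raise MetricError("fundamental collapses onto the DC bin")

    def phase_of(signal: np.ndarray, detrend: bool) -> float:
        sig = signal.astype(float)
        if detrend:
            coef = np.polyfit(t_win, sig, 1)
            sig = sig - np.polyval(coef, t_win)
        sig = sig - sig.mean()
        return float(-np.angle(np.fft.rfft(sig)[fundamental]))

    c = traj.contractions()
    phases = {
        "E": np.array([phase_of(traj.E[sl, i], False) for i in range(N_UNITS)]),
        "f": np.array([phase_of(traj.f[sl, i], False) for i in range(N_UNITS)]),
        "contraction": np.array([phase_of(c[sl, i], True)
                                 for i in range(N_UNITS)]),
    }
    ref = phases["E"][N_UNITS - 1]
    for key in phases:
        phases[key] = np.mod(phases[key] - ref + np.pi, 2 * np.pi) - np.pi
    return phases


# ---------------------------------------------------------------------------
# physical units

@dataclass(frozen=True)
class PhysicalMetrics:
    """Model metrics converted to physical units via an observed wave rate."""

    tau_E_ms: float          # inferred neural time constant
    L_mm: float              # inferred segment length
    speed_mm_per_s: float
    step_size_mm: float
    wave_rate_per_s: float


def to_physical_units(metrics: "GaitMetrics", observed_wave_rate_per_s: float,
                      body_length_mm: float) -> PhysicalMetrics:
    """Infer tau_E and L by matching the model wave rate to an observed one.

    tau_E = wave_freq / observed_rate (model waves per tau_E divided by
    animal waves per second); L = body length / 10.  Converting the
    returned physical rate back recovers the model wave frequency exactly.
    """
    if observed_wave_rate_per_s <= 0 or body_length_mm <= 0:
        raise MetricError("observed rate and body length must be positive")
    if not metrics.wave_freq > 0:
        raise MetricError("cannot convert units with zero wave frequency")
    tau_E_s = metrics.wave_freq / observed_wave_rate_per_s
    L_mm = body_length_mm / 10.0
    return PhysicalMetrics(
        tau_E_ms=tau_E_s * 1e3,
        L_mm=L_mm,
        speed_mm_per_s=metrics.speed * L_mm / tau_E_s,
        step_size_mm=metrics.step_size * L_mm,
        wave_rate_per_s=observed_wave_rate_per_s,
    )


# ---------------------------------------------------------------------------
# one-call summary

@dataclass
class GaitMetrics:
    """Everything measured on one trajectory (times in tau_E, lengths in L)."""

    wave_times: np.ndarray
    wave_freq: float
    speed: float
    step_size: float
    peak_contraction: float          # fraction of L, averaged segments x waves
    offground_median: int
    moving_count_median: float
    delay_nn: float
    delay_np: float
    phases: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "wave_times": list(map(float, self.wave_times)),
            "wave_freq": self.wave_freq,
            "speed": self.speed,
            "step_size": self.step_size,
            "peak_contraction": self.peak_contraction,
            "offground_median": self.offground_median,
            "moving_count_median": self.moving_count_median,
            "delay_nn": self.delay_nn,
            "delay_np": self.delay_np,
        }
        if self.phases:
            d["phases"] = {k: list(map(float, v)) for k, v in self.phases.items()}
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def compute_metrics(traj: Trajectory, params: Params | None = None,
                    t_discard: float = DEFAULT_T_DISCARD,
                    v_move: float | None = None,
                    with_phases: bool = False) -> GaitMetrics:
    """Standard metric suite on the post-transient window of one run.

    For runs shorter than 5x the default transient the discard window is
    shrunk to the first 20% of the run so short diagnostics still work.
    """
    params = params or traj.params
    if t_discard > 0.5 * float(traj.t[-1]):
        t_discard = 0.2 * float(traj.t[-1])
    waves_all = detect_waves(traj, params)
    window = traj.t[-1] - t_discard
    waves = waves_all[waves_all >= t_discard]
    freq = len(waves) / window if window > 0 else float("nan")
    off_med, mov_med = offground_stats(traj, params, t_discard, v_move)
    try:
        delay_nn, delay_np = propagation_delays(traj, params, t_discard)
    except MetricError:
        delay_nn = delay_np = float("nan")
    phases = {}
    if with_phases and freq > 0:
        try:
            phases = phase_analysis(traj, params, wave_freq=freq,
                                    t_start=t_discard)
        except MetricError:
            phases = {}
    return GaitMetrics(
        wave_times=waves,
        wave_freq=freq,
        speed=gait_speed(traj, t_discard),
        step_size=step_size(traj, waves_all, t_discard),
        peak_contraction=peak_contraction(traj, waves, params),
        offground_median=off_med,
        moving_count_median=mov_med,
        delay_nn=delay_nn,
        delay_np=delay_np,
        phases=phases,
    )
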