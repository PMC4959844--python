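# Methods

## Model

The simulator couples four subsystems, one per body segment (10 segments
between 11 point masses; mass 0 is the head, mass 10 the tail):

**Neural dynamics.** Each segment carries an excitatory and an inhibitory
neural population obeying Wilson–Cowan rate equations with a steep sigmoid
activation σ_n[z] = ½ + ½ tanh(g_n z). The excitatory population doubles
as the motor drive. External input to the excitatory population has two
components: activity of the posterior neighbor's excitatory population
(weight `w_En`, the CPG-like neural channel) and the posterior neighbor
segment's stretch-receptor signal (weight `w_Ep`, the proprioceptive
channel). The inhibitory population receives its own segment's
stretch-receptor signal (weight `w_Ip`): a completed contraction both
excites the next anterior segment and shuts down its own — the "mission
accomplished" scheme. The tail unit listens to the most anterior unit
(long-range thoracic-to-abdominal coupling), which re-initiates each
crawl cycle when the wave reaches the head.

**Muscles.** Muscle force relaxes first-order (time constant τ_f) toward
`f_max σ_f[E_i − Ê]`: effectively a binary contractile force switched by
the excitatory activity crossing Ê.

**Body.** Masses are joined by parallel spring–dampers with rest length L;
muscle i pulls masses i−1 and i toward each other. Because the chain is
closed by the head–tail rod, every mass has a spring on each side and the
elastic terms reduce to second differences of position (rest lengths
cancel; a unit test verifies this). The rod — the gut acting as a
"visceral piston" — is enforced by reduction: masses 0 and 10 form one
composite coordinate with inertia 2·m_reg driven by the summed end forces,
so x_0 − x_10 = 10 L holds exactly throughout.

**Substrate.** Each mass feels dry friction up to `F_max`, gated off when
the controlling muscle force exceeds the lift-off threshold `f̂` (the
segment lifts off the ground); the head shares the tail segment's ground
state through the rod. Friction opposes velocity through a smoothed sign
function tanh(ẋ/v_eps).

### Coordinate convention

Positions are absolute, with the head at the largest coordinate and motion
in +x. Segment length is ℓ_i = x_{i−1} − x_i and contraction
c_i = L − ℓ_i. The stretch receptor switches on at
c_hat = L + û·L = L/18 (û = −17/18), i.e. at ≈5.6 % contraction. This is
the only sign assignment under which the receptor is off for a relaxed
body and fires when a segment contracts.

## Parameters

All values are dimensionless (L = k = τ_E = 1). Defaults:

| parameter | default | meaning |
|---|---|---|
| c τ_E/k | 3.5 | segment damping |
| f_max/kL | 5/6 | maximum muscle force |
| τ_f/τ_E | 0.4 | muscle relaxation time |
| F_max/kL | 25/3 | maximum friction |
| f̂/kL | 5/12 | lift-off force threshold |
| τ_I/τ_E | 3 | inhibitory time constant |
| w_EE, w_EI, w_IE, w_II | 1, −2, 0.6, 0 | intra-segment weights |
| w_En | 0.6 | posterior→anterior neural coupling |
| w_Ep, w_Ip | 1.95 | proprioceptive couplings |
| Ê | 0.4 | muscle activation threshold |
| θ̂_E, θ̂_I | 0.6 | neural activation thresholds |
| û/L | −17/18 | contraction threshold (signed) |
| g_n; g_f, g_p, g_F | 40000; 1000 | sigmoid gains |

Fractional defaults are computed from the integer ratios, never from
rounded decimals. Crawling is initiated by a rectangular pulse of height
0.61 for 10 τ_E added to the excitatory input of one unit (the most
posterior by default); 0.61 marginally exceeds θ̂_E = 0.6, so the pulse
starts exactly one wave.

Two additional constants are numerical devices, not biophysics:

* `m_reg = 0.01` (units k·τ_E²): a small segment inertia regularizing the
  otherwise algebraic (inertialess) force balance into an ODE.
* `v_eps = 1e−3` (L/τ_E): velocity scale smoothing sign(ẋ) in the
  friction law, making it a regularized dry-friction model. A grounded
  mass under sub-friction net force creeps at
  v ≈ v_eps·atanh(f_net/F_max) ≲ 1e−4 L/τ_E, negligible over a run.

The property suite verifies that halving either constant changes every
baseline gait metric by less than 2 %, so conclusions do not depend on the
regularization.

## Numerics

The regularized system has local stiffness up to F_max/(v_eps·m_reg) ≈ 1e6
(the friction gate near zero velocity), far beyond what explicit steppers
can integrate in reasonable time. The integrator is therefore LSODA
(adaptive, stiffness-switching) at rtol = 1e−6, atol = 1e−9, supplied with
an analytic Jacobian. The hot path (right-hand side and Jacobian) is
compiled with numba; a plain-numpy reference implementation defines the
module surface, and a unit test pins the two to machine precision. The
analytic Jacobian is validated against central differences at moderated
sigmoid gains (at the production gain of 4·10⁴, finite differences cannot
resolve the curvature).

Pulse edges and clamp windows split the time axis into pieces with a fixed
smooth right-hand side. During a clamp the clamped state variable is set
to the clamp value and its derivative (and Jacobian row/column) zeroed, so
the clamp is exact at every sample; release restores normal dynamics from
the clamped value. This "state clamp" semantics models acute optogenetic
shutdown (or maximal excitation) of one population.

Runs are deterministic: identical parameters, protocol and integrator
settings give bitwise-identical trajectories. Halving the integrator
tolerances moves baseline metrics by < 1 %.

## Analysis conventions

* A peristaltic wave is counted at its initiation: the tail muscle force
  f_10 crossing f̂ upward ("the tail lifts off"), with linear
  interpolation between samples. Events during the initiation pulse are
  discarded. An optional completion-gated count keeps only initiations
  whose wave reaches the most anterior unit; on steady gaits the two
  counts agree.
* Summary metrics discard the first 100 τ_E as transient (shrunk to 20 %
  of the run for short diagnostic runs). Speed is the mean mass
  displacement over the window divided by its length; step size is tail
  displacement per wave; their product reproduces the measured speed to
  within 5 % on steady gaits.
* Peak contraction is max(c_i/L) per wave interval and segment, averaged
  over waves then segments; the A3–A4 readout restricts to the single
  inter-mass distance between masses 5 and 6.
* Off-ground count: segments with f_i > f̂; moving count: masses with
  |ẋ| > v_move = 0.01 L/τ_E (exposed in config). Both reported as
  medians across samples. Slippage is declared when the moving median
  exceeds the off-ground median.
* Propagation delays: neuron-to-neuron is the mean lag between Ê-crossings
  of neighboring excitatory units; neuron-to-proprioceptor is the mean lag
  from a unit's Ê-crossing to its stretch receptor crossing 0.5. The
  delay-curve crossover in `w_En` is found by linear interpolation of the
  sign change of their difference on the sweep grid (0.30–1.00, step
  0.05). The friction sweep uses a 15-point log-spaced grid from 0.005 to
  25/3, with the slippage boundary refined by log-midpoint bisection.
* Phases: each signal is mean-removed (contraction also linearly
  detrended, since the body drifts), the DFT is taken over an integer
  number of measured wave periods, and the phase is the negative complex
  phase at the bin nearest the wave frequency, reported relative to the
  tail excitatory unit.

## Design choices where the design was open

* **Head–tail constraint by reduction** rather than a Lagrange multiplier
  or penalty spring: exact constraint satisfaction and no added stiffness.
* **Pulse injected into the input channel** h^E (not added to E directly):
  h is the designated route for external drive, and the pulse then passes
  through the same sigmoid as every other input.
* **State clamping** for perturbation windows (not input clamping): the
  clamped population's activity is what the experiment fixes; differences
  to input-clamping would only appear in within-window derivative
  bookkeeping.
* **Sweep durations** of 400 τ_E: enough for ≥ 3 waves of the slowest
  (silenced) gaits that crawl at all, keeping full sweeps to minutes on
  one CPU.

## Measured behavior and known limitations

On defaults the simulator produces 0.040 waves/τ_E, speed 0.037 L/τ_E,
29.6 % mean peak contraction and a median of 3 off-ground segments; with
proprioception silenced, 0.010 waves/τ_E, speed 0.014 L/τ_E, 72 % mean
peak contraction (75 % for A3–A4) and a single off-ground segment. The
delay-curve crossover sits at w_En ≈ 0.68 and the slippage onset at
F_max/kL ≈ 0.36 (all computed by `scripts/acceptance.py` and the test
suite).

Limitations to keep in mind:

* One dimension only: no bending, turning, hemisegments or head
  articulation; backward crawling is out of scope.
* The silenced-proprioception model locks into tonic VNC activity for
  w_En ≳ 0.8: with w_IE = θ̂_I the inhibitory fixed point sits exactly at
  0.5, which can no longer shut off a strongly coupled excitatory chain.
  Sweep metrics for the silenced model are therefore reported only where
  it produces waves.
* Muscles are first-order force generators with a single threshold; there
  are no stretch-receptor dynamics (receptors respond instantaneously
  through σ_p), and the gut contributes no friction.
* The friction law is a velocity-smoothed Coulomb model; true stiction is
  only approximated (grounded masses creep at ≲ 1e−4 L/τ_E).
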