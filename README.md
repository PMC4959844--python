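# larvacrawl

A neuromechanical simulator of forward peristaltic crawling in the
*Drosophila melanogaster* larva, for researchers studying how neural
dynamics, body mechanics and substrate interaction jointly produce
locomotion.

The larva's body is modeled as 11 point masses (head to tail) joined by 10
damped linear springs, each segment carrying a contractile muscle driven by
a segmental excitatory/inhibitory (Wilson–Cowan) unit of the ventral nerve
cord (VNC):

```
τ_E Ė_i = −E_i + σ_n[w_EE E_i + w_EI I_i + h_i^E − θ̂_E]
τ_I İ_i = −I_i + σ_n[w_IE E_i + w_II I_i + h_i^I − θ̂_I]
τ_f ḟ_i = −f_i + f_max σ_f[E_i − Ê]
   0    = k Δ²x_i + c Δ²ẋ_i + f_i − f_{i+1} − F_i        (force balance)
  F_i   = F_max sign(ẋ_i) σ_F[f̂ − f_i]                    (gated dry friction)
```

with σ[z] = ½ + ½ tanh(g z). Excitatory drive `h_i^E` carries the two
routes a peristaltic wave can travel: a CPG-like neural coupling from the
posterior neighbor (weight `w_En`) and a proprioceptive "mission
accomplished" signal (weight `w_Ep`) that fires when the posterior neighbor
segment has contracted past the threshold `û` (≈5.6 % of segment length),
while `h_i^I = w_Ip σ_p[·]` suppresses the segment's own activity once its
contraction completes. A rigid head–tail rod models the visceral-piston
coupling through the gut, so a wave arriving at the head re-initiates at
the tail. A segment whose muscle force exceeds `f̂` lifts off the substrate
and loses friction — the physical ratchet behind forward motion.

Everything is dimensionless: lengths in segment rest length `L`, forces in
`kL`, times in the excitatory relaxation time `τ_E`.

## Worked example

```python
import larvacrawl as lc

params = lc.default_params()                       # standard parameter set
traj = lc.simulate(params, lc.preset_protocol("fig2_baseline"))
m = lc.compute_metrics(traj)
print(f"wave frequency   {m.wave_freq:.4f} waves/tau_E")
print(f"speed            {m.speed:.4f} L/tau_E")
print(f"step size        {m.step_size:.3f} L per wave")
print(f"peak contraction {100 * m.peak_contraction:.1f} %")
print(f"off-ground       {m.offground_median} segments (median)")

phys = lc.to_physical_units(m, observed_wave_rate_per_s=1.5,
                            body_length_mm=4.0)
print(f"tau_E = {phys.tau_E_ms:.1f} ms, speed = {phys.speed_mm_per_s:.2f} mm/s")
```

prints

```
wave frequency   0.0400 waves/tau_E
speed            0.0366 L/tau_E
step size        0.922 L per wave
peak contraction 29.6 %
off-ground       3 segments (median)
tau_E = 26.7 ms, speed = 0.55 mm/s
```

A single 10 τ_E excitatory pulse to the tail segment yields sustained
crawling: one peristaltic wave every 25 τ_E advancing the body about one
segment length, with three segments airborne at any moment. Matching the
model wave rate to the ~1.5 waves/s observed in third-instar larvae pins
the neural time constant near 25 ms and predicts a crawling speed of about
half a millimeter per second.

Silencing proprioception (`w_Ep = w_Ip = 0`, preset `fig4_no_proprio`)
slows the gait fourfold and roughly doubles segmental contraction — the
VNC must then relay the wave through its weak neural coupling alone, while
nothing tells a contracting segment to stop.

From the shell:

```sh
larvacrawl presets
larvacrawl run --preset fig2_baseline --out out/
larvacrawl sweep --param w_En --grid 0.4,0.6,0.8 --out sweep.csv
larvacrawl metrics out/trajectory.csv
```

## Experiments included as presets

* `fig2_baseline` — sustained crawling from a tail pulse.
* `fig3_E_clamp`, `fig3_I_clamp` — optogenetic-style perturbations: the
  wave halts at a clamped segment (E8 held at 0, or I8 held at 1, for
  t ∈ [65, 95]) and resumes from that segment on release.
* `fig4_no_proprio` — proprioception silenced.
* `fig5_wEn_sweep` — neural-coupling sweep with and without
  proprioception; the two propagation-delay channels cross near
  w_En ≈ 0.65, below which the full model is insensitive to the CPG
  coupling.
* `fig6_friction_sweep` — substrate-friction sweep; below
  F_max/kL ≈ 0.4 grounded segments start slipping, waves slow down and
  steps lengthen.
* `pure_proprio` — no intersegmental neural coupling at all (w_En = 0);
  proprioception alone sustains a nearly unchanged gait.

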