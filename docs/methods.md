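# Methods

This note documents the models implemented in `myoloop`, the parameter
choices that matter, the numerical conventions, and what the synthetic
subject does and does not emulate.

## Signal model and EMG decoding

Surface EMG is treated as amplitude-modulated band-limited noise:
`emg(t) = x(t)·n(t)·s`, where `x ∈ [0,1]` is the latent motor drive (a
proxy for the net alpha-motoneuron command), `n` is zero-mean Gaussian
noise band-passed to 20–450 Hz and normalized to unit variance, and `s` is
the full-drive amplitude in mV.  Sampling is at 2000 Hz.

**Normalization (`mv_scale`).**  Both decoders divide rectified mV by a
calibration constant so that drive estimates are commensurate with `[0,1]`.
The default calibration is the *mean* of a rectified maximal-effort trace:
for the Gaussian amplitude model the rectified mean at full drive is
`s·sqrt(2/π)`, and both estimators below converge on the mean of the
normalized rectified signal, so mean-normalization makes the expected
estimate equal the true drive.  A 95th-percentile option is provided (a
common MVC convention), but note that for Gaussian EMG it overestimates the
scale by `1.96/sqrt(2/π) ≈ 2.46` and biases recovered drive low by the same
factor; it is not the default for exactly that reason.

**Linear envelope.**  Rectification followed by a causal (single-pass)
3rd-order Butterworth low-pass at 1 Hz, unit DC gain, output clamped to
`[0,1]`.  Causal filtering is deliberate — the controller runs in real
time — so the envelope carries the filter's full group delay.

**Bayesian filter.**  A grid filter over `n = 128` drive levels uniform on
`[1/128, 1]`.  Per 2000 Hz sample:

1. *propagate*: `p′ = (1−β)(p + α·Lap(p)) + β/n`, where `Lap` is the
   discrete second difference with reflecting boundaries.  The diffusion
   term (α = 1e−4 per sample) models slow drift of intent; the uniform
   resetting term (β = 1e−18 per sample) is the discrete form of a Poisson
   jump process — intent occasionally jumps anywhere, which is what lets
   the posterior re-localize quickly after an abrupt change.  Non-negativity
   of the update requires α ≤ 1/2, enforced at parameter construction.
2. *measure*: each level is weighted by the exponential amplitude
   likelihood `(1/x)·exp(−ẽ/x)` with `ẽ` the normalized rectified sample.
   The update is computed in the log domain and renormalized each sample;
   a fully underflowed posterior (possible only with degenerate inputs)
   resets to uniform with a logged warning.
3. *readout*: MAP level, ties broken toward the lower level.

α and β are interpreted per 2000 Hz sample; both are plain config values,
so a per-second interpretation is a one-line change.  The floor level
`x_floor = 1/128` keeps the likelihood finite at zero drive and is the
output for a silent channel.

The `resample_drive` bridge to the 100 Hz loop takes the last sample of
each 20-sample block — the freshest causal estimate — which is also the
convention inside the controller; constant signals are preserved exactly.

## Muscle

Standard Hill-type formulation.  Excitation–activation is a first-order
lag, `da/dt = (u−a)/τ`, with τ_act = 10 ms on the way up and
τ_deact = 40 ms on the way down; integration is explicit Euler at the
control step (the documented discrete update `a + dt/τ·(u−a)`, clamped, so
a step with `dt ≥ τ` lands on `u`).  Force is

    F = F_max·(a·f_L(l)·f_V(v) + f_P(l)),  F ≥ 0

with `f_L(l) = exp(−((l−1)/w)²)`, w = 0.45; the concentric Hill hyperbola
`f_V(v) = (1+v/v_max)/(1−v/(c·v_max))` for lengthening velocity `v ≤ 0`
(c = 0.25, v_max = 10 l_opt/s), an eccentric branch rising from 1 and
saturating at 1.5·F_max; and passive term `f_P = k_p·max(0, l−1)²`,
k_p = 3.  F_max = 10 N puts the task range (0.5–3.4 N) in the lower half of
the muscle's range.  All values are literature-typical defaults and live in
the config.

## Proprioceptive feedback

Both pathways output a dimensionless correction added to the feedforward
drive: `command = clamp(drive + fb, 0, 1)`.  The sign convention is that of
the monosynaptic stretch reflex: stretch beyond the reference length is
*excitatory* (`fb > 0`), and the shortening that accompanies pressing
produces a small inhibitory correction, regulating toward the commanded
length.  With the feedback gain at 0 the loop reduces exactly to open-loop
EMG control — a property used as a test.

**Proportional:** `fb = g·(l − l_ref)`, `g = 0.01/0.10 = 0.1` by the
calibration rule below.

**Spindle:** the Ia population rate is a reduced static+dynamic model,

    r = clip(b(γ_s) + k_p·(l − l_ref) + k_v(γ_d)·sign(v)·|v|^0.6, 0, r_max)

with baseline `b = 10 + 1.0·γ_s` pps (50 pps resting discharge at the fixed
γ_s = 40 pps), stretch gain k_p = 200 pps per unit normalized length
(+20 pps for a 10 % stretch), velocity gain `k_v = 2 + 0.3·γ_d` and the
classic 0.6-power velocity nonlinearity; r_max = 400 pps.  Gamma drive is
fixed at 40/40 pps — no alpha–gamma coactivation is modelled.  The rate
drives 128 independent Poisson afferents (`count_i ~ Poisson(r·dt)` per
10 ms tick); a sliding 100 ms window converts the population count back to
a rate, subtracts the calibrated baseline and applies the decoder gain.
Poisson encoding was chosen over integrate-and-fire neurons because its
mean/variance statistics are analytically checkable; the full
intrafusal-fiber chain of detailed spindle models is a documented extension
point, not implemented.

**Gain calibration.**  Both pathways are calibrated to the same operating
point: a held 10 % stretch elicits a 1 % command change.  For the
proportional pathway this is algebra (g = 0.1).  For the spindle pathway
the decoded value is linear in the decoder gain, so the calibration runs
the Poisson pathway once at unit gain under the held stretch (2000 ticks,
seeded), averages out the encoding noise, and rescales; rerunning with the
same seed is exactly idempotent and different seeds agree to well under a
percent.

## Plant

The motor/tendon/finger chain is collapsed to one translational DOF:

    m·ẍ = F_tendon − k_r·x − d·ẋ − k_c·max(0, x − gap)

with gap = 1 cm, contact stiffness k_c = 2000 N/m (task-range forces at
sub-millimeter penetration — the task is quasi-isometric but not strictly
isometric, and the spindle can pick up the penetration-induced length
change), return-spring k_r = 20 N/m (the hand-opening springs), effective
mass m = 0.2 kg and damping d = 80 N·s/m.  The damping dominates free
motion, so approach speed scales with commanded force and a brisk press
crosses the gap in ~0.3–1.0 s.  Integration is semi-implicit Euler at
100 Hz with the damping term treated implicitly,
`v′ = (v + dt·F_elastic/m)/(1 + dt·d/m)`, which is unconditionally stable
in the damping and stable for the contact stiffness at this step size; the
held-force steady state matches the analytic equilibrium
`k_c(F − k_r·gap)/(k_c + k_r)` to better than 0.1 %.  Contact force is
`k_c·(x − gap)` when penetrating, zero otherwise (complementarity holds at
every step), and the object breaks at `contact ≥ 4.4 N` — threshold
inclusive.

The muscle-length map is linear: `l = l_rest − 10·x` per meter of fingertip
travel, so crossing the gap shortens the flexor by 10 %.

## Task and metrics

A trial succeeds when the contact force stays inside `[F_min, F_max]` for
100 consecutive 100 Hz ticks (1 s); the dwell counter resets on any
excursion (strict reading of "continuous").  The break check precedes the
dwell check within a tick, so breaking on what would be the final dwell
tick fails the trial.  Timeout is 15 s.  MT is the timestamp of the first
tick with nonzero contact force; CT runs from MT to the dwell-completing
tick and therefore includes the dwell second.  Both are sample timestamps,
so a scripted trace whose first contact sample is already in-window yields
CT = dwell − dt; in closed loop the force always rises through sub-window
values first.

Target geometry: six (D, W) pairs with `ID = log2(2D/W)` at 1.5, 2.0, 2.5,
3.0, 3.5, 4.0 bits, display units mapped 1:1 to newtons, distances rising
with difficulty, and the hardest window's upper bound set to 4.4/1.3 N so
the break threshold exceeds the highest target by ~30 %.  A block is 36
trials (6 IDs × 6 reps) in a seeded random order; the experiment is 4
condition blocks (144 trials) in seeded random block order, with the
EMG-scale calibration performed once per experiment, as for a single
subject visit.

TP and the CT–ID regression use successful trials only (CT is undefined
otherwise); the regression is fitted on per-ID mean CT (a 6-point Fitts
plot) by ordinary least squares, with raw-trial fitting available as an
option.  Flat CTs return slope 0 and, by convention, R² = 0.  IP = 1/slope
is flagged NaN for non-positive slopes rather than extrapolated.  A
two-way ANOVA helper is provided as a thin statsmodels call for exploring
simulated logs; it is not part of the validated surface.

## Synthetic subject

The simulated operator closes the visual loop: each 10 ms tick it sees the
displayed contact force delayed by a 200 ms reaction time and emits the
next 20 EMG samples.  Its intent combines

* a **ballistic press** at trial start toward the drive its internal static
  model predicts will land the force near the target, deliberately aimed
  half a half-width *below* the window center (risk aversion toward the
  break zone) and corrupted by ~15 % multiplicative aim error;
* **intermittent re-aims**: while the seen force error exceeds half the
  window width, Poisson-timed jumps (2 events/s) rescale the intent by the
  target/seen ratio, with a refractory period of one reaction delay after
  each jump — the subject waits to observe the outcome of one adjustment
  before making another;
* **slow visual corrections**: an integral-like term, 0.08 command units
  per N·s of seen error;
* **motor noise**: an Ornstein–Uhlenbeck wobble (sd 0.015 drive units,
  300 ms correlation time).

This produces exactly the piecewise-constant-with-jumps intent structure
the Bayesian filter assumes, Fitts-like behavior (narrower windows take
longer to acquire and hold), and occasional breakage when an overshoot or
an ill-judged re-aim carries the force past 4.4 N.  What it does **not**
emulate: electrode-skin idiosyncrasies (crosstalk, shift), additive
baseline noise (available as a config but off by default), learning across
blocks, fatigue, or the variability between human subjects — so passing
tests demonstrate that the controller stack behaves correctly and that the
factor ordering (Bayesian > linear decoding; spindle helping most under
linear decoding) emerges for a plausible operator, not that human success
rates are quantitatively reproduced.  Reproducing human SR/BR/TP
distributions is explicitly out of scope.

## Numerical conventions and degenerate inputs

* All randomness flows from numpy `SeedSequence` spawning: experiment →
  blocks → trials → (controller, subject); identical seeds give
  bit-identical trial logs.
* Posterior mass is renormalized every sample; conservation is asserted to
  1e-9 in tests and the streaming decoder matches the documented
  recursion to 1e-12.
* Drive, command and activation are clamped to `[0,1]` at every tick;
  muscle force and contact force are clamped at 0.
* Empty result sets raise on the rate metrics; blocks with no successes
  report NaN throughput/slope/IP rather than raising, so degenerate
  conditions remain summarizable.
* The config layer rejects unknown keys, coerces YAML's string-typed
  exponent scalars (e.g. `1e-18`) back to floats, and round-trips
  losslessly through YAML or JSON.

## Problem sizes

Recovery and responsiveness checks use 10 s of synthetic EMG per case at
2000 Hz; calibration simulations use 1000–2000 ticks; the structure and
end-to-end checks run the full 144-trial experiment (the natural unit of
the design — one simulated visit), which takes on the order of half a
minute per run on one CPU.
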