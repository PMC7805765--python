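# Methods

This note records the modelling assumptions, parameter choices and numerical
decisions behind the package, and what the synthetic-data tests do and do not
demonstrate about real recordings.

## EMG conditioning

The envelope chain is a 2nd-order Butterworth high-pass at 35 Hz, full-wave
rectification, a 2nd-order Butterworth low-pass at 4 Hz, and division by the
per-muscle MVC amplitude. Two phase modes are exposed: `causal` (single pass,
zero initial conditions — what a streaming controller can compute) and
`zero_phase` (forward–backward, no group delay — the offline analysis
default). Stated orders are prototype orders; forward–backward application
squares the magnitude response. The causal chain's dominant delay is the 4 Hz
low-pass group delay, √2/(2π·4) ≈ 56 ms at DC. MVC is taken as the peak of
the MVC-trial *envelope* (computed with the same chain), which is robust to
single-sample noise in a way a raw peak is not.

The fatigue pre-filter is a 4th-order Butterworth band-pass, 15–450 Hz; the
scipy bilinear design places the −3 dB points at the design corners.

## Torque model

Activation dynamics use the exponential map a = (e^{Au}−1)/(e^A−1); A = 0 is
handled as the linear limit a = u. Envelope values above 1 (possible when a
task exceeds the MVC trial) are clipped with a warning.

The Hill curves are closed forms with configurable constants:

| curve | form | defaults |
|---|---|---|
| active force–length | exp(−(l̃−1)²/γ) | γ = 0.45 |
| force–velocity, concentric (ṽ≤0) | (1+ṽ)/(1−ṽ/k_v) | k_v = 0.25, v_max = 10 l₀/s |
| force–velocity, eccentric (ṽ>0) | (f_ecc ṽ + k_e)/(ṽ + k_e) | f_ecc = 1.4; k_e = (f_ecc−1)k_v/(k_v+1) for C¹ continuity at ṽ=0 |
| passive | (e^{k_p(l̃−1)/ε₀}−1)/(e^{k_p}−1) for l̃>1 | k_p = 4, ε₀ = 0.6, so f_p(1+ε₀)=1 exactly |

Pennation follows the constant-thickness model (l₀ sin φ₀ conserved); with the
tendon rigid at its slack length, fiber length is algebraic in the MTU length
and the fiber velocity is the MTU velocity projected by cos φ. Muscles cannot
push: the tendon-line force is clamped at zero, and a slack MTU
(lmt ≤ tendon slack length) contributes no force, with the fiber length
clamped at 0.3 l₀ for numerical hygiene.

The default geometry tables are cubic polynomials in the elbow angle on
[0, 2.6] rad, built by integrating parabolic moment-arm profiles: the flexor
arm peaks at 4 cm at mid-flexion (2 cm at the range ends), the extensor arm is
−2 to −2.5 cm. These are editable plumbing — plausible magnitudes for the
elbow, not subject-specific truth — and are exactly consistent with
r = −∂lmt/∂φ by construction. Evaluation outside the fitted range clamps with
a warning. MTU velocity uses the chain rule (−r·ω) with the angular velocity
taken from the kinematic input; only when velocity is absent is it obtained by
smoothed numerical differentiation (central differences + 4 Hz zero-phase
low-pass).

Default subject: flexor F_max = 625 N, l₀ = 0.116 m, slack length 0.270 m,
unpennated; extensor F_max = 800 N, l₀ = 0.134 m, slack length 0.143 m,
pennation 0.21 rad; activation shape A = −2 for both. These give a maximal
static flexion torque of ≈ 19 N·m at 90°, so the study tasks (≈ 7–11 N·m
demand) sit at moderate activation.

## Suit and control loop

The printed closed form for the cable displacement is implemented as
h_f(φ) = 2√(a²+b²)·cos(atan(a/b)+φ/2) − 2b — the unique dimensionally
consistent reading with h_f(0) = 0 (cable taut at full extension). The moment
arm is the analytic derivative; because the load cell measures tension only,
the suit torque is |J|·f with f ≥ 0 enforced.

The admittance law (K_p + K_i/s)/(1 + K_d s) is discretised by the bilinear
transform (trapezoidal integrator + first-order lag); with K_i = K_d = 0 the
update is exactly ω_r = K_p e_r. The inner loop the hardware implements is
summarised by a first-order velocity servo (time constant 20 ms) with a unit
joint-velocity feedforward that keeps the cable taut during motion. Tension
comes from a series stiffness (default 5000 N/m) acting on cable stretch: the
physical tendon is nearly inextensible, but a compliant series element is
required for a well-posed tension state. Backlash and Coulomb friction are not
modelled (they are compensated in the hardware's inner loop).

Default admittance gains K_p = 0.6 rad·s⁻¹/N·m, K_i = 6.0 rad·s⁻²/N·m,
K_d = 5 ms give a stiff, slightly underdamped torque step response with the
default plant (settling within ~1 s, DC tracking error < 0.1%). The loop and
plant are integrated by fixed-step RK4 at the 1 kHz controller rate, matching
the study's DAQ. The plant is a rigid pendulum — forearm inertia 0.08 kg·m²,
mass·com 0.225 kg·m, viscous damping 0.5 N·m·s, optional hand load — with the
gravity lever maximal at 90° flexion. Two plant modes exist: dynamic (the
suit drives the arm) and prescribed (the wearer imposes the posture, e.g. an
isometric hold, and only the actuation states evolve). In the NE condition
the device is not worn, so the actuation path is disabled entirely and the
plant follows its passive dynamics exactly.

Divergence (|ω| > 10³ rad/s) aborts with a diagnostic naming the time,
gains and condition.

## Calibration

The dynamic calibration trajectory follows θ_d = A₀ + A sin(2πf t) with
A₀ = A = 45° and the step-wise frequency schedule 0.05→0.5 Hz (20 s per step,
after 20 s of rest at 0°). Phase is carried across frequency steps so the
profile is continuous; taken literally, the sinusoid would also jump 0°→45°
at the end of the rest, so the last 2 s of the rest block are a minimum-jerk
ramp onto the offset — dwell timing and total duration (220 s) are unchanged.
With this schedule the peak velocities span 14.1–141.4 °/s (A·2πf).

The reference torque is a planar single-joint inverse-dynamics surrogate,
τ = I_tot·α + g(m·r_com + m_load·l_load)·sin φ. Tuned parameters are
multiplicative factors on l₀ and tendon slack length (±15%), F_max (×0.5–2),
and the absolute activation shape A ∈ [−5, −0.01]; the objective is the RMS
torque error normalised by the reference RMS (invariant to a common
rescaling). The optimiser is trust-region-reflective bounded least squares on
the torque residuals with five deterministic starts (the nominal point,
clipped into the bounds, plus four fixed-seed uniform draws); the loop stops
early once a start reaches an essentially exact fit. Standard errors come
from a Gauss–Newton linearisation at the optimum. The objective is evaluated
on series down-sampled to 50 Hz — the envelope carries no content above 4 Hz,
so this is lossless for the fit and keeps a five-start calibration under a
few seconds.

**Identifiability.** At unloaded calibration intensities the envelopes stay
below ~0.25 of MVC, where F_max and the activation shape A are nearly
degenerate: parameter pairs far apart on that ridge produce torque profiles
within ~2% of each other. Noiseless calibration therefore recovers all
parameters essentially exactly, but once envelope noise is present the fit
can slide along the ridge (steeper A attenuates transmitted envelope noise,
so noise actively favours one end) while the *torque* remains accurate. Users
who need identified parameters rather than an accurate torque map should
calibrate with loaded trials that push excitations higher, or fix A.

## Synthetic data

The generator emulates the study's three sessions with a default subject of
78.5 kg body weight and 0.30 m forearm: a lifting task (five repetitions of a
20 cm lift, minimum-jerk elbow trajectories, load 2% of body weight), an
isometric task (holds at 90° — 40 s holds, 20 s rests — with a 3 kg wrist
load and imposed fatigue drifts), and the calibration trajectory. Muscle
excitations are solved in closed form so the forward torque model reproduces
the inverse-dynamics demand: the flexor absorbs positive demand above a 5%
tonic co-activation, the extensor negative residuals; demands that would need
activation above 1 raise an error naming the violating instant. The recorded
ground-truth torque is always the forward-model torque of the generated
excitations, which equals the inverse-dynamics torque wherever the demand is
representable.

Raw EMG is an amplitude-modulated carrier at 1 kHz. The default carrier is
band-limited (15–450 Hz) Gaussian noise whose slow amplitude fluctuation is
divided out before modulation; without this flattening, the intrinsic 4 Hz
envelope ripple of band noise (~7% of the mean) would dominate the envelope
tracking budget. The flattened carrier tracks a constant profile within
±2.5% after MVC normalisation. For fatigue studies the carrier is instead a
constant-amplitude periodic triangular frequency sweep over 40–240 Hz (period
0.75 s, so a 3 s epoch holds exactly four sweeps, plus a 5% noise floor): its
spectrum is flat with an analytically known median, so slow imposed spectral
trends remain identifiable within a 24 s window — a Gaussian carrier's
per-epoch median-frequency standard error (~6 Hz over 3 s of a 435 Hz band)
would alone exceed a ±0.1 %/s slope tolerance. The sweep band sits inside the
15–450 Hz analysis band-pass with enough headroom that imposed spectral
scalings up to ±50% stay clear of the filter edges.

Imposed fatigue trends multiply the amplitude by (1 + r_ARV t/100) and warp
time as τ(t) = t + (r_MNF/200)t² (instantaneous spectral scale 1 + r_MNF
t/100), resampled with cubic interpolation on a 4× oversampled grid — plain
linear interpolation at the native rate attenuates the top of the band and
biases the amplitude trend. In isometric sessions the drift restarts at each
hold onset.

What the generator does **not** model: motor-unit recruitment and firing
statistics, electrode crosstalk and movement artefacts, multi-articular
kinematics, co-contraction strategies beyond a fixed tonic level, and any
physiological link between mechanical load and fatigue rates (drifts are
imposed, not emergent). Passing tests therefore demonstrate correctness of
the pipeline's signal path and estimators under controlled conditions, not
fidelity to human EMG.

## Outcome metrics

Segmentation smooths the angle with a Savitzky–Golay filter (defaults:
window 51 samples at 100 Hz, order 3, exposed in the API) and thresholds the
absolute smoothed derivative at 10% of its peak; runs shorter than 50 ms are
discarded as noise stubs, and the sign of the mean derivative labels flexion
vs extension.

SPARC normalises the speed profile and its zero-padded magnitude spectrum by
their maxima (making the index exactly amplitude-invariant), restricts the
spectrum to the adaptive band — up to the last frequency below the 10 Hz
cutoff where the normalised magnitude still exceeds 0.05 — and returns the
negated arc length with the frequency axis scaled by the selected band width.
SPARC is computed per segment with the trial mean reported.

Phase RMS is computed over the union of same-phase segments, on both the
envelope (%MVC) and the raw band-passed signal (signal units, the primary
variant in reports); an absent phase is reported as missing, never zero.

Fatigue indices use eight 3 s epochs laid out from the hold onset of the last
contraction: ARV is the rectified mean; the spectral index is the *median*
frequency of the mean-removed Hann periodogram (a mean-frequency variant is
available behind the `estimator` flag). Rates are least-squares slopes over
epoch mid-times, normalised by the fitted line's value at the contraction
onset — so a signal ramping at r % of its initial value per second is
recovered as r, without propagating the first epoch's estimation noise into
the denominator.

Biological torque is τ_ID − τ_assist; the relative change is reported both as
the ratio of means and as the mean of per-sample ratios (the latter matches
per-subject averaging of ratios).

## Problem sizes

Default sessions are generated at 100 Hz kinematics / 1 kHz EMG: 220 s for
calibration, ~27 s for lifting, one to five 64 s isometric trials. Closed-loop
simulations run at 1 ms steps for 5–64 s. Calibration objectives are evaluated
at 50 Hz; a five-start fit takes a few seconds. These sizes were chosen so a
complete verification run (test suite plus acceptance script) finishes in
about a minute on a single core while every stage still operates at the
study's native sampling rates.
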