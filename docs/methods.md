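# Methods

## The model

A force plate is treated as a single-axis driven, underdamped harmonic
oscillator,

    m x'' + c x' + k x = F(t),      c = 2 ζ √(k m),

with natural frequency f_n = (1/2π)√(k/m) — the plate's *intrinsic
oscillatory property* (IOP).  Any force delivered to the plate (footfalls,
taps, tremor) excites ringing at the damped frequency f_n √(1 − ζ²); the
power at that frequency tracks the kinetic energy delivered, so the
IOP-band power is a readout of overall momentum.  The load cell transduces
the spring force k·x, expressed in gram-gravity and scaled by the cell
sensitivity (33 mV per gram-gravity by default) and preamplifier gain
(1000×), so a static payload of w gram reads 33·1000·w mV at the output.

Tremor severity is the frequency-specific counterpart: the PSD of the
voltage trace is divided by its own integrated 40–50 Hz IOP power over the
same period, and the severity scalar is the *density value* of that
normalized spectrum at the concave-peak frequency inside the 15–25 Hz
tremor window (units 1/Hz).  A density value, rather than a band integral,
is used because the quantity being reported carries 1/Hz units; the choice
is config-exposed.  Because tremor force amplitude scales linearly with
locomotor intensity, both numerator and denominator scale together and the
severity is invariant to how much the animal happened to move.

## Integration scheme

The oscillator is advanced with the exact zero-order-hold discretization of
the linear state-space system (state-transition matrix per step, via
`scipy.signal.cont2discrete`).  This is unconditionally stable and *exact at
the sample instants* for piecewise-constant drive at any rate, so the
integration runs directly at the drive rate; an FIR anti-alias decimation is
applied only when the drive rate exceeds the output rate.  A dedicated
`impulse_response` entry point propagates a true Dirac impulse (post-impulse
state x = 0, x' = 1/m) through the same transition matrix; it matches the
closed form x(t) = (1/(m ω_d)) e^(−ζω_n t) sin(ω_d t) to machine precision
and is the oracle anchor for the simulator.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| mass_kg | 0.5 | kg | plausible plate+payload mass; only the emergent ~42 Hz is physically constrained, so mass is a stand-in and stiffness is derived from it |
| stiffness_N_per_m | k(42 Hz, 0.5 kg) ≈ 34 819 | N/m | tunes f_n to the ~42 Hz resonance of the reference hardware |
| damping_ratio ζ | 0.05 | — | ring-down over a few cycles ("fast attenuation"); exposed as config |
| sensitivity, gain | 33 mV/g, 1000× | | load-cell and preamplifier constants |
| fs_hz | 1000 | Hz | voltage sampling rate |
| IOP band | 40–50 Hz | Hz | denominator of the severity ratio; a 42–50 Hz variant is provided for rhythmic-drive experiments whose 2nd harmonic (40 Hz) would otherwise sit inside the denominator |
| tremor window | 15–25 Hz | Hz | search window for the 20 Hz action tremor |
| GEN bands | 2–30 (video), 2–50 (accelerometer) | Hz | general-activity denominators |
| velocity threshold | 0.4 | mm/s | epochs *not over* the threshold are excluded before velocity normalization |
| PSD estimator | Welch, Hann, 1 s segments, 50% overlap | | 1 Hz resolution separates 16/20/~42 Hz features; all parameters config-exposed |

## Synthetic scenarios

The generators emulate the experimental conditions, not any specific animal:

* **Tapping** — half-sine force pulses ~5 ms wide (broadband below
  ~100 Hz), Poisson-timed with gamma-distributed amplitudes (random) or
  strictly periodic at 5/7 Hz (metronome).
* **Mouse locomotion** — a mean-reverting, zero-clipped activity envelope
  L(t) with 2 s correlation time modulates the *strength* of Poisson
  impulses at a fixed 20/s rate (≈5 footfalls/s across four paws).  Keeping
  the rate fixed makes locomotor band power scale as L², the same power law
  as the tremor term, which is what the linear tremor–momentum coupling
  requires; modulating the rate as well would make locomotor power scale as
  L³ and break the severity invariance by construction.
* **Tremor (Grid2-like)** — a sustained, phase-continuous force
  `coupling · L(t) · sin(2π·20 t)`.  The default coupling (1.2 N per unit
  envelope) puts tremor-band power on the same order as IOP-band power, the
  regime in which a clear 20 Hz peak rides on the locomotor spectrum.
* **Accelerometer** — scaled plate-local force plus a tremor component and a
  background whose PSD decays exponentially with frequency (white noise
  shaped as e^(−0.05 f) in power), emulating the broadband background of
  head-mounted sensors.
* **Video track** — heading random walk with speed ∝ L(t) in a
  280 × 160 mm arena at 60 fps, 0.5-pixel Gaussian marker jitter, then
  quantization to the 0.22 mm pixel grid.
* **Optogenetic drive** — during light-on intervals, non-negative half-sine
  pulses at the drive frequency spanning half a period each (a
  half-wave-rectified sinusoid: the limb pushes, never pulls), amplitude
  linear in the nominal power.  Rectification creates the 2nd harmonic at
  2f while the fundamental stays dominant.  The power→force map is linear
  and synthetic — the true mapping from illumination to force is unknown.
* **Natural movement** — constant-rate broadband impulses whose amplitude
  follows a per-epoch envelope (geometrically spaced levels, shuffled);
  no periodic component in 2–30 Hz.

What the generators do *not* emulate: gait and posture structure, grooming
or rearing, multi-limb phase relationships, nonlinear spring or sensor
saturation, non-Gaussian electronics noise.  Passing tests therefore show
that the *analysis pipeline* behaves as designed under the stated coupling
assumptions, not that real recordings satisfy those assumptions.

## Background subtraction

Movement spectra carry an aperiodic, decaying background that inflates
means (deflating CVs, an illusion of consistency) and biases the local-max
peak rule.  Per channel:

* accelerometer — two-term exponential a·e^(bf) + c·e^(df), fitted by
  bounded least squares (b, d ≤ 0; log-linear initialization, residual-based
  second term, multi-start on failure) on bins outside 0–5 Hz and 13–27 Hz,
  support up to 50 Hz;
* video — one-term exponential, 0–5 Hz excluded;
* force plate — shape-preserving piecewise-cubic (pchip) interpolation
  across the excluded 12–27 Hz tremor band from flanking bins.

Excluded bins never enter the fit support, so a tremor peak of any size
cannot leak into its own background estimate.  Residuals after subtraction
are floored at zero (a PSD and the band powers derived from it must stay
non-negative).

## Numerical and procedural choices

* Band edges are inclusive on both sides; "between 40 and 50 Hz" is read as
  the closed interval.
* The peak rule takes strict local maxima with negative centred second
  difference; among candidates the highest wins, ties break to the lower
  frequency.  Monotone windows return "not found"; severity then falls back
  to the window mean and is flagged.
* Split halves divide the analyzed epochs by count, the extra epoch going to
  the first half; the pair CV uses the n−1 sample SD, i.e.
  √2·|a−b|/(a+b).
* The velocity threshold keeps epochs strictly above 0.4 mm/s ("not over"
  excludes equality).
* Mass calibration regresses 1/f² on added mass: slope 4π²/k, intercept
  4π²m₀/k; Pearson r is reported with a Fisher-z 95% CI.
* Rank tests (Wilcoxon signed-rank) and Pearson correlations are delegated
  to scipy; identical pre/post arms short-circuit to p = 1 (the signed-rank
  statistic is undefined when every difference is zero).

## Problem sizes

Evaluation runs use desk-scale recordings: 60–120 s simulated records,
22 two-second epochs for tremor–IOP correlation, 54 ten-second off-epochs
for the natural-movement correlation (off periods in a block design last
tens of seconds), six 30 s recordings for the mass series, and 20 seeded
recordings for the CV comparison.  At 2 s epochs a band power rests on ~3
Welch segments, so epoch-level correlations carry visible χ² estimator
noise; correlations over longer epochs are correspondingly tighter.

## Known limitations

* Only one spatial axis is modelled; real plates have small cross-axis
  sensitivity.
* The damping ratio is a design default (ζ = 0.05), not a measured value;
  all ring-down statements scale with it.
* The accelerometer channel synthesizes head acceleration directly from the
  drive rather than solving a coupled head–body model.
* The optogenetic power→force map is linear by construction; only ordinal
  statements about dose should be read from it.
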