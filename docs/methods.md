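# Methods

This note documents the models behind `pwmtms`, the calibrated constants,
the numerical choices, and what the synthetic data can and cannot show.

## Coil pulse models

**Conventional monophasic pulse.** A capacitor `C` charged to `V0`
discharges through the coil (`L`, series resistance `R`). While the circuit
is underdamped (`R² < 4L/C`) the closed forms

    i(t) = V0/(ωd L) · e^{−αt} sin(ωd t),      α = R/2L,  ωd = √(1/LC − α²)
    v(t) = V0 · e^{−αt} (cos ωd t + (α/ωd) sin ωd t)

describe the rise. At the coil-current peak (the zero of `L di/dt`) the
model switches to a freewheel path of resistance `R_fw`: the current decays
with time constant `L/(R + R_fw)` and the coil terminal voltage becomes
`−R_fw·i`. The returned voltage is the terminal voltage `v = L di/dt + R i`
throughout; the small resistive drop means it steps from `+R·i_peak` to
`−R_fw·i_peak` at the switch, as a freewheel-diode commutation does.

Defaults: `L = 16.35 µH`, `R = 0.08 Ω`, `R_fw = 0.0908 Ω` (tail time
constant ≈ 180 µs), `V0 = 2800 V` at 100 % output. The capacitance,
`C = 367 µF`, is a calibrated constant: it places the pulse's dominant
spectral component at 2.4615 kHz, exactly 1/13 of the 32 kHz switching
frequency of the PWM device, which is the published relation between the
two. (Textbook constants for this device class, `C ≈ 185 µF`, put the
fundamental near 2.95 kHz; the actual discharge-circuit values of the
modelled devices are not public, so the spectral relation is the anchor.)

**Five-level PWM pulse.** Two cascaded H-bridge cells with a fixed DC link
`V = 800 V` produce the level alphabet {−1600, −800, 0, 800, 1600} V.
Regular-sampled modulation: each 31.25 µs switching period takes the
period-average of the target voltage, selects the adjacent level pair that
brackets it, and sets the upper-level duty cycle so the period's volt-second
integral matches the target's exactly. Pulses are centered in the period
(leading-edge placement is available); out-of-range targets saturate at the
extreme level with a warning. The switching plan stores exact
(continuous-time) duty cycles; the sampled rendering quantizes switch edges
to the grid, with a per-period volt-second error of at most half a sample
times one level step.

Because the DC link is fixed, the device realizes lower intensities by
modulation depth, not by scaling the rails. Relative harmonic content
therefore depends on the operating amplitude: the 32 kHz component is ≈ 39 %
of the fundamental at full modulation depth and ≈ 49 % at the study's
typical operating intensity (the 41.34 %MSO mean resting motor threshold,
a 1157.5 V peak target). The canonical spectral comparison uses the
operating-intensity pulse, i.e. the pulses as delivered in use.

**Numerics.** Time step 0.05 µs (625 samples per switching period; an exact
integer, which the modulator requires). Coil current from voltage uses the
implicit trapezoidal rule, which is A-stable and integrates the voltage
staircase without ringing. Records begin with a 62.5 µs zero lead (two
switching periods) and cover eight freewheel time constants, so both ends of
every record are below 1 % of peak and the last switching period renders as
a clean zero level.

## Spectra

Spectra are zero-padded FFTs (rectangular window — the pulse has compact
support) padded to ≥ 20 ms for 0.05 kHz resolution. The *fundamental* is the
global magnitude maximum over f > 0; all magnitudes are reported as percent
of it. The harmonic summary takes the largest local maximum above a 10 kHz
search floor (safely above the ≈ 2.5 kHz fundamental lobe, safely below the
32 kHz switching component) and probes the comparison spectrum at the same
frequency. Records whose end samples exceed 1 % of peak are rejected rather
than windowed, since a truncated tail would smear leakage across the band.

## Surrogate neuron bank

The reference treatment of TMS activation couples morphologically detailed
multi-compartment neurons to field simulations. This package replaces it
with a declared surrogate: each neuron low-pass filters a pointwise-gained
copy of the induced field,

    dm/dt = (g(e) − m)/τ,   g(e) = gp·e (e ≥ 0),  gn·e (e < 0),   m(0) = 0,

where `e ∝ dI/dt` (unit coupling, central differences), and fires when
`max_t m(t)` reaches its base threshold. The model is positively homogeneous
in the stimulus scale, so the bisection threshold search has an exact linear
closed form against which it is verified (relative tolerance 1e-4).
Thresholds are reported as the peak coil-current rate of change (A/µs) at
the activation scale.

**Matched calibration.** Pulses are compared at matched positive peak coil
voltage: the PWM device at 100 % of its own output (1600 V) against the
conventional pulse scaled to the same peak. At matched peaks both pulses
have the same peak dI/dt (level-driven for the staircase, initial-step for
the discharge), so the threshold ratio reduces to the ratio of membrane
responses. At mismatched peaks the staircase's level-driven instantaneous
dI/dt dominates the metric and the comparison is not meaningful.

**Calibration of the bank.** With the signed gain function above, the
negative-phase gain cannot move the response peak (which occurs at the end
of the depolarizing phase), so the PWM pulse's threshold advantage in this
surrogate comes from switching-ripple overshoot riding on the membrane
trajectory. That overshoot decays quickly with τ: ≈ 6.1 % at τ = 50 µs,
≈ 2 % at 80 µs, < 1 % beyond 150 µs. Reproducing the published ≈ 6 %
per-layer reduction therefore pins the effective time constants near the
short end of the admissible [50, 600] µs range. The calibrated layer
constants are τ = 50.4, 50.7, 51.0, 51.3, 52.0, 51.6 µs for L1, L2, L3, L4,
L5, L6 (ordered L1 shortest → L5 longest, necessarily clustered), negative
gain 0.3 everywhere, and base thresholds spanning a factor of four (deep
output layers most excitable) to give the population its log-scale
threshold spread. Clones jitter τ (±1 %) and base threshold (±15 %) with a
seeded generator (default seed 20220613). These are calibrated constants of
the surrogate, not biophysical measurements; the surrogate reproduces the
*relative* device comparison (layer medians ≈ 5.75–6.04 % reduction,
regression slope 0.939, r² ≈ 1), not absolute layer thresholds.

Outlier trimming (Tukey 1.5·IQR) is provided for display only; all
statistics use the full data.

## Synthetic MEP study

The generator emulates a 12-participant within-subject crossover with the
conventional device ("magstim") and the PWM device ("ptms"), all
intensities on the conventional device's %MSO scale:

* Magstim-condition RMT ~ truncated normal(41.34, 6.07) on (20, 80) %MSO.
* PWM-condition RMT = Magstim RMT − δ, δ ~ normal(3.34, 1.5) truncated
  strictly positive — every participant's PWM threshold is lower, which is
  the generating structure, not a measurement guarantee.
* IO curve on log₁₀ amplitude: cumulative-Gaussian sigmoid with floor
  0.7 (5 µV), ceiling ~ N(3.45, 0.15) log₁₀ µV, width ~ N(7.0, 0.7) %MSO —
  floor, ceiling and width (hence the midpoint slope) are shared across
  devices within a participant; only the midpoint shifts with the device
  RMT. Trial-to-trial noise: SD 0.25 on log₁₀ amplitude.
* Latency ~ N(22, 1.5) ms, identical across devices within a participant.
* EMG sweep: 5 kHz sampling, 100 ms pre-stimulus plus 100 ms post-stimulus
  Gaussian baseline (SD 5 µV), plus a biphasic MEP wavelet (two opposed
  half-sines, 8 ms total, peak-to-peak = drawn amplitude) at the latency.

**Criterion anchoring.** A staircase "success" is a *measured* peak-to-peak
of ≥ 50 µV, and the max−min measurement over a 30 ms window is inflated by
baseline noise riding on the wavelet (by roughly 12 µV near the criterion).
The IO midpoint is therefore placed by solving — with a fixed bank of
seeded noise draws, by bisection — for the IO level at which the measured
criterion is reached with probability exactly one half at the true RMT.
This makes the 5-of-10 staircase estimator unbiased by design up to the
termination rule's own behaviour; the termination rule ("lowest intensity
with ≥ 5/10 whose next-lower visited intensity had < 5/10") retains a
lean of roughly +0.5 %MSO which is identical for both devices and cancels
in the within-participant difference.

**Protocol.** RMT sessions emit 10-pulse blocks whose intensities follow
the staircase (start: five steps above the rounded true threshold, as an
operator would from a suprathreshold hotspot intensity; 1 %MSO steps; at
most 30 blocks). IO sessions deliver 15 trials per intensity, ascending in
3 %MSO steps from 30 to 57 %MSO — the upper limit being the PWM device's
maximum-equivalent intensity (1600/2800 of the conventional maximum).
Inter-pulse intervals are drawn uniformly from 4.25–6 s.

**What the generator does not model.** Coil-position drift, intensity-order
(hysteresis) effects, EMG amplifier filtering, physiological background EMG
structure (the baseline is white), MEP shape variability beyond amplitude
and onset, and participant exclusions. Passing tests therefore show that
the *pipeline* recovers the generating structure at realistic noise levels,
not that the pipeline is robust to every artifact of real recordings.

## Statistics

For a two-level within-subject factor, the repeated-measures ANOVA F with
df (1, n−1) equals the squared paired t statistic; it is computed through
that identity (and cross-checked against an independent implementation in
the tests). Cohen's d defaults to the pooled form
`(m₁ − m₂)/√((s₁² + s₂²)/2)`; the difference-SD variant is available,
because the two conventions differ on the same data and published values do
not always state which was used. Latency comparisons bin trials at 50, 500
and 1000 µV targets with ×/÷1.5 multiplicative bands (bin widths are a
package choice). No multiple-comparison correction is applied to the three
latency tests, matching common practice for this design. The IO fit is
bounded multi-start least squares; fits are flagged unconverged on
degenerate (all-floored) data and excluded pairwise from the slope
comparison.

## Problem sizes and determinism

The study-level replication uses 20 seeded cohorts of 12 participants
(≈ 240 staircases per device condition), which makes the grand-mean RMT
estimates stable to ≈ ±0.4 %MSO; the spectral and threshold computations
are deterministic. Every stochastic component draws from
`numpy.random.Generator` streams derived from explicit seeds, so any result
in this package is exactly reproducible from its configuration.
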