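# Methods

This note documents the generative model and the analysis choices in
`rodpath`: what is being modeled, how the defaults were fixed, which
quantities are calibrated versus emergent, and what the synthetic data
do and do not capture about real recordings.

## Units and conventions

Light levels are photoisomerization rates, R*/rod/s; flash strengths are
total R*/rod delivered in the flash window. Time is seconds internally
and milliseconds in reported statistics. Currents are pA, voltages mV.
A "fixed-contrast" series scales flash strength with the background so
Weber contrast (ΔI/I) is constant; the canonical probe is a 600%
contrast, 10 ms flash, which delivers (1+6)·I·0.01 R*/rod — 0.07 R*/rod
on a 1 R*/rod/s background. The flash-strength convention counts
background plus increment photons; the increment-only convention
(C·I·Δt) is rejected because it cannot reproduce both quoted strengths
(0.07 and 0.7 R*/rod at backgrounds 1 and 10) simultaneously.

## Steady state

**Saturation.** The fraction of dark current suppressed by a background
I is a Hill function s(I) = Iⁿ/(Iⁿ+Kⁿ). Only two anchor points per
species are available (half-suppression and 90% suppression), so the
Hill form is a modeling choice, not a fit to a published curve. The
exponent is pinned by the primate anchors: (250/40)ⁿ = 9 gives
n = ln9/ln6.25 ≈ 1.199, and is reused for mouse; with K = 160 the mouse
90% point then falls exactly at 1000 R*/rod/s.

**Gain.** Rod flash gain is g(I) = [1/(1+I/I₀)]·[1−s(I)] with Weber
constant I₀ = 3 R*/rod/s, chosen so the gain is approximately ∝ 1/I over
3–100 R*/rod/s (log–log slope ≈ −1.2) and collapses ~120-fold between
100 and 1000 R*/rod/s. Ganglion-cell-level gain adds a divisive
post-rod adaptation term driven by the rod-adapted signal,
1/(1 + I_eff/0.3) with I_eff = I/(1+I/3): it accumulates below
~3 R*/rod/s and then saturates, reproducing the faster decline of
ganglion-cell gain at the lowest backgrounds. This term is qualitative —
its constant (0.3 R*/rod/s) shapes the low-background end of the
fixed-contrast amplitude curves but is not pinned by a printed number.

**Voltage.** The steady rod membrane potential is
V(I) = V_dark − ΔV_max·H(I) with V_dark = −44 mV, ΔV_max = 12 mV and a
first-order Hill H. Its half-max constant has the closed form
(53−√649)/6 ≈ 4.59 R*/rod/s, the lower root of the constraint
V(1)−V(60) = 9 mV; the lower root is the physiological branch
(substantial hyperpolarization already in the low mesopic range).

## Kinetics

Flash kernels are cascades of first-order low-pass stages. A
single-stage filter cannot produce the observed shifts (its 4 Hz delay
is capped at 62.5 ms), so both stages are fourth order:

- **Phototransduction**: four identical stages with time constant
  τ_pt(I) = τ_pt,dark/(1+I/I_k)^p.
- **Current-to-voltage**: four first-order stages at the
  voltage-dependent membrane time constant
  τ(V) = τ_dark + (τ_dark/18)·(V−V_dark), linear on [−56, −42] mV and
  clamped outside, so that the 9 mV step hyperpolarization halves τ.
  The standalone `membrane_filter` operation stays first order (its
  pulse response is a clean exponential, so τ recovery by fitting is
  exact); the four-stage voltage block in the full cascade is a
  phenomenological stand-in for the inner-segment filtering chain.

Stage counts and schedules are not published; they are constrained by
three calibration contracts, and the four free constants
(τ_pt,dark, I_k, p, τ_dark) were solved jointly (nonlinear least
squares on the same pipelines the analyses use) so that:

1. the 4 Hz shift of the phototransduction kernels between 0.2 and
   100 R*/rod/s is 40 ms (the phototransduction share of the speeding),
2. the full-cascade On parasol shift is 100 ms, and
3. the integration time of On parasol flash responses contracts 3-fold
   between 0.3 and 300 R*/rod/s.

The solution (τ_pt,dark = 21.1 ms, I_k = 0.039 R*/rod/s, p = 0.257,
τ_dark = 30.6 ms) gives a dark-adapted rod flash time-to-peak of
~180 ms. Because group delays of cascaded stages add, the
phototransduction and membrane shifts decompose additively — a property
the test suite checks directly.

The cone-circuit (secondary-pathway) kernel is a fixed fourth-order
cascade with τ = 10 ms; its kinetics do not adapt with background
(cone adaptation is out of scope).

## Routing

Fixed-contrast response amplitudes decompose additively into pathway
components:

- **Primary** ∝ I·g(I)·post-rod term (Weber-flat in the mid range,
  collapsing with rod saturation). Mouse adds a divisive
  primary-pathway saturation 1/(1+I/K_p): without it the printed
  LY/APB block fractions are unreachable with a Weber-flat primary.
- **Secondary** follows an empirical Hill of background with half-max
  300 R*/rod/s (primate) / 5 R*/rod/s (mouse), exponent 1.
- **Tertiary** is a secondary-shaped term, weight 0 in primate and half
  the mouse secondary weight (rod contacts on Off cone bipolar
  dendrites exist in mouse; the 1:2 split versus secondary is a choice,
  as the two are not separable from the available block fractions).

Mouse K_p (≈4.9 R*/rod/s) and the secondary+tertiary weight were solved
jointly so that removing On-bipolar-derived drive (LY/APB) spares 10%
of the mouse Off-alpha response at 0.5 R*/rod/s and 65% at 5 R*/rod/s;
the model then leaves responses at 50 R*/rod/s essentially unaffected
(~94% sparing), consistent with the qualitative statement it emulates.

Pharmacology: NBQX zeroes the primary drive at the AII; LY/APB scales
all On-bipolar-derived drive by (1−block_fraction), block_fraction
defaulting to 1.0 (the measured block is >90%, so complete block
slightly overestimates non-primary contributions — the parameter is
exposed to study that caveat). Off-pathway cells weight the rod-derived
side at half the On weight. Pharmacological conditions are only defined
for cells at or downstream of the rod bipolar output; protocols skip
incompatible combinations.

**LED spectral factors.** Each LED class drives the two pathway sides
with different efficacy. The rod-preferring (405 nm class) LED drives
the primate secondary readout weakly (factor 0.1): that readout
originates in cones, which short-wavelength light stimulates poorly at
these backgrounds. In mouse the secondary readout at low backgrounds
carries rod signals through gap junctions, so the same LED drives it at
full strength. The cone-preferring LED drives the cone circuit directly
(no background gating) and the rods not at all. There is a real tension
in the source material here — the AII pharmacology figure implies
larger short-wavelength cone-derived responses than the spectral
control (~25% cone contribution at 300 R*/rod/s) does — and the factor
0.1 is a compromise that keeps the 4 Hz kinetics simulations
rod-dominated at ≤100 R*/rod/s while preserving every half-max and
block-fraction result (those are scale-invariant in this factor). The
15 Hz flicker property (monotonically growing modulation, no abrupt
phase change from 1 to 300 R*/rod/s) is checked with the mid (520 nm
class) LED, which drives both pathways at nominal strength; with the
0.1 factor the emerging cone component is too weak to offset the
primary collapse above ~100 R*/rod/s.

## Noise, variability and seeding

Continuous traces get additive Gaussian noise with SD a fraction
(default 0.1) of the response peak (steady level for steps); spikes are
inhomogeneous Poisson. Inter-cell variability is multiplicative
lognormal (mean 1) with CV 0.15 on amplitudes and the hyperpolarization
range, CV 0.10 on the dark current, plus Gaussian SD 3 mV on the dark
resting potential — magnitudes consistent with the printed
standard errors (e.g. −44 ± 1 mV SEM, n = 10 → cell SD ≈ 3 mV). All
randomness flows from one master seed through per-cell and per-trace
`SeedSequence` spawns, so a protocol plus master seed reproduces a
trace store byte-for-byte (HDF5 written with `track_times=False`).

## Analysis choices

- **Peak amplitude**: baseline is the mean of the final 20% of the
  pre-stimulus epoch; response window is onset → onset+500 ms; both
  configurable (the source is silent on windows).
- **Hill fits**: nonlinear least squares with multi-start
  initialization (K at the half-rise abscissa and the geometric mean of
  x; n ∈ {0.5, 1, 2}); overall-decreasing data are flagged unconverged
  rather than fit. The 90% point is derived from the fit, K·9^(1/n),
  not from the nearest sampled background. Inverse-variance weights are
  used when replicates provide them.
- **Temporal shift**: lag of the cross-correlation maximum with
  parabolic sub-sample interpolation. For periodic stimuli the
  correlation is circular over an integer number of periods (windowing
  would otherwise bias the peak by ~1 ms) and the result is reported in
  (−T/2, T/2]; at 4 Hz with shifts ≤100 ms this is unambiguous. A
  phase-based estimate at the stimulus frequency is the built-in
  cross-check and agrees within 2 ms on synthetic data.
- **Sinusoid prediction**: the flash kernel's discrete frequency
  response H(f) = Σ h(t)e^(−i2πft)·Δt; equivalence with direct
  time-domain convolution is tested to 1e-6 relative amplitude.
  Kernels are baseline-subtracted and must span ≥1 period; frequencies
  at or above Nyquist are rejected.
- **Integration time**: ∫r(t)dt up to the first post-peak zero crossing
  (trace end if none, as for the monophasic model kernels), divided by
  the peak; crossings are linearly interpolated.
- **Membrane τ**: exponential fit to the post-pulse relaxation, with
  the resting level taken from the pre-pulse epoch when available.

## Problem sizes

Default pipelines use 12 backgrounds × 20 cells for suppression
recovery, 10 backgrounds × 5 cells for half-max recovery, 3 s sinusoid
epochs at 1 kHz sampling (8 analysis periods at 4 Hz) for shifts, and
10 cells for the voltage-step statistic; the full test suite and the
summary script each run in seconds.

## What the generator does and does not emulate

It emulates: Weber gain scaling and Hill saturation of photocurrents,
steady hyperpolarization with voltage-dependent membrane filtering,
species- and background-dependent pathway weighting with NBQX / LY-APB
switches, background-dependent cascade kinetics, additive Gaussian
trace noise, Poisson spiking, and inter-cell parameter spread.

It does not emulate: biophysical channel kinetics (the voltage block is
a linear cascade, not an Ih/Kx model), cone light adaptation, bleaching
adaptation beyond few-minute steps, spatial structure (all stimuli are
full field), continuous rod noise (photon-driven or thermal — dark
noise enters only as an optional rate in the SNR model), correlated
noise across cells, or recording artifacts. Passing closed-loop tests
therefore shows that the analyses recover known parameters under the
model's assumptions — not that the model captures every feature of
real recordings.

## Known limitations

- The saturation exponent and several schedule constants are derived
  from two-point anchors; real curves may differ in shape between the
  anchors.
- The AII steady-state membrane potential is held flat for both species
  (the mouse hyperpolarization with background is noted in the source
  but not quantified).
- The integration-time contraction is calibrated at the 0.3/300
  endpoint pair; intermediate backgrounds follow the cascade model
  rather than a fitted curve.
- The SNR model is the simplest Poisson photon-count reading of the
  sqrt-shaped curves it mirrors; pooling size (default 1000 rods/RGC)
  and the exclusion of dark noise are interpretations, both exposed as
  parameters.
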