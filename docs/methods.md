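# Methods

This note documents the models, algorithms and parameter choices behind
`t5rf`: what each stage assumes, which knobs matter, what the synthetic data
do and do not emulate, and where the design was genuinely open.

## Stimulus protocols (`t5rf.stimuli`)

Contrast is signed about mid-gray (gray = 0, dark = −1, bright = +1), so
100% Michelson contrast maps to ±1 and linear versus rectified nonlinearities
act symmetrically about zero. Rendered fields live on the 100 Hz stimulus
update grid; event tables tile the time axis exactly (asserted at build
time), which the preprocessing relies on for baseline estimation.

- **Flashed bars**: 5° bars in 2° steps, 1 s flash / 1 s background,
  positions shuffled per trial from the given seed. Bar centers start at
  `bar_width/2` from the screen edge and the last position keeps the bar
  fully on screen — edge handling is not otherwise constrained, and this
  choice makes the position count `floor((extent − width)/step) + 1`
  (28 on a 60° screen).
- **Ternary noise**: 12 bars tiling the screen, each independently black /
  gray / white with probability ⅓, updated every 100 ms, after a 3 s gray
  lead.
- **Sine gratings**: the 6 × 6 grid of spatial wavelengths
  {2, 3.5, 6, 10, 18, 32}° and temporal frequencies
  {0.25, 0.5, 1.25, 3, 8, 16} Hz, 4 s on / 4 s gray, pseudo-random order per
  trial. Initial phase is fixed at 0 (not otherwise constrained; exposed as
  a config). Direction convention: 0° = back-to-front, counter-clockwise
  positive.
- **Full-field flashes**: 2 s ON and OFF epochs separated by 4 s gray.

Projector details (6-bit depth, 300 Hz refresh) are not modelled; the
100 Hz update grid is the stimulus timebase.

## Synthetic recordings (`t5rf.synth`)

Each ROI carries a ground-truth receptive field: a difference of Gaussians
per bar orientation (optionally a second, wider ON component of opposite
sign), an output map (`linear`, `off_rectified`, or the two-kernel `on_off`
combination), a single-exponential calcium-indicator filter, and a baseline
fluorescence. Fluorescence is

    F(t) = F_base · (1 + r(t) + ε(t)) + drift(t),

with r(t) the indicator-filtered kernel response, ε white noise, and drift a
slow sinusoid plus a bounded random walk (so the 150-frame high-pass stage
has something to remove).

Three deliberate conventions:

- **Background adaptation.** Responses are computed from the contrast
  deviation relative to the protocol's standing background frame.
  Photoreceptors and medulla neurons adapt to standing luminance within
  seconds; without this, a linear kernel under a full-field ±1 background
  would hold the baseline far from F_base (for plausible amplitudes, below
  zero fluorescence). Adaptation also pins the background-epoch baseline at
  F_base, which is what makes closed-form recovery oracles possible.
- **Amplitude units.** A_c is the ΔF/F response to the canonical 5° bar
  flashed at the receptive-field center against the opposite-polarity
  background — the unit in which empirical bar tuning curves are reported.
- **Recoverable width.** A 5° probe cannot reveal sub-bar structure: the
  ground truth a bar tuning curve can recover is the *bar-convolved*
  receptive-field profile (closed form via the error function,
  `expected_bar_tuning`). Width-recovery tests compare against that profile;
  center recovery is tested against the raw x₀.

The closed-form oracle also models one second-order effect of the protocol:
with a 1 s inter-stimulus interval, a τ = 0.4 s indicator does not return to
baseline between flashes, inflating the background-epoch F₀ by a predictable
few percent (the decay-tail average over the interval times the mean tuning
amplitude). Real recordings carry the same bias. Residue stacking across
consecutive flashes is ignored (second order); the pipeline-versus-oracle
test tolerances (2–3%) absorb it.

Defaults (chosen once as plausible for Tm-neuron imaging): indicator
τ = 0.4 s; baseline 100 a.u.; OFF center width w_c = 4.5° (so the bar tuning
curve comes out near 7° FWHM), surround 3 × wider at 0.15 × amplitude; ON
component 2.5 × wider with amplitude −0.4 × A_c; centers normal around the
screen center with 5° between-fly and 2° within-fly scatter; widths and
amplitudes log-normal with fly-level random effects (0.15–0.2 log-SD between
flies) so that nested statistics have genuine within-fly correlation to work
with. Not emulated: photon/shot noise statistics, motion artifacts, neuropil
contamination, indicator nonlinearity. Passing recovery tests therefore
demonstrates correctness of the analysis code under its own forward model,
not robustness to those artifacts.

## Preprocessing (`t5rf.preprocess`)

- **High-pass**: subtraction of a 150-frame centered moving average, with
  the grand mean added back so the absolute scale survives for ΔF/F. The
  window (≈15 s at 10 Hz) is configurable.
- **ΔF/F**: F₀ is the mean fluorescence over all background epochs
  (including inter-stimulus intervals). When F₀ < 0.1 · F̄ (near-zero
  baseline), the denominator is augmented to F₀ + F̄; the mode is recorded.
  For ON-bar protocols the background is dark, for OFF-bar protocols bright.
- **Epoching**: linear interpolation of each stimulus epoch onto a common
  10 Hz grid relative to onset (interpolation method not otherwise
  constrained; linear chosen), trials grouped by condition label and
  un-shuffled into sorted condition order. Epochs running past the end of a
  trace drop that trial with a warning.
- **Quality index**: computed on the full (condition × time) response course
  per trial, so it is independent of stimulus structure. Exactly 1 for
  identical trials; undefined (raised) for all-constant trials.

## Receptive-field analysis (`t5rf.rf`)

Tuning-curve amplitudes keep the sign of the extremum, so one free-sign
Gaussian fits both OFF (positive) and ON (negative) curves; reported FWHMs
are sign-independent. Fits are nonlinear least squares (lmfit) initialized
from the data (extremum, empirical half-width), with r² acceptance cutoffs
defaulting to 0.2 and configurable per analysis (0.5 / 0.8 / 0.25 are the
stricter values used in specific comparisons). The difference-of-Gaussians
fit enforces A_c > A_s ≥ 0 by fitting A_s = ρ·A_c with ρ ∈ [0, 1), caps
amplitudes at twice the data range, and re-initializes once with a wider
surround before rejecting. Curves whose extremum is negative are fitted on
the flipped sign with the flip recorded (`sign = −1`), so amplitude
magnitudes and widths remain comparable across polarities.

Reverse correlation runs on the 10 Hz response grid with each 100 ms noise
frame held constant; the default lag window is 2 s. The estimated kernel is
unit-norm; slices pass through the |k| peak and the spatial slice is fitted
with the single Gaussian. Frequency-tuning maps use an amplitude-normalized
Fourier projection (2/N; a unit sinusoid yields 1) at the grating's temporal
frequency after mean removal, so maps are invariant to response offsets;
conditions with less than one cycle in the window or at/above the Nyquist
frequency of the response grid are flagged NaN rather than reported.
Cross-correlation alignment uses an iterative running template (first curve
seeds it; each aligned curve is folded in as a mean) with integer,
zero-padded shifts; a pairwise-template strategy would be equally defensible.

## Resampling statistics (`t5rf.stats`)

The nested permutation test permutes fly-to-group assignments (preserving
group fly counts) with all of a fly's neurons travelling together; the
non-nested variant permutes neurons and is appropriate when flies contribute
too few neurons to carry within-fly structure. Two-tailed p-values use the
add-one convention (1 + exceedances)/(1 + n) so p is never zero; the raw
count convention is reported alongside (a zero-exceedance shuffled-pairing
test reports "< 1/n_shuffles"). Note the nested test's resolution is limited
by the number of distinct fly assignments (C(n_flies, n_A)); with 6 flies
per comparison the smallest attainable p is about 0.1. The shuffled-pairing
test precomputes the pairwise correlation matrix and evaluates permutations
by indexing, so 10⁴–10⁶ shuffles are cheap; its default here is 10⁴ (10⁶
remains a parameter). Bootstrap confidence intervals are percentile
intervals over case resampling with degenerate resamples redrawn.

## The T5 dendrite model (`t5rf.model`)

**LN front ends.** Spatial difference of Gaussians (center FWHM 5°, weak
surround: 3 × wider, 0.1 × amplitude) sampled on a pruned local grid and
normalized to unit absolute mass; temporal filters as printed,
f_LP(t) = 2τ^(−3/2) t e^(−t/τ) and f_HP(t) = 2τ^(−3/2)(τ − t) e^(−t/τ),
L1-normalized so filtered signals stay within the contrast range; an alpha
synapse (1 ms rise, 10 ms decay, unit area); a sign flip to the OFF-positive
convention; then `linear` or `off_rectified` output, a gain of 0.5 and an
offset of 0.5 mapping the result into [0, 1] without clipping (clipping
would log a warning). For drifting gratings the spatial integral collapses
analytically to a single complex weight — an exact shortcut the front end
takes automatically.

**Cable.** Uniform compartments (101 by default), sealed ends, leak to
−65 mV, axial coupling from the printed geometry, point conductances at the
tip (0.95), center (0.5) and base (0.05) fractions, readout at the base end
(fraction 0). Backward-Euler stepping at dt = 0.1 ms via tridiagonal LAPACK
solves — unconditionally stable in this strongly shunted regime (the
effective membrane time constant under synaptic load is microseconds, so
the voltage tracks the conductances almost quasi-statically; halving dt and
doubling compartments moves the F1 amplitude by far less than 1%). The
solver is verified against the closed-form sealed-end finite-cable steady
state (Green's function with the self-consistent synapse voltage).

**Synaptic weighting and I/E.** Weights follow synaptic-count proportions
(Tm9 0.35 tip; Tm1 0.25, Tm2 0.2, Tm4 0.2 center; CT1 1.0 base) times the
fixed amplitudes (2.49×10⁻⁵ μS excitatory, 4.98×10⁻⁴ μS inhibitory). How
those amplitudes combine with the free I/E = 55 is ambiguous (the raw
amplitude ratio is 20), so both interpretations are implemented: the default
`multiplier` mode rescales the total CT1 conductance so that its peak equals
I/E × the peak total excitatory conductance of the same simulation; `raw`
mode uses the printed amplitudes unchanged.

**Readouts.** Voltage deflection Δv is measured against the zero-contrast
resting state (all LN outputs at their offsets, same inhibition multiplier).
Calcium is ([Δv]₊)². Response amplitude per direction: F1 (Fourier amplitude
at the stimulus frequency), V_max, or Ca_mean, over the window after a 1 s
transient discard; DSI is the normalized vector sum over 16 directions
(λ = 24°/cycle, 1 Hz, 6 s).

**Input kinetics — a calibrated choice.** The input neurons' filter time
constants are not printed anywhere usable; defaults are τ = 0.06 s
(high-pass, Tm1/2/4), τ = 0.2 s (low-pass Tm9) and τ = 0.8 s (low-pass CT1).
The CT1 value is the one that matters qualitatively: at 1 Hz and 24°
wavelength, the leading column leads the center by 75° of phase, and a
low-pass filter with τ = 0.2 s adds ≈103° of lag, which would drop CT1's
OFF-driven inhibition squarely into the ON half-cycle at the receptive-field
center — making even the all-rectified model's response sinusoidal. A slower
CT1 (it is the most sustained element of this circuit) moves its inhibition
into the OFF half-cycle, coincident with excitation: the null-suppression
arrangement in which an all-rectified model depolarizes only. All these
parameters are plain fields on `CellTypeSpec` and none of the package's
quantitative claims depend on their exact values.

**Contrast opponency measure.** With a periodic stimulus, "hyperpolarization
to ON" is operationalized as the phase-averaged voltage deflection over the
bright half-cycle at the central column (`on_phase_mean_deflection`),
evaluated in the preferred direction. This is robust to the small
(≲0.02 mV) sub-resting ripple that any modulated conductance inhibition
produces even in the all-rectified variant, which makes the raw minimum of
Δv an unreliable discriminator.

**Known limitations.** The ordering of DSI across variants depends on the
unconstrained filter parameters (here the Tm9-linear variant scores highest;
with other kinetics the all-rectified variant can). Absolute response sizes
(≈0.1–0.4 mV at the base) are likewise placeholder-parameter-dependent;
only signs, identities and qualitative contrasts between variants are
treated as results. T4 (the ON pathway), active conductances, and fitting
the model to recorded data are out of scope.

## Problem sizes

Defaults keep a full run on one CPU comfortable: synthetic experiments use
4 flies × 4 ROIs with 4-trial bar protocols and 5 minutes of noise; STRF
recovery uses a 10-minute noise recording; the permutation-test calibration
uses 1000 simulated datasets × 1000 permutations (12 flies × 3 neurons,
so the fly-level permutation distribution is fine enough for the nominal
5% level); direction sweeps use 16 directions × 6 s at dt = 0.1 ms. The
whole test suite runs in about a minute; `scripts/acceptance.py` in about
one minute.
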