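# Methods

This note documents the models, numerical choices and limitations behind
`circasleep`, in the order the pipeline runs.

## Time base and schedules

All times are measured from the first lights-off (`t = 0`); each zeitgeber
cycle begins with the scotophase.  A `LightSchedule` tiles `n_days`
astronomic (24-h) days with cycles of `period_h` hours and lit fraction
`photofraction`; under constant darkness (DD) every instant is scotophase and
24-h pseudo-cycles are used wherever a cycle index is needed.  Phase-of-day
lookups are instantaneous; an epoch's label is taken at its first sample,
which makes epochs straddling a light transition unambiguous.

## Synthetic data generator

The generator is the ground truth against which the analysis chain is
validated.  Its components:

**Hypnogram.** A first-order Markov chain over {W, N, R} on 4-s epochs with
separate transition matrices for photophase and scotophase.  W→R is
structurally forbidden (REM is entered only from NREM).  The default matrices
give long-run fractions of roughly 35/50/15% (W/N/R) in the light and
72/24/4% in the dark — a nocturnal pattern with REM rates at the
rodent-typical few percent of total time.  These are configuration choices,
not measurements.

**EEG.** A sum of state-dependent narrowband oscillations plus Gaussian
broadband noise (default SD 0.3 of the unit-scale oscillation amplitudes):

- carriers are frequency-modulated: instantaneous frequency = center +
  piecewise-constant Gaussian jitter held for 1 s (θ: 8 ± 0.25 Hz SD, clipped
  at ±0.5; SWA: 2.5 Hz; γ: 37.5 ± 1 Hz SD, clipped at ±2).  Pure sines would
  make cut-and-swap surrogates degenerate (every rotation of a sinusoid's
  envelope is phase-locked again), so jitter is required for the PAC null to
  behave;
- γ amplitude in wake is `base·(1 + κ·cos φ_θ)` with the *generated* θ phase,
  κ ∈ [0, 1] (default 0.6).  κ = 0 produces statistically uncoupled θ phase
  and γ amplitude;
- θ and γ base amplitudes carry a sinusoidal modulation at the zeitgeber
  period (default relative depth 0.4, acrophase mid-scotophase), the rhythm
  the cosinor analysis estimates.  Published effect sizes for PACz magnitudes
  are not available to calibrate κ; the defaults are free parameters of the
  artifact, not claims about animals;
- the NREM SWA *power* envelope is
  `(SWA₀·e^(−t_s/τ) + SWA∞) · g(t_e)` where `t_s` is accumulated NREM time
  (the clock advances only during NREM epochs, the two-process convention)
  and `g` is a logistic onset rise in log₁₀ time, scaled to plateau at 1,
  with defaults (t₅₀ = 10 s, Slope = 2) that reach ~96% of the range by 50 s.
  With noise off the imposed envelope satisfies both equations to machine
  precision (property-tested against a per-sample oracle).

**EMG.** 20–90 Hz band-limited noise with state RMS ratio W:N:R = 5:1:0.5 —
only the ordering matters for scoring.

**Activity.** A rectified cosine at the entrained period (peak
mid-scotophase by default) plus Gaussian noise, in 1-min bins.

Every generator takes one explicit seed driving a single local RNG stream;
identical inputs are bit-identical outputs.

## Preprocessing and epochs

Zero-phase (forward–backward) filtering: 4th-order Butterworth high-pass at
0.5 Hz and 2nd-order 49–51 Hz band-stop, designed for 200 Hz (any other rate
is a configuration error).  Zero-phase filtering was chosen because
instantaneous phase feeds the coupling analysis.  The acquisition chain's
0.3-Hz analog high-pass is dominated by the 0.5-Hz software high-pass and is
not modeled separately.  Epochs are 0-based half-open 800-sample ranges;
trailing partial epochs are dropped.

## Scoring

The original recordings were staged with an external semi-automatic scorer
plus manual verification; that algorithm is not public, so this package
substitutes a transparent three-rule classifier over the same state
definitions: WAKE if EMG RMS ≥ threshold (auto-calibrated as the midpoint of
a deterministic two-means split of log EMG RMS); else NREM if
SWA/total ≥ 0.45; else REM if θ/SWA ≥ 1.5; else NREM.  A post-hoc pass
relabels REM to WAKE unless the preceding non-brief state is NREM (brief
wake intrusions ≤ 4 epochs are looked through).  Thresholds are
configuration, robust to amplitude scale, and recover the generating
hypnogram at ≥ 90% (typically ≈ 100%) under default generator settings —
which says the chain is self-consistent, not that real mouse EEG would score
this well.

Brief awakenings (W runs ≤ 16 s flanked by NREM) are counted as a
fragmentation rate — primarily per hour of NREM, with the per-percent-NREM
variant also emitted since both normalizations appear in the literature —
and are excluded from the wake episode list while still splitting NREM
episodes.

## Spectra and filter bank

A 4-s epoch at 200 Hz is 800 samples while the stated FFT size is 512; the
two are reconciled Welch-style: 512-sample Hann windows at 50% overlap
within the epoch, averaged (two full windows per epoch), 0–50 Hz at
200/512 ≈ 0.39 Hz resolution.  Whether the original analysis truncated or
averaged is unknowable from the description; averaging preserves both stated
parameters.  Per-state spectra are normalized by the median summed 0–50 Hz
power over all epochs of the same zeitgeber cycle (cycle, not astronomic
day — all other analyses are cycle-aligned) and averaged over the last two
cycles.

The analytic decomposition uses Hamming-windowed FIR band-passes of 1501
taps (an odd length so the linear-phase group delay is an integer; nominal
length 1500); the first and last 750 samples are edge-invalid and excluded
from every downstream statistic.  Numerically, filtering and the Hilbert
transform are fused: a windowed-sinc band-pass factors exactly as a lowpass
prototype times a cosine at the band center, so convolving with the complex
quadrature kernel (prototype times the complex exponential) yields the
band's analytic signal directly.  The kernel is time-limited, so overlap-add
with small FFT blocks computes it exactly (cache-friendly on multi-hour
recordings, where one monolithic FFT is memory-bound); it matches the
explicit filter-then-Hilbert construction to the window's stopband level
(~0.1% relative).  Band edges where the field needs names: SWA/δ 1–4 Hz
(1–3 Hz for the homeostasis fits), θ 7–9.5 Hz, α 9.5–15, β 15–30, γ 30–45 —
configurable, documented here as configuration.

Band-power series are means over in-state, edge-valid samples per bin
(10 min, or 2 s for the buildup analysis); bins under 50% qualifying samples
are missing, never filled.  Normalizations: subject-wise by the median power
in the band under the baseline (LD12/12) stage, or by the median over
photophase samples (SWA), or none.

For state-masked rhythm series the pipeline additionally erodes the state
mask by the filter half-length (3.75 s) at every state transition.  Filter
smearing imports power from the neighboring state into boundary samples,
and because the hypnogram itself is rhythmic, the fraction of boundary
samples varies with circadian phase — enough to fake a weak wake-θ rhythm
when none is generated.  Erosion removes this at the cost of a few percent
of samples; the onset-locked buildup analysis is exempt (its signal *is*
the transition).

## Phase–amplitude coupling

`MI = |Σ a_t e^{iφ_t}|/n` per 1-min bin; PACz z-scores MI against surrogates
that cut the power series at a random point and swap the halves, preserving
autocorrelation.  All cut offsets are obtained at once from the circular
cross-correlation of the power series with `e^{iφ}` (an FFT identity, exact
to rounding; property-tested against brute force), and 200 random offsets
are drawn (the surrogate count is a calibration choice — the sources do not
state one — and is reported in output metadata).  Degenerate surrogate
distributions (constant power) yield NaN with a warning.

**Amplitude bandwidth.** A filter of bandwidth B cannot carry envelope
fluctuations faster than ~B, so a uniform 1-Hz amplitude band is physically
unable to represent an 8-Hz θ-locked γ envelope (the AM sidebands at
f ± 8 Hz fall outside the band; verified numerically: PACz ≈ 0 at κ = 0.8
with a 1-Hz amplitude band, ≈ 6 with a widened one).  The comodulogram
therefore follows the standard recommendation: the amplitude series for the
cell (f_phase, f_amp) uses half-width `f_phase + 1` Hz, assembled as the
coherent (complex) sum of the 1-Hz bank's analytic signals — numerically
equivalent to a single wide FIR.  Phase bands stay 1 Hz wide.  Cells whose
widened amplitude band would touch the phase band are meaningless and left
missing.  Phase axis 2–20 Hz, amplitude axis 2–50 Hz by default.

Condition comparison: cell-wise paired t, |t| thresholded at two-sided
p = 0.01, 4-connected clusters formed separately for positive and negative
signs, cluster mass = sum of t, referred to the permutation null of the
maximum absolute mass under subject-wise sign flips (default 500
permutations); clusters with p < 0.05 are significant.  The same engine with
1-D adjacency serves the spectra comparison.  Under the null the
cluster-level false-positive rate is ≈ 5% (calibration-tested).

## Rhythm statistics

**χ² periodogram.** For each candidate period of P whole bins (default
16–32 h in 1-bin steps, bracketing all schedules of interest), data truncated
to K complete cycles are folded into P columns and
`Qp = K·Σ_h(M_h − M)² / s²` (s² the population variance of the folded data)
is referred to χ²(P−1) at p = 0.01.  Qp is affine-invariant and 0 for a
constant series.  White-noise calibration reproduces the nominal rate.

**Cosinor.** ω is fixed by the schedule (the linearized model requires a
known frequency; whether the original fits ever floated it is not stated).
Least squares on `[1, cos ωt, sin ωt]` with missing bins dropped
(unbalanced, not imputed); A = √(β²+γ²), θ = atan2(−γ, β); zero-amplitude
F(2, n−3) test.  Acrophase is reported as the lag of the cosine peak after
lights-off, degrees in [0, 360); circular distance is used in comparisons.
The group cosinor averages per-subject (β, γ), uses their between-subject
covariance for a bivariate confidence region and a Hotelling-type
F(2, k−2) zero-amplitude test, and compares conditions with the two-sample
Hotelling test (Bonferroni over condition pairs).

## Process-S fits

Decay: nonlinear least squares of `SWA₀·e^(−t/τ) + SWA∞` on
photophase-median-normalized 1–3 Hz NREM power in 10-min bins against
accumulated NREM time from the first NREM incidence.  Deterministic starts
(SWA₀ = first − last, SWA∞ = last, τ = span/3), bounds keep all parameters
non-negative; flat series converge to the SWA₀ ≈ 0 boundary and are flagged
unidentifiable rather than silently reported.

Buildup: 4-parameter logistic in log₁₀ t on 2-s bins 0–60 s after
wake→NREM transitions.  The printed form of this model in the source
literature lacks the time variable in the exponent (`10^((log t₅₀ − 1)·Slope)`),
which is presumed a typo for the standard `10^((log t₅₀ − log₁₀ t)·Slope)`;
the implemented form is recorded here as an interpretation.  Qualifying
transitions require ≥ 60 s of uninterrupted wake before and ≥ 60 s of
uninterrupted NREM after onset, so the fitted window is transition-free;
fewer than 5 transitions is an error.

Condition comparison: extra-sum-of-squares F between a null fit sharing a
parameter subset (default: all, i.e. one common curve) and separate fits;
`F = [(SS_null − SS_alt)/k]/[SS_alt/df_alt]` with k freed parameters.
Pooling bins across subjects within a condition is the implemented
convention; degrees of freedom are emitted for transparency.

## Pipeline and problem sizes

The pipeline simulates the staged protocol per subject with seeds derived
from one run seed via `SeedSequence`, writes per-stage CSV/JSON outputs and a
hash manifest, and restricts per-condition analyses to the last two
zeitgeber cycles.  Default sizes are desk-scale choices: a few subjects
(four in the dissociation experiment — with three, the group-cosinor
Hotelling test has denominator df = 1 and its p-values are erratic), two
cycles of EEG per stage, 14 days of activity, a reduced PAC grid — the
generators support the full weeks-long protocol and full 2–100 Hz bank by
configuration.  The end-to-end dissociation experiment (circadian θ/γ
modulation switched off for the final shortened stage while activity stays
entrained, SWA₀ elevated) reproduces, as an artifact behavior on matched
synthetic inputs: loss of the wake-θ cosinor rhythm, a preserved activity
periodogram peak at the entrained period, and a decay F-test flagging the
amplitude difference.

## What the synthetic validation does and does not show

The generator emulates state-dependent narrowband spectra, tunable coupling,
circadian amplitude modulation, two-process SWA dynamics and entrained
activity — but not 1/f background, movement or electrode artifacts,
inter-individual spectral variability, state-transition microstructure, or
volume-conduction effects.  Passing tests therefore demonstrate that the
implementations are mutually consistent and statistically calibrated (exact
nulls, nominal error rates, unbiased recovery), not that the thresholds or
effect sizes transfer to real recordings.  The near-perfect scoring
agreement in particular reflects the generator's clean state signatures.

## Known limitations

- No artifact rejection beyond filtering; no manual-editing workflow.
- No alternative PAC metrics (Tort MI, GLM-PAC), no cross-channel PAC.
- No multitaper/wavelet spectra, no 1/f correction, no Lomb–Scargle.
- Free-running period estimation is limited to the periodogram grid.
- The EDF writer targets the classic continuous layout (16-bit, 1-s
  records); annotations and discontinuous files are out of scope.
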