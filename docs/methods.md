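# Methods

This note documents the models, parameter choices and numerical
conventions behind `strokeeg`, and what the synthetic-data studies do
and do not establish.

## Analysis pipeline

### Band decomposition

Bands are δ (1–4), θ (4–8), α (8–13) and β (13–20 Hz); they tile the
1–20 Hz reference range, so relative powers computed against that range
partition unity.  Filtering is a 4th-order Butterworth band-pass applied
forward–backward (`sosfiltfilt`), i.e. zero-phase with doubled roll-off
(≥ 20 dB one octave outside the band).  Zero-phase filtering matters
because the complexity metrics operate on the filtered waveform: phase
distortion would alter median crossings and template geometry.  The
first and last second of every filtered signal are discarded before
epoching to drop edge transients.

### Spectral estimation and relative power

PSDs are Welch averaged modified periodograms: 2 s Hann windows, 50%
overlap, per-window mean removal.  This satisfies Parseval's relation to
within a few percent on stationary noise and halves the variance of a
plain periodogram at the 4 s epochs used here.  Band power is the
trapezoid integral of the PSD between the band edges; edges that fall
between grid frequencies are linearly interpolated, which keeps the
integral exactly additive across bands sharing an edge — this is what
makes the four RPs sum to 1 to within 1e-9 rather than approximately.
The RP denominator is the 1–20 Hz total (the union of the analysis
bands); it is configurable.

### Epoching

Metrics are computed on non-overlapping 4 s epochs and averaged per
subject (and per channel, with channel means taken afterwards).  Slow
bands get longer epochs so that each epoch holds at least 8 cycles of
the band's lower edge: at the defaults this doubles only the δ epoch to
8 s.  The same epoch grid serves RP, LZC and SampEn so the metrics are
comparable across a record.

### Lempel-Ziv complexity

Epochs are binarized at the epoch median (the prevailing convention in
EEG complexity work; robust to amplitude drift), then parsed with the
Kaspar–Schuster scan of the LZ76 exhaustive production history.  The
scan is verified in the test suite against an independent brute-force
substring parser, exhaustively for all binary strings up to length 12.
Normalization is c(n)·log_α(n)/n with α the alphabet size, the
random-sequence asymptote, so values are ≈ 1 for i.i.d. sequences and
fall toward 0 for periodic ones.  A constant epoch symbolizes to an
all-zero string; this is legal (complexity 2/n·log n) and detectable via
`is_degenerate`.  A quantile rule generalizes symbolization to larger
alphabets.

### Sample entropy

Defaults m = 2, r = 0.2 × epoch SD, Chebyshev distance, self-matches
excluded — the standard parameterization for physiological series.  B
counts ordered-once template pairs of length m within r, A the same at
m + 1, SampEn = −ln(A/B).  The kernel enumerates candidate pairs through
a sliding window over the first template coordinate in sorted order
(numba-compiled), which is exactly equivalent to the O(N²) double loop —
the suite asserts equality to 1e-12 against an independent pure-Python
double-loop oracle — but several times faster on oversampled narrowband
signals.  When no pair matches at either length the value is undefined
and returned as NaN; table builders exclude such epochs from the
per-subject average and tally them in the run report rather than
imputing, so a handful of degenerate epochs cannot drag a mean to
infinity.  A constant epoch yields exactly 0 (every pair matches at both
lengths).  For i.i.d. Gaussian data the expected value is
−ln(2Φ(r/√2)−1) ≈ 2.19 at r = 0.2 SD, which the acceptance study
reproduces to ±0.1.

### Group statistics

Classical fixed-effects one-way ANOVA from the direct sum-of-squares
decomposition; η² = SS_between/SS_total (equal to the R² of a
group-indicator regression, asserted numerically).  Summaries are
mean ± SEM; stars \*/\*\*/\*\*\* at p < 0.05/0.01/0.001 on unadjusted
p-values.  No multiple-testing correction is applied across bands or
metrics by default, matching the fixed analysis path of the experimental
design this package mirrors; a Holm flag exists for users who want it.
Shapiro–Wilk and Levene checks are computed and reported but never
change the analysis path (and never block it: groups too small for the
checks simply omit them).  Welch's ANOVA is available behind a flag for
heteroscedastic data.

## Synthetic cohort

### Signal model

Each subject is

    x(t) = sqrt(1−q)·osc(t) + sqrt(q)·pink(t) + noise_sd·w(t)

with `osc` a unit-variance weighted sum of per-band carriers, `pink`
unit-variance 1/f noise (spectrally shaped white noise, flat below
1 Hz, zero DC), q the broadband variance fraction and w white noise.
Each carrier mixes band-limited Gaussian noise with a phase-random
sinusoid drawn from the middle third of the band:

    carrier_b = sqrt(1−ρ)·bandnoise_b + sqrt(ρ)·tone_b

Band weights and q control where spectral power sits (hence RP); the
rhythmicity ρ controls how stereotyped each band's oscillation is
(hence LZC and SampEn).  These two handles are deliberately separate: a
band-filtered segment of any Gaussian process with a flat in-band
spectrum has essentially the same complexity regardless of its share of
total variance, so band weights alone cannot move LZC or SampEn.  What
does move them is in-band spectral concentration — a tonal, rhythmic
carrier is predictable; band-limited noise is not.  Pathological
post-stroke over-synchronization is therefore modeled as high ρ.

Components are each normalized to exact unit sample variance before
mixing, so the realized broadband fraction tracks q to within the
sampling covariance of independent components (±0.05 at the default
60 s).

### Default group profiles (frozen)

| group      | δ : θ : α : β weights | q (broadband) | ρ (rhythmicity) | noise_sd |
|------------|----------------------|---------------|------------------|----------|
| Control    | 1 : 1 : 1.2 : 0.8    | 0.50          | 0.10             | 0.05     |
| MCAO       | 2.5 : 0.6 : 0.5 : 0.5| 0.015         | 0.99             | 0.05     |
| MCAO_tDCS  | 1.75 : 0.8 : 0.85 : 0.65 | 0.26      | 0.54             | 0.05     |
| MCAO_Sham  | = MCAO               | = MCAO        | = MCAO           | = MCAO   |

Control spreads power across bands with half-broadband, weakly rhythmic
activity; the lesion profile concentrates power in δ and is almost
purely rhythmic (its near-zero broadband share is what drives in-band
tonal purity above ~0.93 in every band, which the SampEn contrast
requires); tDCS sits midway on every parameter; Sham equals MCAO.  The
constants were chosen in a single calibration pass — tone-fraction
sweeps per band followed by multi-seed direction checks — solely so that
every group-contrast direction holds reliably, and then frozen.  They
are stylized: the simulator reproduces directions and gives the pipeline
realistic amplitudes and spectra, not biophysically fitted rat EEG.

Scale defaults are desk-sized: 10 subjects per group, 60 s
single-channel records at 250 Hz (≥ 10 analysis epochs per band), chosen
as this package's own test scale rather than the half-hour recordings a
laboratory study would collect.  Sampling rates and montages are
declared defaults, not inferred from any dataset.  Per-subject seeds
derive deterministically from the master seed as
`SeedSequence(entropy=master_seed, spawn_key=(group_index, subject_index))`,
so cohorts are reproducible across platforms and subjects are
statistically independent.

### What the calibration study shows — and does not

`strokeeg.calibration.direction_study` re-runs the full pipeline over
many master seeds and tallies, per individual check, how often it holds:
δ-RP elevated in MCAO and reduced by tDCS; θ/α/β RP, LZC and SampEn
depressed in MCAO with tDCS recovery; δ-RP omnibus ANOVA significant at
0.05; and Sham within one pooled within-group SD of MCAO per
metric × band.  Each check is evaluated marginally across seeds (the
Sham checks are equivalence tests between identically distributed
groups, so their expected pass rate is ≈ 96% per cell and a joint
all-cells-per-seed criterion would fail by construction; the marginal
thresholds are ≥ 95% for orderings and significance, ≥ 90% for the Sham
cells).  Passing this study demonstrates that the pipeline recovers
known directions from signals with realistic spectra, epoch counts and
between-subject variability.  It does not demonstrate performance on
real EEG: the simulator has no artifacts (blinks, EMG, electrode drift),
no nonstationarity beyond epoch sampling noise, Gaussian carriers, and
group effects far stronger than biological ones (η² near 1 rather than
the 0.35–0.8 typical of real studies).

## Numerical and formatting conventions

- RP ratios are clipped to [0, 1] against floating-point jitter; zero
  total power raises an explicit undefined-RP error rather than
  returning NaN.
- The ANOVA raises a zero-variance error when all values are identical;
  identical group means with within-group spread legitimately return
  F = 0, η² = 0.
- EDF support: reading through mne (any standard 16-bit EDF; channel
  selection by label; values interpreted in µV).  Writing uses a
  minimal built-in writer — one-second records, integer sampling rates,
  full-range 16-bit quantization per channel — sufficient for export
  and round-trip testing; round-trip error is bounded by the
  quantization step.
- CSV cohorts store one column per channel with a header row of labels
  and a tab-separated manifest (`subject_id, group, fs, file`).

## Known limitations

- Band-wise complexity is defined here as metric-on-band-filtered
  signal; computing complexity on broadband signals and reporting it per
  band-figure is an alternative convention some studies use, and values
  are not comparable between the two.
- SampEn on heavily oversampled narrow bands (δ at 250 Hz) compresses
  toward small values and its group contrasts shrink accordingly; the δ
  epochs are lengthened to 8 s to compensate only partly.
- The simulator's sham group is statistically identical to the lesion
  group; it cannot model placebo or procedural effects.
- Post-hoc pairwise tests, repeated-measures designs, time-frequency
  analysis and artifact handling are out of scope.
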