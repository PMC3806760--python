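# Methods

This note documents the generative model, the analysis procedures, the
numerical choices behind them, and what the synthetic benchmarks do and do
not establish.

## Synthetic observers

Each observer is a parameter bundle (`ObserverParams`) with three coupled
components.

**Flicker detection.** The probability of reporting flicker is a decreasing
lapse-adjusted logistic in frequency, P(flicker | f) = λ/2 + (1−λ)·σ(−β(f−α)),
with location α (Hz), slope β (1/Hz) and lapse λ ∈ [0, 0.1]. Cohort α values
are drawn N(49.4, 10.3²) Hz, matching the reported group distribution of
fusion thresholds; β is log-normal around 0.3 /Hz (a transition spanning
roughly 15–20 Hz, consistent with published single-participant curves); λ is
uniform on [0, 0.1].

**Duration dilation.** Internal duration is d·(1 + κ·s(f)) where s(f) is
the *saliency* of the flicker — the lapse-free logistic core, so s → 1 for
clearly-perceived flicker and s → 0 above the fusion range. The default
gain κ = 0.33 reproduces the reported ~30% dilation of a 2 s stimulus at
the slowest frequency. 2AFC comparisons add zero-mean Gaussian noise
(SD 0.3 s by default, a ~15% Weber fraction typical of peri-second duration
discrimination). The saliency account as usually stated peaks at 8–15 Hz;
because the observed dilation profile is monotone-decreasing from ~4 Hz,
the default saliency is monotone, with an optional low-frequency roll-off
parameter (`saliency_rolloff_hz`, off by default) that makes the inverted-U
shape testable.

**Evoked response.** EEG epochs carry A(f)·g_c·sin(2πft + φ + φ_c) per
channel: A(f) is flat at `ssvep_amp_uv` (default 1 µV) up to a 12 Hz peak
and decays exponentially (scale 50 Hz) above it — the published SSVEP
amplitude profile — and is identically zero above the observer's true
neural cutoff, which is drawn N(87.0, 49.6²) Hz and snapped to the tested
frequency grid. The phase φ is stimulus-locked (constant across trials), so
trial averaging preserves the response; channel gains and phase offsets are
fixed per observer (a crude scalp topography). Noise is per-channel
1/f-amplitude-shaped Gaussian noise (default SD 3 µV) plus white noise
(default SD 1 µV). This emulates the spectral structure the detection
procedure assumes; it contains no eye blinks, muscle artifacts, line noise
or head-model spatial structure, so passing detection benchmarks here says
nothing about artifact robustness on real recordings.

All generators draw from explicit `numpy.random.Generator` streams; each
observer carries one seed with per-phase child streams, so every artifact
is bit-reproducible.

## Phase I analysis

Epochs (default 30 s at 512 Hz; desk-scale tests use 6 s at 256–512 Hz)
lose their first 2 s (onset-evoked potential), are truncated to
`floor(floor(T·f)·fs/f)` samples — the largest whole number of stimulation
cycles expressible in whole samples, which places the stimulation frequency
within half a bin of the FFT grid — averaged across trials, Fourier
transformed per channel with unit-sinusoid normalization, and the spectra
averaged across channels (averaging spectra, not traces: out-of-phase
channels must not cancel). "Amplitude at f" is read at the nearest bin.

The significance null resamples `n_draw = 5` whole multichannel trials with
replacement from the pooled single trials of *all* conditions, 5000 times,
pushing each resample through the identical trim/average/spectrum path.
Choices the source procedure leaves open, fixed here: the pool is trimmed of
the same 2 s onset (symmetry with the test statistic); whole multichannel
trials are resampled (preserving cross-channel covariance); and one shared
resample set serves every frequency, read at each frequency's own
cycle-integer window. For speed the null evaluates the single stimulation
bin by direct DFT, which a test pins to the full-FFT path to 1e-12. A peak
is significant when it exceeds the 99.9th percentile of its null; the
threshold is the maximum significant frequency. Note a small-design caveat:
with few pooled conditions the resamples often contain the tested
condition's own coherent trials, inflating the null — the procedure is
conservative there (the calibration benchmark measures ≤ 0.005
false-positive rate at a nominal 0.001, and in practice near 0).

## Phase II analysis

The steady-report curve is fitted by posterior summation over a
deterministic grid: α uniform over the tested frequency range (81 points),
β uniform in log over [0.01, 3] /Hz (61 points), λ either fixed at the
conventional 0.10 or uniform on [0, 0.1] (11 points), with a binomial
likelihood. Point estimates are posterior means (β on the log scale);
credible intervals are marginal quantiles; a flag marks posteriors whose
mean and mode disagree by more than one α cell. The fusion threshold
inverts the fitted curve at P(steady) = 0.90 in closed form; the criterion
is attainable whenever λ < 0.2, and an unattainable criterion raises (the
pipeline then treats every tested frequency as fused). The original
analysis delegated fitting to an external toolbox whose priors are
unpublished; the uniform-grid priors here are the documented substitute,
and the benchmark requirement is calibration (≈95% coverage of α's
credible interval) rather than equality with any toolbox output.

## Phase III analysis

Each frequency runs two interleaved Bayesian staircases (strict alternation,
pair order randomized) of 20 trials each. The staircase state is a posterior
over the threshold *offset* on a signed grid [−2.5, +2.5] s (step 0.01 s):
the long staircase presents tests of duration 2 + x, the short staircase
2 − x, and a negative offset simply means the staircase's criterion point
lies on the far side of the standard — essential, because a strongly
dilated stimulus pushes the long staircase's 82% point below 2 s, and a
positive-only grid would truncate it (this is also why the grid extends
past the ±2 s outlier bound: runaway estimates must be observable, then
excluded, not clipped). The update likelihood is a Watson–Pelli Weibull in
the offset domain with guess rate 0.5, lapse 0.02, fixed slope 1.5
decades/s, shifted so the candidate threshold sits exactly at the 82%
point; placement is the posterior mean clamped to the presentable
0.5–3.5 s range, and the final estimate is the posterior mean (lower
variance than the mode; a config switch selects the mode). A mild Gaussian
prior (mean 0.5 s, SD 1 s) regularizes the first trials.

The bias statistic is Δ_short − Δ_long, the worked-example formula
(balanced 0.2/0.2 deviations give 0). For a symmetric observer this equals
twice the PSE shift; since published group values admit either reading,
both quantities are exposed (`bias`, `pse_shift = bias/2`) and every
recovery test states which it checks. Estimates with |Δ| > 2 s are excluded
before any group statistic.

The criterion-consistency benchmark runs 200 independent 40-trial
staircases against an observer with a known logistic 2AFC function and
measures the observer's true percent-correct at the converged
recommendation. The fixture's slope, 1.7/0.3 per second, is the logistic
equivalent of the default observer's 0.3 s Gaussian decision noise, and its
true 82% point sits at the analytic offset z(0.82)·0.3 ≈ 0.27 s. The
measured mean lands at 82–85%: QUEST's posterior-mean estimate has a known
small-sample upward skew (the likelihood falls off faster below the tested
level than above it), which vanishes with trial count — the suite verifies
±3 percentage points at the design's 40 trials.

## Group inference

Per-frequency one-tailed paired t-tests (overestimation direction, fixed a
priori) compare bias against the reference frequency, pairwise per
frequency (matching the varying per-frequency n after outlier removal);
Holm correction spans the ten non-reference frequencies; frequencies with
fewer than three complete pairs are reported untested. The JZS Bayes factor
BF01 integrates the Cauchy-mixture marginal likelihood by adaptive
quadrature with the H0 likelihood factored into the integrand (keeping it
O(1) for any t); the default prior scale is r = 1.0, the classical
unit-information choice consistent with "uninformed" one-sample priors of
the era — note later conventions default to √2/2, so a `scale_r` argument
exposes it. The within-subject ANOVA is computed from explicit sums of
squares, listwise over complete participants, with no sphericity
correction (uncorrected dfs, as reported in the source analysis — a
documented limitation); polynomial contrasts use orthonormal weights on
equally spaced level ranks, each tested as F(1, n−1) on per-participant
contrast scores.

Range classification is per participant: range 1 is f ≤ fusion threshold
(boundary inclusive), range 2 is fusion < f ≤ SSVEP threshold, range 3 the
rest; a missing SSVEP threshold empties range 2, and an inverted pair
(SSVEP < fusion, atypical but possible) is flagged while still
partitioning. The correlation decomposition z-scores the *predictor* within
each frequency (dropping zero-variance frequencies with a warning) and
pools rows; because pooling treats participant×frequency rows as
exchangeable, the mean of per-frequency correlations is reported alongside
as a sensitivity check. In the pipeline, the per-frequency flicker-report
predictor is the fitted curve's flicker probability (the Phase II and III
frequency grids differ), and the SSVEP-amplitude predictor is the measured
amplitude at the nearest Phase I frequency.

## Problem sizes and defaults

Defaults mirror the full design: 30 observers; Phase I, 5×30 s epochs at
512 Hz across 10 frequencies; Phase II, 20 trials × 10 frequencies; Phase
III, 40 trials × 11 frequencies with the 165.7 Hz / 2 s standard and
0.5–3.5 s tests; 5000 resamples, 5-trial draws. The test and acceptance
suites run the identical code at reduced EEG scale — 6 s epochs, 2–4
channels, 256–512 Hz, 2000 resamples where full resolution is not the
point — chosen so the whole suite completes on one CPU in minutes; the
bootstrap calibration benchmark keeps the full 5000 resamples since the
99.9th percentile is meaningless below that. The spectral benchmarks that
assert exactness use frequencies exactly expressible on the trimmed sample
grid (e.g. 8 Hz at 256 Hz); for arbitrary printed frequencies the
cycle-integer fit is limited by the sampling rate, leaving sub-bin leakage
at the 1e-2 level, which the half-bin matching rule absorbs.

## Known limitations

* Synthetic EEG has no artifacts, no realistic topography, and clean
  stationarity; preprocessing of real recordings (filtering, re-referencing,
  ICA) is out of scope, so the pipeline reads clean epochs only.
* The hardware's +0.015 ms switching tolerance is recorded with the printed
  nominal frequencies but not modeled; the printed frequency lists are used
  verbatim even where they deviate slightly from 1/(on+off).
* Group-level published values (means, t, F, r) derive from unavailable
  participant data; the suites check printed worked examples, design
  arithmetic, procedure calibration, and qualitative structure — not those
  numbers.
* The ANOVA applies no sphericity correction, and BF01's prior scale is a
  convention choice; both are surfaced as parameters rather than decided
  silently.
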