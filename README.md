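# flickerdur

Does perceived flicker dilate subjective duration? A stimulus that changes
over time is judged to last longer than a steady one — but is that driven by
the *objective* rate of change, by the *conscious perception* of the change,
or by the *neural response* to it? `flickerdur` implements, as a fully
synthetic and testable pipeline, a three-phase psychophysics/EEG study
design that separates these accounts using full-field light flickering at
frequencies from ~4 to ~166 Hz:

* **Phase I — frequency-tagged EEG.** 30 s flicker epochs evoke a
  steady-state visual evoked potential (SSVEP) at the stimulation frequency
  *f*. The response is scored as the channel-averaged FFT amplitude of the
  trial-averaged trace on a window trimmed to an integer number of flicker
  cycles, and tested against a resampling null: 5 trials drawn with
  replacement from all conditions, re-analyzed identically, 5000 times; a
  peak above the 99.9th null percentile is significant (p < 0.001). The
  **SSVEP threshold** is the highest *f* with a significant peak.
* **Phase II — flicker fusion threshold.** Yes/no flicker reports are fitted
  with a lapse-adjusted logistic P(steady | f) = λ/2 + (1−λ)·σ(β(f−α)) by
  grid-based Bayesian inference; the **fusion threshold** is the frequency
  at which the fitted curve reaches 90% "steady".
* **Phase III — subjective duration.** A 2AFC duration comparison against a
  2 s quasi-static standard (165.7 Hz), with two interleaved QUEST adaptive
  staircases per frequency estimating the test durations classified
  "longer"/"shorter" with 82% accuracy. The **duration bias** is
  Δ_short − Δ_long (the two staircases' deviations from the standard);
  positive values mean dilation, and estimates more than 2 s from the
  standard are outliers.

Group inference mirrors the study's toolkit: one-tailed paired t-tests of
each frequency's bias against the reference frequency with Bonferroni–Holm
correction, one-sample JZS Bayes factors BF01 (Cauchy prior on effect
size), a within-subject ANOVA with orthogonal polynomial contrasts,
per-participant classification of frequencies into three ranges (perceived
flicker / unperceived-but-tagged / neither), and the between- vs
within-frequency correlation decomposition via per-frequency z-scoring.

Because no participant data are deposited, everything runs on synthetic
observers whose generative model encodes the change-saliency hypothesis:
internal duration is `d · (1 + κ · saliency(f))`, with saliency the
lapse-free core of the observer's own flicker-detection curve, Gaussian
decision noise on comparisons, and EEG epochs of a stimulus-locked sinusoid
(amplitude decaying with frequency, zero above a true neural cutoff) in
1/f-plus-white noise.

## Worked example

```python
import numpy as np
from flickerdur import (ObserverParams, run_dual_staircase, duration_bias,
                        jzs_bf01)

obs = ObserverParams(dilation_gain=0.33, duration_noise_sd=0.3, rng_seed=7)
est = run_dual_staircase(obs, frequency=3.91, seed=1)
print(f"delta_long={est.delta_long:+.3f} s  delta_short={est.delta_short:+.3f} s")
print(f"bias={est.bias:+.3f} s  pse_shift={est.pse_shift:+.3f} s")
print(f"BF01 at t=3.93, n=30: {jzs_bf01(3.93, 30):.4f}")
```

prints

```
delta_long=-0.173 s  delta_short=+0.684 s
bias=+0.857 s  pse_shift=+0.428 s
BF01 at t=3.93, n=30: 0.0172
```

The observer dilates clearly-perceived 3.91 Hz flicker by 33%, so the long
staircase's 82%-correct point sits *below* the standard (a test shorter
than 2 s already feels longer) while the short staircase needs a large
decrement; the positive bias of ≈0.86 s on this single run scatters around
the closed-form value 2·(2 − 2/(1+κ)) ≈ 0.99 s for this observer (the
60-run average in the test suite recovers it to within 0.1 s). The Bayes
factor of ~0.017 (≪ 1/3) says data with t = 3.93 at n = 30 favor the
alternative overwhelmingly.

A whole cohort runs from one config:

```bash
flickerdur simulate --n-observers 30 --seed 0 --out cohort.json
flickerdur run --config study.yaml      # all three phases + group stats
flickerdur stats --cohort study_out     # recompute the group table
```

where `study.yaml` holds any subset of the `RunConfig` fields (cohort size,
per-phase frequency lists and trial counts, epoch length/sampling rate,
resampling settings, seed, output directory). Artifacts are one directory
per participant (epoch HDF5, trial CSVs, fit summaries) plus `group/` with
the duration-bias table, the per-frequency test table
(`table1_analog.csv`), threshold summaries, and a stats report; every
artifact carries the config hash and seed, and completed participants are
skipped when a run is resumed.

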