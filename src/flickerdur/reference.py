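"""Study-design constants and published group-level reference values.

The experiment this package models presented full-field flickering light at
a fixed set of nominal frequencies determined by the LED goggle on/off
periods, in three phases: (I) 30 s trials for frequency-tagged EEG
responses, (II) 2 s trials for yes/no flicker reports, and (III) a 2AFC
duration-discrimination task against a quasi-static 165.7 Hz standard.
"""

from __future__ import annotations

# LED on/off half-cycle durations (ms); on- and off-periods were equal.
ON_OFF_PERIODS_MS: tuple[float, ...] = (3.0, 5.5, 6.0, 7.0, 8.0, 9.0, 12.0, 16.0, 32.0, 64.0)

# Nominal stimulation frequencies (Hz) for Phases I and II, as printed in the
# study design. Due to a fixed +0.015 ms switching tolerance these deviate
# slightly from 1/(2 * period); the printed values are stored verbatim.
PHASE1_FREQUENCIES_HZ: tuple[float, ...] = (
    7.7, 15.7, 31.1, 41.7, 55.4, 62.3, 71.1, 82.9, 90.6, 165.7
)
PHASE2_FREQUENCIES_HZ: tuple[float, ...] = PHASE1_FREQUENCIES_HZ

# Phase III used a shifted frequency range to cover slower flicker.
PHASE3_FREQUENCIES_HZ: tuple[float, ...] = (
    3.91, 7.71, 15.71, 25.00, 31.14, 41.71, 55.43, 62.29, 71.14, 82.86, 165.7
)

SWITCHING_TOLERANCE_MS: float = 0.015  # stored, not modeled

REFERENCE_FREQUENCY_HZ: float = 165.7
STANDARD_DURATION_S: float = 2.0
TEST_DURATION_RANGE_S: tuple[float, float] = (0.5, 3.5)

PHASE1_TRIALS_PER_FREQ: int = 5
PHASE1_EPOCH_LEN_S: float = 30.0
PHASE2_TRIALS_PER_FREQ: int = 20
PHASE2_DURATION_S: float = 2.0
PHASE3_TRIALS_PER_FREQ: int = 40  # 20 longer + 20 shorter

QUEST_CRITERION_P: float = 0.82  # recommended 2AFC performance criterion
OUTLIER_DELTA_S: float = 2.0  # staircase estimates deviating more are dropped

N_BOOTSTRAP_RESAMPLES: int = 5000
N_BOOTSTRAP_DRAW: int = 5
BOOTSTRAP_PERCENTILE: float = 99.9
DISCARD_INITIAL_S: float = 2.0  # onset-ERP window excluded from spectra

FUSION_CRITERION_P: float = 0.90  # P("steady") defining the fusion threshold
ASSUMED_LAPSE_RATE: float = 0.10

# Published group-level summaries (30 observers); used to parameterize the
# synthetic cohort and as design-arithmetic fixtures. These are reported
# values, not anything this package recomputes.
FUSION_THRESHOLD_MEAN_HZ: float = 49.4
FUSION_THRESHOLD_SD_HZ: float = 10.3
SSVEP_THRESHOLD_MEAN_HZ: float = 87.0
SSVEP_THRESHOLD_SD_HZ: float = 49.6

# Group-mean duration-bias estimates (s) per Phase III frequency: the
# difference between the short- and long-staircase deviations from the 2 s
# standard (positive = overestimation). 165.7 Hz served as the reference.
REPORTED_DURATION_BIAS_S: dict[float, float] = {
    3.91: 0.66,
    7.71: 0.59,
    15.71: 0.50,
    25.00: 0.51,
    31.14: 0.35,
    41.71: 0.19,
    55.43: -0.02,
    62.29: -0.18,
    71.14: 0.01,
    82.86: -0.17,
    165.7: -0.22,
}
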