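"""Adaptive duration-discrimination staircases and the duration-bias measure.

Each Phase III frequency runs two interleaved Bayesian adaptive staircases
against the 2 s standard: a *long* staircase estimating the duration
increment Δ⁺ at which the test is classified "longer" with 82% accuracy,
and a *short* staircase estimating the decrement Δ⁻ for 82%-correct
"shorter" classification. The staircase maintains a posterior over the
candidate threshold offset and places each trial at the posterior mean
(clamped to the 0.5–3.5 s test-duration range); its update likelihood is a
fixed-shape Weibull psychometric function with 2AFC guess rate 0.5 and a
small lapse, parameterized so the candidate threshold sits exactly at the
82% point.

Over/underestimation is quantified as ``bias = Δ⁻ − Δ⁺`` (positive =
overestimation). For an observer whose internal durations are symmetric
around the point of subjective equality, this raw difference equals twice
the PSE shift, which is exposed separately. Estimates deviating from the
standard by more than 2 s are outliers and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import reference
from .synthetic import ObserverParams, StimulusSpec, TrialRecord, observer_rng, respond_longer

__all__ = [
    "QuestState",
    "DurationEstimate",
    "quest_init",
    "quest_update",
    "quest_recommend",
    "quest_estimate",
    "weibull_2afc",
    "run_dual_staircase",
    "duration_bias",
    "pse_shift",
    "apply_outlier_rule",
]

#: Default Weibull slope of the update likelihood, in the offset (s) domain.
DEFAULT_QUEST_SLOPE = 1.5
DEFAULT_QUEST_GUESS = 0.5
DEFAULT_QUEST_LAPSE = 0.02


def _criterion_shift(slope: float, guess: float, lapse: float, criterion: float) -> float:
    """Offset ε placing the criterion-p point of the Weibull at u = 0."""
    inner = (criterion - lapse * guess) / (1.0 - lapse)
    if not guess < criterion < 1.0 - lapse * (1.0 - guess):
        raise ValueError(
            f"criterion {criterion} outside attainable range "
            f"({guess}, {1.0 - lapse * (1.0 - guess)})"
        )
    return float(np.log10(-np.log((1.0 - inner) / (1.0 - guess))) / slope)


def weibull_2afc(offset: np.ndarray, threshold: np.ndarray,
                 slope: float = DEFAULT_QUEST_SLOPE,
                 guess: float = DEFAULT_QUEST_GUESS,
                 lapse: float = DEFAULT_QUEST_LAPSE,
                 criterion: float = reference.QUEST_CRITERION_P) -> np.ndarray:
    """P(correct) at tested ``offset`` for a candidate ``threshold`` offset.

    Watson–Pelli Weibull, shifted so P(correct) = ``criterion`` exactly when
    ``offset == threshold``.
    """
    eps = _criterion_shift(slope, guess, lapse, criterion)
    u = np.asarray(offset, dtype=float) - np.asarray(threshold, dtype=float) + eps
    return lapse * guess + (1.0 - lapse) * (
        1.0 - (1.0 - guess) * np.exp(-np.power(10.0, slope * u))
    )


@dataclass(frozen=True)
class QuestState:
    """Posterior over the threshold offset along the staircase's own axis.

    Offsets are signed: the long staircase presents tests of duration
    ``standard + offset`` and the short staircase ``standard − offset``, so
    a *negative* offset means the staircase's 82%-correct point lies on the
    far side of the standard (as happens on the long staircase for a
    strongly dilated stimulus).
    """

    grid: np.ndarray
    log_posterior: np.ndarray
    slope: float = DEFAULT_QUEST_SLOPE
    guess: float = DEFAULT_QUEST_GUESS
    lapse: float = DEFAULT_QUEST_LAPSE
    criterion_p: float = reference.QUEST_CRITERION_P
    trial_count: int = 0

    @property
    def posterior(self) -> np.ndarray:
        return np.exp(self.log_posterior - logsumexp(self.log_posterior))


def quest_init(grid_max: float = 2.5, n_grid: int = 501,
               prior_sd: float | None = 1.0,
               prior_mean: float = 0.5, **shape) -> QuestState:
    """Fresh staircase state on a signed offset grid [−grid_max, grid_max] s.

    The grid deliberately extends past the ±2 s outlier bound so runaway
    estimates are observable (and then excluded) rather than clipped. A
    mild Gaussian prior centered at ``prior_mean`` regularizes early trials
    (``prior_sd=None`` gives a flat prior).
    """
    grid = np.linspace(-grid_max, grid_max, n_grid)
    if prior_sd is None:
        logp = np.zeros_like(grid)
    else:
        logp = -0.5 * ((grid - prior_mean) / prior_sd) ** 2
    logp -= logsumexp(logp)
    return QuestState(grid=grid, log_posterior=logp, **shape)


def quest_update(state: QuestState, tested_offset: float, outcome: str) -> QuestState:
    """Bayes update after one trial at ``tested_offset`` ("correct"/"incorrect")."""
    if outcome not in ("correct", "incorrect"):
        raise ValueError(f"outcome must be 'correct' or 'incorrect', got {outcome!r}")
    p = weibull_2afc(tested_offset, state.grid, state.slope, state.guess,
                     state.lapse, state.criterion_p)
    lik = p if outcome == "correct" else 1.0 - p
    with np.errstate(divide="ignore"):
        logp = state.log_posterior + np.log(lik)
    if not np.any(np.isfinite(logp)):
        raise FloatingPointError("posterior collapsed to zero everywhere")
    logp = logp - logsumexp(logp)
    return replace(state, log_posterior=logp, trial_count=state.trial_count + 1)


def quest_recommend(state: QuestState,
                    standard_duration: float = reference.STANDARD_DURATION_S,
                    duration_range: tuple[float, float] = reference.TEST_DURATION_RANGE_S,
                    ) -> float:
    """Next test offset: the posterior mean, clamped so the resulting test
    duration stays inside the allowed range on either side of the standard."""
    est = float(np.sum(state.posterior * state.grid))
    max_offset = min(duration_range[1] - standard_duration,
                     standard_duration - duration_range[0])
    return float(np.clip(est, -max_offset, max_offset))


def quest_estimate(state: QuestState, mode: str = "mean") -> float:
    """Final threshold-offset estimate: posterior mean (default) or mode."""
    if mode == "mean":
        return float(np.sum(state.posterior * state.grid))
    if mode == "mode":
        return float(state.grid[np.argmax(state.log_posterior)])
    raise ValueError(f"unknown estimate mode {mode!r}")


def duration_bias(delta_long: float, delta_short: float) -> float:
    """Over/underestimation in s: short-staircase deviation minus long's.

    Both arguments are deviations from the standard duration (Δ⁺ above for
    the long staircase, Δ⁻ below for the short one). A stimulus judged
    veridically yields equal deviations and a bias of 0; positive values
    mean the stimulus was overestimated (dilated).
    """
    if not (np.isfinite(delta_long) and np.isfinite(delta_short)):
        raise ValueError("staircase deltas must be finite")
    return delta_short - delta_long


def pse_shift(bias: float) -> float:
    """PSE displacement below the standard implied by a symmetric observer."""
    return bias / 2.0


def apply_outlier_rule(delta_long: float, delta_short: float,
                       limit: float = reference.OUTLIER_DELTA_S,
                       ) -> tuple[float | None, bool]:
    """Exclude estimates whose test duration lies more than ``limit`` s from
    the standard (e.g. a 4.1 s estimate against the 2 s standard); returns
    ``(bias or None, excluded)``."""
    excluded = bool(abs(delta_long) > limit or abs(delta_short) > limit)
    return (None, True) if excluded else (duration_bias(delta_long, delta_short), False)


@dataclass
class DurationEstimate:
    """Dual-staircase outcome at one frequency."""

    frequency: float
    delta_long: float
    delta_short: float
    bias: float | None
    excluded: bool
    participant_id: str = "obs000"

    @property
    def pse_shift(self) -> float | None:
        return None if self.bias is None else pse_shift(self.bias)


def run_dual_staircase(
    obs: ObserverParams,
    frequency: float,
    n_per_staircase: int = reference.PHASE3_TRIALS_PER_FREQ // 2,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    *,
    standard: StimulusSpec | None = None,
    estimate_mode: str = "mean",
    quest_kwargs: dict | None = None,
    record_trials: list[TrialRecord] | None = None,
) -> DurationEstimate:
    """Run two interleaved staircases against a simulated observer.

    Interleaving is strict alternation with the within-pair order randomized
    under the seed. Each trial presents the standard and a test stimulus in
    counterbalanced order and queries the observer's 2AFC duration judgment;
    the staircase scores the response as correct when it matches the test's
    physical side of the standard.
    """
    if rng is None:
        rng = observer_rng(obs, 3) if seed is None else np.random.default_rng(seed)
    if standard is None:
        standard = StimulusSpec(reference.REFERENCE_FREQUENCY_HZ,
                                reference.STANDARD_DURATION_S)
    sd = standard.duration
    states = {"long": quest_init(**(quest_kwargs or {})),
              "short": quest_init(**(quest_kwargs or {}))}
    trial_index = 0
    for _ in range(n_per_staircase):
        pair = ["long", "short"] if rng.random() < 0.5 else ["short", "long"]
        for which in pair:
            offset = quest_recommend(states[which], sd)
            test_dur = sd + offset if which == "long" else sd - offset
            test = StimulusSpec(frequency, test_dur)
            standard_first = bool(rng.random() < 0.5)
            response = respond_longer(obs, test, standard, rng)
            expected = "longer" if which == "long" else "shorter"
            outcome = "correct" if response == expected else "incorrect"
            states[which] = quest_update(states[which], offset, outcome)
            if record_trials is not None:
                record_trials.append(TrialRecord(
                    participant_id=obs.participant_id, phase=3,
                    frequency=frequency, duration=test_dur, response=response,
                    staircase_id=which, trial_index=trial_index,
                    standard_first=standard_first,
                ))
            trial_index += 1
    delta_long = quest_estimate(states["long"], estimate_mode)
    delta_short = quest_estimate(states["short"], estimate_mode)
    bias, excluded = apply_outlier_rule(delta_long, delta_short)
    return DurationEstimate(frequency=frequency, delta_long=delta_long,
                            delta_short=delta_short, bias=bias,
                            excluded=excluded, participant_id=obs.participant_id)


def estimates_to_frame(estimates: list[DurationEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.participant_id, e.frequency, e.delta_long, e.delta_short,
          e.bias, e.excluded) for e in estimates],
        columns=["participant_id", "frequency_hz", "delta_long_s",
                 "delta_short_s", "bias_s", "excluded"],
    )
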