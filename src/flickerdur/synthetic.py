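"""Synthetic observers, stimuli, behavioral responses, and EEG epochs.

Every downstream analysis stage (frequency-tagged spectra, psychometric
fits, adaptive staircases, group statistics) is exercised against data
produced here. The generative model encodes the change-saliency assumption:
an observer's internal duration of a flickering stimulus is dilated in
proportion to how salient the flicker appears, where saliency follows the
(lapse-free) core of the observer's flicker-detection psychometric function.

All draws are reproducible: generators take an explicit
``numpy.random.Generator``; :func:`observer_rng` derives per-phase streams
from an observer's seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import reference

__all__ = [
    "StimulusSpec",
    "ObserverParams",
    "TrialRecord",
    "EpochSet",
    "observer_rng",
    "sample_cohort",
    "make_experiment_design",
    "p_flicker",
    "saliency",
    "respond_flicker",
    "subjective_duration",
    "respond_longer",
    "gen_epochs",
    "trials_to_csv",
    "trials_from_csv",
]

TRIAL_CSV_COLUMNS = (
    "participant_id",
    "phase",
    "frequency_hz",
    "duration_s",
    "response",
    "staircase_id",
    "trial_index",
    "standard_first",
)


@dataclass(frozen=True)
class StimulusSpec:
    """A flickering light stimulus with equal on- and off-periods.

    Parameters
    ----------
    frequency : float
        Nominal flicker rate in Hz.
    duration : float
        Stimulus duration in s.
    on_period_ms, off_period_ms : float, optional
        Half-cycle durations in ms. If omitted they are derived from the
        frequency. Printed nominal frequencies may deviate from
        ``1000 / (on + off)`` by up to 2% (hardware switching tolerance).
    """

    frequency: float
    duration: float
    on_period_ms: float | None = None
    off_period_ms: float | None = None

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError(f"frequency must be positive, got {self.frequency}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if (self.on_period_ms is None) != (self.off_period_ms is None):
            raise ValueError("on_period_ms and off_period_ms must be given together")
        if self.on_period_ms is None:
            half = 1000.0 / (2.0 * self.frequency)
            object.__setattr__(self, "on_period_ms", half)
            object.__setattr__(self, "off_period_ms", half)
        if self.on_period_ms != self.off_period_ms:
            raise ValueError("on- and off-periods must be of equal duration")
        implied = 1000.0 / (self.on_period_ms + self.off_period_ms)
        if abs(implied - self.frequency) / self.frequency > 0.02:
            raise ValueError(
                f"frequency {self.frequency} Hz inconsistent with periods "
                f"(implies {implied:.2f} Hz, >2% off)"
            )


@dataclass(frozen=True)
class ObserverParams:
    """Ground-truth generative parameters of one synthetic participant.

    The flicker-detection curve is a decreasing logistic in frequency with
    location ``fusion_alpha`` (Hz, 50% point), slope ``fusion_beta`` (1/Hz)
    and lapse rate ``lapse``. Subjective duration of a stimulus of physical
    duration ``d`` at frequency ``f`` is ``d * (1 + dilation_gain *
    saliency(f))``. The evoked-response amplitude curve is flat at
    ``ssvep_amp_uv`` up to ``ssvep_peak_hz`` and decays exponentially above
    it with scale ``ssvep_decay_hz``; it is identically zero above
    ``ssvep_threshold_true``.
    """

    fusion_alpha: float = reference.FUSION_THRESHOLD_MEAN_HZ
    fusion_beta: float = 0.3
    lapse: float = 0.05
    dilation_gain: float = 0.33
    duration_noise_sd: float = 0.3
    ssvep_amp_uv: float = 1.0
    ssvep_peak_hz: float = 12.0
    ssvep_decay_hz: float = 50.0
    ssvep_threshold_true: float = 90.6
    saliency_rolloff_hz: float | None = None
    rng_seed: int = 0
    participant_id: str = "obs000"

    def __post_init__(self) -> None:
        if self.fusion_alpha <= 0 or self.fusion_beta <= 0:
            raise ValueError("fusion_alpha and fusion_beta must be positive")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError(f"lapse must lie in [0, 0.1], got {self.lapse}")
        if self.dilation_gain < 0:
            raise ValueError("dilation_gain must be non-negative")
        if self.duration_noise_sd <= 0:
            raise ValueError("duration_noise_sd must be positive")
        if self.ssvep_amp_uv < 0:
            raise ValueError("ssvep_amp_uv must be non-negative")

    def ssvep_amp_curve(self, frequency: float | np.ndarray) -> np.ndarray:
        """Evoked sinusoid amplitude (µV) at stimulation frequency."""
        f = np.asarray(frequency, dtype=float)
        amp = self.ssvep_amp_uv * np.exp(
            -np.maximum(0.0, f - self.ssvep_peak_hz) / self.ssvep_decay_hz
        )
        return np.where(f > self.ssvep_threshold_true, 0.0, amp)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ObserverParams":
        return cls(**d)


@dataclass
class TrialRecord:
    """One trial of any phase; ``response`` is None for unexecuted stubs."""

    participant_id: str
    phase: int
    frequency: float
    duration: float
    response: str | None = None
    staircase_id: str = "none"  # "long", "short", or "none"
    trial_index: int = 0
    standard_first: bool | None = None


@dataclass
class EpochSet:
    """Fixed-length multichannel EEG trials for one stimulation frequency.

    ``data`` has shape (n_trials, n_channels, n_samples); ``fs`` is the
    sampling rate in Hz and ``stim_freq`` the stimulation frequency in Hz.
    """

    data: np.ndarray
    fs: float
    stim_freq: float
    participant_id: str = "obs000"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (n_trials, n_channels, n_samples)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            ds = h5.create_dataset("epochs", data=self.data)
            ds.attrs["fs_hz"] = self.fs
            ds.attrs["stim_freq_hz"] = self.stim_freq
            ds.attrs["participant_id"] = self.participant_id
            ds.attrs["seed"] = -1 if self.seed is None else self.seed

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        import h5py

        with h5py.File(path, "r") as h5:
            ds = h5["epochs"]
            seed = int(ds.attrs["seed"])
            return cls(
                data=ds[...],
                fs=float(ds.attrs["fs_hz"]),
                stim_freq=float(ds.attrs["stim_freq_hz"]),
                participant_id=str(ds.attrs["participant_id"]),
                seed=None if seed < 0 else seed,
            )


def observer_rng(obs: ObserverParams, phase: int) -> np.random.Generator:
    """Per-observer, per-phase random stream (one global seed per observer)."""
    return np.random.default_rng(np.random.SeedSequence([int(obs.rng_seed), int(phase)]))


def sample_cohort(
    n_observers: int = 30,
    seed: int = 0,
    candidate_ssvep_thresholds: Sequence[float] = reference.PHASE1_FREQUENCIES_HZ,
) -> list[ObserverParams]:
    """Draw a cohort of synthetic observers.

    Fusion thresholds (logistic locations) follow the reported group
    distribution N(49.4, 10.3²) Hz; true evoked-response cutoffs follow
    N(87.0, 49.6²) Hz snapped to the nearest tested stimulation frequency.
    Dilation gains scatter around 0.33 (a ~30% dilation of clearly perceived
    flicker, matching the reported effect at the slowest frequency).
    """
    rng = np.random.default_rng(seed)
    cands = np.asarray(sorted(candidate_ssvep_thresholds))
    cohort = []
    for i in range(n_observers):
        alpha = float(np.clip(
            rng.normal(reference.FUSION_THRESHOLD_MEAN_HZ, reference.FUSION_THRESHOLD_SD_HZ),
            25.0, 100.0,
        ))
        thr_draw = np.clip(
            rng.normal(reference.SSVEP_THRESHOLD_MEAN_HZ, reference.SSVEP_THRESHOLD_SD_HZ),
            cands.min(), cands.max(),
        )
        ssvep_thr = float(cands[np.argmin(np.abs(cands - thr_draw))])
        cohort.append(ObserverParams(
            fusion_alpha=alpha,
            fusion_beta=float(np.exp(rng.normal(np.log(0.3), 0.2))),
            lapse=float(rng.uniform(0.0, 0.1)),
            dilation_gain=float(np.clip(rng.normal(0.33, 0.08), 0.05, 0.8)),
            duration_noise_sd=float(np.exp(rng.normal(np.log(0.3), 0.2))),
            ssvep_amp_uv=float(np.exp(rng.normal(0.0, 0.3))),
            ssvep_threshold_true=ssvep_thr,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
            participant_id=f"obs{i:03d}",
        ))
    return cohort


def make_experiment_design(
    frequencies: Sequence[float],
    trials_per_freq: int,
    split: tuple[int, int] | None = None,
    *,
    participant_id: str = "obs000",
    phase: int = 3,
    duration: float = reference.STANDARD_DURATION_S,
    rng: np.random.Generator | None = None,
) -> list[TrialRecord]:
    """Emit randomized trial stubs for one participant and phase.

    For Phase III pass ``split=(n_longer, n_shorter)`` (must sum to
    ``trials_per_freq``; both staircases need equal trial counts, so the
    split must be balanced). Trial order is randomized under ``rng`` and the
    standard/test presentation order counterbalanced within frequency.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if trials_per_freq <= 0:
        raise ValueError("trials_per_freq must be positive")
    if split is not None:
        if sum(split) != trials_per_freq:
            raise ValueError(f"split {split} does not sum to trials_per_freq={trials_per_freq}")
        if split[0] != split[1]:
            raise ValueError(f"unbalanced staircases: split {split} must be equal")
        if trials_per_freq % 2 != 0:
            raise ValueError("trials_per_freq must be even when interleaving two staircases")

    stubs: list[TrialRecord] = []
    for f in frequencies:
        if split is None:
            ids = ["none"] * trials_per_freq
        else:
            ids = ["long"] * split[0] + ["short"] * split[1]
        # counterbalance standard-first within frequency
        order = np.zeros(trials_per_freq, dtype=bool)
        order[: trials_per_freq // 2] = True
        rng.shuffle(order)
        for sc, first in zip(ids, order):
            stubs.append(TrialRecord(
                participant_id=participant_id,
                phase=phase,
                frequency=float(f),
                duration=float(duration),
                staircase_id=sc,
                standard_first=bool(first) if phase == 3 else None,
            ))
    perm = rng.permutation(len(stubs))
    stubs = [stubs[i] for i in perm]
    for i, s in enumerate(stubs):
        s.trial_index = i
    return stubs


def saliency(obs: ObserverParams, frequency: float | np.ndarray) -> np.ndarray:
    """Subjective flicker saliency in [0, 1]: the lapse-free logistic core.

    Optionally attenuated at very low frequencies when
    ``saliency_rolloff_hz`` is set (inverted-U shape); off by default.
    """
    f = np.asarray(frequency, dtype=float)
    s = expit(-obs.fusion_beta * (f - obs.fusion_alpha))
    if obs.saliency_rolloff_hz is not None:
        s = s * (1.0 - np.exp(-f / obs.saliency_rolloff_hz))
    return s


def p_flicker(obs: ObserverParams, frequency: float | np.ndarray) -> np.ndarray:
    """Probability of reporting "flicker", decreasing in frequency.

    Lapse-adjusted logistic: ``λ/2 + (1−λ) / (1 + exp(β (f − α)))``; values
    lie in [λ/2, 1−λ/2].
    """
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    core = expit(-obs.fusion_beta * (f - obs.fusion_alpha))
    return obs.lapse / 2.0 + (1.0 - obs.lapse) * core


def respond_flicker(obs: ObserverParams, stim: StimulusSpec,
                    rng: np.random.Generator) -> str:
    """One yes/no report: "flicker" or "steady" (Bernoulli at p_flicker)."""
    p = float(p_flicker(obs, stim.frequency))
    return "flicker" if rng.random() < p else "steady"


def subjective_duration(obs: ObserverParams, stim: StimulusSpec) -> float:
    """Noise-free internal duration: physical duration dilated by saliency."""
    return stim.duration * (1.0 + obs.dilation_gain * float(saliency(obs, stim.frequency)))


def respond_longer(obs: ObserverParams, test: StimulusSpec, standard: StimulusSpec,
                   rng: np.random.Generator) -> str:
    """2AFC judgment: "longer" iff the noisy internal comparison favors the test.

    The internal difference ``subjective(test) − subjective(standard)`` is
    corrupted by zero-mean Gaussian decision noise of SD ``duration_noise_sd``.
    """
    diff = subjective_duration(obs, test) - subjective_duration(obs, standard)
    return "longer" if diff + rng.normal(0.0, obs.duration_noise_sd) > 0 else "shorter"


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
                sd: float) -> np.ndarray:
    """1/f-amplitude noise, unit-variance shaped white noise scaled to ``sd``."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / freqs[1:]
    pink = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    std = pink.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return sd * pink / std


def gen_epochs(
    obs: ObserverParams,
    stim: StimulusSpec,
    n_trials: int = reference.PHASE1_TRIALS_PER_FREQ,
    n_channels: int = 64,
    fs: float = 512.0,
    epoch_len: float = reference.PHASE1_EPOCH_LEN_S,
    *,
    pink_sd_uv: float = 3.0,
    white_sd_uv: float = 1.0,
    channel_gain_sd: float = 0.3,
    channel_phase_sd: float = 0.5,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> EpochSet:
    """Simulate multichannel EEG epochs frequency-tagged at ``stim.frequency``.

    Each channel carries ``A · g_c · sin(2π f t + φ + φ_c)`` plus independent
    1/f and white noise, where ``A`` is the observer's evoked amplitude at
    ``f`` (zero above the true evoked-response cutoff), ``g_c`` and ``φ_c``
    are channel-specific gains and phase offsets (scalp spread), and ``φ``
    is a stimulus-locked phase constant across trials — trial averaging must
    not cancel the evoked response.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    f = stim.frequency
    if fs < 2.0 * f:
        raise ValueError(f"fs={fs} Hz aliases a {f} Hz stimulus (need fs ≥ 2f)")
    n_samples = int(round(epoch_len * fs))
    t = np.arange(n_samples) / fs

    amp = float(obs.ssvep_amp_curve(f))
    # channel topography: deterministic per (observer, frequency) stream
    chan_rng = np.random.default_rng(
        np.random.SeedSequence([int(obs.rng_seed), 1, int(round(f * 1000))])
    )
    gains = np.exp(chan_rng.normal(0.0, channel_gain_sd, size=n_channels))
    chan_phase = chan_rng.normal(0.0, channel_phase_sd, size=n_channels)
    phi = chan_rng.uniform(0.0, 2.0 * np.pi)

    signal = amp * gains[:, None] * np.sin(
        2.0 * np.pi * f * t[None, :] + phi + chan_phase[:, None]
    )
    data = np.broadcast_to(signal, (n_trials, n_channels, n_samples)).copy()
    if pink_sd_uv > 0:
        data += _pink_noise(rng, (n_trials, n_channels), n_samples, pink_sd_uv)
    if white_sd_uv > 0:
        data += white_sd_uv * rng.standard_normal((n_trials, n_channels, n_samples))
    return EpochSet(data=data, fs=fs, stim_freq=f,
                    participant_id=obs.participant_id, seed=seed)


def trials_to_csv(trials: Iterable[TrialRecord], path) -> None:
    rows = [
        (t.participant_id, t.phase, t.frequency, t.duration, t.response,
         t.staircase_id, t.trial_index, t.standard_first)
        for t in trials
    ]
    pd.DataFrame(rows, columns=TRIAL_CSV_COLUMNS).to_csv(path, index=False)


def trials_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
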