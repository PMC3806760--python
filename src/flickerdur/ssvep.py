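"""Frequency-tagged EEG analysis: cycle-locked spectra and bootstrap detection.

The evoked response at a stimulation frequency is scored as the amplitude of
the channel-averaged FFT spectrum of the trial-averaged trace, computed on a
window trimmed to an integer number of stimulation cycles (which places the
stimulation frequency on — or within half a bin of — the spectral grid and
suppresses leakage). Significance is assessed with a resampling null: five
single trials are drawn with replacement from the pooled trials of all
stimulation conditions, pushed through the identical trim/average/spectrum
path, and the amplitude at the stimulation-frequency bin recorded; with 5000
resamples, a peak exceeding the 99.9th percentile of the null is significant
at p < 0.001. A participant's evoked-response threshold is the highest
stimulation frequency with a significant peak.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import reference
from .synthetic import EpochSet

__all__ = [
    "AmplitudeSpectrum",
    "SsvepResult",
    "SsvepResults",
    "SsvepAnalysis",
    "cycle_window_samples",
    "trim_and_average",
    "amplitude_spectrum",
    "bootstrap_null",
    "ssvep_threshold",
]


@dataclass
class AmplitudeSpectrum:
    """Channel-averaged amplitude spectrum on a cycle-integer window.

    Amplitudes are normalized so a unit sinusoid at a bin frequency yields
    amplitude 1 at that bin.
    """

    freqs: np.ndarray
    amplitude: np.ndarray
    n_samples_used: int
    window_cycles: int | None = None

    def at(self, frequency: float) -> float:
        """Amplitude at the bin nearest ``frequency``."""
        return float(self.amplitude[self.bin_index(frequency)])

    def bin_index(self, frequency: float) -> int:
        return int(np.argmin(np.abs(self.freqs - frequency)))


@dataclass
class SsvepResult:
    """Detection outcome at one stimulation frequency."""

    frequency: float
    amplitude: float
    null_percentile_999: float
    significant: bool
    n_resamples: int = reference.N_BOOTSTRAP_RESAMPLES


def cycle_window_samples(n_avail: int, fs: float, stim_freq: float) -> tuple[int, int]:
    """Largest window ≤ ``n_avail`` samples spanning whole stimulation cycles.

    Returns ``(n_samples, n_cycles)`` with ``n_samples = floor(n_cycles·fs/f)``;
    exactness of the cycle fit is limited by the sampling rate.
    """
    n_cycles = int(np.floor(n_avail / fs * stim_freq))
    if n_cycles < 1:
        raise ValueError(
            f"window of {n_avail} samples at {fs} Hz holds no whole cycle of "
            f"{stim_freq} Hz"
        )
    n_samples = int(np.floor(n_cycles * fs / stim_freq))
    return n_samples, n_cycles


def trim_and_average(
    epochs: EpochSet | np.ndarray,
    stim_freq: float,
    discard_initial: float = reference.DISCARD_INITIAL_S,
    fs: float | None = None,
) -> tuple[np.ndarray, int]:
    """Drop the onset window, trim to whole cycles, average across trials.

    The first ``discard_initial`` seconds are excluded (onset-evoked
    potential), the remainder truncated to the largest whole number of
    stimulation cycles expressible in whole samples, and the trials averaged.
    Returns ``(trace, window_cycles)`` with ``trace`` of shape
    (n_channels, n_window_samples).
    """
    if isinstance(epochs, EpochSet):
        data, fs = epochs.data, epochs.fs
    else:
        data = np.asarray(epochs, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    n_skip = int(round(discard_initial * fs))
    if n_skip >= data.shape[-1]:
        raise ValueError("discard_initial leaves no usable samples")
    n_avail = data.shape[-1] - n_skip
    n_win, n_cycles = cycle_window_samples(n_avail, fs, stim_freq)
    return data[..., n_skip : n_skip + n_win].mean(axis=0), n_cycles


def amplitude_spectrum(trace: np.ndarray, fs: float,
                       window_cycles: int | None = None) -> AmplitudeSpectrum:
    """Per-channel FFT amplitude spectrum, averaged across channels.

    ``trace`` is (n_channels, n_samples) or (n_samples,). A sinusoid of
    amplitude A at a bin frequency appears with amplitude A.
    """
    trace = np.atleast_2d(np.asarray(trace, dtype=float))
    n = trace.shape[-1]
    if n == 0:
        raise ValueError("empty trace")
    spec = np.abs(np.fft.rfft(trace, axis=-1)) * (2.0 / n)
    spec[..., 0] /= 2.0  # DC carries no conjugate pair
    if n % 2 == 0:
        spec[..., -1] /= 2.0  # neither does Nyquist
    return AmplitudeSpectrum(
        freqs=np.fft.rfftfreq(n, d=1.0 / fs),
        amplitude=spec.mean(axis=0),
        n_samples_used=n,
        window_cycles=window_cycles,
    )


def _bin_amplitudes(avg: np.ndarray, fs: float, stim_freq: float) -> np.ndarray:
    """Channel-averaged amplitude at the stimulation-frequency bin.

    ``avg`` is (..., n_channels, n_win) already trimmed to the cycle-integer
    window for ``stim_freq``; single-bin DFT equals the matching rfft bin.
    """
    n = avg.shape[-1]
    k = int(np.round(stim_freq * n / fs))
    phasor = np.exp(-2j * np.pi * k * np.arange(n) / n)
    amps = np.abs(avg @ phasor) * (2.0 / n)
    return amps.mean(axis=-1)


def bootstrap_null(
    pool: np.ndarray,
    fs: float,
    stim_freqs: float | np.ndarray,
    n_draw: int = reference.N_BOOTSTRAP_DRAW,
    n_resamples: int = reference.N_BOOTSTRAP_RESAMPLES,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    chunk: int = 250,
) -> dict[float, np.ndarray]:
    """Resampling null for the stimulation-frequency peak amplitude.

    ``pool`` holds already-trimmed-of-onset single trials pooled across every
    stimulation condition, shape (n_pool, n_channels, n_samples). For each
    of ``n_resamples`` repetitions, ``n_draw`` whole multichannel trials are
    drawn with replacement, averaged, and the channel-averaged spectral
    amplitude read at every requested stimulation frequency (each on its own
    cycle-integer window). One shared resample set serves all frequencies.
    """
    pool = np.asarray(pool, dtype=float)
    if pool.ndim != 3 or pool.shape[0] == 0:
        raise ValueError("pool must be a non-empty (n_pool, n_channels, n_samples) array")
    if rng is None:
        rng = np.random.default_rng(seed)
    freqs = np.atleast_1d(np.asarray(stim_freqs, dtype=float))
    windows = {f: cycle_window_samples(pool.shape[-1], fs, f)[0] for f in freqs}
    out = {f: np.empty(n_resamples) for f in freqs}
    idx = rng.integers(0, pool.shape[0], size=(n_resamples, n_draw))
    for start in range(0, n_resamples, chunk):
        sl = idx[start : start + chunk]
        avg = pool[sl].mean(axis=1)  # (chunk, n_channels, n_samples)
        for f in freqs:
            n_win = windows[f]
            out[f][start : start + sl.shape[0]] = _bin_amplitudes(
                avg[..., :n_win], fs, f
            )
    return out


def ssvep_threshold(results: list[SsvepResult]) -> float | None:
    """Highest frequency with a significant peak; None if none is."""
    sig = [r.frequency for r in results if r.significant]
    return max(sig) if sig else None


class SsvepResults:
    """Per-frequency detection results and the derived threshold."""

    def __init__(self, results: list[SsvepResult], participant_id: str = "obs000",
                 seed: int | None = None):
        self.results = sorted(results, key=lambda r: r.frequency)
        self.participant_id = participant_id
        self.seed = seed

    @property
    def threshold(self) -> float | None:
        return ssvep_threshold(self.results)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.frequency, r.amplitude, r.null_percentile_999, r.significant)
             for r in self.results],
            columns=["frequency_hz", "amplitude", "null_p999", "significant"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "ssvep_threshold_hz": self.threshold,
            "n_significant": int(sum(r.significant for r in self.results)),
            "n_frequencies": len(self.results),
            "n_resamples": self.results[0].n_resamples if self.results else 0,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = [f"Evoked-response detection — {self.participant_id}",
                 f"{'freq (Hz)':>10} {'amplitude':>12} {'null p99.9':>12} {'sig':>5}"]
        for r in self.results:
            lines.append(f"{r.frequency:>10.2f} {r.amplitude:>12.4f} "
                         f"{r.null_percentile_999:>12.4f} {str(r.significant):>5}")
        thr = self.threshold
        lines.append(f"threshold: {'none' if thr is None else f'{thr:.1f} Hz'}")
        return "\n".join(lines)


class SsvepAnalysis:
    """Phase I model: detect frequency-tagged responses in a set of conditions.

    Parameters
    ----------
    epoch_sets : list of EpochSet
        One per stimulation frequency, sharing sampling rate and length.
    discard_initial : float
        Onset window (s) excluded before spectral analysis.
    n_draw, n_resamples : int
        Resampling-null parameters (defaults 5 and 5000).
    """

    def __init__(self, epoch_sets: list[EpochSet],
                 discard_initial: float = reference.DISCARD_INITIAL_S,
                 n_draw: int = reference.N_BOOTSTRAP_DRAW,
                 n_resamples: int = reference.N_BOOTSTRAP_RESAMPLES):
        if len(epoch_sets) < 2:
            raise ValueError("need trials from at least two stimulation conditions")
        fs = {e.fs for e in epoch_sets}
        ns = {e.n_samples for e in epoch_sets}
        if len(fs) != 1 or len(ns) != 1:
            raise ValueError("all epoch sets must share sampling rate and length")
        self.epoch_sets = sorted(epoch_sets, key=lambda e: e.stim_freq)
        self.fs = fs.pop()
        self.discard_initial = discard_initial
        self.n_draw = n_draw
        self.n_resamples = n_resamples

    def condition_spectrum(self, epochs: EpochSet) -> AmplitudeSpectrum:
        trace, n_cycles = trim_and_average(epochs, epochs.stim_freq, self.discard_initial)
        return amplitude_spectrum(trace, self.fs, window_cycles=n_cycles)

    def fit(self, seed: int | None = None,
            rng: np.random.Generator | None = None) -> SsvepResults:
        if rng is None:
            rng = np.random.default_rng(seed)
        n_skip = int(round(self.discard_initial * self.fs))
        pool = np.concatenate([e.data[..., n_skip:] for e in self.epoch_sets], axis=0)
        freqs = [e.stim_freq for e in self.epoch_sets]
        null = bootstrap_null(pool, self.fs, freqs, n_draw=self.n_draw,
                              n_resamples=self.n_resamples, rng=rng)
        results = []
        for e in self.epoch_sets:
            spec = self.condition_spectrum(e)
            amp = spec.at(e.stim_freq)
            p999 = float(np.percentile(null[e.stim_freq], reference.BOOTSTRAP_PERCENTILE))
            results.append(SsvepResult(
                frequency=e.stim_freq, amplitude=amp, null_percentile_999=p999,
                significant=bool(amp > p999), n_resamples=self.n_resamples,
            ))
        return SsvepResults(results, participant_id=self.epoch_sets[0].participant_id,
                            seed=seed)
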