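"""Flicker-fusion threshold estimation from yes/no reports.

The probability of reporting a stimulus as *steady* is modeled as a
lapse-adjusted logistic increasing with flicker frequency,

    P(steady | f) = λ/2 + (1 − λ) / (1 + exp(−β (f − α))),

with location α (Hz, the 50% point of the core logistic), slope β (1/Hz)
and lapse rate λ ∈ [0, 0.1]. Inference is Bayesian on a deterministic
parameter grid with a binomial likelihood and uniform priors (uniform in
log β). The flicker fusion threshold is the frequency at which the fitted
curve reaches 90% "steady" — a criterion deliberately placed high because a
10% lapse rate is commonly assumed, so frequencies classified as fused are
genuinely perceived as steady.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit, logsumexp

from . import reference

__all__ = [
    "PsychometricModel",
    "PsychometricResults",
    "PsychometricFit",
    "steady_curve",
    "threshold_at_params",
]


def steady_curve(f, alpha: float, beta: float, lapse: float):
    """P("steady") at frequency ``f`` under the lapse-adjusted logistic."""
    f = np.asarray(f, dtype=float)
    return lapse / 2.0 + (1.0 - lapse) * expit(beta * (f - alpha))


def threshold_at_params(p: float, alpha: float, beta: float, lapse: float) -> float:
    """Closed-form inverse of the lapse-adjusted logistic.

    Raises ValueError when ``p`` lies outside the curve's attainable range
    (λ/2, 1 − λ/2).
    """
    lo, hi = lapse / 2.0, 1.0 - lapse / 2.0
    if not lo < p < hi:
        raise ValueError(
            f"criterion p={p} unattainable: curve range is ({lo:.3f}, {hi:.3f})"
        )
    return alpha + logit((p - lo) / (1.0 - lapse)) / beta


@dataclass
class PsychometricFit:
    """Point estimates and derived criterion threshold of a fitted curve."""

    alpha: float
    beta: float
    lapse: float
    fusion_threshold_90: float | None
    posterior_summary: dict = field(default_factory=dict)
    degenerate: bool = False


class PsychometricModel:
    """Grid-Bayesian logistic psychometric model for per-frequency counts.

    Parameters
    ----------
    frequencies : array-like
        Tested flicker frequencies (Hz), at least 3 distinct values.
    n_steady : array-like
        Number of "steady" reports per frequency.
    n_total : array-like
        Trials per frequency (all positive).
    lapse_mode : {"fixed", "fitted"}
        Fix the lapse rate at ``lapse_value`` (default, at the conventional
        0.10) or infer it on a grid over [0, 0.1].
    """

    def __init__(self, frequencies, n_steady, n_total,
                 lapse_mode: str = "fixed",
                 lapse_value: float = reference.ASSUMED_LAPSE_RATE,
                 n_alpha: int = 81, n_beta: int = 61, n_lapse: int = 11,
                 beta_range: tuple[float, float] = (1e-2, 3.0)):
        self.frequencies = np.asarray(frequencies, dtype=float)
        self.n_steady = np.asarray(n_steady, dtype=float)
        self.n_total = np.asarray(n_total, dtype=float)
        if len(np.unique(self.frequencies)) < 3:
            raise ValueError("need at least 3 distinct frequencies")
        if np.any(self.n_total <= 0):
            raise ValueError("all totals must be positive")
        if np.any(self.n_steady < 0) or np.any(self.n_steady > self.n_total):
            raise ValueError("counts must satisfy 0 <= n_steady <= n_total")
        if lapse_mode not in ("fixed", "fitted"):
            raise ValueError("lapse_mode must be 'fixed' or 'fitted'")
        self.lapse_mode = lapse_mode
        # uniform priors: alpha over the tested range, beta uniform in log
        self.alpha_grid = np.linspace(self.frequencies.min(), self.frequencies.max(),
                                      n_alpha)
        self.beta_grid = np.geomspace(beta_range[0], beta_range[1], n_beta)
        if lapse_mode == "fixed":
            self.lapse_grid = np.array([lapse_value])
        else:
            self.lapse_grid = np.linspace(0.0, 0.1, n_lapse)

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, **kwargs) -> "PsychometricModel":
        """Build from a Phase II trial table (frequency_hz, response)."""
        g = trials.groupby("frequency_hz")["response"]
        n_total = g.size()
        n_steady = g.apply(lambda s: int((s == "steady").sum()))
        return cls(n_total.index.to_numpy(), n_steady.to_numpy(),
                   n_total.to_numpy(), **kwargs)

    def _log_likelihood(self) -> np.ndarray:
        """Log binomial likelihood over the (alpha, beta, lapse) grid."""
        a = self.alpha_grid[:, None, None, None]
        b = self.beta_grid[None, :, None, None]
        lam = self.lapse_grid[None, None, :, None]
        f = self.frequencies[None, None, None, :]
        p = np.clip(steady_curve(f, a, b, lam), 1e-12, 1.0 - 1e-12)
        ll = self.n_steady * np.log(p) + (self.n_total - self.n_steady) * np.log1p(-p)
        return ll.sum(axis=-1)

    def fit(self) -> "PsychometricResults":
        log_post = self._log_likelihood()
        log_post -= logsumexp(log_post)
        posterior = np.exp(log_post)
        degenerate = bool(
            np.all(self.n_steady == 0) or np.all(self.n_steady == self.n_total)
        )
        return PsychometricResults(self, posterior, degenerate=degenerate)


class PsychometricResults:
    """Posterior over (α, β, λ) and the derived fusion threshold."""

    def __init__(self, model: PsychometricModel, posterior: np.ndarray,
                 degenerate: bool = False):
        self.model = model
        self.posterior = posterior
        self.degenerate = degenerate
        self.alpha = float(np.sum(posterior.sum(axis=(1, 2)) * model.alpha_grid))
        # slope summarized on the log scale (grid is geometric)
        self.beta = float(np.exp(
            np.sum(posterior.sum(axis=(0, 2)) * np.log(model.beta_grid))
        ))
        self.lapse = float(np.sum(posterior.sum(axis=(0, 1)) * model.lapse_grid))
        self._mode_idx = np.unravel_index(np.argmax(posterior), posterior.shape)

    # -- parameter summaries -------------------------------------------------

    def _marginal_ci(self, axis: int, grid: np.ndarray,
                     level: float = 0.95) -> tuple[float, float]:
        axes = tuple(i for i in range(3) if i != axis)
        marg = self.posterior.sum(axis=axes)
        cdf = np.cumsum(marg)
        lo = grid[np.searchsorted(cdf, (1 - level) / 2)]
        hi = grid[min(np.searchsorted(cdf, 1 - (1 - level) / 2), len(grid) - 1)]
        return float(lo), float(hi)

    def credible_interval(self, param: str, level: float = 0.95) -> tuple[float, float]:
        axis, grid = {
            "alpha": (0, self.model.alpha_grid),
            "beta": (1, self.model.beta_grid),
            "lapse": (2, self.model.lapse_grid),
        }[param]
        return self._marginal_ci(axis, grid, level)

    @property
    def mean_mode_disagree(self) -> bool:
        """Flag multimodal posteriors: mean off the modal cell by >1 cell."""
        a_mode = self.model.alpha_grid[self._mode_idx[0]]
        da = np.diff(self.model.alpha_grid).mean()
        return bool(abs(self.alpha - a_mode) > 1.5 * da)

    # -- thresholds ----------------------------------------------------------

    def predict(self, f) -> np.ndarray:
        """Fitted P("steady") at frequency ``f``."""
        return steady_curve(f, self.alpha, self.beta, self.lapse)

    def threshold_at(self, p: float) -> float:
        """Frequency at which the fitted curve attains P("steady") = p."""
        return threshold_at_params(p, self.alpha, self.beta, self.lapse)

    @property
    def fusion_threshold_90(self) -> float | None:
        """The flicker fusion threshold: 90%-"steady" point (None if the
        fitted curve cannot attain 0.90)."""
        try:
            return self.threshold_at(reference.FUSION_CRITERION_P)
        except ValueError:
            return None

    def threshold_ci(self, p: float = reference.FUSION_CRITERION_P,
                     level: float = 0.95) -> tuple[float, float]:
        """Posterior credible interval of the criterion threshold."""
        a = self.model.alpha_grid[:, None, None]
        b = self.model.beta_grid[None, :, None]
        lam = self.model.lapse_grid[None, None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            arg = (p - lam / 2.0) / (1.0 - lam)
            thr = a + np.where((arg > 0) & (arg < 1),
                               np.log(arg / (1.0 - arg)), np.nan) / b
        ok = np.isfinite(thr)
        w = self.posterior[ok]
        if w.sum() == 0:
            return (float("nan"), float("nan"))
        order = np.argsort(thr[ok])
        cdf = np.cumsum(w[order]) / w.sum()
        vals = thr[ok][order]
        lo = vals[np.searchsorted(cdf, (1 - level) / 2)]
        hi = vals[min(np.searchsorted(cdf, 1 - (1 - level) / 2), len(vals) - 1)]
        return float(lo), float(hi)

    # -- reporting -----------------------------------------------------------

    def observed_proportions(self) -> pd.DataFrame:
        m = self.model
        return pd.DataFrame({
            "frequency_hz": m.frequencies,
            "n_steady": m.n_steady.astype(int),
            "n_total": m.n_total.astype(int),
            "prop_steady": m.n_steady / m.n_total,
            "fitted_prop_steady": self.predict(m.frequencies),
        })

    def summary_dict(self) -> dict:
        a_ci = self.credible_interval("alpha")
        b_ci = self.credible_interval("beta")
        thr = self.fusion_threshold_90
        t_ci = self.threshold_ci() if thr is not None else (None, None)
        return {
            "alpha_hz": self.alpha, "alpha_ci95": list(a_ci),
            "beta_per_hz": self.beta, "beta_ci95": list(b_ci),
            "lapse": self.lapse, "lapse_mode": self.model.lapse_mode,
            "fusion_threshold_90_hz": thr,
            "fusion_threshold_ci95": list(t_ci),
            "degenerate": self.degenerate,
            "mean_mode_disagree": self.mean_mode_disagree,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)

    def summary(self) -> str:
        d = self.summary_dict()
        thr = d["fusion_threshold_90_hz"]
        lines = [
            "Psychometric fit (P('steady') vs flicker frequency)",
            f"  alpha  {d['alpha_hz']:8.2f} Hz   95% CI [{d['alpha_ci95'][0]:.2f}, {d['alpha_ci95'][1]:.2f}]",
            f"  beta   {d['beta_per_hz']:8.3f} /Hz  95% CI [{d['beta_ci95'][0]:.3f}, {d['beta_ci95'][1]:.3f}]",
            f"  lapse  {d['lapse']:8.3f}      ({d['lapse_mode']})",
            f"  fusion threshold (90% steady): "
            + ("unattainable" if thr is None else f"{thr:.2f} Hz"),
        ]
        if self.degenerate:
            lines.append("  WARNING: degenerate fit (identical responses everywhere)")
        return "\n".join(lines)
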