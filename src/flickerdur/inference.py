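"""Group-level statistics for the duration-bias table.

Covers the study's inferential toolkit: one-tailed paired t-tests of each
frequency's duration bias against the quasi-static reference frequency with
Bonferroni–Holm correction, one-sample JZS Bayes factors (BF01, the ratio
of evidence for the null over the alternative), a within-subject one-way
ANOVA with orthogonal polynomial (linear/cubic) contrasts, per-participant
classification of frequencies into three ranges relative to the fusion and
evoked-response thresholds, and the between/within-frequency correlation
decomposition (raw pooled Pearson r versus r after z-scoring the predictor
separately within each frequency, which removes all between-frequency
variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "paired_t_onetailed",
    "holm_adjust",
    "jzs_bf01",
    "AnovaResult",
    "rm_anova_contrasts",
    "classify_ranges",
    "CorrelationResult",
    "within_frequency_correlation",
    "reference_comparison_table",
]


@dataclass
class TestResult:
    """Per-frequency comparison against the reference frequency."""

    frequency: float
    mean_bias: float
    t_stat: float
    df: int
    p_raw: float
    p_holm: float | None
    bayes_factor_01: float
    n: int


def paired_t_onetailed(x, y) -> tuple[float, int, float]:
    """Paired t-test, one-tailed for x > y (overestimation direction).

    Returns ``(t, df, p)``. Raises on zero variance of the differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            # identical vectors: no evidence either way
            return 0.0, len(d) - 1, 0.5
        raise ValueError("differences have zero variance")
    res = stats.ttest_rel(x, y, alternative="greater")
    return float(res.statistic), int(res.df), float(res.pvalue)


def holm_adjust(p_values) -> np.ndarray:
    """Bonferroni–Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]


def jzs_bf01(t: float, n: int, scale_r: float = 1.0) -> float:
    """One-sample JZS Bayes factor BF01 = P(data|H0) / P(data|H1).

    H1 places a Cauchy(0, ``scale_r``) prior on the standardized effect
    size, equivalent to a scaled inverse-chi² mixture over the variance
    ratio g; the marginal likelihood is computed by adaptive quadrature of

        BF10 = ∫₀^∞ (1+ng)^{-1/2} [(1+t²/ν) / (1+t²/((1+ng)ν))]^{(ν+1)/2}
               π(g; r) dg,

    with ν = n−1 and π(g; r) = r (2π)^{-1/2} g^{-3/2} exp(−r²/(2g)).
    Values below ~1/3 favor the alternative, above ~3 the null.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if scale_r <= 0:
        raise ValueError("scale_r must be positive")
    nu = n - 1
    t2 = float(t) ** 2

    def integrand(g: float) -> float:
        # likelihood ratio vs H0 folded in to keep the integrand O(1)
        dlog = (-0.5 * np.log1p(n * g)
                + 0.5 * (nu + 1) * (np.log1p(t2 / nu)
                                    - np.log1p(t2 / ((1.0 + n * g) * nu))))
        prior = scale_r / np.sqrt(2.0 * np.pi) * g ** -1.5 * np.exp(
            -scale_r**2 / (2.0 * g))
        return float(np.exp(dlog) * prior)

    bf10, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    if not np.isfinite(bf10) or bf10 <= 0 or err > 1e-6 * max(bf10, 1.0):
        raise ArithmeticError(
            f"Bayes-factor quadrature did not converge (value={bf10}, err={err})"
        )
    return 1.0 / bf10


@dataclass
class ContrastResult:
    name: str
    weights: np.ndarray
    F: float
    df: tuple[int, int]
    partial_eta_sq: float
    p: float


@dataclass
class AnovaResult:
    F: float
    df: tuple[int, int]
    p: float
    partial_eta_sq: float
    ss_levels: float
    ss_error: float
    ss_subjects: float
    contrasts: dict[str, ContrastResult] = field(default_factory=dict)


def _orthogonal_poly_weights(k: int, max_degree: int) -> np.ndarray:
    """Orthonormal polynomial contrast weights on equally spaced level ranks."""
    x = np.arange(k, dtype=float)
    V = np.vander(x, max_degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    return Q[:, 1:].T  # drop the constant column; rows: linear, quadratic, ...


def rm_anova_contrasts(matrix, degrees: tuple[int, ...] = (1, 3)) -> AnovaResult:
    """One-way within-subject ANOVA on a participants × levels matrix.

    Levels are assumed ordered (ascending frequency). Polynomial contrasts
    use orthogonal weights on equally spaced level ranks; each contrast is
    tested with F(1, n−1) on the per-participant contrast scores. No
    sphericity correction is applied (uncorrected dfs are reported).
    """
    y = np.asarray(matrix, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("matrix must be participants x >=2 levels")
    if np.any(~np.isfinite(y)):
        raise ValueError("matrix contains missing values; drop cases listwise first")
    n, k = y.shape
    grand = y.mean()
    subj_means = y.mean(axis=1)
    level_means = y.mean(axis=0)
    ss_total = float(((y - grand) ** 2).sum())
    ss_subj = float(k * ((subj_means - grand) ** 2).sum())
    ss_lvl = float(n * ((level_means - grand) ** 2).sum())
    ss_err = ss_total - ss_subj - ss_lvl
    df_lvl, df_err = k - 1, (n - 1) * (k - 1)
    tol = 1e-12 * (abs(ss_total) + 1e-30)
    if ss_err <= tol:
        F = 0.0 if ss_lvl <= tol else float("inf")
    else:
        F = (ss_lvl / df_lvl) / (ss_err / df_err)
    p = float(stats.f.sf(F, df_lvl, df_err))
    result = AnovaResult(
        F=float(F), df=(df_lvl, df_err), p=p,
        partial_eta_sq=ss_lvl / (ss_lvl + ss_err) if (ss_lvl + ss_err) > 0 else 0.0,
        ss_levels=ss_lvl, ss_error=ss_err, ss_subjects=ss_subj,
    )
    names = {1: "linear", 2: "quadratic", 3: "cubic", 4: "quartic"}
    max_deg = max(degrees)
    if max_deg > k - 1:
        raise ValueError(f"degree {max_deg} contrast undefined with {k} levels")
    W = _orthogonal_poly_weights(k, max_deg)
    for d in degrees:
        w = W[d - 1]
        scores = y @ w
        mean_l, var_l = scores.mean(), scores.var(ddof=1)
        if var_l == 0:
            Fc, pc = 0.0, 1.0
        else:
            Fc = n * mean_l**2 / var_l
            pc = float(stats.f.sf(Fc, 1, n - 1))
        result.contrasts[names.get(d, f"degree{d}")] = ContrastResult(
            name=names.get(d, f"degree{d}"), weights=w, F=float(Fc),
            df=(1, n - 1), partial_eta_sq=float(Fc / (Fc + (n - 1))), p=pc,
        )
    return result


def classify_ranges(fusion_thr: float, ssvep_thr: float | None,
                    frequencies) -> tuple[np.ndarray, bool]:
    """Label each frequency 1, 2, or 3 relative to the observer's thresholds.

    1: perceived as flicker (f ≤ fusion threshold); 2: not perceived but
    still evoking a tagged response (fusion < f ≤ evoked-response
    threshold); 3: beyond both. A missing evoked-response threshold sends
    everything above the fusion threshold to range 3. Returns
    ``(labels, inverted)`` where ``inverted`` flags the atypical case of the
    fusion threshold exceeding the evoked-response threshold (labels still
    partition the list: range 2 is then empty).
    """
    f = np.asarray(frequencies, dtype=float)
    labels = np.full(f.shape, 3, dtype=int)
    labels[f <= fusion_thr] = 1
    inverted = False
    if ssvep_thr is not None:
        inverted = bool(ssvep_thr < fusion_thr)
        labels[(f > fusion_thr) & (f <= ssvep_thr)] = 2
    return labels, inverted


@dataclass
class CorrelationResult:
    r_raw: float
    p_raw: float
    r_z: float
    p_z: float
    n_rows: int
    dropped_groups: list = field(default_factory=list)
    mean_within_group_r: float | None = None


def within_frequency_correlation(x, y, group) -> CorrelationResult:
    """Pooled correlation of a predictor with bias, raw and within-frequency.

    The raw variant pools all (participant, frequency) rows. The z variant
    standardizes the predictor separately within each frequency (removing
    all between-frequency variance) before pooling; groups with zero
    predictor variance are dropped from it with a warning. The mean of the
    per-group correlations is reported as a sensitivity check that does not
    treat rows across frequencies as exchangeable.
    """
    df = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float),
                       "g": np.asarray(group)}).dropna()
    counts = df.groupby("g").size()
    if (counts >= 3).sum() < 2:
        raise ValueError("need at least 2 groups with at least 3 rows each")
    r_raw, p_raw = stats.pearsonr(df["x"], df["y"])

    dropped = []
    zparts = []
    within_rs = []
    for g, sub in df.groupby("g"):
        sd = sub["x"].std(ddof=0)
        if sd < 1e-12 or len(sub) < 3:
            dropped.append(g)
            continue
        z = (sub["x"] - sub["x"].mean()) / sd
        zparts.append(pd.DataFrame({"x": z, "y": sub["y"]}))
        within_rs.append(float(np.corrcoef(sub["x"], sub["y"])[0, 1]))
    if dropped:
        warnings.warn(f"groups dropped from z-scored correlation: {dropped}")
    if len(zparts) < 2:
        raise ValueError("too few groups with predictor variance for z-scoring")
    zdf = pd.concat(zparts)
    r_z, p_z = stats.pearsonr(zdf["x"], zdf["y"])
    return CorrelationResult(
        r_raw=float(r_raw), p_raw=float(p_raw), r_z=float(r_z), p_z=float(p_z),
        n_rows=len(df), dropped_groups=dropped,
        mean_within_group_r=float(np.mean(within_rs)) if within_rs else None,
    )


def reference_comparison_table(
    bias: pd.DataFrame,
    reference_frequency: float,
    scale_r: float = 1.0,
) -> list[TestResult]:
    """Per-frequency one-tailed tests of bias against the reference frequency.

    ``bias`` is a long table (participant_id, frequency_hz, bias_s) with NaN
    for excluded estimates. Pairing is pairwise per frequency (participants
    missing either cell drop from that frequency only); Holm correction
    spans the non-reference frequencies.
    """
    wide = bias.pivot_table(index="participant_id", columns="frequency_hz",
                            values="bias_s", dropna=False)
    if reference_frequency not in wide.columns:
        raise ValueError(f"reference frequency {reference_frequency} missing")
    ref = wide[reference_frequency]
    results: list[TestResult] = []
    for f in sorted(c for c in wide.columns if c != reference_frequency):
        pair = pd.concat([wide[f], ref], axis=1, keys=["x", "y"]).dropna()
        if len(pair) < 3:
            # too few complete pairs after outlier removal: untestable cell
            results.append(TestResult(
                frequency=float(f),
                mean_bias=float(pair["x"].mean()) if len(pair) else float("nan"),
                t_stat=float("nan"), df=max(len(pair) - 1, 0),
                p_raw=float("nan"), p_holm=None,
                bayes_factor_01=float("nan"), n=len(pair),
            ))
            continue
        t, df_, p = paired_t_onetailed(pair["x"].to_numpy(), pair["y"].to_numpy())
        results.append(TestResult(
            frequency=float(f), mean_bias=float(pair["x"].mean()),
            t_stat=t, df=df_, p_raw=p, p_holm=None,
            bayes_factor_01=jzs_bf01(t, len(pair), scale_r=scale_r),
            n=len(pair),
        ))
    testable = [r for r in results if np.isfinite(r.p_raw)]
    adj = holm_adjust([r.p_raw for r in testable])
    for r, a in zip(testable, adj):
        r.p_holm = float(a)
    return results
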