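"""Repeated-measures statistics, power analysis, FDR maps and bootstrap.

The study design is two-level within-subject (every participant measured
once meditating and once mind-wandering), so the repeated-measures ANOVA
reduces to the classical subject x condition decomposition with
``F(1, n-1)`` equal to the square of the paired t statistic. Effect size
is partial eta squared, ``SS_state / (SS_state + SS_error)``, converted
to Cohen's f by ``f = sqrt(eta2 / (1 - eta2))``.

Achieved power follows the GPower "ANOVA: repeated measures, within
factors" convention: noncentrality ``lambda = f^2 * N * m * eps /
(1 - rho)`` with ``m`` repeated measures, correlation among measures
``rho`` (0.5 by default) and nonsphericity ``eps`` (1 for two levels);
power is the upper tail of the noncentral F beyond the central-F critical
value.

Channel x band contrast maps use paired two-tailed t-tests with
Benjamini-Hochberg FDR across all cells jointly, and per-frequency
difference curves use a percentile bootstrap over participants with the
(k+1)/(B+1) two-sided p-value convention, again BH-corrected across bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RmAnovaResult",
    "PowerAnalysisSpec",
    "rm_anova_two_level",
    "cohens_f_from_eta2",
    "rm_power",
    "cell_tests",
    "bootstrap_band_difference",
    "covariate_correlation",
]


@dataclass
class RmAnovaResult:
    """Two-level within-subject ANOVA summary."""

    F: float
    df1: int
    df2: int
    p: float
    partial_eta2: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n: int

    def format_line(self, label_a: str = "A", label_b: str = "B") -> str:
        return (
            f"F({self.df1}, {self.df2}) = {self.F:.2f}, p = {self.p:.3f}, "
            f"partial eta2 = {self.partial_eta2:.2f}; "
            f"{label_a}: M = {self.mean_a:.2f}, SD = {self.sd_a:.2f}; "
            f"{label_b}: M = {self.mean_b:.2f}, SD = {self.sd_b:.2f}"
        )


def rm_anova_two_level(a, b) -> RmAnovaResult:
    """Repeated-measures ANOVA for one within factor with two levels.

    ``a`` and ``b`` are the paired per-participant values of the two
    conditions (same order). F = MS_state / MS_error from the subject x
    condition decomposition; equals the squared paired t statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired inputs must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("paired inputs must be finite (no missing cells)")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    grand = (a.mean() + b.mean()) / 2.0
    subject_means = (a + b) / 2.0
    ss_state = n * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
    resid_a = a - subject_means - (a.mean() - grand)
    resid_b = b - subject_means - (b.mean() - grand)
    ss_error = float(np.sum(resid_a**2) + np.sum(resid_b**2))
    df1, df2 = 1, n - 1
    if ss_error == 0.0:
        f_stat = 0.0 if ss_state == 0.0 else np.inf
    else:
        f_stat = (ss_state / df1) / (ss_error / df2)
    p = float(sps.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0
    denom = ss_state + ss_error
    eta2 = float(ss_state / denom) if denom > 0 else 0.0
    return RmAnovaResult(
        F=float(f_stat), df1=df1, df2=df2, p=p, partial_eta2=eta2,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)), n=n,
    )


def cohens_f_from_eta2(eta2: float) -> float:
    """Cohen's f = sqrt(eta2 / (1 - eta2)); eta2 must be in [0, 1)."""
    if not 0.0 <= eta2 < 1.0:
        raise ValueError(f"eta2 must be in [0, 1), got {eta2}")
    return float(np.sqrt(eta2 / (1.0 - eta2)))


@dataclass
class PowerAnalysisSpec:
    """Design parameters for repeated-measures power analysis."""

    f: float
    alpha: float = 0.05
    n_total: int = 28
    n_groups: int = 2
    n_measurements: int = 2
    corr_among_measures: float = 0.5
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_total <= self.n_groups:
            raise ValueError("n_total must exceed n_groups")
        if not -1.0 < self.corr_among_measures < 1.0:
            raise ValueError("correlation among measures must be in (-1, 1)")
        if self.f < 0:
            raise ValueError("Cohen's f must be >= 0")


def rm_power(spec: PowerAnalysisSpec) -> float:
    """Achieved power of the within-factors repeated-measures F test."""
    m, g = spec.n_measurements, spec.n_groups
    df1 = (m - 1) * spec.epsilon
    df2 = (spec.n_total - g) * (m - 1) * spec.epsilon
    if df2 <= 0:
        raise ValueError("error degrees of freedom must be positive")
    lam = (
        spec.f**2 * spec.n_total * m * spec.epsilon
        / (1.0 - spec.corr_among_measures)
    )
    f_crit = sps.f.isf(spec.alpha, df1, df2)
    if lam == 0.0:
        return float(spec.alpha)
    return float(sps.ncf.sf(f_crit, df1, df2, lam))


def cell_tests(differences: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Paired t-tests per (channel, band) cell with joint BH correction.

    ``differences`` is participants x cells (columns may be a MultiIndex
    of (channel, band)); each column holds per-participant condition
    differences. Zero-variance cells get p = 1 with a warning. Returns a
    table with mean difference, t, raw p, BH-adjusted p and a
    significance flag at ``alpha``.
    """
    if len(differences) < 3:
        raise ValueError("need at least 3 participants")
    values = differences.to_numpy(dtype=float)
    n = values.shape[0]
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    t_stats = np.zeros(values.shape[1])
    p_raw = np.ones(values.shape[1])
    nonzero = sds > 0
    if (~nonzero).any():
        warnings.warn(
            f"{(~nonzero).sum()} zero-variance cell(s); p set to 1",
            stacklevel=2,
        )
    t_stats[nonzero] = means[nonzero] / (sds[nonzero] / np.sqrt(n))
    p_raw[nonzero] = 2.0 * sps.t.sf(np.abs(t_stats[nonzero]), n - 1)
    reject, p_adj, *_ = multipletests(p_raw, alpha=alpha, method="fdr_bh")
    out = pd.DataFrame(
        {
            "mean_difference": means,
            "t": t_stats,
            "p": p_raw,
            "p_fdr": p_adj,
            "significant": reject,
        },
        index=differences.columns,
    )
    return out


def bootstrap_band_difference(
    difference_spectra: pd.DataFrame,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Percentile bootstrap of the mean difference at each frequency bin.

    ``difference_spectra`` is participants x frequency bins (columns are
    the frequencies). Participants are resampled with replacement; the
    two-sided p per bin uses the (k+1)/(B+1) convention; BH correction is
    applied across bins. Deterministic for a fixed seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    values = difference_spectra.to_numpy(dtype=float)
    n, n_bins = values.shape
    if n < 3:
        raise ValueError("need at least 3 participants")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = values[idx].mean(axis=1)  # n_boot x n_bins
    k_le = (boot_means <= 0).sum(axis=0)
    k_ge = (boot_means >= 0).sum(axis=0)
    p_raw = np.minimum(
        1.0, 2.0 * (np.minimum(k_le, k_ge) + 1) / (n_boot + 1)
    )
    reject, p_adj, *_ = multipletests(p_raw, alpha=alpha, method="fdr_bh")
    lo = np.quantile(boot_means, alpha / 2, axis=0)
    hi = np.quantile(boot_means, 1 - alpha / 2, axis=0)
    return pd.DataFrame(
        {
            "freq_hz": np.asarray(difference_spectra.columns, dtype=float),
            "mean_difference": values.mean(axis=0),
            "ci_low": lo,
            "ci_high": hi,
            "p": p_raw,
            "p_fdr": p_adj,
            "significant": reject,
        }
    )


def covariate_correlation(values, covariate) -> tuple[float, float]:
    """Pearson r and two-tailed p between a measure and a covariate."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need paired 1-D vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
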