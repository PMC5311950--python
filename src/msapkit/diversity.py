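"""Diversity and group-comparison statistics for binary MSAP markers.

Per-locus Shannon diversity over the two-state (methylated/unmethylated or
band present/absent) frequencies quantifies epigenetic vs genetic
variation; the MSL and NML per-locus index vectors are compared with the
Wilcoxon rank-sum test.  Population methylation levels are compared with
the classic battery: one-way ANOVA (replaced by the Welch F when the
Shapiro-Wilk test on residuals rejects normality or is uninterpretable),
Kruskal-Wallis for medians, and Tukey-Kramer / Mann-Whitney post-hoc
pairwise tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.oneway import anova_oneway

from .io_formats import EmptyAnalysisError


@dataclass
class ShannonProfile:
    """Per-locus Shannon diversity indices for one marker partition.

    ``values[j]`` is I_j = -(p ln p + (1-p) ln(1-p)) in nats, with p the
    frequency of state 1 among non-missing entries at locus j; for binary
    loci I_j is in [0, ln 2].
    """

    values: np.ndarray
    loci: list[str]
    partition: str  # "MSL" or "NML"
    base: float = np.e

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.values.size else np.nan

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.values.size > 1 else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"locus": self.loci, "partition": self.partition, "shannon_i": self.values})


@dataclass
class StatsReport:
    """The group mean/median comparison battery on methylation levels.

    ``means_test`` is either classic ANOVA or the Welch F, chosen by the
    Shapiro-Wilk check on ANOVA residuals; both post-hoc tables are
    symmetric DataFrames indexed by population.
    """

    shapiro_statistic: float
    shapiro_p: float
    shapiro_interpretable: bool
    means_test: str                      # "anova" or "welch"
    means_F: float
    means_df: tuple[float, float]
    means_p: float
    kruskal_H: float
    kruskal_Hc: float
    kruskal_p: float
    tukey_q: pd.DataFrame
    tukey_p: pd.DataFrame
    mannwhitney_p: pd.DataFrame
    outliers_removed: list[str] = field(default_factory=list)
    group_summary: pd.DataFrame | None = None


def shannon_per_locus(
    matrix: np.ndarray,
    loci: list[str] | None = None,
    partition: str = "MSL",
    base: float = np.e,
) -> ShannonProfile:
    """Shannon diversity index per locus on a binary matrix with missing.

    p is computed over non-missing entries only; loci with all entries
    missing are excluded with a warning.  0*log 0 is taken as 0.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] == 0:
        raise EmptyAnalysisError("shannon_per_locus needs at least one locus")
    loci = list(loci) if loci is not None else [f"L{j}" for j in range(m.shape[1])]
    n_obs = np.sum(~np.isnan(m), axis=0)
    empty = n_obs == 0
    if empty.any():
        warnings.warn(
            f"excluding {int(empty.sum())} all-missing loci from Shannon profile",
            stacklevel=2,
        )
        m = m[:, ~empty]
        loci = [l for l, e in zip(loci, empty) if not e]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(m, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0) + np.where(p < 1, (1 - p) * np.log1p(-p), 0.0)
    values = -terms / np.log(base)
    return ShannonProfile(values=values, loci=loci, partition=partition, base=base)


def wilcoxon_rank_sum(
    x: np.ndarray, y: np.ndarray, continuity: bool = True
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test with tie correction.

    Returns ``(W, p)`` where W is the rank-sum statistic of ``x`` minus
    its minimum (the Mann-Whitney U of ``x``), matching the W reported by
    R's ``wilcox.test``; p uses the normal approximation with tie
    correction and, by default, the continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EmptyAnalysisError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both samples; p set to 1", stacklevel=2)
        return float(x.size * y.size / 2), 1.0
    res = stats.mannwhitneyu(
        x, y, use_continuity=continuity, alternative="two-sided", method="asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def _tukey_kramer(
    groups: dict[str, np.ndarray]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tukey-Kramer pairwise Q statistics and studentized-range p-values."""
    labels = list(groups)
    k = len(labels)
    n_total = sum(v.size for v in groups.values())
    df_w = n_total - k
    ss_w = sum(np.sum((v - v.mean()) ** 2) for v in groups.values())
    ms_w = ss_w / df_w if df_w > 0 else np.nan
    q = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    p = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for a, b in itertools.combinations(labels, 2):
        xa, xb = groups[a], groups[b]
        se = np.sqrt(ms_w / 2 * (1 / xa.size + 1 / xb.size))
        qq = abs(xa.mean() - xb.mean()) / se if se > 0 else 0.0
        pp = float(stats.studentized_range.sf(qq, k, df_w)) if df_w > 0 else np.nan
        q.loc[a, b] = q.loc[b, a] = qq
        p.loc[a, b] = p.loc[b, a] = min(1.0, pp)
    return q, p


def _kruskal_uncorrected(samples: list[np.ndarray]) -> float:
    """Kruskal-Wallis H without the tie correction (average ranks)."""
    pooled = np.concatenate(samples)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for s in samples:
        r = ranks[start : start + s.size]
        h += r.sum() ** 2 / s.size
        start += s.size
    return 12 / (n * (n + 1)) * h - 3 * (n + 1)


def group_battery(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    outliers_removed: list[str] | None = None,
    alpha_shapiro: float = 0.05,
) -> StatsReport:
    """Compare per-individual methylation levels across populations.

    Runs classic one-way ANOVA with a Shapiro-Wilk normality check on its
    residuals; if the check rejects at ``alpha_shapiro`` or is not
    interpretable (statistic outside [0,1] or p not computable), the
    Welch F test for unequal variances replaces ANOVA.  Kruskal-Wallis
    (with tie-corrected Hc) compares medians.  Post-hoc: Tukey-Kramer on
    means and pairwise Mann-Whitney on medians.  ``outliers_removed``
    lists individual IDs (index labels of ``values``) excluded before all
    tests — exclusion is always explicit, never automatic.  Groups left
    with fewer than 2 members are dropped from post-hoc tables with a
    warning.
    """
    v = pd.Series(np.asarray(values, dtype=float)) if not isinstance(values, pd.Series) else values.astype(float)
    g = pd.Series(np.asarray(groups, dtype=object), index=v.index)
    keep = v.notna()
    if outliers_removed:
        keep &= ~v.index.isin(outliers_removed)
    v, g = v[keep], g[keep]

    group_arrays = {str(label): sub.to_numpy() for label, sub in v.groupby(g, sort=False)}
    small = [label for label, arr in group_arrays.items() if arr.size < 2]
    if small:
        warnings.warn(f"groups of size < 2 excluded from post-hoc tests: {small}", stacklevel=2)
    usable = {label: arr for label, arr in group_arrays.items() if arr.size >= 2}
    if len(usable) < 2:
        raise EmptyAnalysisError("group battery needs >= 2 groups with >= 2 members")
    samples = list(usable.values())
    labels = list(usable)
    n_total = sum(s.size for s in samples)
    k = len(samples)

    anova_F, anova_p = stats.f_oneway(*samples)
    residuals = np.concatenate([s - s.mean() for s in samples])
    try:
        sh_stat, sh_p = stats.shapiro(residuals)
        interpretable = bool(0 <= sh_stat <= 1 and np.isfinite(sh_p))
    except Exception:  # degenerate residuals
        sh_stat, sh_p, interpretable = np.nan, np.nan, False

    if not interpretable or sh_p < alpha_shapiro:
        welch = anova_oneway(samples, use_var="unequal", welch_correction=True)
        means_test = "welch"
        means_F = float(welch.statistic)
        means_df = (float(welch.df_num), float(welch.df_denom))
        means_p = float(welch.pvalue)
    else:
        means_test = "anova"
        means_F = float(anova_F)
        means_df = (float(k - 1), float(n_total - k))
        means_p = float(anova_p)

    kw_stat, kw_p = stats.kruskal(*samples)
    h_uncorrected = _kruskal_uncorrected(samples)

    tukey_q, tukey_p = _tukey_kramer(usable)
    mw = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for a, b in itertools.combinations(labels, 2):
        res = stats.mannwhitneyu(usable[a], usable[b], use_continuity=True, alternative="two-sided")
        mw.loc[a, b] = mw.loc[b, a] = float(res.pvalue)

    summary = pd.DataFrame(
        {
            "population": labels,
            "n": [usable[l].size for l in labels],
            "mean": [usable[l].mean() for l in labels],
            "median": [float(np.median(usable[l])) for l in labels],
            "sd": [usable[l].std(ddof=1) for l in labels],
        }
    )
    return StatsReport(
        shapiro_statistic=float(sh_stat),
        shapiro_p=float(sh_p),
        shapiro_interpretable=interpretable,
        means_test=means_test,
        means_F=means_F,
        means_df=means_df,
        means_p=means_p,
        kruskal_H=float(h_uncorrected),
        kruskal_Hc=float(kw_stat),
        kruskal_p=float(kw_p),
        tukey_q=tukey_q,
        tukey_p=tukey_p,
        mannwhitney_p=mw,
        outliers_removed=list(outliers_removed or []),
        group_summary=summary,
    )
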