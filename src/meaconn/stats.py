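"""Basal activity metrics and the hypothesis-testing layer.

Routing convention: group normality is assessed with the Shapiro-Wilk test
(alpha 0.05). Normal data go to Welch's t-test (2 groups) or one-way ANOVA
with Tukey's HSD (more); otherwise the two-sided Wilcoxon rank-sum test
(exact for combined n <= 20) or Kruskal-Wallis with Dunn's post hoc and
Benjamini-Hochberg adjustment. Groups too small for Shapiro (n < 3) route to
the nonparametric branch with a warning.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .core import Recording, SpikeTrain

logger = logging.getLogger("meaconn")

SHAPIRO_ALPHA = 0.05
EXACT_WILCOXON_MAX_N = 20


# ---------------------------------------------------------------------------
# basal activity


@dataclass
class BasalActivity:
    """Per-train activity summary: spike count, mean ISI, burst frequency."""

    electrode_id: str
    number_of_spikes: int
    mean_isi: float | None
    burst_frequency: float
    duration: float


def detect_bursts(
    times: np.ndarray, max_isi: float = 0.100, min_spikes: int = 5
) -> list[tuple[int, int]]:
    """Maximal runs of >= min_spikes spikes whose successive ISIs are all
    <= max_isi (the max-interval method). Returns (start, stop) index pairs,
    stop exclusive."""
    t = np.asarray(times, dtype=float)
    if t.size < min_spikes:
        return []
    short = np.diff(t) <= max_isi
    bursts = []
    i = 0
    while i < short.size:
        if short[i]:
            j = i
            while j < short.size and short[j]:
                j += 1
            if (j - i + 1) >= min_spikes:
                bursts.append((i, j + 1))
            i = j
        i += 1
    return bursts


def basal_metrics(
    train: SpikeTrain, max_isi: float = 0.100, min_spikes_in_burst: int = 5
) -> BasalActivity:
    """Spike count, mean inter-spike interval and burst frequency for a train."""
    n = len(train)
    mean_isi = float(np.mean(np.diff(train.times))) if n >= 2 else None
    bursts = detect_bursts(train.times, max_isi, min_spikes_in_burst)
    return BasalActivity(
        electrode_id=train.electrode_id,
        number_of_spikes=n,
        mean_isi=mean_isi,
        burst_frequency=len(bursts) / train.duration,
        duration=train.duration,
    )


def mean_firing_rate(recording: Recording) -> float:
    """Whole-array mean rate: total spikes / (electrodes x duration)."""
    if recording.duration <= 0:
        raise ValueError("recording duration must be > 0")
    return recording.total_spikes / (recording.n_electrodes * recording.duration)


# ---------------------------------------------------------------------------
# normalisation and outlier handling


def batch_normalize(values, batch_labels) -> np.ndarray:
    """Divide each value by the mean of its batch; per-batch output mean is 1."""
    v = np.asarray(values, dtype=float)
    labels = np.asarray(batch_labels)
    if v.shape != labels.shape:
        raise ValueError("values and batch_labels must have the same length")
    out = np.empty_like(v)
    for lab in np.unique(labels):
        mask = labels == lab
        m = v[mask].mean()
        if m == 0:
            raise ValueError(f"batch {lab!r} has zero mean; cannot normalise")
        out[mask] = v[mask] / m
    return out


def iqr_outlier_filter(values) -> tuple[np.ndarray, np.ndarray]:
    """IQR proximity rule: drop values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation (numpy default, R type 7). Fewer than
    4 values pass through untouched with a warning. Returns (kept, removed)
    in input order.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        logger.warning("iqr_outlier_filter: fewer than 4 values, passing through")
        return v.copy(), np.array([], dtype=float)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (v >= lo) & (v <= hi)
    return v[keep], v[~keep]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    return scipy.stats.false_discovery_control(np.asarray(pvalues, dtype=float))


def significance_stars(p: float) -> str:
    """Star convention: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# hypothesis tests


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test (Mann-Whitney U form).

    Exact null distribution for combined n <= EXACT_WILCOXON_MAX_N and no
    ties; normal approximation with continuity correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = (
        "exact" if (pooled.size <= EXACT_WILCOXON_MAX_N and not has_ties) else "asymptotic"
    )
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def dunn_test(groups: list[np.ndarray]) -> list[dict]:
    """Dunn's z tests on mean ranks for all group pairs, tie-corrected,
    with Benjamini-Hochberg adjustment across the pairs."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = scipy.stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    stops = np.cumsum(sizes)
    starts = np.concatenate(([0], stops[:-1]))
    mean_ranks = [ranks[s:e].mean() for s, e in zip(starts, stops)]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * scipy.stats.norm.sf(abs(z))
        rows.append({"i": i, "j": j, "z": float(z), "p": float(min(p, 1.0))})
    adj = bh_adjust([r["p"] for r in rows]) if rows else np.array([])
    for r, q in zip(rows, adj):
        r["p_adj"] = float(q)
        r["stars"] = significance_stars(float(q))
    return rows


@dataclass
class TestReport:
    """Outcome of the routed group comparison."""

    test: str
    statistic: float
    pvalue: float
    normal: bool
    shapiro_p: list[float | None]
    posthoc: list[dict] = field(default_factory=list)
    stars: str = "ns"


def hypothesis_tests(groups, group_names=None, alpha: float = SHAPIRO_ALPHA) -> TestReport:
    """Route >= 2 groups through the normality-gated test battery."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("groups must be non-empty")

    shapiro_p: list[float | None] = []
    normal = True
    for g in groups:
        if g.size < 3:
            logger.warning("group of size %d too small for Shapiro; routing nonparametric", g.size)
            shapiro_p.append(None)
            normal = False
        elif np.all(g == g[0]):
            shapiro_p.append(None)
            normal = False
        else:
            p = float(scipy.stats.shapiro(g).pvalue)
            shapiro_p.append(p)
            normal = normal and (p > alpha)

    posthoc: list[dict] = []
    if len(groups) == 2:
        if normal:
            res = scipy.stats.ttest_ind(groups[0], groups[1], equal_var=False)
            test, stat, p = "welch_t", float(res.statistic), float(res.pvalue)
        else:
            stat, p = wilcoxon_rank_sum(groups[0], groups[1])
            test = "wilcoxon_rank_sum"
    else:
        if normal:
            res = scipy.stats.f_oneway(*groups)
            test, stat, p = "anova_oneway", float(res.statistic), float(res.pvalue)
            tk = scipy.stats.tukey_hsd(*groups)
            for i, j in itertools.combinations(range(len(groups)), 2):
                q = float(tk.pvalue[i, j])
                posthoc.append(
                    {"i": i, "j": j, "p": q, "p_adj": q, "stars": significance_stars(q)}
                )
        else:
            pooled = np.concatenate(groups)
            if np.all(pooled == pooled[0]):
                test, stat, p = "kruskal_wallis", 0.0, 1.0
            else:
                res = scipy.stats.kruskal(*groups)
                test, stat, p = "kruskal_wallis", float(res.statistic), float(res.pvalue)
                posthoc = dunn_test(groups)

    if group_names is not None:
        names = list(group_names)
        for row in posthoc:
            row["group_i"] = names[row["i"]]
            row["group_j"] = names[row["j"]]

    return TestReport(
        test=test,
        statistic=stat,
        pvalue=p,
        normal=normal,
        shapiro_p=shapiro_p,
        posthoc=posthoc,
        stars=significance_stars(p),
    )
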