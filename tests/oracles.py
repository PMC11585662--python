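"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately avoid the package's vectorised code paths: everything is
done with plain loops / O(n^2) enumeration so they stay an independent check.
"""

from __future__ import annotations

import numpy as np


def brute_tiling_fraction(times, dt, t_start, t_stop) -> float:
    """Union length of [s-dt, s+dt] tiles via interval merging, per spike."""
    intervals = sorted(
        (max(s - dt, t_start), min(s + dt, t_stop)) for s in np.asarray(times)
    )
    total = 0.0
    cur_lo = cur_hi = None
    for lo, hi in intervals:
        if cur_hi is None or lo > cur_hi:
            if cur_hi is not None:
                total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_hi is not None:
        total += cur_hi - cur_lo
    return total / (t_stop - t_start)


def brute_proportion(a, b, dt) -> float:
    """Fraction of spikes in a within dt of any spike in b, by full scan."""
    a = np.asarray(a)
    b = np.asarray(b)
    hits = 0
    for s in a:
        if np.any(np.abs(b - s) <= dt):
            hits += 1
    return hits / a.size


def brute_sttc(a_times, b_times, dt, t_start, t_stop) -> float:
    """Direct evaluation of the tiling-coefficient formula."""
    ta = brute_tiling_fraction(a_times, dt, t_start, t_stop)
    tb = brute_tiling_fraction(b_times, dt, t_start, t_stop)
    pa = brute_proportion(a_times, b_times, dt)
    pb = brute_proportion(b_times, a_times, dt)

    def term(p, t):
        denom = 1.0 - p * t
        return 1.0 if denom == 0 else (p - t) / denom

    return 0.5 * (term(pa, tb) + term(pb, ta))


def brute_correlogram_counts(a, b, bin_width, half_window):
    """All-pairs signed differences histogram by double loop."""
    n = int(round(half_window / bin_width))
    counts = np.zeros(2 * n + 1, dtype=int)
    for s in np.asarray(a):
        for t in np.asarray(b):
            d = t - s
            if abs(d) <= half_window:
                k = int(np.floor(d / bin_width + 0.5))
                if -n <= k <= n:
                    counts[k + n] += 1
    return counts


def bh_stepup(pvalues):
    """Benjamini-Hochberg step-up adjustment from the defining formula."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return adjusted


def exact_ranksum_pvalue(a, b):
    """Two-sided exact rank-sum p by full enumeration of rank assignments."""
    import itertools

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    import scipy.stats

    ranks = scipy.stats.rankdata(pooled)
    observed = ranks[: a.size].sum()
    n = pooled.size
    mean = a.size * (n + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), a.size):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mean) >= abs(observed - mean) - 1e-12:
            count += 1
    return count / total


def poisson_train(rng, rate, duration):
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, n))
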