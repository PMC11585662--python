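"""Pairwise spike-train connectivity: tiling coefficient, cross-correlogram,
significance-gated conduction delay and propagation speed.

The tiling coefficient for trains A and B with half-window ``dt`` is

    0.5 * [(P_A - T_B) / (1 - P_A * T_B) + (P_B - T_A) / (1 - P_B * T_A)]

where ``P_X`` is the proportion of X's spikes falling within ``dt`` of any
spike of the other train and ``T_X`` is the fraction of the recording window
tiled by the union of ``[s - dt, s + dt]`` intervals around X's spikes.

Cross-correlogram sign convention: differences are ``t_b - t_a``, so a
positive significant delay reads "the first electrode leads the second".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    AnalysisConfig,
    PairwiseResult,
    Recording,
    SpikeTrain,
    UndefinedResultError,
)

logger = logging.getLogger("meaconn")


def tiling_fraction(
    times, dt: float, t_start: float, t_stop: float
) -> float:
    """Fraction of [t_start, t_stop] covered by the union of +/- dt tiles."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        return 0.0
    lo = np.clip(t - dt, t_start, t_stop)
    hi = np.clip(t + dt, t_start, t_stop)
    # tiles are sorted because times are; merge overlapping neighbours
    covered = hi[0] - lo[0]
    run_hi = hi[0]
    for a, b in zip(lo[1:], hi[1:]):
        if a > run_hi:
            covered += b - a
            run_hi = b
        elif b > run_hi:
            covered += b - run_hi
            run_hi = b
    return float(covered / (t_stop - t_start))


def _proportion_tiled(a: np.ndarray, b: np.ndarray, dt: float) -> float:
    """Proportion of spikes in `a` lying within dt of some spike in `b`."""
    idx = np.searchsorted(b, a)
    left = np.where(idx > 0, a - b[np.maximum(idx - 1, 0)], np.inf)
    right = np.where(idx < b.size, b[np.minimum(idx, b.size - 1)] - a, np.inf)
    return float(np.mean(np.minimum(left, right) <= dt))


def sttc(a: SpikeTrain, b: SpikeTrain, dt: float = 0.010) -> float:
    """Spike time tiling coefficient of two trains on a shared window.

    Raises :class:`UndefinedResultError` for empty trains rather than
    silently returning 0. When a term's denominator vanishes (only possible
    for P = T = 1) that term contributes 1, the continuous limit.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if len(a) == 0 or len(b) == 0:
        raise UndefinedResultError("STTC is undefined for empty spike trains")
    if (a.t_start, a.t_stop) != (b.t_start, b.t_stop):
        raise ValueError("trains must share a recording window")

    ta = tiling_fraction(a.times, dt, a.t_start, a.t_stop)
    tb = tiling_fraction(b.times, dt, b.t_start, b.t_stop)
    pa = _proportion_tiled(a.times, b.times, dt)
    pb = _proportion_tiled(b.times, a.times, dt)

    def term(p: float, t: float) -> float:
        denom = 1.0 - p * t
        if denom == 0.0:
            return 1.0
        return (p - t) / denom

    return 0.5 * (term(pa, tb) + term(pb, ta))


@dataclass
class Correlogram:
    """Probability histogram of signed spike-time differences t_b - t_a.

    Bins are centred on multiples of the bin width: bin k covers
    ``[(k - 1/2) * bin, (k + 1/2) * bin)``.
    """

    bin_centers: np.ndarray
    counts: np.ndarray
    bin_width: float

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())

    @property
    def empty(self) -> bool:
        return self.total_count == 0

    @property
    def probabilities(self) -> np.ndarray:
        tot = self.counts.sum()
        if tot == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / tot

    def mirrored(self) -> "Correlogram":
        return Correlogram(
            bin_centers=-self.bin_centers[::-1].copy(),
            counts=self.counts[::-1].copy(),
            bin_width=self.bin_width,
        )


def cross_correlogram(
    a: SpikeTrain,
    b: SpikeTrain,
    bin_width: float = 0.0005,
    half_window: float = 0.010,
) -> Correlogram:
    """Histogram of t_b - t_a over all spike pairs with |difference| within
    the window, normalised to a probability when non-empty."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if half_window < bin_width:
        raise ValueError("half_window must be >= bin_width")
    n = int(round(half_window / bin_width))
    edges = (np.arange(-n, n + 2) - 0.5) * bin_width
    centers = np.arange(-n, n + 1) * bin_width

    ta, tb = a.times, b.times
    if ta.size and tb.size:
        lo = np.searchsorted(tb, ta - half_window, side="left")
        hi = np.searchsorted(tb, ta + half_window, side="right")
        m = hi - lo
        total = int(m.sum())
        if total:
            starts = np.concatenate(([0], np.cumsum(m)[:-1]))
            flat = np.arange(total) + np.repeat(lo - starts, m)
            diffs = tb[flat] - np.repeat(ta, m)
            counts, _ = np.histogram(diffs, bins=edges)
        else:
            counts = np.zeros(centers.size, dtype=int)
    else:
        counts = np.zeros(centers.size, dtype=int)
    return Correlogram(bin_centers=centers, counts=counts, bin_width=bin_width)


def significant_delay(
    correlogram: Correlogram,
    sig_sd: float = 5.0,
    min_count: int = 5,
) -> float | None:
    """Centre of the maximal bin iff the maximum clears mean + sig_sd * SD.

    The SD is the sample standard deviation of the per-bin probabilities,
    maximal bin included. Histograms whose maximal bin holds fewer than
    ``min_count`` events are never significant: with only a handful of
    coincidences per bin the mean + k*SD rule fires on Poisson noise alone.
    Uniform (zero-SD) histograms are never significant. Ties between maximal
    bins resolve to the smallest |delay|, then to the positive delay.
    """
    if correlogram.empty:
        logger.debug("correlogram empty: no significant delay")
        return None
    p = correlogram.probabilities
    mean = float(p.mean())
    sd = float(p.std(ddof=1)) if p.size > 1 else 0.0
    cmax = int(correlogram.counts.max())
    if sd == 0.0 or cmax < min_count:
        return None
    if p.max() <= mean + sig_sd * sd:
        return None
    idx = np.flatnonzero(correlogram.counts == correlogram.counts.max())
    centers = correlogram.bin_centers[idx]
    order = np.lexsort((-np.sign(centers), np.abs(centers)))
    if idx.size > 1:
        logger.warning(
            "tie between %d maximal correlogram bins; choosing delay %.4g s",
            idx.size,
            centers[order[0]],
        )
    return float(centers[order[0]])


def propagation_speed(distance_m: float, delay_s: float) -> float:
    """Propagation speed distance / |delay| in m/s; undefined for zero delay."""
    if distance_m <= 0:
        raise ValueError("distance must be > 0")
    if delay_s == 0:
        raise UndefinedResultError("speed undefined for zero delay")
    return distance_m / abs(delay_s)


def pairwise_table(
    recording: Recording, config: AnalysisConfig | None = None
) -> list[PairwiseResult]:
    """Compute one :class:`PairwiseResult` per unordered active-electrode pair.

    Electrodes with fewer than ``min_spikes_per_electrode`` spikes are
    excluded (and logged). Delay sign follows the e1-leads-e2 convention
    with pairs ordered by grid position (row-major).
    """
    config = config or AnalysisConfig()
    active = [
        e
        for e in recording.grid.electrode_ids
        if e in recording.trains
        and len(recording.trains[e]) >= config.min_spikes_per_electrode
    ]
    excluded = [
        e
        for e in recording.trains
        if len(recording.trains[e]) < config.min_spikes_per_electrode
    ]
    if excluded:
        logger.info(
            "%d electrode(s) below the %d-spike floor excluded",
            len(excluded),
            config.min_spikes_per_electrode,
        )
    if len(active) < 2:
        logger.warning("fewer than 2 active electrodes: empty pairwise table")
        return []

    results: list[PairwiseResult] = []
    grid = recording.grid
    for i, e1 in enumerate(active):
        for e2 in active[i + 1 :]:
            a, b = recording.trains[e1], recording.trains[e2]
            value = sttc(a, b, dt=config.dt_sttc)
            cg = cross_correlogram(
                a, b, bin_width=config.cc_bin, half_window=config.cc_half_window
            )
            delay = significant_delay(
                cg, sig_sd=config.sig_sd, min_count=config.sig_min_count
            )
            dist_pitch = grid.distance_pitch(e1, e2)
            dist_m = grid.distance_m(e1, e2)
            speed = None
            if delay is not None and delay != 0 and dist_m > 0:
                speed = propagation_speed(dist_m, delay)
            results.append(
                PairwiseResult(
                    e1=e1,
                    e2=e2,
                    sttc=value,
                    significant=delay is not None,
                    delay_s=delay,
                    distance_pitch=dist_pitch,
                    distance_m=dist_m,
                    speed_mps=speed,
                    correlogram=cg,
                )
            )
    return results
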