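"""Adaptive-threshold spike detection on raw voltage traces.

The noise scale is estimated robustly (median absolute deviation / 0.6745)
over rolling windows, and events are excursions of |voltage| beyond
``k`` times the local noise SD (k = 6 by default). Both polarities are
detected; an event is stamped at its absolute-extremum sample and excursions
closer than the refractory interval are merged into one event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SpikeTrain

MAD_TO_SD = 1.0 / 0.6745  # Gaussian consistency factor

MIN_WINDOW_SAMPLES = 32


@dataclass
class VoltageTrace:
    """A regularly sampled extracellular voltage series in microvolts."""

    samples: np.ndarray
    sample_rate: float
    electrode_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if not np.isfinite(self.samples).all():
            raise ValueError("trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


def estimate_noise_sd(trace: VoltageTrace, window_s: float = 1.0) -> np.ndarray:
    """Robust noise SD (MAD / 0.6745) per rolling window, in microvolts.

    Returns one estimate per (non-overlapping) window; the trailing partial
    window is folded into the last full one. Raises if the trace is shorter
    than one window or the window holds fewer than MIN_WINDOW_SAMPLES samples.
    """
    w = int(round(window_s * trace.sample_rate))
    if w < MIN_WINDOW_SAMPLES:
        raise ValueError(
            f"window of {w} samples is below the {MIN_WINDOW_SAMPLES}-sample minimum"
        )
    x = trace.samples
    if x.size < w:
        raise ValueError("trace shorter than one noise-estimation window")
    n_windows = x.size // w
    sigmas = np.empty(n_windows)
    for i in range(n_windows):
        stop = x.size if i == n_windows - 1 else (i + 1) * w
        seg = x[i * w : stop]
        sigmas[i] = np.median(np.abs(seg - np.median(seg))) * MAD_TO_SD
    return sigmas


def detection_threshold(sigma: float, k: float = 6.0) -> float:
    """Amplitude threshold in microvolts: k times the noise SD."""
    return k * sigma


def detect_spikes(
    trace: VoltageTrace,
    k: float = 6.0,
    window_s: float = 1.0,
    refractory_s: float = 0.001,
) -> SpikeTrain:
    """Detect threshold-crossing events and return them as a spike train.

    Thresholds are local: each noise window uses its own k * sigma. A
    contiguous supra-threshold excursion yields one event at the sample of
    largest |voltage|; events closer than ``refractory_s`` are merged,
    keeping the larger-amplitude one.
    """
    x = trace.samples
    sigmas = estimate_noise_sd(trace, window_s=window_s)
    w = int(round(window_s * trace.sample_rate))
    thr = np.empty_like(x)
    for i, s in enumerate(sigmas):
        stop = x.size if i == len(sigmas) - 1 else (i + 1) * w
        thr[i * w : stop] = detection_threshold(s, k)

    above = np.abs(x) > thr
    t_stop = trace.duration
    if not above.any():
        return SpikeTrain(trace.electrode_id, [], 0.0, t_stop)

    # contiguous excursions -> extremum sample each
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [x.size]))

    peaks = []
    for s, e in zip(starts, ends):
        peaks.append(s + int(np.argmax(np.abs(x[s:e]))))
    peaks = np.asarray(peaks)

    # refractory merge: keep the larger-amplitude event of any close pair
    ref_n = refractory_s * trace.sample_rate
    merged: list[int] = []
    for p in peaks:
        if merged and p - merged[-1] < ref_n:
            if abs(x[p]) > abs(x[merged[-1]]):
                merged[-1] = int(p)
        else:
            merged.append(int(p))

    times = np.asarray(merged, dtype=float) / trace.sample_rate
    return SpikeTrain(trace.electrode_id, times, 0.0, t_stop)
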