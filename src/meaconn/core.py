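"""Core domain types: spike trains, the electrode grid, recordings and analysis
configuration.

Geometry convention
-------------------
Electrodes are addressed as ``R<row>C<col>`` with 1-based indices. Row 1 sits
at the MO (midbrain organoid) edge of the array and row numbers increase
toward the StrO (striatum organoid) edge, so the y axis is oriented MO -> StrO
positive. All positions and distances are expressed in pitch units (the
centre-to-centre electrode spacing); conversion to metres happens only where
a physical pitch enters (e.g. propagation speed).
"""

from __future__ import annotations

import dataclasses
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import yaml

logger = logging.getLogger("meaconn")

MO = "MO"
STRO = "StrO"

_ELECTRODE_RE = re.compile(r"^R(\d+)C(\d+)$")


class FormatError(ValueError):
    """Malformed input file (missing columns, unknown electrode codes...)."""


class UndefinedResultError(ValueError):
    """A quantity is mathematically undefined for the given input."""


def parse_electrode_id(code: str) -> tuple[int, int]:
    """Parse an ``R<row>C<col>`` code into 1-based (row, col)."""
    m = _ELECTRODE_RE.match(code.strip())
    if m is None:
        raise FormatError(f"unrecognised electrode code {code!r}")
    return int(m.group(1)), int(m.group(2))


def electrode_id(row: int, col: int) -> str:
    return f"R{row}C{col}"


@dataclass(frozen=True)
class ElectrodeGrid:
    """Rectangular electrode array split into two contiguous compartments.

    Rows strictly below ``boundary_row`` belong to the MO compartment, rows at
    or above it to StrO.
    """

    pitch_um: float
    boundary_row: int
    n_rows: int = 8
    n_cols: int = 8

    def __post_init__(self) -> None:
        if self.pitch_um <= 0:
            raise ValueError(f"pitch_um must be > 0, got {self.pitch_um}")
        if not (1 <= self.boundary_row <= self.n_rows):
            raise ValueError(
                f"boundary_row must be in [1, {self.n_rows}], got {self.boundary_row}"
            )
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def electrode_ids(self) -> list[str]:
        return [
            electrode_id(r, c)
            for r in range(1, self.n_rows + 1)
            for c in range(1, self.n_cols + 1)
        ]

    def __contains__(self, code: str) -> bool:
        try:
            r, c = parse_electrode_id(code)
        except FormatError:
            return False
        return 1 <= r <= self.n_rows and 1 <= c <= self.n_cols

    def _check(self, code: str) -> tuple[int, int]:
        r, c = parse_electrode_id(code)
        if not (1 <= r <= self.n_rows and 1 <= c <= self.n_cols):
            raise FormatError(
                f"electrode {code!r} outside {self.n_rows}x{self.n_cols} grid"
            )
        return r, c

    def position(self, code: str) -> tuple[float, float]:
        """(x, y) in pitch units; x along columns, y positive toward StrO."""
        r, c = self._check(code)
        return float(c - 1), float(r - 1)

    def compartment(self, code: str) -> str:
        r, _ = self._check(code)
        return MO if r < self.boundary_row else STRO

    def distance_pitch(self, a: str, b: str) -> float:
        xa, ya = self.position(a)
        xb, yb = self.position(b)
        return math.hypot(xb - xa, yb - ya)

    def distance_m(self, a: str, b: str) -> float:
        return self.distance_pitch(a, b) * self.pitch_um * 1e-6

    def displacement_pitch(self, a: str, b: str) -> tuple[float, float]:
        """Displacement from *a* to *b* in pitch units."""
        xa, ya = self.position(a)
        xb, yb = self.position(b)
        return xb - xa, yb - ya

    def mirrored(self) -> "ElectrodeGrid":
        """Grid with MO/StrO compartments swapped (row order reversed)."""
        return ElectrodeGrid(
            pitch_um=self.pitch_um,
            boundary_row=self.n_rows - self.boundary_row + 2,
            n_rows=self.n_rows,
            n_cols=self.n_cols,
        )


def build_grid(
    pitch_um: float, boundary_row: int, n_rows: int = 8, n_cols: int = 8
) -> ElectrodeGrid:
    """Build an electrode grid; rows < ``boundary_row`` are MO, the rest StrO."""
    return ElectrodeGrid(
        pitch_um=pitch_um, boundary_row=boundary_row, n_rows=n_rows, n_cols=n_cols
    )


class SpikeTrain:
    """One electrode's sorted spike times within a recording window.

    Times are strictly increasing and clipped-validated to
    ``[t_start, t_stop]``. Duplicate times are collapsed to a single event
    with a logged warning (true duplicates are physically impossible at the
    nominal 12.5 kHz sampling).
    """

    __slots__ = ("electrode_id", "times", "t_start", "t_stop")

    def __init__(
        self,
        electrode_id: str,
        times,
        t_start: float,
        t_stop: float,
    ) -> None:
        if not t_stop > t_start:
            raise ValueError(f"t_stop ({t_stop}) must exceed t_start ({t_start})")
        t = np.asarray(times, dtype=float)
        if t.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if t.size and (t.min() < t_start or t.max() > t_stop):
            raise ValueError(
                f"spike times outside window [{t_start}, {t_stop}] on {electrode_id}"
            )
        t = np.sort(t)
        if t.size > 1:
            keep = np.concatenate(([True], np.diff(t) > 0))
            if not keep.all():
                logger.warning(
                    "%d duplicate spike time(s) collapsed on electrode %s",
                    int((~keep).sum()),
                    electrode_id,
                )
                t = t[keep]
        self.electrode_id = str(electrode_id)
        self.times = t
        self.t_start = float(t_start)
        self.t_stop = float(t_stop)

    def __len__(self) -> int:
        return int(self.times.size)

    def __repr__(self) -> str:
        return (
            f"SpikeTrain({self.electrode_id!r}, n={len(self)}, "
            f"window=[{self.t_start}, {self.t_stop}])"
        )

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    @property
    def rate(self) -> float:
        """Mean firing rate in Hz."""
        return len(self) / self.duration

    def shifted(self, dt: float) -> "SpikeTrain":
        return SpikeTrain(
            self.electrode_id, self.times + dt, self.t_start + dt, self.t_stop + dt
        )


@dataclass
class Recording:
    """A set of spike trains on a grid, sharing one recording window."""

    trains: dict[str, SpikeTrain]
    grid: ElectrodeGrid
    assembloid_id: str = ""
    batch_id: str = ""
    day_in_vitro: int = 0
    sample_rate: float | None = None

    def __post_init__(self) -> None:
        if self.day_in_vitro < 0:
            raise ValueError("day_in_vitro must be >= 0")
        windows = {(tr.t_start, tr.t_stop) for tr in self.trains.values()}
        if len(windows) > 1:
            raise ValueError(f"trains disagree on recording window: {windows}")
        for code in self.trains:
            if code not in self.grid:
                raise FormatError(f"train electrode {code!r} not on grid")

    @property
    def t_start(self) -> float:
        return next(iter(self.trains.values())).t_start

    @property
    def t_stop(self) -> float:
        return next(iter(self.trains.values())).t_stop

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    @property
    def n_electrodes(self) -> int:
        return self.grid.n_rows * self.grid.n_cols

    @property
    def total_spikes(self) -> int:
        return sum(len(tr) for tr in self.trains.values())

    def __iter__(self) -> Iterator[SpikeTrain]:
        return iter(self.trains.values())

    def active_electrodes(self, min_spikes: int) -> list[str]:
        return [e for e, tr in self.trains.items() if len(tr) >= min_spikes]


@dataclass
class PairwiseResult:
    """Connectivity summary for one unordered electrode pair (e1, e2).

    ``delay_s`` is signed with the convention that a positive delay means e1
    leads e2 (spikes on e2 lag those on e1).
    """

    e1: str
    e2: str
    sttc: float
    significant: bool
    delay_s: float | None
    distance_pitch: float
    distance_m: float
    speed_mps: float | None
    correlogram: "object | None" = None  # connectivity.Correlogram, optional


@dataclass
class DirectionalityField:
    """Per-electrode direction vectors and the assembloid-level verdict.

    ``vertical_y`` and ``lateral_abs_x`` are the components of the assembloid
    vector after normalising by the pair-attachment multiplicity, so the
    establishment threshold reads in inter-electrode distances regardless of
    the attachment rule.
    """

    electrode_vectors: dict[str, tuple[float, float]]
    assembloid_vector: tuple[float, float]
    vertical_y: float
    lateral_abs_x: float
    established: bool
    mean_firing_rate: float
    threshold: float
    conventions: dict = field(default_factory=dict)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline.

    Defaults follow the published analysis where stated (STTC window 10 ms,
    correlogram bin 0.5 ms, mean + 5 SD significance, STTC cut-off 0.3,
    establishment threshold 2 pitch units, detection at 6 noise SD); the
    remaining knobs are engineering choices surfaced here.
    """

    dt_sttc: float = 0.010
    cc_bin: float = 0.0005
    cc_half_window: float = 0.010
    sig_sd: float = 5.0
    sig_min_count: int = 5
    sttc_cutoff: float = 0.3
    establishment_threshold: float = 2.0
    min_spikes_per_electrode: int = 10
    detection_k: float = 6.0
    detection_window_s: float = 1.0
    refractory_s: float = 0.001
    burst_max_isi: float = 0.100
    burst_min_spikes: int = 5
    attachment: str = "both"  # "both" or "lead"
    pitch_um: float | None = None
    boundary_row: int = 5

    def __post_init__(self) -> None:
        for name in (
            "dt_sttc",
            "cc_bin",
            "cc_half_window",
            "sig_sd",
            "establishment_threshold",
            "detection_k",
            "detection_window_s",
            "refractory_s",
            "burst_max_isi",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.cc_bin >= self.cc_half_window:
            raise ValueError("cc_bin must be smaller than cc_half_window")
        if self.min_spikes_per_electrode < 1:
            raise ValueError("min_spikes_per_electrode must be >= 1")
        if self.burst_min_spikes < 2:
            raise ValueError("burst_min_spikes must be >= 2")
        if self.attachment not in ("both", "lead"):
            raise ValueError("attachment must be 'both' or 'lead'")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    @classmethod
    def from_mapping(cls, data: Mapping) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)
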