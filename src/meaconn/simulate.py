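"""Synthetic two-compartment MEA recordings with known ground truth.

Each electrode fires as a homogeneous Poisson process (optionally with
superimposed renewal bursts). Directed connections copy every source spike to
the target with a transmission probability, delayed by distance / conduction
speed plus truncated Gaussian jitter; propagated spikes falling outside the
recording window are dropped. A single integer seed drives the whole
recording through deterministic per-electrode substreams, so fixtures are
bit-stable across platforms.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as mio
from .core import ElectrodeGrid, Recording, SpikeTrain, build_grid

logger = logging.getLogger("meaconn")


@dataclass(frozen=True)
class Connection:
    """A directed source -> target link with a transmission probability."""

    source: str
    target: str
    transmission_prob: float
    jitter_sd: float = 0.0002

    def __post_init__(self) -> None:
        if not (0.0 <= self.transmission_prob <= 1.0):
            raise ValueError("transmission_prob must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


@dataclass(frozen=True)
class BurstModel:
    """Renewal bursts of fixed size and intra-burst interval."""

    burst_rate: float  # bursts per second per electrode
    spikes_per_burst: int = 5
    intra_burst_isi: float = 0.010

    def __post_init__(self) -> None:
        if self.burst_rate < 0:
            raise ValueError("burst_rate must be >= 0")
        if self.spikes_per_burst < 2:
            raise ValueError("spikes_per_burst must be >= 2")
        if self.intra_burst_isi <= 0:
            raise ValueError("intra_burst_isi must be > 0")


@dataclass
class SimulationConfig:
    """Generative parameters for a two-compartment recording.

    Fixture firing rates are engineering defaults (the source work reports
    no assembloid rate figures); the default conduction speed sits inside
    the biologically reported 0.2-0.5 m/s band.
    """

    duration: float = 180.0
    background_rate: float = 2.0
    burst: BurstModel | None = None
    connections: list[Connection] = field(default_factory=list)
    conduction_speed: float = 0.3
    pitch_um: float = 300.0
    boundary_row: int = 5
    n_rows: int = 8
    n_cols: int = 8
    forward_bias: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.conduction_speed <= 0:
            raise ValueError("conduction_speed must be > 0")
        if not (0.0 <= self.forward_bias <= 1.0):
            raise ValueError("forward_bias must be in [0, 1]")

    def make_grid(self) -> ElectrodeGrid:
        return build_grid(
            self.pitch_um, self.boundary_row, self.n_rows, self.n_cols
        )


@dataclass
class SyntheticGroundTruth:
    """Planted parameters enabling parameter-recovery tests."""

    connections: list[dict]
    conduction_speed: float
    net_direction_sign: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticGroundTruth":
        return cls(
            connections=list(d["connections"]),
            conduction_speed=float(d["conduction_speed"]),
            net_direction_sign=int(d["net_direction_sign"]),
        )


def simulate_background(rate: float, duration: float, rng) -> np.ndarray:
    """Homogeneous Poisson spike times on [0, duration), sorted."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, n))


def _burst_times(model: BurstModel, duration: float, rng) -> np.ndarray:
    n_bursts = rng.poisson(model.burst_rate * duration)
    onsets = rng.uniform(0.0, duration, n_bursts)
    offsets = np.arange(model.spikes_per_burst) * model.intra_burst_isi
    times = (onsets[:, None] + offsets[None, :]).ravel()
    return times[times < duration]


def _truncated_normal(sd: float, size: int, rng, clip_sd: float = 3.0) -> np.ndarray:
    if sd == 0:
        return np.zeros(size)
    draws = rng.normal(0.0, sd, size)
    # redraw outside +/- clip_sd rather than clipping, keeping the density shape
    bad = np.abs(draws) > clip_sd * sd
    while bad.any():
        draws[bad] = rng.normal(0.0, sd, int(bad.sum()))
        bad = np.abs(draws) > clip_sd * sd
    return draws


def planted_delay(grid: ElectrodeGrid, conn: Connection, speed: float) -> float:
    """Conduction delay in seconds: grid distance in metres over speed."""
    return grid.distance_m(conn.source, conn.target) / speed


def simulate_assembloid(
    config: SimulationConfig, seed: int | None = None
) -> tuple[Recording, SyntheticGroundTruth]:
    """Generate a recording plus its ground truth.

    Background (and optional burst) activity is drawn independently per
    electrode from substreams of the master seed; each connection then copies
    source spikes to its target with the configured probability, delay and
    jitter.
    """
    grid = config.make_grid()
    master = config.seed if seed is None else seed
    for conn in config.connections:
        for code in (conn.source, conn.target):
            if code not in grid:
                raise ValueError(f"connection references non-grid electrode {code!r}")

    base: dict[str, np.ndarray] = {}
    for k, code in enumerate(grid.electrode_ids):
        rng = np.random.default_rng([master, k])
        t = simulate_background(config.background_rate, config.duration, rng)
        if config.burst is not None:
            t = np.sort(np.concatenate([t, _burst_times(config.burst, config.duration, rng)]))
        base[code] = t

    extra: dict[str, list[np.ndarray]] = {code: [] for code in grid.electrode_ids}
    truth_conns = []
    net = 0.0
    for j, conn in enumerate(config.connections):
        rng = np.random.default_rng([master, 10_000 + j])
        delay = planted_delay(grid, conn, config.conduction_speed)
        src = base[conn.source]
        sent = src[rng.random(src.size) < conn.transmission_prob]
        arr = sent + delay + _truncated_normal(conn.jitter_sd, sent.size, rng)
        arr = arr[(arr >= 0.0) & (arr < config.duration)]
        extra[conn.target].append(arr)
        dx, dy = grid.displacement_pitch(conn.source, conn.target)
        net += conn.transmission_prob * dy
        truth_conns.append(
            {
                "source": conn.source,
                "target": conn.target,
                "transmission_prob": conn.transmission_prob,
                "jitter_sd": conn.jitter_sd,
                "delay_s": delay,
                "direction_sign": int(np.sign(dy)),
            }
        )

    trains = {}
    for code in grid.electrode_ids:
        t = np.concatenate([base[code]] + extra[code]) if extra[code] else base[code]
        trains[code] = SpikeTrain(code, np.sort(t), 0.0, config.duration)

    truth = SyntheticGroundTruth(
        connections=truth_conns,
        conduction_speed=config.conduction_speed,
        net_direction_sign=int(np.sign(net)),
    )
    return Recording(trains=trains, grid=grid, assembloid_id=f"sim-{master}"), truth


def draw_tunnel_connections(
    grid: ElectrodeGrid,
    n: int,
    rng,
    forward_prob: float = 0.8,
    backward_prob: float = 0.2,
    max_span_pitch: float = 6.0,
    jitter_sd: float = 0.0002,
) -> list[Connection]:
    """Draw a balanced set of boundary-crossing connections.

    Half the connections run MO -> StrO with transmission ``forward_prob``,
    half StrO -> MO with ``backward_prob``, so the directional asymmetry is
    carried by the transmission probabilities (the "forward bias"). Distinct
    electrode pairs are used, kept within ``max_span_pitch`` so planted
    delays stay inside the correlogram window at the default speed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    mo = [e for e in grid.electrode_ids if grid.compartment(e) == "MO"]
    stro = [e for e in grid.electrode_ids if grid.compartment(e) == "StrO"]
    if not mo or not stro:
        raise ValueError("grid must have both compartments to draw tunnel connections")
    conns: list[Connection] = []
    used: set[frozenset] = set()
    n_forward = n // 2
    while len(conns) < n:
        a = mo[rng.integers(len(mo))]
        b = stro[rng.integers(len(stro))]
        if grid.distance_pitch(a, b) > max_span_pitch or frozenset((a, b)) in used:
            continue
        used.add(frozenset((a, b)))
        if len(conns) < n_forward:
            conns.append(Connection(a, b, forward_prob, jitter_sd))
        else:
            conns.append(Connection(b, a, backward_prob, jitter_sd))
    return conns


FIXTURE_NAMES = ("null", "forward", "backward", "shifted_pair")


def fixture_config(name: str, seed: int = 0, pitch_um: float = 300.0) -> SimulationConfig:
    """Canonical fixture configurations used across the test-suite and CLI."""
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    cfg = SimulationConfig(pitch_um=pitch_um, seed=seed)
    grid = cfg.make_grid()
    if name == "null":
        cfg.connections = []
        cfg.forward_bias = 0.5
    elif name in ("forward", "backward"):
        # forward fixture: MO->StrO links transmit at 0.8, reverse links at 0.2;
        # the backward fixture mirrors the two probabilities
        fwd, bwd = (0.8, 0.2) if name == "forward" else (0.2, 0.8)
        cfg.forward_bias = fwd / (fwd + bwd)
        cfg.connections = draw_tunnel_connections(
            grid,
            n=10,
            rng=np.random.default_rng([seed, 777]),
            forward_prob=fwd,
            backward_prob=bwd,
        )
    elif name == "shifted_pair":
        # one high-fidelity connection along a column, 5 pitch apart
        cfg.connections = [Connection("R2C4", "R7C4", 1.0, 0.0002)]
        cfg.background_rate = 2.0
    return cfg


def make_fixture_suite(out_dir, seed: int = 0) -> dict[str, dict[str, Path]]:
    """Write the canonical fixtures as spike-list CSV + ground-truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, dict[str, Path]] = {}
    for name in FIXTURE_NAMES:
        cfg = fixture_config(name, seed=seed)
        rec, truth = simulate_assembloid(cfg)
        csv_path = out_dir / f"{name}.csv"
        json_path = out_dir / f"{name}.truth.json"
        mio.write_spike_list(rec, csv_path)
        payload = truth.to_dict()
        payload["duration"] = cfg.duration
        payload["pitch_um"] = cfg.pitch_um
        payload["boundary_row"] = cfg.boundary_row
        payload["seed"] = seed
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
        written[name] = {"spikes": csv_path, "truth": json_path}
        logger.info("fixture %s: %d spikes", name, rec.total_spikes)
    return written
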