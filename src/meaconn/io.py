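"""Readers and writers for the spike-list CSV dialect and result files.

The spike-list dialect mirrors multiwell-MEA software exports: a CSV with a
header row and columns ``time_s``, ``electrode`` (``R<row>C<col>`` codes) and
an optional ``amplitude_uV``. One file holds one recording.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AnalysisConfig,
    DirectionalityField,
    ElectrodeGrid,
    FormatError,
    PairwiseResult,
    Recording,
    SpikeTrain,
)

logger = logging.getLogger("meaconn")

REQUIRED_COLUMNS = ("time_s", "electrode")

PAIRWISE_COLUMNS = (
    "e1",
    "e2",
    "sttc",
    "significant",
    "delay_s",
    "distance_pitch",
    "distance_m",
    "speed_mps",
)


def read_spike_list(
    path,
    grid: ElectrodeGrid,
    t_start: float | None = None,
    t_stop: float | None = None,
    **metadata,
) -> Recording:
    """Read a spike-list CSV into a :class:`Recording`.

    Every grid electrode gets a train (possibly empty). The recording window
    defaults to [0, max spike time] unless given explicitly. Unknown
    electrode codes raise a :class:`FormatError` listing the offenders.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    codes = df["electrode"].astype(str)
    unknown = sorted(set(codes) - set(grid.electrode_ids))
    if unknown:
        raise FormatError(f"{path}: unknown electrode code(s) {unknown}")

    times = df["time_s"].to_numpy(dtype=float)
    if not np.isfinite(times).all():
        raise FormatError(f"{path}: non-finite spike times")

    if t_start is None:
        t_start = min(0.0, float(times.min())) if times.size else 0.0
    if t_stop is None:
        t_stop = float(times.max()) if times.size else t_start + 1.0

    trains: dict[str, SpikeTrain] = {}
    grouped = {k: g["time_s"].to_numpy(dtype=float) for k, g in df.groupby(codes)}
    for code in grid.electrode_ids:
        trains[code] = SpikeTrain(code, grouped.get(code, ()), t_start, t_stop)
    return Recording(trains=trains, grid=grid, **metadata)


def write_spike_list(recording: Recording, path) -> None:
    """Write a recording in the spike-list CSV dialect (sorted by time)."""
    rows = []
    for code in recording.grid.electrode_ids:
        tr = recording.trains[code]
        for t in tr.times:
            rows.append((t, code))
    rows.sort()
    df = pd.DataFrame(rows, columns=["time_s", "electrode"])
    df.to_csv(path, index=False, float_format="%.9f")


def pairwise_to_frame(results: list[PairwiseResult]) -> pd.DataFrame:
    records = [
        {
            "e1": r.e1,
            "e2": r.e2,
            "sttc": r.sttc,
            "significant": r.significant,
            "delay_s": np.nan if r.delay_s is None else r.delay_s,
            "distance_pitch": r.distance_pitch,
            "distance_m": r.distance_m,
            "speed_mps": np.nan if r.speed_mps is None else r.speed_mps,
        }
        for r in results
    ]
    return pd.DataFrame(records, columns=list(PAIRWISE_COLUMNS))


def write_pairwise(results: list[PairwiseResult], path) -> None:
    pairwise_to_frame(results).to_csv(path, index=False, float_format="%.12g")


def read_pairwise(path) -> list[PairwiseResult]:
    df = pd.read_csv(path)
    missing = [c for c in PAIRWISE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing pairwise column(s) {missing}")
    out = []
    for row in df.itertuples(index=False):
        delay = None if pd.isna(row.delay_s) else float(row.delay_s)
        speed = None if pd.isna(row.speed_mps) else float(row.speed_mps)
        out.append(
            PairwiseResult(
                e1=str(row.e1),
                e2=str(row.e2),
                sttc=float(row.sttc),
                significant=bool(row.significant),
                delay_s=delay,
                distance_pitch=float(row.distance_pitch),
                distance_m=float(row.distance_m),
                speed_mps=speed,
            )
        )
    return out


def field_to_dict(field: DirectionalityField) -> dict:
    return {
        "electrode_vectors": {
            k: [v[0], v[1]] for k, v in field.electrode_vectors.items()
        },
        "assembloid_vector": list(field.assembloid_vector),
        "vertical_y": field.vertical_y,
        "lateral_abs_x": field.lateral_abs_x,
        "established": field.established,
        "mean_firing_rate": field.mean_firing_rate,
        "threshold": field.threshold,
        "conventions": field.conventions,
    }


def field_from_dict(d: dict) -> DirectionalityField:
    return DirectionalityField(
        electrode_vectors={k: (v[0], v[1]) for k, v in d["electrode_vectors"].items()},
        assembloid_vector=tuple(d["assembloid_vector"]),
        vertical_y=d["vertical_y"],
        lateral_abs_x=d["lateral_abs_x"],
        established=d["established"],
        mean_firing_rate=d["mean_firing_rate"],
        threshold=d["threshold"],
        conventions=d.get("conventions", {}),
    )


def write_field(field: DirectionalityField, path) -> None:
    with open(path, "w") as fh:
        json.dump(field_to_dict(field), fh, indent=2)
        fh.write("\n")


def read_field(path) -> DirectionalityField:
    with open(path) as fh:
        return field_from_dict(json.load(fh))


def write_results(
    results: list[PairwiseResult],
    field: DirectionalityField | None,
    out_dir,
    prefix: str = "results",
) -> dict[str, Path]:
    """Write the pairwise CSV and (optionally) the directionality JSON.

    Returns the paths written, keyed by kind.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    csv_path = out_dir / f"{prefix}_pairwise.csv"
    write_pairwise(results, csv_path)
    paths["pairwise"] = csv_path
    if field is not None:
        json_path = out_dir / f"{prefix}_directionality.json"
        write_field(field, json_path)
        paths["directionality"] = json_path
    return paths


def read_trace_matrix(path, sample_rate: float) -> dict[str, np.ndarray]:
    """Read raw voltage traces from a CSV matrix (one column per electrode).

    Column headers are electrode codes; values are microvolts sampled at
    ``sample_rate``.
    """
    df = pd.read_csv(path)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no trace columns")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be > 0")
    return {str(c): df[c].to_numpy(dtype=float) for c in df.columns}
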