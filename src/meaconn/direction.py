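"""Directionality vector field and the compartment-connection verdict.

An accepted pair (significant correlogram maximum AND tiling coefficient at
or above the cut-off) contributes the displacement vector from its leading to
its lagging electrode, in pitch units. Per-electrode vectors are the sums of
the pair vectors attached to each electrode; the assembloid vector is the sum
of the per-electrode vectors.

Attachment rule: by default each pair vector is attached to BOTH member
electrodes, so the raw assembloid sum counts every pair twice. The vertical
and lateral components used for the establishment decision are therefore
normalised by the attachment multiplicity (2 for "both", 1 for "lead"),
keeping the threshold readable in inter-electrode distances under either
convention. The verdict uses |y| so that net flow in either direction
establishes the connection.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
import scipy.stats

from .core import (
    AnalysisConfig,
    DirectionalityField,
    ElectrodeGrid,
    PairwiseResult,
    Recording,
)

logger = logging.getLogger("meaconn")


def accept_pair(result: PairwiseResult, sttc_cutoff: float = 0.3) -> bool:
    """A connection exists iff the delay is significant and STTC >= cut-off."""
    return bool(result.significant) and result.sttc >= sttc_cutoff


def pair_vector(
    grid: ElectrodeGrid, e_lead: str, e_lag: str
) -> tuple[float, float]:
    """Displacement (x, y) from the leading to the lagging electrode, pitch units."""
    if e_lead == e_lag:
        raise ValueError("lead and lag electrodes must differ")
    return grid.displacement_pitch(e_lead, e_lag)


def electrode_vector(
    electrode: str, attached: dict[str, list[tuple[float, float]]]
) -> tuple[float, float]:
    """Componentwise sum of the pair vectors attached to one electrode."""
    vecs = attached.get(electrode, [])
    if not vecs:
        return (0.0, 0.0)
    arr = np.asarray(vecs, dtype=float)
    return (float(arr[:, 0].sum()), float(arr[:, 1].sum()))


def connection_established(field_or_y, threshold: float = 2.0) -> bool:
    """Connection verdict: |y| at or above the threshold (in pitch units).

    Accepts either a :class:`DirectionalityField` or a bare vertical
    component.
    """
    y = getattr(field_or_y, "vertical_y", field_or_y)
    return abs(y) >= threshold


def assembloid_directionality(
    recording: Recording,
    results: list[PairwiseResult],
    config: AnalysisConfig | None = None,
) -> DirectionalityField:
    """Build the directionality field and the establishment verdict.

    Positive vertical component means net signal flow from the MO toward the
    StrO compartment. The lateral component is reported as |x|, with no
    left/right distinction.
    """
    config = config or AnalysisConfig()
    grid = recording.grid
    attached: dict[str, list[tuple[float, float]]] = defaultdict(list)
    n_accepted = 0
    for r in results:
        if not accept_pair(r, sttc_cutoff=config.sttc_cutoff):
            continue
        if r.delay_s is None or r.delay_s == 0:
            logger.info(
                "accepted pair (%s, %s) has zero delay: no direction, skipped",
                r.e1,
                r.e2,
            )
            continue
        n_accepted += 1
        lead, lag = (r.e1, r.e2) if r.delay_s > 0 else (r.e2, r.e1)
        v = pair_vector(grid, lead, lag)
        attached[lead].append(v)
        if config.attachment == "both":
            attached[lag].append(v)

    electrode_vectors = {
        e: electrode_vector(e, attached) for e in grid.electrode_ids
    }
    total = np.sum(
        [electrode_vectors[e] for e in grid.electrode_ids], axis=0
    ) if electrode_vectors else np.zeros(2)
    assembloid_vector = (float(total[0]), float(total[1]))

    multiplicity = 2.0 if config.attachment == "both" else 1.0
    y = assembloid_vector[1] / multiplicity
    abs_x = abs(assembloid_vector[0]) / multiplicity
    established = connection_established(y, config.establishment_threshold)
    duration = recording.duration
    mfr = recording.total_spikes / (recording.n_electrodes * duration)

    if n_accepted == 0:
        logger.info("no accepted pairs: zero field, not established")

    return DirectionalityField(
        electrode_vectors=electrode_vectors,
        assembloid_vector=assembloid_vector,
        vertical_y=y,
        lateral_abs_x=abs_x,
        established=established,
        mean_firing_rate=mfr,
        threshold=config.establishment_threshold,
        conventions={
            "attachment": config.attachment,
            "multiplicity": multiplicity,
            "y_axis": "MO->StrO positive",
            "units": "pitch",
        },
    )


def maturation_trajectory(
    fields_by_stage: dict[str, list[DirectionalityField]],
) -> dict:
    """Per-stage summaries of y and |x| with a Kruskal-Wallis omnibus test.

    Stages with fewer than 2 observations are excluded with a warning.
    Returns a dict with per-stage means/SDs and, per component, the H
    statistic and p value (identical samples in every stage give H = 0,
    p = 1 by convention).
    """
    usable: dict[str, list[DirectionalityField]] = {}
    for stage, fields in fields_by_stage.items():
        if len(fields) < 2:
            logger.warning("stage %r has < 2 observations: excluded", stage)
            continue
        usable[stage] = fields
    if len(usable) < 2:
        raise ValueError("need at least 2 stages with >= 2 observations each")

    summaries = {}
    samples = {"vertical_y": [], "lateral_abs_x": []}
    for stage, fields in usable.items():
        ys = np.array([f.vertical_y for f in fields], dtype=float)
        xs = np.array([f.lateral_abs_x for f in fields], dtype=float)
        summaries[stage] = {
            "n": len(fields),
            "vertical_y_mean": float(ys.mean()),
            "vertical_y_sd": float(ys.std(ddof=1)),
            "lateral_abs_x_mean": float(xs.mean()),
            "lateral_abs_x_sd": float(xs.std(ddof=1)),
        }
        samples["vertical_y"].append(ys)
        samples["lateral_abs_x"].append(xs)

    from .stats import dunn_test

    stage_names = list(usable)
    tests = {}
    for component, groups in samples.items():
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            tests[component] = {"H": 0.0, "p": 1.0, "posthoc": []}
        else:
            h, p = scipy.stats.kruskal(*groups)
            posthoc = dunn_test(groups) if len(groups) > 2 else []
            for row in posthoc:
                row["stage_i"] = stage_names[row["i"]]
                row["stage_j"] = stage_names[row["j"]]
            tests[component] = {"H": float(h), "p": float(p), "posthoc": posthoc}
    return {"stages": summaries, "kruskal_wallis": tests}
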