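"""Per-patient intereye differences and asymmetry indices.

For each patient and each metric the absolute intereye difference is
``delta_abs = |right - left|`` and the asymmetry index is the absolute
difference normalized by the two-eye mean,

    AI = |R - L| / ((R + L) / 2) * 100   [percent],

which is scale-invariant and bounded by 200 for non-negative metrics.
Patients lacking a fellow-eye measurement cannot be paired and are reported
in the log, mirroring the exclusion of single-eye patients from paired
analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntereyePair:
    patient_id: str
    stage: str
    metric: str
    right_value: float
    left_value: float
    delta_abs: float
    asymmetry_index: float


def asymmetry(right: float, left: float) -> tuple[float, float]:
    """Absolute intereye difference and asymmetry index (percent).

    The index is undefined when the two-eye mean is not positive.
    """
    mean = (right + left) / 2.0
    if not mean > 0:
        raise ValueError(f"asymmetry index undefined for non-positive mean ({mean})")
    delta = abs(right - left)
    return delta, delta / mean * 100.0


def pair_eyes(metrics: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pair right/left rows per (patient, metric) from a tidy metrics table.

    ``metrics`` must contain columns ``patient_id, side, metric, value`` and
    may carry ``stage`` (and any further identifying columns folded into
    ``metric``, e.g. plexus/sector).  Only patients with both eyes present
    for a metric are paired; the ids of unpaired (patient, metric) entries
    are returned (and logged) for the exclusion accounting.

    Returns ``(pairs, unpaired)`` where ``pairs`` has one row per patient and
    metric with columns ``patient_id, stage, metric, right, left, delta_abs,
    asymmetry_index``.
    """
    required = {"patient_id", "side", "metric", "value"}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing columns {sorted(missing)}")
    if metrics.empty:
        return (pd.DataFrame(columns=["patient_id", "stage", "metric", "right",
                                      "left", "delta_abs", "asymmetry_index"]), [])

    dup = metrics.duplicated(subset=["patient_id", "side", "metric"])
    if dup.any():
        first = metrics.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate eye: patient {first['patient_id']!r} side {first['side']!r} "
            f"metric {first['metric']!r}")

    has_stage = "stage" in metrics.columns
    if has_stage:
        stage_check = metrics.groupby("patient_id")["stage"].nunique()
        mixed = stage_check[stage_check > 1]
        if not mixed.empty:
            raise ValueError(
                f"patients with different stage labels between eyes: {list(mixed.index)}")

    rows, unpaired = [], []
    for (pid, metric), grp in metrics.groupby(["patient_id", "metric"], sort=True):
        sides = dict(zip(grp["side"], grp["value"]))
        if "right" not in sides or "left" not in sides:
            unpaired.append(f"{pid}:{metric}")
            continue
        delta, ai = asymmetry(float(sides["right"]), float(sides["left"]))
        stage = grp["stage"].iloc[0] if has_stage else ""
        rows.append((pid, stage, metric, float(sides["right"]), float(sides["left"]),
                     delta, ai))
    if unpaired:
        logger.warning("unpaired eyes excluded from intereye analysis: %s",
                       ", ".join(unpaired))
    pairs = pd.DataFrame(rows, columns=["patient_id", "stage", "metric", "right",
                                        "left", "delta_abs", "asymmetry_index"])
    return pairs, unpaired
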