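"""Constructed-data inflation: a deliberately crude event-rate stressor.

Multiplying every event count by a fixed factor while holding patients and
exposure constant pushes the average event rates upward, which is exactly
the regime where the simple odds-ratio model and the shared-parameter
hazard-ratio model start to disagree.  Counts are capped per outcome at the
number of patients in the arm.  For competing-risks (format-1) studies the
per-outcome cap alone can leave the arm's first-event counts summing above
the number of patients; those arms are reconciled by proportionally
reducing the capped counts (largest-remainder rounding, preserving the
relative outcome composition) and the adjustment is reported loudly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .data import ArmRecord, NMADataset, StudyRecord

__all__ = ["InflationSpec", "inflate", "average_event_rate"]

logger = logging.getLogger(__name__)

#: inflation factors of the constructed-data experiment (1 = base case)
DEFAULT_FACTORS = (1, 2, 5, 10, 20)


@dataclass(frozen=True)
class InflationSpec:
    factors: tuple[int, ...] = DEFAULT_FACTORS

    def __post_init__(self):
        if any(f < 1 for f in self.factors):
            raise ValueError("inflation factors must be >= 1")


def inflate(dataset: NMADataset, factor: int) -> NMADataset:
    """Multiply every count by ``factor``, capping per outcome at n.

    Patients, exposure and mean follow-up are left untouched — that is what
    drives the average event rates upward.  Returns a new validated dataset.
    """
    if factor < 1:
        raise ValueError(f"inflation factor must be >= 1, got {factor}")
    studies = []
    for study in dataset.studies:
        arms = []
        for arm in study.arms:
            counts = {
                m: min(factor * r, arm.n_randomized) for m, r in arm.counts.items()
            }
            if study.data_format == 1:
                counts = _reconcile_first_event_cap(counts, arm, study, factor)
            arms.append(replace(arm, counts=counts))
        studies.append(replace(study, arms=arms))
    out = replace(dataset, studies=studies)
    out.validate()
    return out


def _reconcile_first_event_cap(
    counts: dict[int, int], arm: ArmRecord, study: StudyRecord, factor: int
) -> dict[int, int]:
    """Scale a format-1 arm's capped counts so first events sum to <= n.

    Largest-remainder rounding keeps the relative composition of outcomes
    while restoring the pigeonhole constraint each-patient-has-at-most-one-
    first-event.
    """
    total = sum(counts.values())
    n = arm.n_randomized
    if total <= n:
        return counts
    keys = sorted(counts)
    raw = np.array([counts[m] for m in keys], dtype=float) * (n / total)
    floor = np.floor(raw).astype(int)
    remainder = raw - floor
    short = n - int(floor.sum())
    order = np.argsort(-remainder)
    floor[order[:short]] += 1
    logger.warning(
        "inflate(factor=%d): study %r arm %d first-event counts summed to %d "
        "> n=%d after per-outcome capping; proportionally reduced",
        factor, study.study_id, arm.arm_index, total, n,
    )
    return {m: int(c) for m, c in zip(keys, floor)}


def average_event_rate(dataset: NMADataset, outcome: int) -> float:
    """Mean of r/n over every arm reporting the outcome, across all trials."""
    props = [
        arm.counts[outcome] / arm.n_randomized
        for study in dataset.studies
        for arm in study.arms
        if outcome in arm.counts
    ]
    if not props:
        raise ValueError(f"outcome {outcome} is not reported by any study")
    return float(np.mean(props))
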