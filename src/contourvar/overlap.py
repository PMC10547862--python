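"""Volume statistics and Dice overlap statistics for an observer cohort.

Two overlap summaries are computed: the mean +/- SD of the Dice
coefficient over all unordered observer pairs, and the generalized
(multi-observer) Dice coefficient, which aggregates all pairwise overlaps
and sizes into one number and reduces to the pairwise Dice when n = 2.
Volumes are voxel counts times the voxel volume (exact), in cm^3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import BinaryMask, ObserverCohort

__all__ = [
    "OverlapStats",
    "dice",
    "generalized_dice",
    "cohort_overlap_stats",
    "write_dice_matrix",
]


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|) by voxel counts.

    1 means identical volumes, 0 means no overlap. Two empty masks are
    defined as Dice 1 (perfect agreement on absence) with a warning; an
    empty mask against a non-empty one gives 0.
    """
    a.grid.require_match(b.grid, context=f"dice({a.label!r}, {b.label!r})")
    na, nb = a.count, b.count
    if na == 0 and nb == 0:
        warnings.warn(
            "Dice of two empty masks defined as 1 (agreement on absence)",
            stacklevel=2,
        )
        return 1.0
    inter = int(np.count_nonzero(a.voxels & b.voxels))
    return 2.0 * inter / (na + nb)


def generalized_dice(cohort: ObserverCohort) -> float:
    """Multi-observer Dice: 2 * sum_pairs |A_i ∩ A_j| / sum_pairs (|A_i| + |A_j|).

    Equals ``dice(a, b)`` exactly when the cohort has two observers.
    """
    counts = [m.count for m in cohort.masks]
    if sum(counts) == 0:
        warnings.warn(
            "generalized Dice of an all-empty cohort defined as 1", stacklevel=2
        )
        return 1.0
    inter_sum = 0
    size_sum = 0
    for i, j in combinations(range(cohort.n_observers), 2):
        inter_sum += int(
            np.count_nonzero(cohort.masks[i].voxels & cohort.masks[j].voxels)
        )
        size_sum += counts[i] + counts[j]
    return 2.0 * inter_sum / size_sum


@dataclass
class OverlapStats:
    """Pairwise Dice matrix plus volume and Dice summary statistics."""

    observer_labels: list[str]
    pairwise_dice: np.ndarray  # symmetric, unit diagonal
    dice_mean: float
    dice_sd: float  # NaN when only one pair exists
    generalized_dice: float
    per_observer_volume_cm3: np.ndarray
    volume_mean_cm3: float
    volume_sd_cm3: float
    volume_min_cm3: float
    volume_max_cm3: float

    @property
    def volume_range_cm3(self) -> tuple[float, float]:
        return (self.volume_min_cm3, self.volume_max_cm3)


def cohort_overlap_stats(cohort: ObserverCohort) -> OverlapStats:
    """All volume and overlap statistics for one cohort.

    ``dice_mean``/``dice_sd`` are the mean and sample SD over the
    n(n-1)/2 unordered pairs; with a single pair (n = 2) the SD is NaN.
    """
    n = cohort.n_observers
    mat = np.eye(n)
    pairs = []
    for i, j in combinations(range(n), 2):
        d = dice(cohort.masks[i], cohort.masks[j])
        mat[i, j] = mat[j, i] = d
        pairs.append(d)
    pairs = np.asarray(pairs)
    vols = np.asarray([m.volume_cm3 for m in cohort.masks])
    return OverlapStats(
        observer_labels=cohort.labels,
        pairwise_dice=mat,
        dice_mean=float(pairs.mean()),
        dice_sd=float(pairs.std(ddof=1)) if len(pairs) > 1 else float("nan"),
        generalized_dice=generalized_dice(cohort),
        per_observer_volume_cm3=vols,
        volume_mean_cm3=float(vols.mean()),
        volume_sd_cm3=float(vols.std(ddof=1)),
        volume_min_cm3=float(vols.min()),
        volume_max_cm3=float(vols.max()),
    )


def write_dice_matrix(stats: OverlapStats, path: str | Path) -> None:
    """Export the pairwise Dice matrix as CSV with observer labels."""
    df = pd.DataFrame(
        stats.pairwise_dice, index=stats.observer_labels, columns=stats.observer_labels
    )
    df.to_csv(path, float_format="%.6f")
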