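"""Per-case agreement report: the summary-table schema and its serialisation.

One report row per case: median structure volume (cm^3), mean +/- SD and
range of the observer volumes (cm^3), overall RMS-SD (cm), Dice mean +/- SD
over all observer pairs, and the generalized Dice. The CSV carries one row
per case; the JSON companion additionally holds per-observer volumes, the
full pairwise Dice matrix and a provenance block complete enough to
reproduce every number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["AgreementReport", "write_report", "read_report", "REPORT_COLUMNS"]

REPORT_COLUMNS = [
    "case_id",
    "n_observers",
    "median_structure_volume_cm3",
    "volume_mean_cm3",
    "volume_sd_cm3",
    "volume_min_cm3",
    "volume_max_cm3",
    "rms_sd_cm",
    "dice_mean",
    "dice_sd",
    "generalized_dice",
]


@dataclass
class AgreementReport:
    """Summary statistics for one multi-observer case."""

    case_id: str
    n_observers: int
    median_structure_volume_cm3: float
    volume_mean_cm3: float
    volume_sd_cm3: float
    volume_min_cm3: float
    volume_max_cm3: float
    rms_sd_cm: float  # NaN when the median structure is empty
    dice_mean: float
    dice_sd: float  # NaN when only one observer pair exists
    generalized_dice: float
    per_observer_volume_cm3: dict[str, float] = field(default_factory=dict)
    pairwise_dice: dict[str, dict[str, float]] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("dice_mean", "generalized_dice"):
            v = getattr(self, name)
            if np.isfinite(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in (
            "median_structure_volume_cm3",
            "volume_mean_cm3",
            "volume_sd_cm3",
        ):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name}={v} must be >= 0")

    def row(self) -> dict:
        return {c: getattr(self, c) for c in REPORT_COLUMNS}

    def to_json_dict(self) -> dict:
        doc = self.row()
        doc["per_observer_volume_cm3"] = self.per_observer_volume_cm3
        doc["pairwise_dice"] = self.pairwise_dice
        doc["provenance"] = self.provenance
        return doc


def _frame(reports: list[AgreementReport]) -> pd.DataFrame:
    return pd.DataFrame([r.row() for r in reports], columns=REPORT_COLUMNS)


def write_report(
    reports: AgreementReport | list[AgreementReport], path: str | Path
) -> None:
    """Write report rows as CSV (numbers to 3 decimals, NaN as empty cell).

    A JSON file with full per-observer and per-pair detail plus provenance
    is written alongside (same stem, ``.json`` suffix).
    """
    if isinstance(reports, AgreementReport):
        reports = [reports]
    path = Path(path)
    _frame(reports).to_csv(path, index=False, float_format="%.3f", na_rep="")
    payload = [r.to_json_dict() for r in reports]
    path.with_suffix(".json").write_text(json.dumps(payload, indent=1, allow_nan=True))


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back the CSV rows (empty cells become NaN)."""
    return pd.read_csv(path)
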