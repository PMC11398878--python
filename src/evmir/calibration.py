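"""Inter-plate calibrator (IPC) correction.

Identical calibrator reactions are run in triplicate on every plate;
plate-to-plate shifts of their mean Cq estimate the plate effect.  The
default correction mean-centres every plate to the grand mean IPC Cq
(no privileged plate); a reference-plate mode centres to one named
plate instead.  Within-plate Cq differences — and hence every dCq — are
unchanged by either mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CalibrationError
from .plate_io import CqMatrix, RunData


@dataclass
class PlateFactors:
    """Additive per-plate Cq corrections; corrected plate means equal
    ``reference_level``."""

    corrections: dict[str, float]
    reference_level: float
    plate_ipc_means: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path, run_id: str | None = None) -> None:
        payload = {
            "run_id": run_id,
            "written_at": datetime.now(timezone.utc).isoformat(timespec="seconds"),
            "reference_level": self.reference_level,
            "plate_ipc_means": self.plate_ipc_means,
            "corrections": self.corrections,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def ipc_factors(run: RunData, reference_plate: str | None = None) -> PlateFactors:
    """Per-plate correction from the IPC wells.

    correction_p = L - m_p where m_p is the plate's mean IPC Cq and L is
    the grand mean of the m_p (or the reference plate's m_p when
    ``reference_plate`` is given).
    """
    ipc = run.wells.loc[(run.wells["role"] == "ipc") & run.wells["cq"].notna()]
    plate_ids = run.plate_ids
    means: dict[str, float] = {}
    for plate in plate_ids:
        vals = ipc.loc[ipc["plate_id"] == plate, "cq"]
        if vals.empty:
            raise CalibrationError(f"plate {plate!r} has no usable IPC wells")
        means[plate] = float(vals.mean())
    if reference_plate is not None:
        if reference_plate not in means:
            raise CalibrationError(f"unknown reference plate {reference_plate!r}")
        level = means[reference_plate]
    else:
        level = float(np.mean(list(means.values())))
    corrections = {p: level - m for p, m in means.items()}
    return PlateFactors(corrections=corrections, reference_level=level, plate_ipc_means=means)


def apply_calibration(matrix: CqMatrix, factors: PlateFactors) -> CqMatrix:
    """Shift each sample's Cqs by its plate's correction; missing stays missing."""
    unknown = {p for p in matrix.plate_of.values() if p not in factors.corrections}
    if unknown:
        raise CalibrationError(f"no correction for plate(s) {sorted(unknown)}")
    shift = pd.Series(
        {sid: factors.corrections[p] for sid, p in matrix.plate_of.items()}
    ).reindex(matrix.values.index)
    out = matrix.copy()
    out.values = matrix.values.add(shift, axis=0)
    return out
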