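"""Sample-level quality control.

Three layers, mirroring standard practice for plasma miRNA qPCR panels:

* spike-in monitoring — UniSp2/4/5 track RNA extraction, UniSp6 and
  cel-miR-39-3p track reverse transcription; a sample whose spike-in Cq
  falls outside the run-level acceptance window fails;
* endogenous signal — the mean Cq over six endogenous miRNAs measures
  overall cDNA yield;
* haemolysis — dCq = Cq(miR-23a-3p) - Cq(miR-451a); miR-451a is
  erythrocyte-enriched, so large values indicate red-cell contamination.
  Flagged samples whose panel Cqs still sit inside the Tukey fences are
  retained with a note rather than excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError
from .panel import (
    HAEMOLYSIS_PAIR,
    SIGNAL_QC_TARGETS,
    SPIKEIN_EXTRACTION,
    SPIKEIN_RT,
)
from .plate_io import CqMatrix, RunData

HAEMOLYSIS_THRESHOLD = 7.0  # dCq cycles at or above which a sample is flagged
IQR_MULTIPLIER = 1.5


def haemolysis_delta(
    cq_23a: float, cq_451a: float, threshold: float = HAEMOLYSIS_THRESHOLD
) -> tuple[float, bool | None]:
    """Haemolysis dCq and flag.

    Returns ``(delta, flagged)``; ``flagged`` is inclusive at the
    threshold (delta >= threshold).  If either Cq is absent the result is
    indeterminate: ``(nan, None)`` — never a silent pass.
    """
    if cq_23a is None or cq_451a is None or math.isnan(cq_23a) or math.isnan(cq_451a):
        return math.nan, None
    delta = cq_23a - cq_451a
    return delta, delta >= threshold


class IqrFences(NamedTuple):
    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float


def iqr_fences(values: Sequence[float], k: float = IQR_MULTIPLIER) -> IqrFences:
    """Quartiles and Tukey fences with multiplier ``k``.

    Quartiles use linear interpolation of the empirical distribution
    (numpy's default, the "type 7" rule).  Requires at least 4 finite
    values.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 4:
        raise InsufficientDataError(
            f"need >= 4 finite values for quartiles, got {arr.size}"
        )
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    return IqrFences(float(q1), float(q3), float(iqr), float(q1 - k * iqr), float(q3 + k * iqr))


@dataclass
class QCConfig:
    haemolysis_threshold: float = HAEMOLYSIS_THRESHOLD
    iqr_k: float = IQR_MULTIPLIER
    spikein_sd_mult: float = 2.0  # run-level window: mean +/- mult * SD
    low_signal_max_cq: float = 35.0  # signal mean above this flags low_signal
    exclude_flagged: bool = False  # drop haemolysis-flagged samples on request


@dataclass
class QCReport:
    """Per-sample QC table plus run-level context.

    ``table`` has one row per sample: spike-in Cqs, ``signal_mean``,
    ``haemolysis_delta``, boolean flags (``haemolysis_flag`` is NA when
    indeterminate), ``within_iqr`` for flagged samples, and a free-text
    ``note``.
    """

    table: pd.DataFrame
    iqr_context: IqrFences
    spikein_windows: dict[str, tuple[float, float]] = field(default_factory=dict)
    excluded_samples: list[str] = field(default_factory=list)

    @property
    def flagged_samples(self) -> list[str]:
        flags = self.table["haemolysis_flag"]
        return list(self.table.index[flags.fillna(False).astype(bool)])


def _spikein_cqs(run: RunData) -> pd.DataFrame:
    """Mean spike-in Cq per sample (spike-ins live outside the Cq grid)."""
    spikes = [*SPIKEIN_EXTRACTION, *SPIKEIN_RT]
    sw = run.wells.loc[
        (run.wells["role"] == "sample") & (run.wells["target"].isin(spikes))
    ]
    return sw.groupby(["sample_id", "target"])["cq"].mean().unstack("target")


def run_qc(matrix: CqMatrix, run: RunData, config: QCConfig | None = None) -> QCReport:
    """Evaluate every sample against the QC panel.

    The spike-in acceptance window per assay is learned from the run
    itself (mean +/- ``spikein_sd_mult`` SD across samples).  Haemolysis
    flagging is inclusive at the threshold; flagged samples whose
    fingerprint/panel Cqs lie within the pooled IQR fences are retained
    with a note (``excluded_samples`` is populated only when
    ``exclude_flagged`` is set).
    """
    config = config or QCConfig()
    present = set(run.wells["target"])
    needed = [*SPIKEIN_EXTRACTION, *SPIKEIN_RT, *SIGNAL_QC_TARGETS]
    for target in needed:
        if target not in present:
            raise ConfigurationError(f"QC target {target!r} absent from the run")

    spikes = _spikein_cqs(run).reindex(matrix.sample_ids)
    windows: dict[str, tuple[float, float]] = {}
    spike_fail = pd.Series(False, index=matrix.values.index)
    for target in spikes.columns:
        col = spikes[target]
        mu, sd = float(col.mean()), float(col.std(ddof=1))
        lo, hi = mu - config.spikein_sd_mult * sd, mu + config.spikein_sd_mult * sd
        windows[target] = (lo, hi)
        spike_fail |= (col < lo) | (col > hi) | col.isna()

    signal = matrix.values[[t for t in SIGNAL_QC_TARGETS]]
    signal_mean = signal.mean(axis=1)

    cq23 = matrix.values[HAEMOLYSIS_PAIR[0]]
    cq451 = matrix.values[HAEMOLYSIS_PAIR[1]]
    delta = cq23 - cq451
    flag = pd.array(
        [None if math.isnan(d) else d >= config.haemolysis_threshold for d in delta],
        dtype="boolean",
    )

    # Pooled Cq distribution of the endogenous panel, as IQR context.
    pooled = matrix.values.to_numpy(dtype=float).ravel()
    fences = iqr_fences(pooled, k=config.iqr_k)

    # "otherwise within acceptable ranges": judge the sample's remaining
    # panel Cqs, excluding the haemolysis marker pair itself.
    rest = matrix.values[[t for t in matrix.targets if t not in HAEMOLYSIS_PAIR]]
    within = rest.apply(
        lambda row: bool(
            np.all(
                (row.dropna() >= fences.lower_fence) & (row.dropna() <= fences.upper_fence)
            )
        ),
        axis=1,
    )

    notes = []
    for sid, fl, w in zip(matrix.sample_ids, flag, within):
        if fl is pd.NA or fl is None:
            notes.append("haemolysis indeterminate")
        elif fl and w:
            notes.append("haemolysis flagged; panel Cqs within IQR fences; retained")
        elif fl:
            notes.append("haemolysis flagged; panel Cqs outside IQR fences")
        else:
            notes.append("")

    table = pd.DataFrame(index=pd.Index(matrix.sample_ids, name="sample_id"))
    for target in spikes.columns:
        table[f"cq_{target}"] = spikes[target]
    table["signal_mean"] = signal_mean
    table["haemolysis_delta"] = delta
    table["haemolysis_flag"] = flag
    table["spikein_fail"] = spike_fail
    table["low_signal"] = signal_mean > config.low_signal_max_cq
    table["within_iqr"] = within
    table["note"] = notes

    excluded = []
    if config.exclude_flagged:
        excluded = list(table.index[table["haemolysis_flag"].fillna(False).astype(bool)])

    return QCReport(
        table=table,
        iqr_context=fences,
        spikein_windows=windows,
        excluded_samples=excluded,
    )
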