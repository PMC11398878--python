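"""Plate-level qPCR data: reading, writing, validation, replicate collapse.

The on-disk dialect is a long-format CSV per plate with the columns
``plate_id, well, role, sample_id, target, cq, melt_pass`` plus a
metadata CSV with ``sample_id, cohort, sex, age_group, batch``.  A Cq is
absent ("Undetermined" or empty) when no amplification was detected
within 40 cycles; absence is kept as a missing value, never imputed as
the cycle ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import PlateFormatError, ValidationError
from .panel import COHORTS, GRID_ROLES, TARGET_ROLE_VALUES, default_target_roles

PLATE_COLUMNS = ["plate_id", "well", "role", "sample_id", "target", "cq", "melt_pass"]
METADATA_COLUMNS = ["sample_id", "cohort", "sex", "age_group", "batch"]
REQUIRED_METADATA_COLUMNS = ["sample_id", "cohort"]

#: Strings the reader maps to an absent Cq (no amplification in 40 cycles).
UNDETERMINED_SENTINELS = {"", "undetermined", "n/a", "na", "nan"}

MAX_CYCLES = 40.0


@dataclass(frozen=True)
class Well:
    """One reaction well of a qPCR plate."""

    plate_id: str
    well_id: str
    role: str  # sample | ipc | ntc
    target: str
    sample_id: str | None = None
    cq: float | None = None
    melt_pass: bool | None = None

    def __post_init__(self) -> None:
        if self.role not in {"sample", "ipc", "ntc"}:
            raise ValidationError(f"unknown well role {self.role!r}")
        if self.role == "ntc" and self.sample_id is not None:
            raise ValidationError("no-template control wells carry no sample_id")
        if self.role == "sample" and self.sample_id is None:
            raise ValidationError("sample wells require a sample_id")
        if self.cq is not None:
            if not math.isfinite(self.cq) or not (0.0 < self.cq <= MAX_CYCLES):
                raise ValidationError(
                    f"cq must be finite and in (0, {MAX_CYCLES:g}], got {self.cq!r}"
                )


@dataclass
class RunData:
    """All wells of one or more plates plus the sample metadata.

    ``wells`` and ``metadata`` are kept as DataFrames with the dialect
    columns; ``target_roles`` assigns each target appearing in the wells
    one role.
    """

    wells: pd.DataFrame
    metadata: pd.DataFrame
    target_roles: dict[str, str]

    def validate(self) -> None:
        for col in PLATE_COLUMNS:
            if col not in self.wells.columns:
                raise PlateFormatError(f"wells table is missing column {col!r}")
        for col in REQUIRED_METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise PlateFormatError(f"metadata table is missing column {col!r}")

        dup = self.wells.duplicated(subset=["plate_id", "well"])
        if dup.any():
            first = self.wells.loc[dup, ["plate_id", "well"]].iloc[0]
            raise ValidationError(
                f"duplicate well {first['well']!r} on plate {first['plate_id']!r}"
            )

        bad_roles = set(self.wells["role"]) - {"sample", "ipc", "ntc"}
        if bad_roles:
            raise ValidationError(f"unknown well roles: {sorted(bad_roles)}")

        ntc = self.wells["role"] == "ntc"
        if self.wells.loc[ntc, "sample_id"].notna().any():
            raise ValidationError("no-template control wells must not carry a sample_id")

        cq = self.wells["cq"]
        present = cq.notna()
        if present.any():
            vals = cq[present].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)) or np.any(vals <= 0) or np.any(vals > MAX_CYCLES):
                raise ValidationError(f"cq values must be finite and in (0, {MAX_CYCLES:g}]")

        if self.metadata["sample_id"].duplicated().any():
            dups = self.metadata.loc[self.metadata["sample_id"].duplicated(), "sample_id"]
            raise ValidationError(f"duplicate sample_id in metadata: {dups.iloc[0]!r}")
        bad_cohorts = set(self.metadata["cohort"]) - set(COHORTS)
        if bad_cohorts:
            raise ValidationError(
                f"cohort labels outside {COHORTS}: {sorted(bad_cohorts)}"
            )

        sample_wells = self.wells.loc[self.wells["role"] == "sample"]
        known = set(self.metadata["sample_id"])
        missing = set(sample_wells["sample_id"].dropna()) - known
        if missing:
            raise ValidationError(
                f"sample ids present on plates but absent from metadata: {sorted(missing)[:5]}"
            )

        targets = set(self.wells["target"])
        unmapped = targets - set(self.target_roles)
        if unmapped:
            raise ValidationError(
                f"targets without an assigned role: {sorted(unmapped)[:5]}"
            )
        bad = {t: r for t, r in self.target_roles.items() if r not in TARGET_ROLE_VALUES}
        if bad:
            raise ValidationError(f"unknown target roles: {bad}")

    @property
    def plate_ids(self) -> list[str]:
        return sorted(self.wells["plate_id"].unique())

    def grid_targets(self) -> list[str]:
        """Targets that enter the sample x target Cq grid, in panel order."""
        order = {t: i for i, t in enumerate(self.target_roles)}
        keep = [
            t
            for t in self.wells["target"].unique()
            if self.target_roles[t] in GRID_ROLES
        ]
        return sorted(keep, key=lambda t: order.get(t, len(order)))


@dataclass
class CqMatrix:
    """Calibrated or raw Cq values, samples x targets, NaN = not detected."""

    values: pd.DataFrame  # index: sample_id, columns: target
    plate_of: dict[str, str]
    replicate_report: pd.DataFrame | None = field(default=None, compare=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def targets(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "CqMatrix":
        return CqMatrix(self.values.copy(), dict(self.plate_of), self.replicate_report)


def _parse_cq(raw: object) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return math.nan
    text = str(raw).strip()
    if text.lower() in UNDETERMINED_SENTINELS:
        return math.nan
    try:
        return float(text)
    except ValueError as exc:
        raise PlateFormatError(f"unparseable cq value {raw!r}") from exc


def _parse_melt(raw: object) -> object:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return pd.NA
    text = str(raw).strip().lower()
    if text in {"", "na", "nan"}:
        return pd.NA
    if text in {"true", "1", "pass"}:
        return True
    if text in {"false", "0", "fail"}:
        return False
    raise PlateFormatError(f"unparseable melt_pass value {raw!r}")


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    """Read one plate file in the long CSV dialect."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise PlateFormatError(f"{path}: missing column {missing[0]!r}")
    df = df[PLATE_COLUMNS].copy()
    df["cq"] = [_parse_cq(v) for v in df["cq"]]
    df["melt_pass"] = pd.array([_parse_melt(v) for v in df["melt_pass"]], dtype="boolean")
    df["sample_id"] = df["sample_id"].replace("", np.nan)
    return df


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise PlateFormatError(f"{path}: missing column {missing[0]!r}")
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df = df[METADATA_COLUMNS]
    return df.where(df != "", other=np.nan)


def load_run(
    plate_paths: Sequence[str | Path],
    metadata_path: str | Path,
    target_roles: Mapping[str, str] | None = None,
) -> RunData:
    """Load plate files plus metadata into a validated :class:`RunData`.

    Unknown targets must be covered by ``target_roles`` (defaults to the
    standard panel role map); anything unmapped is rejected.
    """
    frames = [read_plate_csv(p) for p in plate_paths]
    wells = pd.concat(frames, ignore_index=True)
    metadata = read_metadata_csv(metadata_path)
    roles = default_target_roles()
    if target_roles:
        roles.update(target_roles)
    run = RunData(wells=wells, metadata=metadata, target_roles=roles)
    run.validate()
    return run


def write_run(run: RunData, directory: str | Path) -> dict[str, Path]:
    """Write one CSV per plate plus ``metadata.csv``; returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for plate_id, chunk in run.wells.groupby("plate_id", sort=True):
        out = chunk.copy()
        out["cq"] = [("" if pd.isna(v) else repr(float(v))) for v in out["cq"]]
        out["melt_pass"] = [
            ("" if pd.isna(v) else ("true" if v else "false")) for v in out["melt_pass"]
        ]
        out["sample_id"] = out["sample_id"].fillna("")
        path = directory / f"plate_{plate_id}.csv"
        out[PLATE_COLUMNS].to_csv(path, index=False)
        paths[str(plate_id)] = path
    meta = run.metadata.fillna("")
    meta_path = directory / "metadata.csv"
    meta.to_csv(meta_path, index=False)
    paths["metadata"] = meta_path
    return paths


def build_cq_matrix(run: RunData, spread_threshold: float = 1.0) -> CqMatrix:
    """Collapse replicate sample wells into a sample x target Cq grid.

    Replicates are averaged (arithmetic mean of present Cqs, equivalent to
    a geometric mean on the linear expression scale); IPC and NTC wells
    are excluded.  Replicate spreads above ``spread_threshold`` cycles and
    single-replicate cells are recorded in ``replicate_report``, not
    raised.
    """
    run.validate()
    sw = run.wells.loc[run.wells["role"] == "sample"].copy()
    grid_targets = run.grid_targets()
    sw = sw.loc[sw["target"].isin(grid_targets)]

    plate_of: dict[str, str] = {}
    for sid, chunk in sw.groupby("sample_id"):
        plates = sorted(chunk["plate_id"].unique())
        if len(plates) > 1:
            raise ValidationError(
                f"sample {sid!r} spans plates {plates}; one plate per sample required"
            )
        plate_of[str(sid)] = plates[0]

    grouped = sw.groupby(["sample_id", "target"])["cq"]
    mean = grouped.mean()
    n_present = grouped.count()
    n_wells = grouped.size()
    spread = grouped.max() - grouped.min()

    sample_order = [s for s in run.metadata["sample_id"] if s in plate_of]
    values = mean.unstack("target").reindex(index=sample_order, columns=grid_targets)

    notes = []
    for (sid, target), k in n_present.items():
        total = n_wells.loc[(sid, target)]
        if k == 0:
            continue
        if k < total:
            notes.append((sid, target, "single-replicate" if k == 1 else "partial", float("nan")))
        s = spread.loc[(sid, target)]
        if k >= 2 and s > spread_threshold:
            notes.append((sid, target, "discordant", float(s)))
    report = pd.DataFrame(notes, columns=["sample_id", "target", "note", "spread"])
    return CqMatrix(values=values, plate_of=plate_of, replicate_report=report)


def runs_equal(a: RunData, b: RunData) -> bool:
    """Structural equality of two runs; row order is not significant."""

    def canon(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
        df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)
        # unify the None / NaN missing representations per column
        return df.apply(lambda col: col.where(col.notna(), np.nan))

    try:
        pd.testing.assert_frame_equal(
            canon(a.wells, ["plate_id", "well"]),
            canon(b.wells, ["plate_id", "well"]),
            check_dtype=False,
        )
        pd.testing.assert_frame_equal(
            canon(a.metadata, ["sample_id"]),
            canon(b.metadata, ["sample_id"]),
            check_dtype=False,
        )
    except AssertionError:
        return False
    common = set(a.wells["target"])
    return all(a.target_roles[t] == b.target_roles[t] for t in common)
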