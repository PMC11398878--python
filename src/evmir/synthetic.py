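"""Synthetic plate-structured qPCR cohorts with known ground truth.

The generator emulates the statistical structure of a multi-plate
SYBR-green miRNA study on plasma neural-enriched EVs: four cohorts
(ALS / HC / PD / PLS), eight fingerprint miRNAs whose default group
effects encode the published ALS-vs-control fold regulations, three
reference miRNAs, six endogenous signal-QC miRNAs (two of which form the
haemolysis indicator pair), five spike-ins, triplicate inter-plate
calibrator wells and no-template controls on every plate.

Generative model, on the quantification-cycle (log2 expression) scale::

    Cq(sample s, target t, well w) = base_cq[t] - effect_log2fc[t, cohort(s)]
                                     + u_s + b_st + plate_offset[plate(s)] + eps_w

with per-sample global shift u_s ~ N(0, sigma_sample^2) (extraction yield
and handling, cancelled by reference normalization), per-(sample, target)
biological variation b_st ~ N(0, sigma_bio(t)^2) (small for the stable
reference and signal-QC miRNAs, larger and scaling with dysregulation for
the fingerprint targets) and per-well technical noise
eps_w ~ N(0, sigma_noise^2).  Lower Cq encodes higher expression, so an
effect of +1 on the log2 fold-change scale lowers Cq by one cycle.
Spike-in and IPC wells receive base value + plate offset + technical
noise only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SizingError, ValidationError
from .panel import (
    COHORTS,
    FINGERPRINT_TARGETS,
    HAEMOLYSIS_PAIR,
    IPC_TARGET,
    REFERENCE_TARGETS,
    SIGNAL_QC_TARGETS,
    SPIKEIN_EXTRACTION,
    SPIKEIN_RT,
    default_target_roles,
)
from .plate_io import PLATE_COLUMNS, RunData

#: Published ALS-vs-control fold regulations of the eight-miRNA fingerprint
#: (current cohort, n = 269); negative values are down-regulation and are
#: converted to log2 fold change as -log2(|FR|).
DEFAULT_FOLD_REGULATION_ALS = {
    "miR-10b-5p": -7.38,
    "miR-4454": -2.55,
    "miR-199a-3p": 2.03,
    "miR-151a-3p": 2.09,
    "miR-151a-5p": 1.77,
    "miR-199a-5p": 2.54,
    "miR-146a-5p": 1.57,
    "miR-29b-3p": -1.35,
}


def fold_regulation_to_log2fc(fr: float) -> float:
    """Signed fold regulation -> log2 fold change (FR < 0 means -1/FC)."""
    if fr == 0:
        raise ValueError("fold regulation cannot be 0")
    return math.log2(fr) if fr > 0 else -math.log2(-fr)


def _default_effects() -> dict[tuple[str, str], float]:
    effects: dict[tuple[str, str], float] = {}
    for target, fr in DEFAULT_FOLD_REGULATION_ALS.items():
        effects[(target, "ALS")] = fold_regulation_to_log2fc(fr)
    # PD and PLS resemble healthy controls on this panel by default.
    return effects


def _default_base_cq() -> dict[str, float]:
    base = {
        "miR-10b-5p": 31.0,
        "miR-4454": 29.5,
        "miR-199a-3p": 30.5,
        "miR-151a-3p": 28.5,
        "miR-151a-5p": 29.0,
        "miR-199a-5p": 32.0,
        "miR-146a-5p": 27.5,
        "miR-29b-3p": 30.0,
        "miR-126-5p": 28.0,
        "miR-142-3p": 29.0,
        "miR-451a": 26.0,
        "miR-23a-3p": 30.0,
        "miR-30c-5p": 31.0,
        "miR-103a-3p": 28.5,
        "miR-191-5p": 27.0,
        "UniSp2": 20.0,
        "UniSp4": 24.0,
        "UniSp5": 28.0,
        "UniSp6": 19.0,
        "cel-miR-39-3p": 21.0,
    }
    return base


@dataclass
class SyntheticDesign:
    """Study conditions of a simulated cohort run."""

    cohort_sizes: dict[str, int] = field(
        default_factory=lambda: {"ALS": 119, "HC": 150, "PD": 20, "PLS": 42}
    )
    effect_log2fc: dict[tuple[str, str], float] = field(default_factory=_default_effects)
    ref_targets: tuple[str, ...] = REFERENCE_TARGETS
    base_cq: dict[str, float] = field(default_factory=_default_base_cq)
    sigma_sample: float = 0.8  # per-sample global shift (yield/handling), cycles
    sigma_noise: float = 0.2  # per-well technical noise, cycles
    # per-(sample, target) biological variance: stable for reference and
    # signal-QC miRNAs, scaling with dysregulation for fingerprint targets
    # (strongly regulated miRNAs also vary most between individuals)
    sigma_bio_stable: float = 0.25
    sigma_bio_base: float = 0.35
    sigma_bio_slope: float = 0.15
    plate_offsets: dict[str, float] = field(default_factory=dict)
    plate_offset_sd: float = 0.5  # used when plate_offsets not given
    ipc_base: float = 22.0
    haemolysis_rate: float = 0.02
    haemolysis_shift: float = 4.0  # Cq decrease on miR-451a in affected samples
    outlier_rate: float = 0.002  # fraction of (sample, fingerprint) cells
    outlier_cq_shift: float = 8.0  # cycles subtracted from displaced cells
    invalid_sample_count: int = 3
    invalid_targets_per_sample: int = 5  # 5 of 8 fingerprint targets (>= 50%)
    samples_per_plate: int = 9
    n_plates: int | None = None  # None: as many plates as needed
    replicate_wells: int = 2

    def validate(self) -> None:
        sds = (
            self.sigma_sample,
            self.sigma_noise,
            self.plate_offset_sd,
            self.sigma_bio_stable,
            self.sigma_bio_base,
            self.sigma_bio_slope,
        )
        if min(sds) < 0:
            raise ValidationError("noise SDs must be >= 0")
        for name in ("haemolysis_rate", "outlier_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {rate}")
        bad = set(self.cohort_sizes) - set(COHORTS)
        if bad:
            raise ValidationError(f"unknown cohorts in design: {sorted(bad)}")
        if any(n < 0 for n in self.cohort_sizes.values()):
            raise ValidationError("cohort sizes must be >= 0")
        if self.samples_per_plate < 1 or self.replicate_wells < 1:
            raise ValidationError("samples_per_plate and replicate_wells must be >= 1")
        n = sum(self.cohort_sizes.values())
        if self.n_plates is not None and n > self.n_plates * self.samples_per_plate:
            raise SizingError(
                f"{n} samples exceed capacity of {self.n_plates} plates "
                f"x {self.samples_per_plate} samples"
            )

    def sigma_bio(self, target: str) -> float:
        """Between-individual SD (cycles) of a measured endogenous target."""
        if target in self.ref_targets or target in SIGNAL_QC_TARGETS:
            return self.sigma_bio_stable
        effects = [
            abs(v) for (t, _), v in self.effect_log2fc.items() if t == target
        ]
        return self.sigma_bio_base + self.sigma_bio_slope * (max(effects) if effects else 0.0)

    @property
    def measured_targets(self) -> list[str]:
        """Endogenous targets measured per sample (fingerprint, refs, signal QC)."""
        seen: list[str] = []
        for t in (*FINGERPRINT_TARGETS, *REFERENCE_TARGETS, *SIGNAL_QC_TARGETS):
            if t not in seen:
                seen.append(t)
        return seen

    @property
    def spikein_targets(self) -> list[str]:
        return [*SPIKEIN_EXTRACTION, *SPIKEIN_RT]


@dataclass
class GroundTruth:
    """What the generator injected, for parameter-recovery checks."""

    true_log2fc: dict[tuple[str, str], float]
    plate_assignment: dict[str, str]
    plate_offsets: dict[str, float]
    haemolysed_samples: list[str] = field(default_factory=list)
    outlier_cells: list[tuple[str, str]] = field(default_factory=list)
    invalid_samples: list[str] = field(default_factory=list)


_WELL_IDS = [f"{row}{col}" for row in "ABCDEFGHIJKLMNOP" for col in range(1, 25)]


def _male_fraction(cohort: str) -> float:
    return {"ALS": 0.72, "HC": 0.73, "PD": 0.70, "PLS": 0.59}[cohort]


def simulate_run(design: SyntheticDesign, seed: int) -> tuple[RunData, GroundTruth]:
    """Generate a clean multi-plate run; deterministic for a fixed seed."""
    design.validate()
    rng = np.random.default_rng(seed)

    sample_ids: list[str] = []
    cohorts: list[str] = []
    for cohort in COHORTS:
        n = design.cohort_sizes.get(cohort, 0)
        for i in range(n):
            sample_ids.append(f"{cohort}-{i + 1:03d}")
            cohorts.append(cohort)
    n_samples = len(sample_ids)
    if n_samples == 0:
        raise ValidationError("design yields zero samples")

    # Round-robin blocks of samples_per_plate, in sample order.
    n_plates = math.ceil(n_samples / design.samples_per_plate)
    if design.n_plates is not None:
        n_plates = design.n_plates
    plate_ids = [f"P{i + 1:02d}" for i in range(n_plates)]
    plate_assignment = {
        sid: plate_ids[i // design.samples_per_plate] for i, sid in enumerate(sample_ids)
    }

    if design.plate_offsets:
        offsets = {p: design.plate_offsets.get(p, 0.0) for p in plate_ids}
    else:
        draws = rng.normal(0.0, design.plate_offset_sd, size=n_plates)
        offsets = {p: float(d) for p, d in zip(plate_ids, draws)}

    u = rng.normal(0.0, design.sigma_sample, size=n_samples)

    measured = design.measured_targets
    spikeins = design.spikein_targets
    all_targets = measured + spikeins
    reps = design.replicate_wells
    per_sample = len(all_targets) * reps
    if design.samples_per_plate * per_sample + 6 > len(_WELL_IDS):
        raise SizingError(
            f"{design.samples_per_plate} samples x {per_sample} wells + controls "
            f"exceed a 384-well plate"
        )

    # Expected Cq per sample x target (spike-ins carry no group effect or u_s).
    base = np.array([design.base_cq[t] for t in all_targets])
    effect = np.zeros((n_samples, len(all_targets)))
    for j, target in enumerate(measured):
        for i, cohort in enumerate(cohorts):
            effect[i, j] = design.effect_log2fc.get((target, cohort), 0.0)
    sample_shift = np.zeros((n_samples, len(all_targets)))
    sample_shift[:, : len(measured)] = u[:, None]
    off_vec = np.array([offsets[plate_assignment[s]] for s in sample_ids])

    # between-individual variation per endogenous target (spike-ins exempt)
    bio_sd = np.zeros(len(all_targets))
    bio_sd[: len(measured)] = [design.sigma_bio(t) for t in measured]
    bio = rng.normal(0.0, 1.0, size=(n_samples, len(all_targets))) * bio_sd[None, :]

    mu = base[None, :] - effect + sample_shift + bio + off_vec[:, None]

    eps = rng.normal(0.0, design.sigma_noise, size=(n_samples, len(all_targets), reps))
    cq = np.clip(mu[:, :, None] + eps, 0.5, 40.0)

    well_arr = np.array(_WELL_IDS)
    pos = np.arange(n_samples) % design.samples_per_plate
    sample_well_idx = pos[:, None] * per_sample + np.arange(per_sample)[None, :]

    plate_col = np.repeat([plate_assignment[s] for s in sample_ids], per_sample)
    well_col = well_arr[sample_well_idx.ravel()]
    sid_col = np.repeat(sample_ids, per_sample)
    target_col = np.tile(np.repeat(all_targets, reps), n_samples)
    cq_col = cq.reshape(n_samples, -1).ravel()

    wells = pd.DataFrame(
        {
            "plate_id": plate_col,
            "well": well_col,
            "role": "sample",
            "sample_id": sid_col,
            "target": target_col,
            "cq": cq_col,
            "melt_pass": True,
        }
    )

    # IPC triplicates and no-template controls per plate, after sample wells.
    samples_on_plate = {
        p: sum(1 for s in sample_ids if plate_assignment[s] == p) for p in plate_ids
    }
    ipc_eps = rng.normal(0.0, design.sigma_noise, size=(n_plates, 3))
    control_rows = []
    for p_idx, plate in enumerate(plate_ids):
        cursor = samples_on_plate[plate] * per_sample
        for k in range(3):
            val = float(np.clip(design.ipc_base + offsets[plate] + ipc_eps[p_idx, k], 0.5, 40.0))
            control_rows.append(
                (plate, _WELL_IDS[cursor + k], "ipc", None, IPC_TARGET, val, True)
            )
        for k, target in enumerate(FINGERPRINT_TARGETS[:3]):
            control_rows.append(
                (plate, _WELL_IDS[cursor + 3 + k], "ntc", None, target, math.nan, None)
            )
    controls = pd.DataFrame(control_rows, columns=PLATE_COLUMNS)
    wells = pd.concat([wells, controls], ignore_index=True)[PLATE_COLUMNS]
    wells["melt_pass"] = pd.array(wells["melt_pass"], dtype="boolean")

    sex_draw = rng.random(n_samples)
    sex = [
        "M" if d < _male_fraction(c) else "F" for d, c in zip(sex_draw, cohorts)
    ]
    age_bins = ["<30", "30-39", "40-49", "50-59", "60-69", "70-79", "80-89"]
    age = [age_bins[i] for i in rng.choice(len(age_bins), size=n_samples, p=[0.02, 0.06, 0.12, 0.35, 0.25, 0.16, 0.04])]
    half = n_plates // 2 or 1
    batch = ["Jan2023" if int(plate_assignment[sid][1:]) <= half else "Aug2023" for sid in sample_ids]
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort": cohorts,
            "sex": sex,
            "age_group": age,
            "batch": batch,
        }
    )

    run = RunData(wells=wells, metadata=metadata, target_roles=default_target_roles())
    run.validate()

    truth = GroundTruth(
        true_log2fc={
            (t, c): design.effect_log2fc.get((t, c), 0.0)
            for t in FINGERPRINT_TARGETS
            for c in COHORTS
            if c != "HC" and design.cohort_sizes.get(c, 0) > 0
        },
        plate_assignment=plate_assignment,
        plate_offsets=offsets,
    )
    return run, truth


def corrupt_run(
    run: RunData, design: SyntheticDesign, seed: int, truth: GroundTruth | None = None
) -> tuple[RunData, GroundTruth]:
    """Inject haemolysis, extreme outlier cells and invalid samples.

    Haemolysis lowers the miR-451a Cq (more erythrocyte miRNA) in a random
    fraction of samples; extreme cells and invalid samples have selected
    fingerprint Cqs displaced downward by ``outlier_cq_shift`` cycles,
    i.e. far beyond the four-standard-deviation band on the fold-change
    scale.  With all corruption rates zero the run is returned unchanged.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    wells = run.wells.copy()
    sample_ids = list(run.metadata["sample_id"])
    n = len(sample_ids)

    if design.invalid_sample_count > n:
        raise SizingError(
            f"cannot invalidate {design.invalid_sample_count} of {n} samples"
        )

    if truth is None:
        truth = GroundTruth(true_log2fc={}, plate_assignment={}, plate_offsets={})
    truth = GroundTruth(
        true_log2fc=dict(truth.true_log2fc),
        plate_assignment=dict(truth.plate_assignment),
        plate_offsets=dict(truth.plate_offsets),
    )

    n_haem = int(round(design.haemolysis_rate * n))
    haemolysed = sorted(rng.choice(sample_ids, size=n_haem, replace=False).tolist()) if n_haem else []
    marker = HAEMOLYSIS_PAIR[1]  # miR-451a
    for sid in haemolysed:
        mask = (wells["sample_id"] == sid) & (wells["target"] == marker)
        wells.loc[mask, "cq"] = (wells.loc[mask, "cq"] - design.haemolysis_shift).clip(lower=0.5)
    truth.haemolysed_samples = haemolysed

    # Displace only fingerprint targets that are not simultaneously
    # normalization references: a displaced reference shifts the sample's
    # own normalization factor and partially conceals the aberration the
    # downstream filter is defined on.
    pool = [t for t in FINGERPRINT_TARGETS if t not in design.ref_targets]
    if design.invalid_targets_per_sample > len(pool):
        pool = list(FINGERPRINT_TARGETS)

    invalid = (
        sorted(rng.choice(sample_ids, size=design.invalid_sample_count, replace=False).tolist())
        if design.invalid_sample_count
        else []
    )
    outlier_cells: list[tuple[str, str]] = []
    for sid in invalid:
        picks = rng.choice(len(pool), size=design.invalid_targets_per_sample, replace=False)
        for t_idx in sorted(picks):
            outlier_cells.append((sid, pool[t_idx]))
    truth.invalid_samples = invalid

    eligible = [
        (sid, t) for sid in sample_ids if sid not in invalid for t in pool
    ]
    n_out = int(round(design.outlier_rate * len(eligible)))
    if n_out:
        picks = rng.choice(len(eligible), size=n_out, replace=False)
        extreme = [eligible[i] for i in sorted(picks)]
    else:
        extreme = []
    truth.outlier_cells = extreme
    all_displaced = outlier_cells + extreme

    # Displace on the fold-change scale: the new Cq is set relative to the
    # sample's own reference mean so that, after dCq/ddCq normalization,
    # every displaced cell lands near 2^outlier_cq_shift times the control
    # baseline — uniformly across cohorts and noise realizations, far
    # beyond the 4-SD band even after the displaced values themselves
    # inflate the pooled SD.
    base_ref_mean = float(np.mean([design.base_cq[r] for r in design.ref_targets]))
    for sid, target in all_displaced:
        sel_ref = (wells["sample_id"] == sid) & wells["target"].isin(design.ref_targets)
        ref_mean = float(wells.loc[sel_ref, "cq"].mean())
        baseline_dcq = design.base_cq[target] - base_ref_mean
        new_cq = max(ref_mean + baseline_dcq - design.outlier_cq_shift, 0.5)
        mask = (wells["sample_id"] == sid) & (wells["target"] == target)
        wells.loc[mask, "cq"] = new_cq

    out = RunData(wells=wells, metadata=run.metadata.copy(), target_roles=dict(run.target_roles))
    out.validate()
    return out, truth
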