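"""The measured assay panel.

Eight fingerprint miRNAs form the diagnostic signature; three miRNAs serve
as the normalization reference set (two of them — miR-146a-5p and
miR-29b-3p — are simultaneously fingerprint members, a deliberate overlap
of the assay design that the pipeline reproduces); six endogenous miRNAs
monitor sample signal, two of which double as the haemolysis indicator
pair; five synthetic spike-ins monitor RNA extraction (UniSp2/4/5) and
reverse transcription (UniSp6, cel-miR-39-3p); a single inter-plate
calibrator assay is run in triplicate on every plate.
"""

from __future__ import annotations

FINGERPRINT_TARGETS: tuple[str, ...] = (
    "miR-10b-5p",
    "miR-4454",
    "miR-199a-3p",
    "miR-151a-3p",
    "miR-151a-5p",
    "miR-199a-5p",
    "miR-146a-5p",
    "miR-29b-3p",
)

REFERENCE_TARGETS: tuple[str, ...] = ("miR-146a-5p", "miR-29b-3p", "miR-126-5p")

SIGNAL_QC_TARGETS: tuple[str, ...] = (
    "miR-142-3p",
    "miR-451a",
    "miR-23a-3p",
    "miR-30c-5p",
    "miR-103a-3p",
    "miR-191-5p",
)

# cq(miR-23a-3p) - cq(miR-451a); miR-451a is erythrocyte-enriched, so a large
# difference indicates red-cell contamination of the plasma sample.
HAEMOLYSIS_PAIR: tuple[str, str] = ("miR-23a-3p", "miR-451a")

SPIKEIN_EXTRACTION: tuple[str, ...] = ("UniSp2", "UniSp4", "UniSp5")
SPIKEIN_RT: tuple[str, ...] = ("UniSp6", "cel-miR-39-3p")
IPC_TARGET: str = "IPC"

COHORTS: tuple[str, ...] = ("ALS", "HC", "PD", "PLS")

#: Roles a target may take in a run.  A target carries exactly one role;
#: overlaps of the assay design (fingerprint miRNAs reused as references,
#: signal miRNAs reused as the haemolysis pair) are expressed by the named
#: tuples above, with precedence fingerprint > reference > signal_qc.
TARGET_ROLE_VALUES = frozenset(
    {
        "fingerprint",
        "reference",
        "signal_qc",
        "haemolysis",
        "spikein_extraction",
        "spikein_rt",
        "ipc",
    }
)

#: Roles whose targets enter the sample x target Cq grid.
GRID_ROLES = frozenset({"fingerprint", "reference", "signal_qc", "haemolysis"})


def default_target_roles() -> dict[str, str]:
    """Role map for the standard panel (single role per target)."""
    roles: dict[str, str] = {}
    for t in SIGNAL_QC_TARGETS:
        roles[t] = "signal_qc"
    for t in REFERENCE_TARGETS:
        roles[t] = "reference"
    for t in FINGERPRINT_TARGETS:
        roles[t] = "fingerprint"
    for t in SPIKEIN_EXTRACTION:
        roles[t] = "spikein_extraction"
    for t in SPIKEIN_RT:
        roles[t] = "spikein_rt"
    roles[IPC_TARGET] = "ipc"
    return roles
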