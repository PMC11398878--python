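import numpy as np
import pandas as pd
import pytest

from evmir import SyntheticDesign, build_cq_matrix, simulate_run
from evmir.panel import FINGERPRINT_TARGETS
from evmir.plate_io import PLATE_COLUMNS, RunData
from evmir.panel import default_target_roles


@pytest.fixture(scope="session")
def small_design() -> SyntheticDesign:
    """Scaled-down cohort keeping the default effect sizes and noise."""
    return SyntheticDesign(
        cohort_sizes={"ALS": 12, "HC": 12, "PD": 6, "PLS": 6},
        invalid_sample_count=0,
        outlier_rate=0.0,
        haemolysis_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_run(small_design):
    run, truth = simulate_run(small_design, seed=42)
    return run, truth


@pytest.fixture(scope="session")
def small_matrix(small_run):
    run, _ = small_run
    return build_cq_matrix(run)


def make_mini_run(
    well_specs: list[tuple],
    cohorts: dict[str, str] | None = None,
) -> RunData:
    """Hand-built run from (plate, well, role, sample, target, cq) tuples."""
    rows = [(p, w, r, s, t, c, True) for (p, w, r, s, t, c) in well_specs]
    wells = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    wells["melt_pass"] = pd.array(wells["melt_pass"], dtype="boolean")
    sample_ids = sorted(
        {s for s in wells.loc[wells["role"] == "sample", "sample_id"] if s is not None}
    )
    cohorts = cohorts or {}
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort": [cohorts.get(s, "HC") for s in sample_ids],
            "sex": np.nan,
            "age_group": np.nan,
            "batch": np.nan,
        }
    )
    return RunData(wells=wells, metadata=metadata, target_roles=default_target_roles())


@pytest.fixture
def mini_run_factory():
    return make_mini_run


@pytest.fixture(scope="session")
def fingerprint() -> list[str]:
    return list(FINGERPRINT_TARGETS)
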