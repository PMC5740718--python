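import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")

from twinewas.methylation import CELL_TYPES, CellReferencePanel
from twinewas.standardization import standardize_cohort
from twinewas.synthetic_data import (
    CohortConfig,
    default_lms_table,
    generate_cell_reference_panel,
    generate_cohort,
    generate_manifest,
)


@pytest.fixture(scope="session")
def lms_table():
    return default_lms_table()


@pytest.fixture(scope="session")
def small_cohort(lms_table):
    cfg = CohortConfig(n_male_pairs=12, n_female_pairs=12, seed=7)
    return generate_cohort(cfg, lms_table)


@pytest.fixture(scope="session")
def small_zpanel(small_cohort, lms_table):
    return standardize_cohort(small_cohort, lms_table)


@pytest.fixture(scope="session")
def small_manifest():
    return generate_manifest(n_probes=300, n_genes=80, na_fraction=0.2, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_manifest):
    return generate_cell_reference_panel(small_manifest.index, seed=12)


@pytest.fixture(scope="session")
def small_fractions(small_cohort):
    """Deterministic per-subject cell fractions summing to one."""
    rng = np.random.default_rng(13)
    subs = list(small_cohort["subject_id"])
    frac = rng.dirichlet(np.array([0.08, 0.30, 0.02, 0.55, 0.05]) * 150, size=len(subs))
    return pd.DataFrame(frac, index=pd.Index(subs, name="sample_id"),
                        columns=list(CELL_TYPES))


@pytest.fixture(autouse=True)
def _quiet_pair_exclusion_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="pair .* excluded")
        yield
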