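import numpy as np
import pandas as pd
import pytest

import vaxbiome as vb


@pytest.fixture(scope="session")
def default_cohort() -> vb.SyntheticCohort:
    """Full-size synthetic cohort shared across read-only tests."""
    return vb.generate_cohort(vb.CohortConfig(seed=3))


@pytest.fixture(scope="session")
def small_config() -> vb.CohortConfig:
    """Desk-scale cohort configuration for fast generation tests."""
    return vb.CohortConfig(
        n_subjects=20, n_kos=30, n_genera=10, n_otus=12, n_metabolites=8,
        stool_depth=2000, nasal_depth=1000, genus_depth=1000, seed=11,
    )


def titer_table(rows) -> pd.DataFrame:
    """Build a long-format titer table from (subject, antigen, timepoint,
    value) tuples."""
    return pd.DataFrame(rows, columns=["subject_id", "antigen", "timepoint", "value"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
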