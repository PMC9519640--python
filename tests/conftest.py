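import numpy as np
import pytest

from tbict.cohort import (CohortParams, expand_crosstab, generate_cohort,
                          niris_outcome_crosstab)


@pytest.fixture(scope="session")
def table_records():
    """Patient-level expansion of the printed NIRIS-by-outcome table."""
    return expand_crosstab(niris_outcome_crosstab())


@pytest.fixture(scope="session")
def table_outcomes(table_records):
    return np.array([r.dead_6mo for r in table_records])


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter synthetic cohort at the source-cohort size."""
    return generate_cohort(CohortParams(n=3031, seed=0))
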