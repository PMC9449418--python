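import numpy as np
import pandas as pd
import pytest

from milkcog import CohortConfig, simulate_cohort
from milkcog.preprocess import build_analysis_frame


@pytest.fixture(scope="session")
def cohort():
    """Default study-sized cohort, fixed seed, shared read-only."""
    return simulate_cohort(CohortConfig(), seed=20260921)


@pytest.fixture(scope="session")
def ibq_frame(cohort):
    return build_analysis_frame(cohort.baseline, "ibq")


@pytest.fixture(scope="session")
def msel_frame(cohort):
    return build_analysis_frame(cohort.baseline, "msel")


def random_correlation(p: int, rng: np.random.Generator, n: int = 40) -> pd.DataFrame:
    """Generic sample correlation matrix (no tied merge heights a.s.)."""
    x = rng.standard_normal((n, p)) @ rng.standard_normal((p, p))
    return pd.DataFrame(x, columns=[f"v{i}" for i in range(p)])
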