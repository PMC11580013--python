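import numpy as np
import pytest

from netstates import synthcohort as sc


@pytest.fixture(scope="session")
def small_cohort() -> sc.Cohort:
    """Reduced default-condition cohort shared by read-only tests."""
    cfg = sc.CohortConfig(
        n_patients=8,
        n_controls=8,
        scan=sc.ScanConfig(n_volumes=130, n_discard=10),
    )
    return sc.generate_cohort(cfg, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
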