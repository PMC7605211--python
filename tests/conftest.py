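import pytest

from trisnp import synthetic


@pytest.fixture(scope="session")
def cohort_bundle():
    """A discovery cohort with 20 planted markers and 6 decoys per class."""
    spec = synthetic.CohortSpec(n_markers=20, n_decoys_per_class=6, seed=7)
    return synthetic.generate_discovery_cohort(spec)


@pytest.fixture(scope="session")
def small_bundle():
    """A fast 5-marker cohort with 1 decoy per class for IO round-trips."""
    spec = synthetic.CohortSpec(
        n_markers=5, n_decoys_per_class=1, n_population=20, seed=11
    )
    return synthetic.generate_discovery_cohort(spec)
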