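import numpy as np
import pytest

from lgeviab import CohortConfig, PhantomSpec, ScarWedge, cohort_frames, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def wedge_spec():
    """Noise-free phantom: one 0.4-depth wedge over 0-90 deg on the mid slice."""
    return PhantomSpec(wedges=(ScarWedge(2, 0.0, 90.0, 0.4),))


@pytest.fixture(scope="session")
def wedge_stack(wedge_spec):
    return generate_phantom(wedge_spec)


@pytest.fixture(scope="session")
def demo_cohort():
    """The 33-patient demo cohort at the bundled seed."""
    studies = generate_cohort(CohortConfig(n_patients=33, seed=1))
    return cohort_frames(studies)


@pytest.fixture(scope="session")
def large_cohort():
    studies = generate_cohort(CohortConfig(n_patients=200, seed=3))
    return cohort_frames(studies)
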