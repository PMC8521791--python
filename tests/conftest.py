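import numpy as np
import pytest

import worktrack as wt

COHORT_SEED = 0  # default study cohort: 12 subjects, full protocol


@pytest.fixture(scope="session")
def cohort12():
    """The default 12-subject synthetic cohort at 50 Hz."""
    return wt.simulate_cohort(12, cohort_seed=COHORT_SEED)


@pytest.fixture(scope="session")
def dataset27(cohort12):
    return wt.build_dataset(cohort12, cooperativity=True)


@pytest.fixture(scope="session")
def dataset18(cohort12):
    return wt.build_dataset(cohort12, cooperativity=False)


@pytest.fixture(scope="session")
def small_session():
    """One short labeled session (cheap fixture for pipeline tests)."""
    profile = wt.SubjectProfile(subject_id="S01", seed=7)
    protocol = wt.Protocol(tuple(
        wt.synth.Episode(loc, limb, 1.0, label)
        for loc, limb, label in [
            ("walking", "neutral", "W_N"),
            ("standing", "neutral", "St_N"),
            ("standing", "reading", "Re"),
            ("standing", "typing", "Ty"),
            ("standing", "writing", "Wr"),
            ("sitting", "neutral", "Si_N"),
            ("lying", "neutral", "L_N"),
        ]
    ))
    return wt.simulate_protocol_session(profile, protocol)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_window(rng, n=100):
    """A random 100x9 basic window."""
    return wt.BasicWindow(values=rng.standard_normal((n, 9)), subject_id="S", index=0,
                          start_sample=0)
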