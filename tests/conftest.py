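import numpy as np
import pytest

import dfnckit as dk
from dfnckit import simulate as sim


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_specs():
    """Five planted states at the default scale (C=20)."""
    return dk.default_state_specs(seed=1)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A fast 4-subject two-visit cohort with default planted effects."""
    design = dk.default_design(n_subjects=4, retention=1.0, seed=5)
    sessions, truth = sim.simulate_cohort(design)
    return design, sessions, truth


@pytest.fixture(scope="session")
def outcome_table_500():
    """Ground-truth dwell metrics of a 200-subject cohort, as a long table.

    Built once per test session; used by the longitudinal model tests.
    """
    from dfnckit.stats import outcome_table_from_metrics

    design = dk.default_design(n_subjects=200, retention=1.0, seed=42)
    sessions, truth = sim.simulate_cohort(design)
    meta = [(s.subject_id, s.visit, s.age, s.sex) for s in sessions]
    return outcome_table_from_metrics(meta, [s.true_metrics for s in sessions], design.K)
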