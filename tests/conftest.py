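import numpy as np
import pytest

from denopk import estimation, reference, synthetic_trial
from denopk.dataset_io import apply_blq_policy_all


@pytest.fixture(scope="session")
def phase1_truth():
    return reference.phase1_reference_model()


@pytest.fixture(scope="session")
def pooled_truth():
    return reference.pooled_reference_model()


@pytest.fixture(scope="session")
def small_phase1_trial(phase1_truth):
    """8 subjects/arm rich-design trial with BLQ policy applied."""
    design = synthetic_trial.phase1_design(n_per_arm=8, seed=101)
    trial = synthetic_trial.simulate_trial(design, phase1_truth, seed=101)
    subjects, report = apply_blq_policy_all(trial.subjects)
    return trial, subjects, report


@pytest.fixture(scope="session")
def medium_phase1_trial(phase1_truth):
    """16 subjects/arm rich-design trial (~900 usable observations)."""
    design = synthetic_trial.phase1_design(n_per_arm=16, seed=202)
    trial = synthetic_trial.simulate_trial(design, phase1_truth, seed=202)
    subjects, _ = apply_blq_policy_all(trial.subjects)
    return trial, subjects


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(424242)
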