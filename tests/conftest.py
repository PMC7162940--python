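import numpy as np
import pytest

from audlearn import classify, cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default 76-participant cohort, shared across tests."""
    return cohort.generate_cohort(master_seed=11)


@pytest.fixture(scope="session")
def cohort_frame(default_cohort):
    return cohort.cohort_to_frame(default_cohort)


@pytest.fixture(scope="session")
def feature_table(cohort_frame):
    return classify.build_feature_table(cohort_frame)


def random_trials(rng, n=40, p_target=0.25, p_press=0.5):
    """Random trial list with arbitrary responses, for counting oracles."""
    trials = []
    tones = cohort.enumerate_tones()
    for i in range(1, n + 1):
        tone = tones[rng.integers(len(tones))]
        is_target = bool(rng.random() < p_target)
        response = "target_button" if rng.random() < p_press else "nontarget_button"
        correct = (is_target and response == "target_button") or (
            not is_target and response == "nontarget_button"
        )
        trials.append(cohort.Trial(i, tone, is_target, response, correct))
    return trials
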