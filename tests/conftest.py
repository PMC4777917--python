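import numpy as np
import pytest

import foxgate as fg


@pytest.fixture(scope="session")
def default_sample():
    """The shipped default analog sample (20,000 events) with ground truth."""
    spec = fg.default_sample_spec(n_events=20_000, seed=1)
    table, labels = fg.generate_sample(spec)
    return table, labels


@pytest.fixture(scope="session")
def small_sample():
    """A 6,000-event sample for faster pipeline-level unit tests."""
    spec = fg.default_sample_spec(n_events=6_000, seed=5)
    table, labels = fg.generate_sample(spec)
    return table, labels


@pytest.fixture(scope="session")
def hkk_result(default_sample):
    table, _ = default_sample
    return fg.run_pipeline(table, fg.hkk_config(seed=3))


def foxp3_pos_mask(labels):
    return np.isin(labels, ["effector_treg", "naive_treg", "non_treg"])


def cd4_pos_mask(labels):
    return np.isin(labels, ["cd4_foxp3neg", "effector_treg", "naive_treg",
                            "non_treg"])
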