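import numpy as np
import pandas as pd
import pytest

from ppx import neuronet as net_mod
from ppx import synthdata as syn
from ppx.cli import _immune_indices, _mediator_indices


@pytest.fixture(scope="session")
def default_data():
    """One full synthetic study at generator defaults (fixed seed)."""
    return syn.generate_cohort(syn.GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def blood_data():
    """Blood-only synthetic study (no RT/EEG), faster for index/net tests."""
    return syn.generate_cohort(
        syn.GeneratorConfig(seed=42, include_rt=False, include_eeg=False)
    )


@pytest.fixture(scope="session")
def model_frame(blood_data):
    """Mediator indices merged with the ILC activation index (modeled cohorts)."""
    med, _ = _mediator_indices(blood_data)
    imm, _ = _immune_indices(blood_data)
    return med.merge(imm["ilc_activation"], on=["participant_id", "cohort"])


@pytest.fixture(scope="session")
def model_xy(model_frame):
    X = model_frame[list(net_mod.INPUT_NAMES)].to_numpy(float)
    y = model_frame["score"].to_numpy(float)
    return X, y


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_panels():
    """Matched baseline/post marker panels for three participants."""
    base = pd.DataFrame(
        {
            "participant_id": ["a", "b", "c"],
            "cohort": ["neutral", "neutral", "infection"],
            "timepoint": "baseline",
            "f1": [10.0, 12.0, 14.0],
            "f2": [1.0, 2.0, 3.0],
        }
    )
    post = base.copy()
    post["timepoint"] = "post"
    post["f1"] = [12.0, 11.0, 20.0]
    post["f2"] = [2.0, 2.0, 5.0]
    return base, post
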