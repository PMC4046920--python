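import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from radr.pipeline import train_simulated_classifier


@pytest.fixture(scope="session")
def trained():
    """Default two-stage classifier trained on simulator-labeled data,
    plus the annotation table it was trained on. Shared across the suite."""
    model, annotations = train_simulated_classifier(seed=7)
    return model, annotations


@pytest.fixture(scope="session")
def trained_model(trained):
    return trained[0]


@pytest.fixture(scope="session")
def annotation_table(trained):
    return trained[1]
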