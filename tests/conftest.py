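import sys
from pathlib import Path

import pytest

# make the flat reference transliteration importable as a plain module
sys.path.insert(0, str(Path(__file__).parent))

from heatstrain.exposure import SubjectTask  # noqa: E402
from heatstrain.fixtures import ensemble_properties  # noqa: E402


@pytest.fixture(scope="session")
def sc_ensemble():
    return ensemble_properties("sc")


@pytest.fixture(scope="session")
def cp_ensemble():
    return ensemble_properties("cp")


@pytest.fixture(scope="session")
def field_subject():
    """The published subject/task configuration: 70 kg, 1.75 m, standing,
    acclimatized, drinking freely, walking 0.5 m/s, 8 h shift."""
    return SubjectTask()
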