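import numpy as np
import pandas as pd
import pytest

from epiclone.params import SPParams


@pytest.fixture
def balanced():
    """Homeostatic wild-type parameter set."""
    return SPParams()


@pytest.fixture
def biased():
    """Fate-imbalanced mutant parameter set."""
    return SPParams(delta=0.25)
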