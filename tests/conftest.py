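import logging
import warnings

import numpy as np
import pytest

from mvimpute.types import ExpressionMatrix, MissingMask, ClassLabels

logging.getLogger("mvimpute").setLevel(logging.ERROR)


@pytest.fixture(autouse=True)
def _quiet_bpca_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="BPCA did not converge",
                                category=RuntimeWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_masked(rng):
    """Random 20x10 matrix with ~10% missing, no empty rows."""
    values = rng.normal(size=(20, 10))
    flags = rng.random((20, 10)) < 0.1
    flags[:, 0] = False  # keep every gene observed somewhere
    return ExpressionMatrix.from_values(values), MissingMask(flags)


@pytest.fixture
def two_class_labels():
    return ClassLabels([0] * 5 + [1] * 5)
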