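import numpy as np
import pytest

from cellopt import ANNResponseSurface, load_reference_dataset
from cellopt.ann import TrainConfig


@pytest.fixture(scope="session")
def reference_dataset():
    return load_reference_dataset()


@pytest.fixture(scope="session")
def reference_fit():
    """One converged network on the bundled dataset, shared across tests."""
    return ANNResponseSurface.reference().fit(TrainConfig(seed=0))


@pytest.fixture(scope="session")
def reference_columns(reference_dataset):
    """Experimental and published network-fitted columns, training trials."""
    y_exp = reference_dataset.efficiencies("training")
    y_fit = np.array([t.ann_fitted for t in reference_dataset.training])
    return y_exp, y_fit
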