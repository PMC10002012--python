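import numpy as np
import pytest

import histovae as hv


@pytest.fixture(scope="session")
def small_bundle():
    """120 synthetic patches (60/class) split train/test/validation."""
    return hv.make_synthetic_bundle(60, seed=7)


@pytest.fixture(scope="session")
def tiny_images():
    """A 20-patch balanced synthetic dataset (images, labels)."""
    return hv.generate_dataset(10, seed=3)


@pytest.fixture(scope="session")
def degenerate_truth():
    """The 10,000-sample near-balanced truth vector: 5,002 of class 0."""
    return np.array([0] * 5002 + [1] * 4998)
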