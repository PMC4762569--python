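import numpy as np
import pytest

from sascifio.synth import SphereTruth, generate_entry, make_entry


@pytest.fixture(scope="session")
def truth():
    return SphereTruth()


@pytest.fixture(scope="session")
def entry(truth):
    """Full in-memory entry: curve, distribution, one model + fit."""
    return make_entry(truth)


@pytest.fixture(scope="session")
def two_model_entry(truth):
    return make_entry(truth, n_models=2)


@pytest.fixture()
def file_set(truth, tmp_path):
    """Legacy file set (.dat/.out/.pdb/.fit/config) on disk."""
    return generate_entry(truth, tmp_path)
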