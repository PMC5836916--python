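import numpy as np
import pytest

from bloodwalk.geometry import CompartmentParams, build_unit_cell


@pytest.fixture(scope="session")
def reference_cell():
    """Mean-blood-count unit cell: HCT 43%, MCV 87.7 fL."""
    return build_unit_cell(0.43, 87.7)


@pytest.fixture(scope="session")
def reference_params(reference_cell):
    return CompartmentParams().for_cell(reference_cell)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
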