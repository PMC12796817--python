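import numpy as np
import pytest

from segrefine import synthkit


@pytest.fixture(scope="session")
def sparse_fixture():
    """A moderate sparse-regime tissue fixture shared across tests."""
    params = synthkit.regime_params("sparse_highcontrast", n_cells=50, seed=7)
    image, mask, records = synthkit.generate_tissue(params)
    return params, image, mask, records


@pytest.fixture()
def two_cell_mask():
    """Tiny mask with two rectangular cells (labels 3 and 9)."""
    mask = np.zeros((10, 12), dtype=np.int32)
    mask[1:4, 1:5] = 3
    mask[6:9, 7:11] = 9
    return mask
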