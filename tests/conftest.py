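import numpy as np
import pytest

from ndiskit import (
    difference_weights,
    second_order_weight,
    tma_pyridine_composition,
)

#: relabelling that lumps the generator's fine atom classes into the
#: correlation classes the difference equations use
LUMP = {"C_TMA": "C", "C_ring": "C", "N_TMA": "N", "N_ring": "N", "O_W": "O"}


@pytest.fixture(scope="session")
def comp_d2o():
    return tma_pyridine_composition("D2O")


@pytest.fixture(scope="session")
def comp_h2o():
    return tma_pyridine_composition("H2O")


@pytest.fixture(scope="session")
def weights_d2o(comp_d2o):
    return difference_weights(comp_d2o)


@pytest.fixture(scope="session")
def weights_h2o(comp_h2o):
    return difference_weights(comp_h2o)


@pytest.fixture(scope="session")
def hw_weight(weights_d2o, weights_h2o):
    return second_order_weight(weights_d2o, weights_h2o)


@pytest.fixture(scope="session")
def small_traj():
    """A few small planted-complex frames with lumped correlation classes."""
    from ndiskit import synth

    frames, truth = synth.planted_complex(
        n_aromatic=4, n_cation=4, n_water=60, n_chloride=4,
        box=13.0, n_frames=2, seed=11,
    )
    return [f.relabel(LUMP) for f in frames], truth
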