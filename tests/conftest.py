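import numpy as np
import pytest

from bcsm.sampler import LayerDesign, ModelSpec, PriorHyper
from bcsm.suffstats import RTDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_dataset(values, groups=None):
    values = np.asarray(values, dtype=float)
    if groups is None:
        groups = np.zeros(values.shape[0], dtype=int)
    return RTDataset(values=values, group_index=np.asarray(groups, dtype=int))


@pytest.fixture
def tiny_dataset():
    # two persons, two items: person means 2 and 4, item means 2 and 4
    return make_dataset([[1.0, 3.0], [3.0, 5.0]])


@pytest.fixture
def testlet_spec():
    """Six items, two testlets of three, moderately informative prior."""
    layers = (
        LayerDesign("testlet1", np.array([[1, 1, 1, 0, 0, 0]], dtype=float)),
        LayerDesign("testlet2", np.array([[0, 0, 0, 1, 1, 1]], dtype=float)),
    )
    return ModelSpec(n_items=6, n_groups=1, layers=layers, prior=PriorHyper(1e-3, 1e-3))
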