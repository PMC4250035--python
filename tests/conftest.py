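import numpy as np
import pytest

from connview.core import Ordering, bind_matrix
from connview.fixtures import (
    FixtureSpec,
    make_modular_network,
    make_toy_brain,
    write_fixture_dataset,
)
from connview.views import ViewStyle


def names(n):
    return Ordering(tuple(f"n{i}" for i in range(n)))


def network_from(weights):
    """Bind a raw (symmetric) weight matrix to a generic ordering."""
    w = np.asarray(weights, dtype=float)
    return bind_matrix(w, names(w.shape[0]))


def random_network(rng, n, p=0.5, signed=False):
    """Random symmetric weighted network for oracle comparisons."""
    w = (rng.random((n, n)) < p) * rng.uniform(0.1, 2.0, (n, n))
    if signed:
        w *= rng.choice([-1.0, 1.0], size=(n, n))
    w = np.triu(w, 1)
    return network_from(w + w.T)


@pytest.fixture(scope="session")
def tiny_spec():
    return FixtureSpec(n_nodes_per_hemisphere=8, surface_subdivisions=1, seed=7)


@pytest.fixture(scope="session")
def tiny_brain(tiny_spec):
    return make_toy_brain(tiny_spec)


@pytest.fixture(scope="session")
def tiny_network(tiny_spec, tiny_brain):
    network, _labels = make_modular_network(tiny_spec, tiny_brain.parcellation)
    return network


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, tiny_spec):
    out = tmp_path_factory.mktemp("dataset") / "ds"
    write_fixture_dataset(out, tiny_spec)
    return out


@pytest.fixture(scope="session")
def small_style():
    """Small raster size keeps render-heavy tests fast."""
    return ViewStyle(image_size=(240, 180))
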