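import numpy as np
import pytest

from sspyct import GenSpec, SemiDataset, SplitConfig, gen_clustered, mask_labels


@pytest.fixture
def separable_bc():
    """Two well-separated Gaussian clusters with cluster-aligned binary labels."""
    spec = GenSpec(task="BC", n=200, D=4, n_clusters=2, separation=8.0, seed=11)
    ds, ids = gen_clustered(spec)
    return ds, ids


@pytest.fixture
def masked_bc(separable_bc):
    ds, ids = separable_bc
    return mask_labels(ds, 30, np.random.default_rng(3)), ids


@pytest.fixture
def toy_1d():
    """1-D features at -10 and +10 with matching regression targets."""
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.normal(-10, 1, 25), rng.normal(10, 1, 25)])
    y = np.where(x < 0, -1.0, 1.0) + 0.01 * rng.normal(size=50)
    order = rng.permutation(50)
    return SemiDataset(x[order][:, None], y[order], "STR")


@pytest.fixture(params=["svm", "grad"])
def variant(request):
    return request.param


def make_config(**kw):
    return SplitConfig(**kw)
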