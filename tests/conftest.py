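import numpy as np
import pytest

from jade import SliceData, SyntheticConfig, generate_paired_slices


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_pair():
    """A small, quick synthetic slice pair with ground truth."""
    cfg = SyntheticConfig(n_spots=80, n_genes=40, n_domains=3, seed=7)
    return generate_paired_slices(cfg)


def random_slice(n, p, seed=0):
    r = np.random.default_rng(seed)
    return SliceData(
        coords=r.random((n, 2)),
        expr=r.poisson(3.0, size=(n, p)).astype(float),
        gene_ids=[f"g{j}" for j in range(p)],
        spot_ids=[f"s{i}" for i in range(n)],
    )
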