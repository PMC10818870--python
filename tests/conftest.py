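import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from micronet.io import AbundanceTable

settings.register_profile("default", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("default")


def planted_blocks_frame(seed: int, n_taxa: int = 150, n_samples: int = 24,
                         n_blocks: int = 2, block_size: int = 20,
                         rho: float = 0.95):
    """Gaussian log-abundance frame with exchangeable correlated blocks.

    Returns (DataFrame taxa x samples, taxon -> block membership dict).
    Block taxa share a latent factor giving within-block correlation rho;
    the remaining taxa are independent noise.
    """
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n_taxa, n_samples))
    shared = rng.normal(size=(n_blocks, n_samples))
    member = {}
    for b in range(n_blocks):
        for i in range(b * block_size, (b + 1) * block_size):
            z[i] = np.sqrt(rho) * shared[b] + np.sqrt(1 - rho) * z[i]
            member[f"t{i}"] = b
    frame = pd.DataFrame(z, index=[f"t{i}" for i in range(n_taxa)],
                         columns=[f"s{j}" for j in range(n_samples)])
    return frame, member


@pytest.fixture
def small_counts():
    """3 taxa x 4 samples counts table with one zero-heavy taxon."""
    return AbundanceTable(pd.DataFrame(
        [[10, 0, 3, 7],
         [5, 5, 5, 5],
         [0, 0, 0, 12]],
        index=["taxA", "taxB", "taxC"],
        columns=["s1", "s2", "s3", "s4"]))
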