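import numpy as np
import pandas as pd
import pytest

from sharedshift.io_norm import CountMatrix, SampleTable
from sharedshift.synthetic import SimConfig, simulate_counts


def small_meta_frame():
    """3 pairs x 2 habitats x 2 replicates."""
    rows = []
    for k in range(1, 4):
        for hab in ("desert", "mesic"):
            for r in (1, 2):
                rows.append({"sample_id": f"p{k}{hab[0]}{r}", "species": f"sp{k}{hab[0]}",
                             "pair": f"pair{k}", "habitat": hab})
    return pd.DataFrame(rows)


@pytest.fixture
def small_meta():
    return SampleTable(small_meta_frame())


@pytest.fixture
def small_cm(small_meta):
    rng = np.random.default_rng(42)
    counts = rng.poisson(50, size=(20, len(small_meta.sample_ids)))
    return CountMatrix(pd.DataFrame(counts, index=[f"g{i}" for i in range(20)],
                                    columns=small_meta.sample_ids))


@pytest.fixture(scope="session")
def sim_default():
    """Moderate simulated dataset with all three truth classes."""
    cfg = SimConfig(n_genes=600, seed=7, shared_fraction=0.1, interaction_fraction=0.1,
                    shared_log2fc_mean=np.log(1.4), shared_log2fc_sd=0.3,
                    shared_log2fc_min=1.0, dispersion_max=0.1)
    return simulate_counts(cfg)
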