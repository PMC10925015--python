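import numpy as np
import pytest

import edgecdr as e


@pytest.fixture(scope="session")
def tiny_dataset():
    """5 drugs x 10 cells x 20 genes with the planted linear rule."""
    spec = e.FixtureSpec(n_drugs=5, n_cells=10, n_genes=20, noise_sd=0.1,
                         seed=1)
    drugs, omics, records, truth = e.make_dataset(spec)
    profiles = e.preprocess_omics(omics["exp"], omics["mut"], omics["meth"],
                                  omics["copy"], log_transform_exp=False)
    return drugs, profiles, records, truth


@pytest.fixture(scope="session")
def tiny_trained(tiny_dataset):
    """A small model trained for a few epochs; reused across read-only tests."""
    drugs, profiles, records, _ = tiny_dataset
    cfg = e.TrainConfig.small(epochs=30, seed=0, batch_size=50)
    return e.train(records, drugs, profiles, cfg), drugs, profiles, records
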