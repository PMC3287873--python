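import numpy as np
import pytest

from bndissect.synthetic_data import GeneratorConfig, default_gene_ids, generate_replicate_set


@pytest.fixture(scope="session")
def tiny_replicates():
    """Small but non-trivial cohort shared by read-only tests."""
    ids = default_gene_ids(12)
    cfg = GeneratorConfig(
        n_individuals=150,
        n_genes=12,
        n_replicates=6,
        causal_genes={"Q1": tuple(ids[:3])},
        effect_size=0.8,
        seed=9,
    )
    return generate_replicate_set(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
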