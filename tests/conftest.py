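import numpy as np
import pytest

from amplicnv.simulate import GeneSpec, PopulationSpec, SimulationConfig, VariantSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_config(seed=0, **overrides):
    """A fast two-gene, three-population male panel for unit tests."""
    base = dict(
        seed=seed,
        populations=(PopulationSpec("popA", 5), PopulationSpec("popB", 5),
                     PopulationSpec("popC", 5)),
        genes=(GeneSpec("geneL", 5000, base_cn=5.0, cn_sd=1.0),
               GeneSpec("geneS", 2000, base_cn=3.0, cn_sd=0.8)),
        per_copy_depth=40.0,
        control_length=8000,
        variants=(VariantSpec("geneL", 100, "NS", carrier_freq=0.4, copy_freq=0.4),
                  VariantSpec("geneL", 900, "S", carrier_freq=1.0, copy_freq=1.0),
                  VariantSpec("geneS", 50, "NS", carrier_freq=0.3, copy_freq=0.5)),
        outgroup_divergence=0.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture
def sim_config():
    return small_config()
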