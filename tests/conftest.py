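import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_pair():
    """A small deterministic domain pair (overlapping labels, ambiguity on)."""
    from trigrec.synthetic import SynthConfig, generate_domain_pair

    cfg = SynthConfig(n_source_docs=6, n_target_docs=4, sentences_per_doc=3,
                      seed=42, ambiguity=0.3)
    source, target, ledger = generate_domain_pair(cfg)
    return cfg, source, target, ledger


@pytest.fixture(scope="session")
def small_feature_configs():
    from trigrec.features import FeatureConfig

    source = FeatureConfig(dim_word=8, dim_char=4, dim_char_in=3, dim_pos=3,
                           dim_entity=3, dim_dep=4)
    target = FeatureConfig(dim_word=8, dim_char=4, dim_char_in=3, dim_pos=3,
                           dim_entity=5, dim_dep=4)
    return source, target


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
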