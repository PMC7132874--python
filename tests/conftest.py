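import numpy as np
import pytest

from covinform import MethylationStudy, m_to_beta


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_study(rng):
    """A 60-feature, 24-sample study with replicates and binary phenotype."""
    m, n = 60, 24
    mu = rng.choice([-2.5, 2.5], size=m) + rng.normal(0, 0.5, size=m)
    m_values = mu[:, None] + rng.normal(0, 0.6, size=(m, n))
    phenotype = np.repeat([0.0, 1.0], n // 2)
    replicate = np.repeat(np.arange(n // 2), 2)
    return MethylationStudy(
        beta=m_to_beta(m_values),
        feature_ids=np.array([f"cg{i:05d}" for i in range(m)]),
        sample_ids=np.array([f"s{j}" for j in range(n)]),
        phenotype=phenotype,
        replicate_group=replicate,
    )
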