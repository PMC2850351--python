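import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture()
def planted_sequences():
    """Three planted OTUs, four members each, 99% within / <=90% between."""
    from taxenv import synthetic

    return synthetic.generate_sequences(
        n_otus=3, members_per_otu=4, within_identity=0.99,
        between_identity_max=0.90, length=500, seed=5,
    )


@pytest.fixture()
def small_matrix():
    """A 6x4 community matrix with deterministic counts."""
    import pandas as pd
    from taxenv import community

    rng = np.random.default_rng(17)
    counts = pd.DataFrame(
        rng.integers(0, 30, (6, 4)),
        index=[f"fam{i}" for i in range(6)],
        columns=[f"env{j}" for j in range(4)],
    )
    n_samples = pd.Series([5, 3, 8, 2], index=counts.columns)
    return community.CommunityMatrix(counts, n_samples)
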