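import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20210717)


@pytest.fixture
def small_responses(rng) -> pd.DataFrame:
    """200 synthetic respondents with all five items, moderately correlated."""
    from swlslink.simulate import LikertSimConfig, generate_responses

    cfg = LikertSimConfig(
        n=200,
        target_means=(3.8, 3.8, 4.3, 4.5, 3.7),
        target_sds=(1.8, 1.8, 1.8, 1.8, 1.9),
        rho=0.6,
        seed=11,
    )
    return pd.DataFrame(
        generate_responses(cfg), columns=["item1", "item2", "item3", "item4", "item5"]
    )


@pytest.fixture
def scored(small_responses) -> pd.DataFrame:
    from swlslink.pipeline import score_frame

    return score_frame(small_responses)
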