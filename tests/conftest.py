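import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lvtool import synthgen

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FOUR_CLASSES = {"cNF": 8, "pNF": 8, "NF": 8, "MPNST": 8}


@pytest.fixture(scope="session")
def small_model():
    return synthgen.gen_model(n_genes=120, n_lvs=20, sparsity=0.15, seed=1)


@pytest.fixture(scope="session")
def cohort(small_model):
    """Four balanced classes, 2 planted LVs each at 3 SD, mild noise."""
    return synthgen.gen_cohort(
        small_model,
        dict(FOUR_CLASSES),
        planted_per_class=2,
        effect_size=3.0,
        noise_sd=0.5,
        seed=2,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def labels(cohort):
    _, meta, _ = cohort
    return pd.Series(
        meta["tumor_type"].to_numpy(), index=meta["sample_id"], name="tumor_type"
    )
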