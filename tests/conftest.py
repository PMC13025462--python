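import numpy as np
import pytest

from mitosig import synthetic as syn


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort: 6 vs 14 samples, 30 analytes, two planted effects."""
    spec = syn.SyntheticCohortSpec(
        n_case=6, n_control=14, n_analytes=30, n_mito_flagged=12,
        planted_up=((0, 3.0), (1, 2.6)), planted_down=((13, -2.5),),
        seed=42,
    )
    data, truth = syn.generate_cohort(spec)
    data = syn.attach_survival(data, truth, spec)
    return data, truth, spec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
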