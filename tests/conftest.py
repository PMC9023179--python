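import numpy as np
import pandas as pd
import pytest

from periopredict.datagen import CohortSpec, generate_cohort, surgery_view, emergence_view
from periopredict.preprocess import PipelineConfig, preprocess_pipeline


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return generate_cohort(CohortSpec(n_cases=600, effect_size=2.0, seed=11))


@pytest.fixture(scope="session")
def separable_cohort() -> pd.DataFrame:
    """Strongly separable fixture: class signal of 3 within-class sds."""
    return generate_cohort(CohortSpec(n_cases=2000, effect_size=3.0, seed=7))


@pytest.fixture(scope="session")
def small_surgery_view(small_cohort) -> pd.DataFrame:
    return surgery_view(small_cohort)


@pytest.fixture(scope="session")
def small_emergence_view(small_cohort) -> pd.DataFrame:
    return emergence_view(small_cohort)


@pytest.fixture(scope="session")
def small_prepared(small_surgery_view):
    """Preprocessed small surgery dataset (M=1, no enrichment) for fast training."""
    cfg = PipelineConfig(system="surgery", enrichment_multiple=1, seed=11)
    return preprocess_pipeline(small_surgery_view, cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
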