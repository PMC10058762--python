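import numpy as np
import pandas as pd
import pytest

from dnas.guidelines import GuidelineSpec
from dnas.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def spec10() -> GuidelineSpec:
    """An explicit 10-group guideline with varied reference magnitudes."""
    rng = np.random.default_rng(0)
    low = rng.uniform(5, 300, 10).round(0)
    high = low + rng.uniform(10, 200, 10).round(0)
    return GuidelineSpec(
        groups=tuple(f"g{i}" for i in range(10)), low_g=low, high_g=high
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small clean synthetic cohort shared across read-only tests."""
    return generate_cohort(CohortConfig.well_separated(n_subjects=300, seed=42))


def make_panel(spec: GuidelineSpec, grams: np.ndarray) -> pd.DataFrame:
    """Wrap a (rows x groups) grams matrix as a one-round intake panel."""
    n = grams.shape[0]
    df = pd.DataFrame(grams, columns=list(spec.groups))
    df.insert(0, "subject_id", [f"S{i}" for i in range(n)])
    df.insert(1, "round", 2004)
    df.insert(2, "age_years", 40.0)
    df.insert(3, "energy_kcal", 2000.0)
    return df
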