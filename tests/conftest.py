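import numpy as np
import pandas as pd
import pytest

from nutriwin.cohort import CohortTable, NutrientDictionary
from nutriwin.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_dictionary() -> NutrientDictionary:
    return NutrientDictionary(pd.DataFrame({
        "name": ["Iron", "Zinc", "DHA", "Alanine", "Total fats"],
        "category": ["mineral", "mineral", "fatty_acid", "amino_acid",
                     "other"],
        "unit": ["mg/day", "mg/day", "mg/day", "g/day", "g/day"],
        "excluded": [False, False, False, True, True],
        "exclusion_reason": ["none", "none", "none",
                             "non_essential_amino_acid",
                             "redundant_aggregate"],
    }))


def make_cohort(n=40, seed=0, dictionary=None, nutrients=("Iron", "Zinc"),
                effect=0.0, effect_nutrient=None, noise_sd=0.005):
    """Hand-rolled small cohort: mwf = 0.1 + 0.03*log(age) (+ effect*z)."""
    rng = np.random.default_rng(seed)
    age = np.sort(rng.uniform(6, 60, n))
    df = pd.DataFrame({
        "subject_id": [f"c{i:03d}" for i in range(n)],
        "age_months": age,
    })
    for nut in nutrients:
        df[nut] = rng.gamma(4.0, 2.0, n)
    mwf = 0.1 + 0.03 * np.log(age) + rng.normal(0, noise_sd, n)
    if effect and effect_nutrient:
        x = df[effect_nutrient].to_numpy()
        mwf = mwf + effect * (x - x.mean()) / x.std()
    df["mwf"] = np.clip(mwf, 1e-3, 1 - 1e-3)
    return CohortTable(df, dictionary) if dictionary is not None \
        else CohortTable(df)


@pytest.fixture
def tiny_cohort(small_dictionary):
    return make_cohort(n=40, seed=1, dictionary=small_dictionary,
                       nutrients=("Iron", "Zinc", "DHA"))


@pytest.fixture(scope="session")
def default_synthetic():
    """One default synthetic cohort shared across tests (seed 42)."""
    return generate_cohort(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def null_config() -> GeneratorConfig:
    return GeneratorConfig(effects=(), noise_sd=0.004)
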