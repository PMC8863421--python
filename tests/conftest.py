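import numpy as np
import pandas as pd
import pytest

from stressmwas import CohortDesign, PhenotypeSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """120 samples x 300 CpGs, family + plate structure, null phenotypes."""
    design = CohortDesign(n_individuals=120, n_cpgs=300, seed=7)
    return simulate_cohort(design)


@pytest.fixture(scope="session")
def causal_cohort():
    """Cohort with planted causal CpGs on a continuous phenotype."""
    design = CohortDesign(
        n_individuals=400, n_cpgs=300, seed=21,
        phenotypes={"quant": PhenotypeSpec(kind="continuous", prevalence=None,
                                           n_causal=3, effect_size=0.5,
                                           familial=0.0)})
    return simulate_cohort(design)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_records():
    return pd.DataFrame({
        "sample_id": [f"I{i}" for i in range(6)],
        "gestation_weeks": [36, 37, 28, np.nan, 40, 39],
        "birth_weight_g": [2000.0, 3100.0, 1100.0, 3300.0, 3500.0, np.nan],
        "sex": ["F", "M", "F", "M", "F", "M"],
        "birth_doy": [355.0, 172.0, 81.25, 59.5, 1.0, 365.0],
        "birth_month": [12, 6, 3, 2, 1, 12],
        "mother_age": [20.0, 21.0, np.nan, 34.0, 19.0, np.nan],
        "father_age": [30.0, 21.0, np.nan, 36.0, np.nan, np.nan],
        "lives_with": ["both", "both", "both", "both", "mother", "both"],
        "birth_region": ["Glasgow", "Highland", "Dundee", "Fife", "Fife", None],
        "mother_region": ["Glasgow", "Highland", "Moray", "Moray", "Fife", "Fife"],
        "father_region": ["Glasgow", "Highland", "Dundee", "Angus", "Angus", "Fife"],
        "birth_year": [1960, 1970, 1980, 1985, 1990, 1995],
    }).set_index("sample_id")
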