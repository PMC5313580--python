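import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from riskselect import EqualizationModel, MarketConfig

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> MarketConfig:
    return MarketConfig(n_persons=20_000, n_insurers=4, seed=123)


@pytest.fixture(scope="session")
def toy_panel() -> pd.DataFrame:
    """Six persons, two insurers, two years; expenses chosen by hand.

    Persons 1 and 5 switch 1->2, person 3 switches 2->1; the rest stay.
    """
    rows = [
        # person, year, insurer, expenses
        (1, 2008, 1, 1000.0), (1, 2009, 2, 500.0),
        (2, 2008, 1, 700.0), (2, 2009, 1, 600.0),
        (3, 2008, 2, 2000.0), (3, 2009, 1, 1800.0),
        (4, 2008, 2, 850.0), (4, 2009, 2, 900.0),
        (5, 2008, 1, 300.0), (5, 2009, 2, 400.0),
        (6, 2008, 2, 1200.0), (6, 2009, 2, 1100.0),
    ]
    return pd.DataFrame(rows, columns=["person_id", "year", "insurer_id", "expenses"])


@pytest.fixture(scope="session")
def flat_model() -> EqualizationModel:
    """Supplied intercept-only model: everyone predicted at 800."""
    return EqualizationModel(
        adjusters=(),
        intercept=800.0,
        coefficients={},
        p_share=50.0,
        overall_mean=800.0,
        fit_year=2008,
    )
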