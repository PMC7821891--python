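import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dietseason.diets import NutrientComposition, RequirementSet
from dietseason.foods import FRUITS_VEGETABLES, STARCHY_STAPLES
from dietseason.synthetic import (
    CompositionSpec,
    generate_composition_and_requirements,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def synth_comp_req():
    """Feasible synthetic composition table and requirement set."""
    return generate_composition_and_requirements(CompositionSpec(), seed=1)


@pytest.fixture()
def two_item_fixture():
    """Staple + vegetable with one binding micronutrient.

    With EAR_X = 50 and only the vegetable carrying X (100 units/kg),
    q_veg = 0.5 kg; energy 2000 kcal forces q_staple = 0.875 kg, so the
    optimum is known in closed form: cost 8.75 + 20 = 28.75.
    """
    comp = NutrientComposition(
        pd.DataFrame(
            {
                "group": [STARCHY_STAPLES, FRUITS_VEGETABLES],
                "kcal_per_kg": [2000.0, 500.0],
                "nutrient_x": [0.0, 100.0],
            },
            index=pd.Index(["staple", "veg"], name="item"),
        )
    )
    req = RequirementSet(energy_kcal=2000.0, lower={"nutrient_x": 50.0})
    prices = pd.Series({"staple": 10.0, "veg": 40.0})
    return prices, comp, req


def harmonic_series(
    beta0=1.0,
    beta_s=0.03,
    beta_c=0.04,
    n_months=60,
    trend=0.0,
    noise_sd=0.0,
    seed=0,
    start_year=2011,
):
    """Noise-controlled single-market log-harmonic series as a tidy frame."""
    t = np.arange(1, n_months + 1)
    rng = np.random.default_rng(seed)
    log_v = (
        beta0
        + beta_s * np.sin(2 * np.pi * t / 12)
        + beta_c * np.cos(2 * np.pi * t / 12)
        + trend * t
        + noise_sd * rng.standard_normal(n_months)
    )
    return pd.DataFrame(
        {
            "year": start_year + (t - 1) // 12,
            "month": ((t - 1) % 12) + 1,
            "value": np.exp(log_v),
        }
    )


@pytest.fixture()
def make_harmonic_series():
    return harmonic_series
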