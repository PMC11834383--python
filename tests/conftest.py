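import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_sim():
    """One panel at the study's design: 32 populations, 1956-2022,
    staggered windows, truth (0.35, 0, 650 km)."""
    from demosync import SimulationConfig, simulate_latent_field

    return simulate_latent_field(SimulationConfig(seed=3))


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast panel for plumbing tests."""
    from demosync import SimulationConfig, simulate_latent_field

    return simulate_latent_field(
        SimulationConfig(seed=5, n_populations=6, year_start=1990, year_end=2015,
                         window_length_range=(12, 26))
    )


@pytest.fixture()
def toy_records():
    """Hand-written capture records covering all ageing paths."""
    rows = [
        # hatch year known, breeding twice-recaptured
        ("A", 2000, "b1", 1998, "chick", "F"),
        ("A", 2001, "b1", 1998, "chick", "F"),
        # first captured as adult in 2000, seen again 2002
        ("A", 2000, "b2", np.nan, "adult", "M"),
        ("A", 2002, "b2", np.nan, "adult", "M"),
        # first captured as subadult (hatch year implied)
        ("A", 2005, "b3", np.nan, "subadult", "F"),
        # unidentified parent
        ("A", 2000, None, np.nan, "", "unknown"),
    ]
    return pd.DataFrame(
        rows,
        columns=["population_id", "year", "individual_id", "hatch_year",
                 "first_capture_age_class", "sex"],
    )
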