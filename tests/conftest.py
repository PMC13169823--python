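import hypothesis
import numpy as np
import pandas as pd
import pytest

import ocmbtriage as ot

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture
def four_cell_cohort() -> pd.DataFrame:
    """One patient per confusion cell under Model C (IgMi 0.2 / FKLCi 250)."""
    return pd.DataFrame(
        {
            "patient_id": ["tp", "fp", "fn", "tn"],
            "igmi": [0.50, 0.30, 0.10, 0.05],
            "fklci": [100.0, 100.0, 100.0, 50.0],
            "ocmb": [True, False, True, False],
        }
    )


@pytest.fixture
def model_c() -> ot.DecisionModel:
    return ot.DecisionModel("Model C", 0.2, 250.0)


@pytest.fixture(scope="session")
def sim_cohort():
    """A default synthetic cohort (n=97, fixed 54/43 split) as samples."""
    return ot.generate_cohort(ot.CohortParams(seed=7, fixed_counts=True))


@pytest.fixture(scope="session")
def sim_frame(sim_cohort) -> pd.DataFrame:
    return ot.attach_panels(ot.samples_to_frame(sim_cohort))


def random_labelled_frame(rng: np.random.Generator, n: int = 60) -> pd.DataFrame:
    """Small random cohort frame with ties possible (integer-ish scores)."""
    n_pos = int(rng.integers(1, n))
    ocmb = np.zeros(n, dtype=bool)
    ocmb[:n_pos] = True
    rng.shuffle(ocmb)
    return pd.DataFrame(
        {
            "patient_id": [f"r{i}" for i in range(n)],
            "igmi": np.round(rng.lognormal(np.log(0.1), 1.0, n), 2),
            "fklci": np.round(rng.lognormal(np.log(80), 1.0, n), 0) + 1.0,
            "ocmb": ocmb,
        }
    )
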