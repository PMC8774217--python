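from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from sgus_ic.cohort import default_study_spec, generate
from sgus_ic.model import PosteriorDraws
from sgus_ic.scoring import default_scoring_config

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def config():
    return default_scoring_config()


@pytest.fixture(scope="session")
def fixture_responses():
    return pd.read_csv(
        DATA_DIR / "responses_fixture.csv",
        dtype={"patient_id": str, "device_id": str, "level": str},
    )


@pytest.fixture(scope="session")
def fixture_golden():
    return pd.read_csv(DATA_DIR / "scores_golden.csv", dtype={"patient_id": str})


@pytest.fixture(scope="session")
def default_cohort():
    return generate(default_study_spec(seed=11))


def make_draws(
    delta: np.ndarray,
    device_ids: tuple[str, ...],
    mu: np.ndarray | None = None,
    sigma: np.ndarray | None = None,
    tau: np.ndarray | None = None,
) -> PosteriorDraws:
    """Hand-constructed draws for ranking/heterogeneity unit tests."""
    delta = np.asarray(delta, dtype=float)
    n = delta.shape[0]
    return PosteriorDraws(
        device_ids=tuple(device_ids),
        patient_ids=(),
        reference_device=device_ids[0],
        mu=np.zeros(n) if mu is None else np.asarray(mu, dtype=float),
        delta=delta,
        u=np.zeros((n, 0)),
        sigma=np.ones(n) if sigma is None else np.asarray(sigma, dtype=float),
        tau=np.ones(n) if tau is None else np.asarray(tau, dtype=float),
    )
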