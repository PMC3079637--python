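import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import qmap

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rank_one_matrix() -> qmap.FitnessMatrix:
    """Exactly rank-one 3x3 fitness matrix (all entries positive)."""
    x = np.array([1.0, 0.5, 0.9])
    y = np.array([1.0, 0.8, 0.6])
    return qmap.FitnessMatrix(
        query_ids=["qA", "qB", "qC"], array_ids=["aA", "aB", "aC"],
        values=np.outer(x, y), name="rank-one")


@pytest.fixture
def planted_lethal_matrix(rank_one_matrix) -> qmap.FitnessMatrix:
    """The rank-one matrix with the centre cell set to 0 (synthetic lethal)."""
    fm = rank_one_matrix.copy()
    fm.values[1, 1] = 0.0
    fm.name = "planted-lethal"
    return fm


@pytest.fixture(scope="session")
def default_screen() -> qmap.SyntheticScreen:
    """One default-parameter synthetic screen, shared across tests."""
    return qmap.simulate_screen(seed=20260925)


@pytest.fixture(scope="session")
def default_screen_scored(default_screen):
    """Merged matrix, QMA fit and product scores for the default screen."""
    fm = qmap.merge_duplicates(default_screen.fm)
    est = qmap.qma_estimate(fm)
    sm = qmap.score_interactions(fm, est, "product")
    return fm, est, sm
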