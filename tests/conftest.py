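import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import settings

from ehrpairs import FeatureMatrix, PlantedPair, SimConfig, simulate_cohort
from ehrpairs.cohort import STRUCTURED, UNSTRUCTURED

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated cohort with one planted heterogeneous pair."""
    config = SimConfig(
        n_subjects=3000,
        case_fraction=0.05,
        seed=7,
        planted_pairs=[
            PlantedPair(
                "str_0000", "nlp_0000", 6.0, 6.0, 0.30, 0.10, 0.30, 0.10
            )
        ],
        prevalence_overrides={"str_0001": (0.15, 0.15)},
    )
    events, labels = simulate_cohort(config)
    return config, events, labels


def binary_matrix(X, y, kinds=None, feature_ids=None, tag="s"):
    """Helper: wrap a dense 0/1 array into a FeatureMatrix."""
    X = np.asarray(X)
    n, p = X.shape
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(p)]
    if kinds is None:
        kinds = np.array([STRUCTURED] * p, dtype=object)
    return FeatureMatrix(
        subject_ids=np.array([f"{tag}{i:05d}" for i in range(n)]),
        feature_ids=list(feature_ids),
        kinds=np.asarray(kinds, dtype=object),
        counts=sp.csr_matrix(X),
        labels=np.asarray(y, dtype=int),
    )


def sample_joint_columns(p_a, p_b, odds_ratio, n, rng):
    """Sample paired binary columns with the requested 2x2 distribution."""
    from ehrpairs import solve_cell_probs

    probs = solve_cell_probs(p_a, p_b, odds_ratio).ravel()
    cell = rng.choice(4, size=n, p=probs)
    return (cell < 2).astype(int), ((cell == 0) | (cell == 2)).astype(int)
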