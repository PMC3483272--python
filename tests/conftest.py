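import numpy as np
import pytest

from homogwas.spheres import Cohort, build_neighbor_index


def make_cohort(coords, diseased, weights=None, ids=None):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] == 1 and coords.shape[1] > 1 and np.ndim(diseased) == 1 and len(diseased) == coords.shape[1]:
        coords = coords.T  # 1-D positions given as a flat list
    n = coords.shape[0]
    return Cohort(
        ids=np.array([f"s{i}" for i in range(n)], dtype=object) if ids is None else np.asarray(ids, dtype=object),
        diseased=np.asarray(diseased, dtype=bool),
        coords=coords,
        weights=weights,
    )


@pytest.fixture
def line_cohort():
    """Four subjects on a line at 0, 1, 2, 9 (2 diseased, 2 healthy)."""
    return make_cohort([[0.0], [1.0], [2.0], [9.0]], [True, False, True, False])


@pytest.fixture
def colocated_pairs_cohort():
    """Two locations, each with one diseased + one healthy unit-weight subject."""
    return make_cohort(
        [[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]],
        [True, False, True, False],
    )


@pytest.fixture(scope="session")
def random_cohorts():
    """Random small weighted cohorts for oracle-equivalence sweeps."""
    rng = np.random.default_rng(20260920)
    cohorts = []
    for _ in range(100):
        n = int(rng.integers(10, 201))
        coords = rng.normal(size=(n, 3)) * rng.uniform(0.5, 3.0)
        diseased = rng.random(n) < rng.uniform(0.3, 0.7)
        if diseased.all() or not diseased.any():
            diseased[0] = ~diseased[0]
        weights = np.where(rng.random(n) < 0.15, 0.2, 1.0)
        cohorts.append(make_cohort(coords, diseased, weights))
    return cohorts


@pytest.fixture(scope="session")
def structured_cohort():
    """A mid-size structured synthetic cohort with its neighbor index."""
    from homogwas.simulate import StructuredCohortSpec, simulate_cohort

    cohort = simulate_cohort(StructuredCohortSpec(n_subjects=800, seed=42))
    return cohort, build_neighbor_index(cohort)
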