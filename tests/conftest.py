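import warnings

import numpy as np
import pytest

import fnirsnet as fn

# the study-design seed used for cohort-level fixtures throughout the suite
STUDY_SEED = 1


@pytest.fixture(scope="session")
def montage_atlas():
    return fn.load_montage()


@pytest.fixture(scope="session")
def atlas(montage_atlas):
    return montage_atlas[1]


@pytest.fixture(scope="session")
def small_cohort():
    """Four-subject cohort for fast structural tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fn.generate_cohort(fn.SynthConfig(n_hc=2, n_mcs=2,
                                                 seed=STUDY_SEED))


@pytest.fixture(scope="session")
def full_cohort():
    """The study-scale cohort: 16 HC vs 15 MCS, attenuation 0.6."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fn.generate_cohort(fn.SynthConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def full_result(full_cohort, atlas):
    """Pipeline output on the study-scale cohort (sigma skipped for speed;
    the small-worldness nulls are exercised separately)."""
    cfg = fn.RunConfig(seed=STUDY_SEED, compute_sigma=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fn.run_pipeline(full_cohort.raws, full_cohort.records,
                               atlas, cfg)


def random_binary_graph(rng, n, p):
    """Random undirected graph as a BinaryGraph."""
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    a = a | a.T
    return fn.BinaryGraph(tuple(range(1, n + 1)), a, 0.0)
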