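import logging
import warnings

import numpy as np
import pytest

import pedload as pl

logging.getLogger("pedload").setLevel(logging.ERROR)


# ---------------------------------------------------------------------------
# Toy pedigrees used across modules
# ---------------------------------------------------------------------------

@pytest.fixture
def mother_son_ped():
    """A,B founders; C = A x B (son of A); D = A x C (dam-son mating)."""
    return pl.pedigree_from_arrays([1, 2, 3, 4], [0, 0, 1, 1], [0, 0, 2, 3])


@pytest.fixture
def full_sib_ped():
    """A,B founders; C and D full sibs; E = C x D."""
    return pl.pedigree_from_arrays(
        [1, 2, 3, 4, 5], [0, 0, 1, 1, 3], [0, 0, 2, 2, 4]
    )


@pytest.fixture
def nested_ped():
    """G1,G2 founders; A = G1 x G2; B founder; C = A x B; D = A x C."""
    return pl.pedigree_from_arrays(
        [1, 2, 3, 4, 5, 6], [0, 0, 1, 0, 3, 3], [0, 0, 2, 0, 4, 5]
    )


def small_sim_config(seed=0, **kw):
    """A quick synthetic population for structural tests."""
    base = dict(
        n_founders=30,
        n_generations=5,
        sires_per_generation=5,
        dams_per_generation=20,
        offspring_per_dam=2,
        records_per_female=2.0,
        seed=seed,
    )
    base.update(kw)
    return pl.SimConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated dataset reused by design/model structural tests.

    Random mating keeps a usable amount of inbreeding in a tiny pedigree.
    """
    cfg = small_sim_config(seed=5, n_founders=20, n_generations=4,
                           dams_per_generation=12, sires_per_generation=4,
                           mating_policy="random")
    return pl.simulate_dataset(cfg, seed=5)


# ---------------------------------------------------------------------------
# Heavy shared experiments (computed once per session)
# ---------------------------------------------------------------------------

RECOVERY_CONFIG = pl.SimConfig(
    n_founders=120,
    n_generations=10,
    sires_per_generation=12,
    dams_per_generation=110,
    offspring_per_dam=3,
    records_per_female=2.0,
    # random mating keeps enough close inbreeding loops for the load design
    # to carry measurable information at this population size
    mating_policy="random",
    # truth on the dairy-sheep milk-yield scale
    sigma_u2=800.0,
    sigma_i2=10_000.0,
    sigma_ui=-300.0,
    sigma_p2=400.0,
    sigma_e2=1300.0,
    b=-110.0,
    seed=1,
)

NULL_CONFIG = pl.SimConfig(
    n_founders=40,
    n_generations=8,
    sires_per_generation=5,
    dams_per_generation=35,
    offspring_per_dam=2,
    records_per_female=2.0,
    mating_policy="random",
    sigma_i2=0.0,
    sigma_ui=0.0,
    seed=1,
)

SIGN_CONFIG = pl.SimConfig(
    n_founders=120,
    n_generations=10,
    sires_per_generation=12,
    dams_per_generation=110,
    offspring_per_dam=3,
    records_per_female=3.7,
    mating_policy="random",
    # strongly negative u-i covariance (r about -0.9) so its sign is
    # identifiable at desk scale
    sigma_ui=-2500.0,
    seed=1,
)


@pytest.fixture(scope="session")
def recovery_table():
    """20 simulate-and-refit replicates under a non-zero inbreeding load."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pl.recovery_experiment(RECOVERY_CONFIG, n_replicates=20, seed=42)


@pytest.fixture(scope="session")
def null_lrt_table():
    """200 scaled-down replicates under sigma_i2 = 0 for LRT calibration."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pl.recovery_experiment(NULL_CONFIG, n_replicates=200, seed=7)


@pytest.fixture(scope="session")
def sign_table():
    """10 replicates under a strongly negative u-i covariance."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pl.recovery_experiment(SIGN_CONFIG, n_replicates=10, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
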