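import numpy as np
import pytest

import bindspec as bs


@pytest.fixture(scope="session")
def planted_pwm():
    return bs.e2f8_like_pwm()


@pytest.fixture(scope="session")
def planted_dinuc():
    return bs.e2f8_like_dinuc()


@pytest.fixture(scope="session")
def small_selex_pools(planted_pwm):
    """A moderate 3-cycle SELEX run shared across tests.

    The virtual library (5,000 x 220 molecules) is just deep enough to
    hold a handful of exact consensus sites, so seed-anchored counting on
    the final cycle recovers the planted consensus.
    """
    cfg = bs.SelexSimConfig(n_reads_per_cycle=5000, n_cycles=3,
                            planted_model=planted_pwm, library_depth=220,
                            rng_seed=11)
    return bs.simulate_selex(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dinuc_model(rng, L=6):
    """A valid random DinucModel (rows Dirichlet-distributed).

    Rows are drawn independently, so the model need not be chain-
    consistent; the riverlake math only requires valid rows.
    """
    rows = rng.dirichlet(np.ones(16), size=L - 1)
    return bs.DinucModel(rows)


def chain_consistent_dinuc(rng, L=6):
    """A DinucModel generated from a genuine Markov chain, so that
    first/second-base marginals agree between neighbouring rows."""
    m = rng.dirichlet(np.ones(4))
    rows = []
    for _ in range(L - 1):
        T = rng.dirichlet(np.ones(4), size=4)
        joint = m[:, None] * T
        rows.append(joint.ravel())
        m = joint.sum(axis=0)
    return bs.DinucModel(np.asarray(rows))
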