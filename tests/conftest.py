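import numpy as np
import pytest

import rspqbd as rq


@pytest.fixture(scope="session")
def table1_solution():
    """The reference run: N=20, delta=5, epsilon=0.01, solved both ways."""
    game = rq.make_symmetric_general(5.0)
    space = rq.enumerate_states(20)
    gen = rq.build_generator(space, game, rq.RateSpec(epsilon=0.01))
    dist_bgs, rep_bgs = rq.solve_stationary(gen, method="block_gauss_seidel")
    dist_dir, rep_dir = rq.solve_stationary(gen, method="direct")
    return {
        "game": game, "space": space, "gen": gen,
        "bgs": (dist_bgs, rep_bgs), "direct": (dist_dir, rep_dir),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20160627)
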