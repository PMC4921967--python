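"""State enumeration, switch rates, and the QBD generator."""

import numpy as np
import pytest
import scipy.sparse as sp

import rspqbd as rq
from rspqbd.chain import SWITCH_PAIRS


class TestStateSpace:
    @pytest.mark.parametrize("N,count", [(1, 3), (2, 6), (5, 21), (20, 231)])
    def test_cardinality(self, N, count):
        space = rq.enumerate_states(N)
        assert len(space) == count == (N + 1) * (N + 2) // 2

    def test_states_partition_and_order(self):
        space = rq.enumerate_states(7)
        seen = set()
        prev = None
        for st in space:
            assert sum(st) == 7 and min(st) >= 0
            seen.add(st)
            key = (space.level_of(st), space.phase_of(st))
            assert key == (st[0], st[1])
            if prev is not None:
                assert key > prev
            prev = key
        assert len(seen) == len(space)

    def test_index_is_bijective(self):
        space = rq.enumerate_states(9)
        assert [space.index(st) for st in space] == list(range(len(space)))

    def test_level_slices_tile_the_space(self):
        space = rq.enumerate_states(6)
        covered = []
        for l in range(7):
            sl = space.level_slice(l)
            assert all(st[0] == l for st in space.states[sl])
            covered.extend(range(sl.start, sl.stop))
        assert covered == list(range(len(space)))

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            rq.enumerate_states(0)


class TestCyclicPermutation:
    @pytest.mark.parametrize("state,image", [
        ((7, 6, 7), (7, 7, 6)),
        ((20, 0, 0), (0, 20, 0)),
        ((0, 0, 5), (5, 0, 0)),
    ])
    def test_examples(self, state, image):
        assert rq.cyclic_permute_state(state) == image

    def test_three_applications_are_identity(self):
        st = (3, 9, 2)
        for _ in range(3):
            st = rq.cyclic_permute_state(st)
        assert st == (3, 9, 2)


class TestSwitchRate:
    def test_same_strategy_is_a_usage_error(self):
        with pytest.raises(ValueError):
            rq.switch_rate((1, 1, 0), 0, 0, rq.make_standard(), 2,
                           rq.RateSpec(0.1))

    @pytest.mark.parametrize("kernel", ["payoff_difference",
                                        "prevalence_weighted"])
    def test_nobody_to_switch_means_zero_rate(self, kernel):
        g = rq.make_symmetric_general(5.0)
        spec = rq.RateSpec(0.5, kernel=kernel)
        assert rq.switch_rate((0, 3, 2), 0, 1, g, 5, spec) == 0.0

    def test_no_imitation_of_weakly_worse_strategies_without_noise(self):
        g = rq.make_symmetric_general(5.0)
        spec = rq.RateSpec(0.0)
        state, N = (7, 6, 7), 20
        pi = rq.average_payoffs(g, state, N)
        for frm, to in SWITCH_PAIRS:
            r = rq.switch_rate(state, frm, to, g, N, spec)
            if pi[to] <= pi[frm]:
                assert r == 0.0
            else:
                assert r > 0.0

    def test_hand_computed_rate_at_table1_state(self):
        """delta=5, N=20, eps=0.01, state (7,6,7), R -> S, step by step."""
        g = rq.make_symmetric_general(5.0)
        # payoffs of R, S, P players: population mean against (7,6,7)/20
        # A row R = (0, -1, 6): pi_R = (-6 + 42)/20 = 1.8
        # A row S = (6, 0, -1): pi_S = (42 - 7)/20 = 1.75
        # A row P = (-1, 6, 0): pi_P = (-7 + 36)/20 = 1.45
        pi = rq.average_payoffs(g, (7, 6, 7), 20)
        assert np.allclose(pi, [1.8, 1.75, 1.45])
        spec = rq.RateSpec(0.01)
        # S is worse than R: only the noise term remains
        assert rq.switch_rate((7, 6, 7), 0, 1, g, 20, spec) == \
            pytest.approx(0.01)
        # R is better than S by 0.05: imitation + noise
        assert rq.switch_rate((7, 6, 7), 1, 0, g, 20, spec) == \
            pytest.approx(0.05 + 0.01)

    def test_bad_kernel_and_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            rq.RateSpec(-0.1)
        with pytest.raises(ValueError, match="kernel"):
            rq.RateSpec(0.1, kernel="mystery")


@pytest.fixture(scope="module")
def gen20():
    return rq.build_generator(rq.enumerate_states(20),
                              rq.make_symmetric_general(5.0),
                              rq.RateSpec(0.01))


class TestGenerator:
    def test_rows_sum_to_zero(self, gen20):
        assert np.abs(gen20.Q.sum(axis=1)).max() <= 1e-12

    def test_off_diagonals_nonnegative(self, gen20):
        coo = gen20.Q.tocoo()
        off = coo.data[coo.row != coo.col]
        assert np.all(off >= 0)

    def test_one_switch_locality(self, gen20):
        coo = gen20.Q.tocoo()
        states = np.asarray(gen20.space.states)
        mask = (coo.row != coo.col) & (coo.data > 0)
        diff = np.abs(states[coo.row[mask]] - states[coo.col[mask]])
        assert np.all(diff.sum(axis=1) == 2)

    def test_block_tridiagonal_in_level(self, gen20):
        coo = gen20.Q.tocoo()
        states = np.asarray(gen20.space.states)
        dlevel = np.abs(states[coo.row, 0] - states[coo.col, 0])
        assert dlevel.max() <= 1
        with pytest.raises(ValueError):
            gen20.block(0, 2)
        # block view reassembles the full matrix
        N = gen20.N
        dense = gen20.Q.toarray()
        for l in range(N + 1):
            for m in range(max(0, l - 1), min(N, l + 1) + 1):
                sl, sm = gen20.space.level_slice(l), gen20.space.level_slice(m)
                assert np.array_equal(gen20.block(l, m), dense[sl, sm])

    def test_cyclic_symmetry_equivariance(self, gen20):
        """For the symmetric game, relabeling strategies permutes Q onto
        itself: P Q P^T = Q."""
        space = gen20.space
        n = len(space)
        perm = np.array([space.index(rq.cyclic_permute_state(st))
                         for st in space])
        P = sp.csr_matrix((np.ones(n), (perm, np.arange(n))), shape=(n, n))
        diff = (P @ gen20.Q @ P.T - gen20.Q)
        assert abs(diff).max() < 1e-12

    def test_irreducible_with_noise(self, gen20):
        assert gen20.is_irreducible()
        assert len(gen20.components()) == 1

    def test_monomorphic_absorbing_without_noise_prevalence_kernel(self):
        gen = rq.build_generator(rq.enumerate_states(6),
                                 rq.make_symmetric_general(1.0),
                                 rq.RateSpec(0.0, kernel="prevalence_weighted"))
        for st in [(6, 0, 0), (0, 6, 0), (0, 0, 6)]:
            i = gen.space.index(st)
            assert gen.Q[i].count_nonzero() == 0

    def test_triplet_export_reconstructs_q(self, gen20):
        trip, idx = gen20.to_triplets()
        Q2 = sp.csr_matrix((trip["value"], (trip["row"], trip["col"])),
                           shape=gen20.Q.shape)
        assert abs(Q2 - gen20.Q).max() == 0
        assert list(idx.columns) == ["index", "n_R", "n_S", "n_P"]
        assert len(idx) == len(gen20.space)

    def test_population_of_one_rejected(self):
        with pytest.raises(ValueError, match="N >= 2"):
            rq.build_generator(rq.enumerate_states(1), rq.make_standard(),
                               rq.RateSpec(0.1))
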