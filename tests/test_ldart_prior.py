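"""Longitudinal grouped Dirichlet prior: schedule, selection probabilities,
conjugate updates, and the sparsity ordering of the concentration hyperpriors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gfbart.ldart_prior import (
    DartPrior,
    LdartPrior,
    LongitudinalGrouping,
    _init_state,
    c_schedule,
    dart_prior,
    selection_prob,
    update_state,
)


class TestSchedule:
    def test_four_waves(self):
        np.testing.assert_allclose(c_schedule(4), [0.5, 2 / 3, 5 / 6])

    @pytest.mark.parametrize("t", [2, 3, 4, 7, 25])
    def test_first_timepoint_always_half(self, t):
        sched = c_schedule(t)
        assert sched[0] == 0.5
        assert np.all(np.diff(sched) > 0)
        assert sched[-1] < 1.0

    def test_two_waves(self):
        np.testing.assert_allclose(c_schedule(2), [0.5])

    def test_single_wave_has_no_past_groups(self):
        assert c_schedule(1).size == 0


def _grouping(t=4, sizes=(5, 5, 5), current=5):
    idx = np.arange(current + sum(sizes))
    past, start = [], current
    for s in sizes:
        past.append(idx[start:start + s])
        start += s
    return LongitudinalGrouping(t=t, current=idx[:current], past=tuple(past))


class TestSelectionProb:
    def test_uniform_hierarchy_gives_uniform_q(self):
        g = _grouping(t=4, sizes=(5, 5, 5), current=5)
        st_ = _init_state(g)
        st_.w = 0.25  # 5 of 20 predictors are current
        q = selection_prob(st_, g)
        np.testing.assert_allclose(q, np.full(20, 0.05))

    def test_w_one_zeroes_past_mass(self):
        g = _grouping()
        st_ = _init_state(g)
        st_.w = 1.0
        q = selection_prob(st_, g)
        assert q[:5].sum() == pytest.approx(1.0)
        assert np.all(q[5:] == 0.0)

    def test_printed_product_rule(self):
        # wave-2 predictors under w=0.6, u=(0.1,0.3,0.6), uniform v^2 of size 5
        g = _grouping(t=4, sizes=(5, 5, 5), current=5)
        st_ = _init_state(g)
        st_.w = 0.6
        st_.u = np.array([0.1, 0.3, 0.6])
        q = selection_prob(st_, g)
        wave2 = q[g.past[1]]
        np.testing.assert_allclose(wave2, 0.4 * 0.3 / 5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 5))
    def test_always_normalized(self, seed, t):
        rng = np.random.default_rng(seed)
        sizes = tuple(int(rng.integers(1, 6)) for _ in range(t - 1))
        g = _grouping(t=t, sizes=sizes, current=int(rng.integers(1, 6)))
        state = _init_state(g)
        state = update_state(state, rng.integers(0, 10, size=g.P), g, rng)
        q = selection_prob(state, g)
        assert q.min() >= 0
        assert q.sum() == pytest.approx(1.0)


class TestUpdates:
    def test_zero_counts_draw_from_prior(self):
        """With no splits the w posterior is its Beta(1,1) prior."""
        g = _grouping()
        draws = [
            update_state(_init_state(g), np.zeros(g.P), g,
                         np.random.default_rng(i)).w
            for i in range(4000)
        ]
        d, p = stats.kstest(draws, "uniform")
        assert p > 0.001

    def test_w_posterior_matches_beta_conjugate(self):
        """Fixed counts: w | counts ~ Beta(1 + n_cur, 1 + n_past)."""
        g = _grouping()
        counts = np.zeros(g.P)
        counts[:5] = [4, 3, 0, 0, 0]   # 7 current splits
        counts[5:10] = [1, 1, 1, 0, 0]  # 3 past splits
        draws = np.array([
            update_state(_init_state(g), counts, g, np.random.default_rng(i)).w
            for i in range(4000)
        ])
        d, p = stats.kstest(draws, stats.beta(8, 4).cdf)
        assert p > 0.001

    def test_concentrated_counts_concentrate_q(self):
        g = _grouping()
        counts = np.zeros(g.P)
        counts[0] = 200.0  # every split on one current predictor
        rng = np.random.default_rng(0)
        state = _init_state(g)
        qs = []
        for _ in range(300):
            state = update_state(state, counts, g, rng)
            qs.append(selection_prob(state, g)[0])
        assert np.mean(qs) > 0.9

    def test_within_group_permutation_exchangeability(self):
        """Permuting counts within a group permutes the posterior draw law."""
        g = _grouping()
        counts = np.zeros(g.P)
        counts[5:10] = [5, 1, 0, 0, 0]
        perm = counts.copy()
        perm[5:10] = [0, 0, 1, 5, 0]
        q1 = np.mean([
            selection_prob(update_state(_init_state(g), counts, g,
                                        np.random.default_rng(i)), g)[5]
            for i in range(800)
        ])
        q2 = np.mean([
            selection_prob(update_state(_init_state(g), perm, g,
                                        np.random.default_rng(i)), g)[8]
            for i in range(800)
        ])
        assert q1 == pytest.approx(q2, rel=0.15)

    def test_negative_counts_rejected(self):
        g = _grouping()
        with pytest.raises(ValueError):
            update_state(_init_state(g), np.full(g.P, -1.0), g, 0)

    def test_alpha_hyperprior_stochastically_ordered(self):
        """E[alpha_1] < E[alpha_{t-1}] under the c_j schedule (prior draws)."""
        g = _grouping(t=4)
        rng = np.random.default_rng(3)
        a1, a3 = [], []
        state = _init_state(g)
        for _ in range(2000):
            state = update_state(state, np.zeros(g.P), g, rng)
            a1.append(state.alpha[0])
            a3.append(state.alpha[2])
        assert np.mean(a1) < np.mean(a3)

    def test_single_wave_degenerates_to_flat_dirichlet(self):
        g = LongitudinalGrouping(t=1, current=np.arange(6))
        state = update_state(_init_state(g), np.zeros(6), g, 0)
        assert state.w == 1.0
        q = selection_prob(state, g)
        assert q.sum() == pytest.approx(1.0)


class TestDart:
    def test_single_predictor(self):
        p = dart_prior(1)
        p.update(np.array([5]), np.random.default_rng(0))
        np.testing.assert_allclose(p.q, [1.0])

    def test_prior_mean_uniform_by_symmetry(self):
        p = dart_prior(8)
        rng = np.random.default_rng(1)
        qs = []
        for _ in range(3000):
            p.update(np.zeros(8), rng)
            qs.append(p.q.copy())
        np.testing.assert_allclose(np.mean(qs, axis=0), np.full(8, 1 / 8),
                                   atol=0.02)

    def test_counts_tilt_q(self):
        p = dart_prior(10)
        rng = np.random.default_rng(2)
        counts = np.zeros(10)
        counts[3] = 50
        qs = []
        for _ in range(500):
            p.update(counts, rng)
            qs.append(p.q[3])
        assert np.mean(qs) > 0.5

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            dart_prior(0)
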