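"""Capacity, marginal/shuffle channels and the information decomposition.

Closed-form channels (binary symmetric, noiseless F-ary, XOR) provide exact
expectations; random channels are checked against a brute-force grid search
over the input simplex.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wormcode.infotheory import (CapacityResult, DiscreteChannel,
                                 channel_capacity, decompose,
                                 marginalize_channel, mutual_information,
                                 shuffle_channel)
from conftest import make_channel, random_channel


def H2(p):
    return -p * np.log2(p) - (1 - p) * np.log2(1 - p)


def bsc(p):
    return make_channel([[1 - p, p], [p, 1 - p]])


def simplex_grid_search_capacity(P, step=1e-3):
    """Brute-force capacity of a 3-input channel: exhaustive MI over the simplex."""
    P = np.asarray(P)
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    best = 0.0
    logP = np.where(P > 0, np.log2(np.where(P > 0, P, 1.0)), 0.0)
    for a in ticks:
        bs = np.arange(0.0, 1.0 - a + step / 2, step)
        pin = np.stack([np.full_like(bs, a), bs, 1.0 - a - bs], axis=1)
        pin = np.clip(pin, 0.0, 1.0)
        q = pin @ P
        with np.errstate(divide="ignore"):
            logq = np.where(q > 0, np.log2(np.where(q > 0, q, 1.0)), 0.0)
        contrib = (P[None, :, :] * (logP[None, :, :] - logq[:, None, :]))
        mi = (pin[:, :, None] * np.where(P[None, :, :] > 0, contrib, 0.0)).sum(axis=(1, 2))
        best = max(best, float(mi.max()))
    return best


class TestMutualInformation:
    def test_identical_rows_carry_zero_bits(self):
        ch = make_channel([[0.2, 0.3, 0.5]] * 3)
        for p_in in ([1 / 3] * 3, [0.7, 0.2, 0.1]):
            assert mutual_information(ch, p_in) == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_binary_channel_is_one_bit(self):
        assert mutual_information(make_channel(np.eye(2)), [0.5, 0.5]) == \
            pytest.approx(1.0)

    def test_bsc_closed_form_and_explicit_double_sum(self, rng):
        p = 0.1
        ch = bsc(p)
        mi = mutual_information(ch, [0.5, 0.5])
        assert mi == pytest.approx(1 - H2(p), abs=1e-12)
        # independent double-sum oracle over the joint distribution
        pin = np.array([0.5, 0.5])
        joint = pin[:, None] * ch.P
        acc = sum(joint[f, m] * np.log2(joint[f, m] / (pin[f] * joint.sum(0)[m]))
                  for f in range(2) for m in range(2))
        assert mi == pytest.approx(acc, abs=1e-12)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(bsc(0.2), [0.7, 0.7])


class TestChannelCapacity:
    @pytest.mark.parametrize("F", [2, 4, 6])
    def test_noiseless_channel_reaches_log2_F_at_uniform_input(self, F):
        res = channel_capacity(make_channel(np.eye(F)))
        assert res.capacity == pytest.approx(np.log2(F), abs=1e-8)
        np.testing.assert_allclose(res.p_star, np.full(F, 1 / F), atol=1e-6)

    @pytest.mark.parametrize("p", [0.01, 0.1, 0.25])
    def test_bsc_capacity_closed_form(self, p):
        res = channel_capacity(bsc(p), tol=1e-10)
        assert res.capacity == pytest.approx(1 - H2(p), abs=1e-6)
        np.testing.assert_allclose(res.p_star, [0.5, 0.5], atol=1e-4)

    def test_random_channel_matches_simplex_grid_search(self, rng):
        ch = random_channel(rng, 3, 5)
        res = channel_capacity(ch, tol=1e-10)
        brute = simplex_grid_search_capacity(ch.P, step=1e-3)
        assert res.capacity == pytest.approx(brute, abs=1e-4)

    def test_capacity_dominates_mi_at_any_input(self, rng):
        ch = random_channel(rng, 4, 6)
        cap = channel_capacity(ch, tol=1e-9).capacity
        for _ in range(20):
            p = rng.dirichlet(np.ones(4))
            assert mutual_information(ch, p) <= cap + 1e-9

    def test_lower_bound_nondecreasing_and_gap_reported(self, rng):
        ch = random_channel(rng, 3, 4)
        caps = [channel_capacity(ch, tol=1e-12, max_iter=n).capacity
                for n in (1, 2, 5, 20, 200)]
        assert all(a <= b + 1e-12 for a, b in zip(caps, caps[1:]))
        res = channel_capacity(ch, tol=1e-9)
        assert res.converged and res.gap < 1e-9

    def test_nonconvergence_is_flagged_not_raised(self, rng):
        res = channel_capacity(random_channel(rng, 5, 9), tol=1e-13, max_iter=2)
        assert isinstance(res, CapacityResult) and not res.converged


class TestMarginalizeAndShuffle:
    def make_product_channel(self, rng, F=3, g1=4, g2=5):
        A = rng.dirichlet(np.ones(g1), size=F)
        B = rng.dirichlet(np.ones(g2), size=F)
        P = np.einsum("fi,fj->fij", A, B).reshape(F, g1 * g2)
        return make_channel(P, shape=(g1, g2)), A, B

    def test_marginal_of_product_channel_recovers_the_factor(self, rng):
        ch, A, B = self.make_product_channel(rng)
        np.testing.assert_allclose(marginalize_channel(ch, 0).P, A, atol=1e-12)
        np.testing.assert_allclose(marginalize_channel(ch, 1).P, B, atol=1e-12)

    def test_one_dimensional_marginalization_is_identity(self, rng):
        ch = random_channel(rng, 3, 7)
        assert marginalize_channel(ch, 0) is ch

    def test_marginal_rows_stay_normalized(self, rng):
        ch = random_channel(rng, 4, 12, shape=(3, 4))
        for i in range(2):
            np.testing.assert_allclose(marginalize_channel(ch, i).P.sum(axis=1),
                                       1.0, atol=1e-12)

    def test_shuffle_fixes_conditionally_independent_channels(self, rng):
        ch, _, _ = self.make_product_channel(rng)
        np.testing.assert_allclose(shuffle_channel(ch).P, ch.P, atol=1e-12)

    def test_shuffle_spreads_diagonal_mass_to_product(self):
        # perfectly correlated readouts: all mass on the 2x2 diagonal
        ch = make_channel([[0.5, 0.0, 0.0, 0.5], [0.25] * 4], shape=(2, 2))
        sh = shuffle_channel(ch)
        np.testing.assert_allclose(sh.P[0], [0.25, 0.25, 0.25, 0.25], atol=1e-12)
        np.testing.assert_allclose(sh.P[1], ch.P[1], atol=1e-12)

    def test_shuffle_preserves_per_condition_marginals(self, rng):
        ch = random_channel(rng, 3, 24, shape=(2, 3, 4))
        sh = shuffle_channel(ch)
        for i in range(3):
            np.testing.assert_allclose(marginalize_channel(sh, i).P,
                                       marginalize_channel(ch, i).P, atol=1e-12)

    def test_shuffle_requires_two_dimensions(self, rng):
        with pytest.raises(ValueError):
            shuffle_channel(random_channel(rng, 3, 7))

    def test_data_processing_marginal_capacity_bounded_by_joint(self, rng):
        ch = random_channel(rng, 4, 25, shape=(5, 5))
        joint = channel_capacity(ch, tol=1e-9).capacity
        for i in range(2):
            marg = channel_capacity(marginalize_channel(ch, i), tol=1e-9).capacity
            assert marg <= joint + 1e-8


class TestDecompose:
    def test_duplicated_readout_is_fully_redundant(self, rng):
        A = rng.dirichlet(np.ones(4), size=3)  # p(g1|f)
        F, G = A.shape
        P = np.zeros((F, G, G))
        idx = np.arange(G)
        P[:, idx, idx] = A  # g2 == g1 always
        ch = make_channel(P.reshape(F, G * G), shape=(G, G))
        dec = decompose(ch, tol=1e-12)
        assert dec.I_marginal[0] == pytest.approx(dec.I_joint, abs=1e-9)
        assert dec.I_marginal[1] == pytest.approx(dec.I_joint, abs=1e-9)
        assert dec.redundancy == pytest.approx(dec.I_marginal[0], abs=1e-9)
        assert dec.label == "redundant"

    def test_xor_channel_is_purely_synergistic(self):
        # f = g1 XOR g2; given f, (g1,g2) uniform over the matching pairs
        P = np.array([[0.5, 0.0, 0.0, 0.5],
                      [0.0, 0.5, 0.5, 0.0]])
        dec = decompose(make_channel(P, shape=(2, 2)), tol=1e-12)
        assert dec.I_joint == pytest.approx(1.0, abs=1e-9)
        assert dec.I_marginal == (pytest.approx(0.0, abs=1e-9),) * 2
        assert dec.redundancy == pytest.approx(-1.0, abs=1e-9)
        assert dec.label == "synergistic"

    def test_independent_informative_readouts_have_no_redundancy(self, rng):
        # 4 states = 2 bits; readout i sees only bit i, noiselessly
        bits = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        P = np.zeros((4, 2, 2))
        P[np.arange(4), bits[:, 0], bits[:, 1]] = 1.0
        dec = decompose(make_channel(P.reshape(4, 4), shape=(2, 2)), tol=1e-12)
        assert dec.I_joint == pytest.approx(2.0, abs=1e-8)
        assert dec.redundancy == pytest.approx(0.0, abs=1e-8)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_decomposition_identities_hold_exactly(self, seed):
        rng = np.random.default_rng(seed)
        F = int(rng.integers(2, 5))
        shape = tuple(rng.integers(2, 4, size=int(rng.integers(2, 4))))
        ch = random_channel(rng, F, int(np.prod(shape)), shape=shape)
        dec = decompose(ch, tol=1e-10)
        assert dec.redundancy == pytest.approx(sum(dec.I_marginal) - dec.I_joint,
                                               abs=1e-12)
        assert dec.noise_corr == pytest.approx(dec.I_joint - dec.I_shuffle, abs=1e-12)
        assert dec.signal_corr == pytest.approx(dec.I_shuffle - sum(dec.I_marginal),
                                                abs=1e-12)
        assert dec.signal_corr + dec.noise_corr == pytest.approx(-dec.redundancy,
                                                                 abs=1e-12)

    def test_capacity_bounded_by_log2_F(self, rng):
        for _ in range(5):
            ch = random_channel(rng, 6, 10)
            assert 0 <= channel_capacity(ch).capacity <= np.log2(6) + 1e-9
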