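"""Attention blocks against the hand-computed toy oracle and their invariants."""

import math

import numpy as np
import pytest

from mvifusion.fixtures import get_fixture
from mvifusion.nn.attention import CollaborativeAttention3d, SelfAttention3d
from mvifusion.nn.autodiff import Tensor


def test_fixture_registry_regenerates_identically():
    from mvifusion.fixtures import REGISTRY

    for name in REGISTRY:
        a, b = get_fixture(name), get_fixture(name)
        assert a.params == b.params
        for key in a.expected:
            np.testing.assert_array_equal(np.asarray(a.expected[key]), np.asarray(b.expected[key]))
    counts = get_fixture("augmentation_counts").expected
    assert counts["total_stride2"] == 729 and counts["per_axis_stride2"] == 9
    assert counts["total_stride4"] == 125 and counts["total_cut32"] == 1


def make_self_block(channels=1, d_qk=1, gamma=0.0):
    return SelfAttention3d(channels, d_qk, np.random.default_rng(0), gamma)


def set_toy_weights(block, wq, wk, wv, gamma):
    block.wq.data = np.array([[wq]], dtype=np.float64)
    block.wk.data = np.array([[wk]], dtype=np.float64)
    block.wv.data = np.array([[wv]], dtype=np.float64)
    block.gamma.data = np.asarray(gamma, dtype=np.float64)


class TestSelfAttention:
    def test_toy_fixture_oracle(self):
        fx = get_fixture("toy_attention")
        block = make_self_block()
        set_toy_weights(block, fx.params["wq"], fx.params["wk"], fx.params["wv"], fx.params["gamma"])
        out = block(Tensor(fx.data["x"]))
        np.testing.assert_allclose(out.attention.data[0], fx.expected["attention"], atol=1e-6)
        np.testing.assert_allclose(out.features.data[0], fx.expected["output"], atol=1e-6)

    def test_gamma_zero_is_exact_identity(self, rng):
        block = SelfAttention3d(8, 2, rng, gamma_init=0.0)
        x = Tensor(rng.standard_normal((3, 8, 27)))
        out = block(x)
        np.testing.assert_array_equal(out.features.data, x.data)

    def test_rows_sum_to_one_and_coefficients_in_unit_interval(self, rng):
        block = SelfAttention3d(6, 2, rng, gamma_init=0.5)
        for _ in range(5):
            out = block(Tensor(rng.standard_normal((2, 6, 16)) * 3.0))
            sums = out.attention.data.sum(axis=-1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-6)
            # open interval (0,1) mathematically; closed bounds numerically
            assert (out.attention.data >= 0).all() and (out.attention.data <= 1).all()

    def test_symmetric_scores_give_uniform_rows(self):
        block = make_self_block(gamma=0.0)
        set_toy_weights(block, 0.0, 0.7, 1.0, 0.0)  # zero query weight -> all scores equal
        out = block(Tensor(np.array([[[2.0, -1.0]]])))
        np.testing.assert_allclose(out.attention.data[0], 0.5, atol=1e-12)

    def test_score_gap_follows_two_way_softmax(self):
        # with q=x (wq=1), k=x (wk=1): row i has gap s_i1-s_i2 = x_i*(x1-x2)
        block = make_self_block()
        set_toy_weights(block, 1.0, 1.0, 1.0, 0.0)
        x1, x2 = 1.2, 0.4
        out = block(Tensor(np.array([[[x1, x2]]])))
        for i, xi in enumerate((x1, x2)):
            gap = xi * (x1 - x2)
            sig = 1.0 / (1.0 + math.exp(-gap))
            np.testing.assert_allclose(out.attention.data[0, i], [sig, 1 - sig], atol=1e-12)

    def test_nonfinite_input_rejected(self, rng):
        block = SelfAttention3d(2, 1, rng, 0.0)
        x = np.ones((1, 2, 4))
        x[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            block(Tensor(x))


class TestCollaborativeAttention:
    def test_gamma_zero_returns_own_features(self, rng):
        block = CollaborativeAttention3d(8, 2, rng, gamma_init=0.0)
        own = Tensor(rng.standard_normal((2, 8, 27)))
        others = [Tensor(rng.standard_normal((2, 8, 27))) for _ in range(3)]
        out = block(own, others)
        np.testing.assert_array_equal(out.features.data, own.data)

    def test_cross_collapses_to_self_when_others_equal_own(self, rng):
        sa = SelfAttention3d(4, 2, rng, gamma_init=0.8)
        ca = CollaborativeAttention3d(4, 2, rng, gamma_init=0.8)
        for name in ("wq", "wk", "wv", "gamma"):
            getattr(ca, name).data = getattr(sa, name).data.copy()
        x = Tensor(rng.standard_normal((2, 4, 8)))
        self_out = sa(x)
        cross_out = ca(x, [Tensor(x.data.copy()), Tensor(x.data.copy())])
        np.testing.assert_allclose(cross_out.features.data, self_out.features.data, atol=1e-6)
        np.testing.assert_allclose(cross_out.attention.data, self_out.attention.data, atol=1e-6)

    def test_two_phase_toy_matches_hand_computed_cross_attention(self):
        fx = get_fixture("toy_attention")
        a, b, c, g = fx.params["wq"], fx.params["wk"], fx.params["wv"], fx.params["gamma"]
        block = CollaborativeAttention3d(1, 1, np.random.default_rng(0), g)
        set_toy_weights(block, a, b, c, g)
        own = np.array([[[1.0, -1.0]]])
        other = np.array([[[0.5, 2.0]]])
        out = block(Tensor(own), [Tensor(other)])
        # hand computation: queries from own, keys/values from the other phase
        expect_attn = np.empty((2, 2))
        expect_y = np.empty(2)
        for i, xi in enumerate(own[0, 0]):
            s = [a * xi * b * oj for oj in other[0, 0]]
            e = np.exp(s - np.max(s))
            p = e / e.sum()
            expect_attn[i] = p
            expect_y[i] = xi + g * float(np.dot(p, c * other[0, 0]))
        np.testing.assert_allclose(out.attention.data[0], expect_attn, atol=1e-6)
        np.testing.assert_allclose(out.features.data[0, 0], expect_y, atol=1e-6)

    def test_mean_of_pair_matrices_is_row_stochastic(self, rng):
        block = CollaborativeAttention3d(4, 2, rng, gamma_init=0.3)
        own = Tensor(rng.standard_normal((1, 4, 8)))
        others = [Tensor(rng.standard_normal((1, 4, 8))) for _ in range(3)]
        out = block(own, others)
        np.testing.assert_allclose(out.attention.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_shape_mismatch_and_empty_others_rejected(self, rng):
        block = CollaborativeAttention3d(4, 2, rng, 0.0)
        own = Tensor(rng.standard_normal((1, 4, 8)))
        with pytest.raises(ValueError, match="mismatch"):
            block(own, [Tensor(rng.standard_normal((1, 4, 9)))])
        with pytest.raises(ValueError, match="at least one"):
            block(own, [])
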