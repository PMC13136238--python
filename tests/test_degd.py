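"""Dirichlet evidential decoder: the evidence algebra and the decode contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from espdnet.degd import (DEGDecoder, DirichletAttention,
                          EvidenceGuidedAttention, dirichlet_uncertainty,
                          evidence_to_alpha, expected_probability,
                          modulate_skip)
from espdnet.encoder import Encoder, EncoderConfig
from espdnet.nn import Tensor


class TestEvidenceToAlpha:
    def test_zero_evidence_limit(self):
        assert evidence_to_alpha(np.array([-40.0, -40.0])) == pytest.approx(
            [1.0, 1.0], abs=1e-12)

    def test_softplus_at_zero(self):
        assert evidence_to_alpha(np.zeros(2)) == pytest.approx(
            [1.0 + np.log(2.0)] * 2, abs=1e-9)

    def test_linear_asymptote(self):
        assert evidence_to_alpha(np.array([20.0]))[0] == pytest.approx(21.0, abs=1e-6)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            evidence_to_alpha(np.array([np.nan, 0.0]))


class TestDirichletAlgebra:
    @pytest.mark.parametrize("alpha,S,U", [
        ([1.0, 1.0], 2.0, 1.0),
        ([9.0, 1.0], 10.0, 0.2),
        ([199.0, 1.0], 200.0, 0.01),
    ])
    def test_uncertainty_closed_forms(self, alpha, S, U):
        s, u = dirichlet_uncertainty(np.array(alpha))
        assert s == pytest.approx(S, abs=1e-12)
        assert u == pytest.approx(U, abs=1e-12)

    def test_alpha_below_one_rejected(self):
        with pytest.raises(ValueError):
            dirichlet_uncertainty(np.array([0.5, 1.5]))

    @pytest.mark.parametrize("alpha,p", [
        ([1.0, 1.0], [0.5, 0.5]),
        ([3.0, 1.0], [0.75, 0.25]),
    ])
    def test_expected_probability(self, alpha, p):
        assert expected_probability(np.array(alpha)) == pytest.approx(p)

    def test_equal_probability_different_uncertainty(self):
        """p ~= [0.5, 0.5] from S=2 and S=200: identical means, opposite
        epistemic status (ambiguous region vs confident boundary)."""
        lo, hi = np.array([1.0, 1.0]), np.array([100.0, 100.0])
        assert expected_probability(lo) == pytest.approx(expected_probability(hi))
        assert dirichlet_uncertainty(lo)[1] == pytest.approx(1.0)
        assert dirichlet_uncertainty(hi)[1] == pytest.approx(0.01)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(1.0, 50.0), min_size=2, max_size=2),
           st.integers(0, 1), st.floats(0.01, 5.0))
    def test_uncertainty_strictly_decreasing_in_evidence(self, alpha, k, delta):
        a = np.array(alpha)
        bumped = a.copy()
        bumped[k] += delta
        assert dirichlet_uncertainty(bumped)[1] < dirichlet_uncertainty(a)[1]

    def test_probabilities_sum_to_one(self, rng):
        a = 1.0 + rng.gamma(2.0, 3.0, size=(2, 5, 4, 4))
        p = expected_probability(a, axis=1)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_expected_probability_is_dirichlet_mean(self, rng):
        """Monte-Carlo cross-check: alpha/S equals the empirical mean of
        Dir(alpha) samples within 3 standard errors."""
        for _ in range(10):
            a = 1.0 + rng.gamma(2.0, 2.0, size=2)
            draws = rng.dirichlet(a, size=100_000)
            mc = draws.mean(axis=0)
            se = draws.std(axis=0) / np.sqrt(draws.shape[0])
            assert np.all(np.abs(expected_probability(a) - mc) < 3 * se + 1e-9)


class TestAttention:
    def test_full_uncertainty_means_zero_confidence(self):
        u = Tensor(np.ones((1, 1, 4, 4)))
        k_conf = (1.0 - u).data
        assert np.allclose(k_conf, 0.0)

    def test_zero_mlp_gives_half(self, rng):
        att = EvidenceGuidedAttention(4, np.random.default_rng(0))
        for p in att.mlp1.parameters() + att.mlp2.parameters():
            p.data = np.zeros_like(p.data)
        q = Tensor(rng.uniform(0, 1, (1, 1, 4, 4)))
        k = Tensor(rng.uniform(0, 1, (1, 1, 4, 4)))
        v = Tensor(rng.normal(0, 1, (1, 4, 4, 4)))
        assert np.allclose(att(q, k, v).data, 0.5)

    def test_output_bounded(self, rng):
        att = EvidenceGuidedAttention(4, np.random.default_rng(1))
        out = att(Tensor(rng.uniform(0, 1, (2, 1, 4, 4))),
                  Tensor(rng.uniform(0, 1, (2, 1, 4, 4))),
                  Tensor(rng.normal(0, 2, (2, 4, 4, 4)))).data
        assert np.all(out > 0) and np.all(out < 1)

    def test_shape_mismatch_raises(self, rng):
        att = EvidenceGuidedAttention(4, np.random.default_rng(1))
        with pytest.raises(ValueError):
            att(Tensor(np.zeros((1, 1, 4, 4))), Tensor(np.zeros((1, 1, 8, 8))),
                Tensor(np.zeros((1, 4, 4, 4))))

    def test_dirichlet_attention_bounded_and_shaped(self, rng):
        att = DirichletAttention(8, np.random.default_rng(2))
        out = att(Tensor(rng.uniform(0, 1, (2, 1, 8, 8))),
                  Tensor(rng.normal(0, 1, (2, 8, 8, 8))),
                  Tensor(rng.uniform(0, 1, (2, 1, 8, 8)))).data
        assert out.shape == (2, 1, 8, 8)
        assert np.all(out > 0) and np.all(out < 1)

    def test_zeroed_edge_input_removes_edge_sensitivity(self, rng):
        att = DirichletAttention(8, np.random.default_rng(2))
        p = Tensor(rng.uniform(0, 1, (1, 1, 8, 8)))
        sem = Tensor(rng.normal(0, 1, (1, 8, 8, 8)))
        e1 = Tensor(rng.uniform(0, 1, (1, 1, 8, 8)))
        e2 = Tensor(rng.uniform(0, 1, (1, 1, 8, 8)))
        zero = Tensor(np.zeros((1, 1, 8, 8)))
        assert np.array_equal(att(p, sem, zero * e1).data,
                              att(p, sem, zero * e2).data)


class TestModulateSkip:
    def test_alpha_zero_identity(self, rng):
        f = Tensor(rng.normal(0, 1, (1, 6, 4, 4)))
        a = Tensor(rng.uniform(0, 1, (1, 1, 4, 4)))
        assert np.array_equal(modulate_skip(f, a, 0.0).data, f.data)

    def test_arithmetic(self):
        f = Tensor(np.full((1, 1, 2, 2), 4.0))
        a = Tensor(np.full((1, 1, 2, 2), 0.5))
        assert np.allclose(modulate_skip(f, a, 1.0).data, 6.0)

    def test_closed_gate_leaves_feature_unchanged(self, rng):
        f = Tensor(rng.normal(0, 1, (1, 3, 4, 4)))
        a = Tensor(np.zeros((1, 1, 4, 4)))
        assert np.array_equal(modulate_skip(f, a, 1.7).data, f.data)


def build_decoder_inputs(rng, evidential=True, size=64):
    cs = (8, 16, 32, 64)
    enc = Encoder(EncoderConfig(stage_channels=cs), np.random.default_rng(0))
    pyr = enc(Tensor(rng.uniform(0, 1, (2, 1, size, size)).astype(np.float32)))
    dec = DEGDecoder(cs, 64, np.random.default_rng(1), evidential=evidential)
    s_final = Tensor(rng.normal(0, 1, (2, 64, size // 8, size // 8)).astype(np.float32))
    e_b = Tensor(rng.uniform(0, 1, (2, 1, size, size)).astype(np.float32))
    return dec, pyr, s_final, e_b


class TestDecode:
    def test_shapes_ranges_and_scale_ladder(self, rng):
        dec, pyr, s_final, e_b = build_decoder_inputs(rng)
        m, pyramid, _ = dec(pyr, s_final, e_b)
        assert m.shape == (2, 1, 64, 64)
        assert np.all(m.data >= 0) and np.all(m.data <= 1)
        sizes = [tuple(u.shape[1:]) for u in pyramid.uncertainty_maps]
        assert sizes == [(4, 4), (8, 8), (16, 16), (32, 32)]

    def test_field_invariants_propagate(self, rng):
        dec, pyr, s_final, e_b = build_decoder_inputs(rng)
        _, pyramid, _ = dec(pyr, s_final, e_b)
        for f in pyramid.fields:
            assert np.all(f.alpha.data >= 1.0)
            assert np.all(f.S.data >= 2.0)
            assert np.all(f.U.data > 0) and np.all(f.U.data <= 1.0)
            assert np.allclose(f.p.data.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_evidence_heads_give_symmetric_ignorance(self, rng):
        """All-zero head weights: alpha = 1 + ln 2 per class everywhere, so
        U = 2/(2 + 2 ln 2) ~= 0.5907 and the coarse mask is exactly 0.5."""
        dec, pyr, s_final, e_b = build_decoder_inputs(rng)
        for head in dec.heads:
            head.weight.data = np.zeros_like(head.weight.data)
            head.bias.data = np.zeros_like(head.bias.data)
        m, pyramid, _ = dec(pyr, s_final, e_b)
        expected_u = 2.0 / (2.0 + 2.0 * np.log(2.0))
        for f in pyramid.fields:
            assert np.allclose(f.alpha.data, 1.0 + np.log(2.0), atol=1e-6)
            assert np.allclose(f.U.data, expected_u, atol=1e-6)
        assert np.allclose(m.data, 0.5, atol=1e-6)
        assert expected_u == pytest.approx(0.5907, abs=2e-4)

    def test_softmax_variant_outputs_distribution(self, rng):
        dec, pyr, s_final, e_b = build_decoder_inputs(rng, evidential=False)
        m, probs, _ = dec(pyr, s_final, e_b)
        assert m.shape == (2, 1, 64, 64)
        assert np.allclose(probs.data.sum(axis=1), 1.0, atol=1e-6)
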