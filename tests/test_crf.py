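"""Linear-chain CRF: scoring, partition function, Viterbi — all checked
against exhaustive enumeration on small instances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pascal import CrfParams, TerHeadParams, crf_log_partition, crf_score_sequence, fuse, ter_forward, viterbi_decode
from pascal.crf import (
    crf_nll_batch,
    emissions,
    enumerate_best_path,
    enumerate_log_partition,
)


def random_instance(rng, N=None, L=None, d=4):
    N = N or int(rng.integers(1, 6))
    L = L or int(rng.integers(2, 5))
    Hc = rng.normal(size=(N, d))
    params = CrfParams(rng.normal(size=(d, L)), rng.normal(size=(L, L)))
    return Hc, params, N, L


class TestTerHead:
    def test_zero_parameters_give_uniform_rows(self):
        H = np.random.default_rng(0).normal(size=(2, 5, 6))
        P = ter_forward(H, TerHeadParams(np.zeros((3, 6)), np.zeros(3)))
        np.testing.assert_allclose(P, 1.0 / 3.0)

    def test_rows_normalize(self):
        rng = np.random.default_rng(1)
        P = ter_forward(rng.normal(size=(4, 7, 6)), TerHeadParams(rng.normal(size=(3, 6)), rng.normal(size=3)))
        np.testing.assert_allclose(P.sum(axis=-1), 1.0, atol=1e-6)
        assert (P >= 0).all() and (P <= 1).all()

    def test_hand_set_logits_match_closed_form_softmax(self):
        # logits [2, 0, 0] -> probabilities e^2/(e^2+2), 1/(e^2+2), ...
        H = np.array([[[1.0]]])
        head = TerHeadParams(np.array([[2.0], [0.0], [0.0]]), np.zeros(3))
        P = ter_forward(H, head)
        z = np.exp(2.0) + 2.0
        np.testing.assert_allclose(P[0, 0], [np.exp(2.0) / z, 1 / z, 1 / z], rtol=1e-12)

    def test_masked_rows_emitted_uniform(self):
        rng = np.random.default_rng(2)
        H = rng.normal(size=(1, 4, 6))
        mask = np.array([[1.0, 1.0, 0.0, 0.0]])
        P = ter_forward(H, TerHeadParams(rng.normal(size=(3, 6)), rng.normal(size=3)), mask)
        np.testing.assert_allclose(P[0, 2:], 1.0 / 3.0)


class TestFuse:
    def test_concatenation_preserves_both_parts(self):
        rng = np.random.default_rng(3)
        H = rng.normal(size=(2, 5, 8))
        P = rng.dirichlet(np.ones(3), size=(2, 5))
        Hc = fuse(H, P)
        assert Hc.shape == (2, 5, 11)
        np.testing.assert_array_equal(Hc[..., :8], H)
        np.testing.assert_array_equal(Hc[..., 8:], P)

    def test_default_widths_fuse_to_259(self):
        H = np.zeros((1, 2, 256))
        P = np.full((1, 2, 3), 1 / 3)
        assert fuse(H, P).shape[-1] == 259

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse(np.zeros((1, 4, 8)), np.zeros((1, 5, 3)))


class TestScoring:
    def test_all_zero_parameters_score_zero(self):
        Hc = np.random.default_rng(4).normal(size=(5, 3))
        params = CrfParams(np.zeros((3, 2)), np.zeros((2, 2)))
        assert crf_score_sequence(Hc, np.array([0, 1, 0, 1, 1]), params) == 0.0

    def test_hand_computed_score(self):
        # identity emissions: e_1 = [1, 0], e_2 = [0, 1]; T[1, 0] = 5
        Hc = np.array([[1.0, 0.0], [0.0, 1.0]])
        params = CrfParams(np.eye(2), np.array([[0.0, 2.0], [5.0, 0.0]]))
        # labels (0, 1): em 1 + 1, transition T[1, 0] = 5
        assert crf_score_sequence(Hc, np.array([0, 1]), params) == pytest.approx(7.0)

    def test_probabilities_over_all_labelings_sum_to_one(self):
        from itertools import product

        rng = np.random.default_rng(5)
        Hc, params, N, L = random_instance(rng, N=4, L=3)
        logZ = crf_log_partition(Hc, params)
        total = sum(
            np.exp(crf_score_sequence(Hc, np.array(y), params) - logZ)
            for y in product(range(L), repeat=N)
        )
        assert total == pytest.approx(1.0, abs=1e-10)


class TestLogPartition:
    def test_uniform_case_equals_n_log_l(self):
        for N, L in [(1, 2), (3, 4), (6, 3)]:
            Hc = np.random.default_rng(6).normal(size=(N, 5))
            params = CrfParams(np.zeros((5, L)), np.zeros((L, L)))
            assert crf_log_partition(Hc, params) == pytest.approx(N * np.log(L), rel=1e-12)

    def test_single_position_is_logsumexp_of_emissions(self):
        rng = np.random.default_rng(7)
        Hc, params, _, _ = random_instance(rng, N=1, L=4)
        em = emissions(Hc, params)[0]
        expected = np.log(np.exp(em).sum())
        assert crf_log_partition(Hc, params) == pytest.approx(expected, rel=1e-10)

    def test_matches_enumeration_on_many_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            Hc, params, _, _ = random_instance(rng)
            assert crf_log_partition(Hc, params) == pytest.approx(
                enumerate_log_partition(Hc, params), abs=1e-5
            )


class TestViterbi:
    def test_zero_transitions_reduce_to_positionwise_argmax(self):
        rng = np.random.default_rng(9)
        Hc = rng.normal(size=(6, 4))
        params = CrfParams(rng.normal(size=(4, 3)), np.zeros((3, 3)))
        labels, score = viterbi_decode(Hc, params)
        em = emissions(Hc, params)
        np.testing.assert_array_equal(labels, em.argmax(axis=1))
        assert score == pytest.approx(em.max(axis=1).sum())

    def test_all_zero_parameters_tie_break_to_label_zero(self):
        Hc = np.zeros((4, 3))
        params = CrfParams(np.zeros((3, 3)), np.zeros((3, 3)))
        labels, score = viterbi_decode(Hc, params)
        assert (labels == 0).all() and score == 0.0

    def test_matches_enumeration_argmax_on_random_instances(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            Hc, params, _, _ = random_instance(rng)
            labels, score = viterbi_decode(Hc, params)
            ref_labels, ref_score = enumerate_best_path(Hc, params)
            np.testing.assert_array_equal(labels, ref_labels)
            assert score == pytest.approx(ref_score, abs=1e-8)
            assert score == pytest.approx(crf_score_sequence(Hc, labels, params), abs=1e-8)

    def test_viterbi_score_never_exceeds_log_partition(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            Hc, params, _, _ = random_instance(rng)
            _, score = viterbi_decode(Hc, params)
            assert score <= crf_log_partition(Hc, params) + 1e-9

    def test_boosting_decoded_labels_keeps_the_decoded_path(self):
        rng = np.random.default_rng(12)
        Hc, params, N, L = random_instance(rng, N=5, L=3)
        labels, _ = viterbi_decode(Hc, params)
        em = emissions(Hc, params)
        em2 = em.copy()
        em2[np.arange(N), labels] += 1.0
        from pascal.crf import _viterbi_em

        labels2, _ = _viterbi_em(em2, params.T)
        np.testing.assert_array_equal(labels, labels2)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_normalization_property_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        Hc, params, N, L = random_instance(rng, N=int(rng.integers(1, 5)), L=int(rng.integers(2, 4)))
        assert crf_log_partition(Hc, params) == pytest.approx(
            enumerate_log_partition(Hc, params), abs=1e-6
        )


class TestBatchedNll:
    def test_loss_matches_single_sentence_formula(self):
        rng = np.random.default_rng(13)
        Hc, params, N, L = random_instance(rng, N=5, L=3)
        gold = rng.integers(0, L, size=N)
        em = emissions(Hc, params)[None]
        loss, _, _ = crf_nll_batch(em, params.T, gold[None], np.ones((1, N)))
        expected = crf_log_partition(Hc, params) - crf_score_sequence(Hc, gold, params)
        assert loss == pytest.approx(expected, abs=1e-8)

    def test_masking_ignores_padded_positions(self):
        rng = np.random.default_rng(14)
        N, L = 6, 3
        em = rng.normal(size=(1, N, L))
        T = rng.normal(size=(L, L))
        gold = rng.integers(0, L, size=(1, N))
        mask = np.ones((1, N))
        mask[0, 4:] = 0.0
        loss_a, _, _ = crf_nll_batch(em, T, gold, mask)
        em2 = em.copy()
        em2[0, 4:] = rng.normal(size=(2, L)) * 100  # junk beyond the mask
        gold2 = gold.copy()
        gold2[0, 4:] = (gold2[0, 4:] + 1) % L
        loss_b, _, _ = crf_nll_batch(em2, T, gold2, mask)
        assert loss_a == pytest.approx(loss_b, abs=1e-9)

    def test_emission_gradient_is_marginals_minus_gold(self):
        # finite-difference check of d_em on a tiny instance
        rng = np.random.default_rng(15)
        N, L = 4, 3
        em = rng.normal(size=(1, N, L))
        T = rng.normal(size=(L, L))
        gold = rng.integers(0, L, size=(1, N))
        mask = np.ones((1, N))
        _, d_em, d_T = crf_nll_batch(em, T, gold, mask)
        eps = 1e-6
        for (i, j) in [(0, 0), (2, 1), (3, 2)]:
            for sgn_arr, idx in [(em, (0, i, j))]:
                em_p = em.copy(); em_p[idx] += eps
                em_m = em.copy(); em_m[idx] -= eps
                lp, _, _ = crf_nll_batch(em_p, T, gold, mask)
                lm, _, _ = crf_nll_batch(em_m, T, gold, mask)
                assert d_em[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5)
        T_p = T.copy(); T_p[1, 2] += eps
        T_m = T.copy(); T_m[1, 2] -= eps
        lp, _, _ = crf_nll_batch(em, T_p, gold, mask)
        lm, _, _ = crf_nll_batch(em, T_m, gold, mask)
        assert d_T[1, 2] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5)
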