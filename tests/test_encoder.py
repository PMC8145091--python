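"""Hierarchical encoder: GRU equations, attention pooling, masking, gradients."""

import numpy as np
import pytest

from knowdiag.autodiff import Tensor
from knowdiag.encoder import (AttentionParams, EncoderParams, GRUParams,
                              attention_pool, bigru_encode, encode_batch,
                              encode_document, gru_step, load_encoder,
                              save_encoder)


def zero_gru(input_dim, hidden):
    z = lambda *s: Tensor(np.zeros(s), requires_grad=True)
    return GRUParams(Wr=z(input_dim, hidden), Ur=z(hidden, hidden), br=z(hidden),
                     Wz=z(input_dim, hidden), Uz=z(hidden, hidden), bz=z(hidden),
                     Wh=z(input_dim, hidden), Uh=z(hidden, hidden), bh=z(hidden))


def gru_oracle(x, h, p):
    """Independent elementwise evaluation of the four GRU equations."""
    sig = lambda a: 1.0 / (1.0 + np.exp(-a))
    r = sig(x @ p.Wr.data + h @ p.Ur.data + p.br.data)
    z = sig(x @ p.Wz.data + h @ p.Uz.data + p.bz.data)
    h_cand = np.tanh(x @ p.Wh.data + (r * h) @ p.Uh.data + p.bh.data)
    return (1.0 - z) * h + z * h_cand


class TestGRUStep:
    def test_zero_params_halve_hidden_state(self):
        p = zero_gru(2, 3)
        v = np.array([1.0, -2.0, 0.5])
        np.testing.assert_allclose(gru_step(np.zeros(2), v, p), 0.5 * v)

    def test_zero_params_zero_state_fixed_point(self):
        p = zero_gru(2, 3)
        np.testing.assert_allclose(gru_step(np.ones(2), np.zeros(3), p), 0.0)

    def test_matches_scalar_oracle_on_random_parameterizations(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = GRUParams.init(1, 1, rng)
            x = rng.normal(size=1)
            h = rng.normal(size=1)
            np.testing.assert_allclose(gru_step(x, h, p),
                                       gru_oracle(x, h, p), atol=1e-6)

    def test_matches_vector_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = GRUParams.init(4, 3, rng)
            x, h = rng.normal(size=4), rng.normal(size=3)
            np.testing.assert_allclose(gru_step(x, h, p),
                                       gru_oracle(x, h, p), atol=1e-10)

    def test_shape_mismatch_raises(self):
        p = zero_gru(2, 3)
        with pytest.raises(ValueError, match="shape"):
            gru_step(np.zeros(5), np.zeros(3), p)


class TestBigru:
    def test_length_one_sequence(self):
        rng = np.random.default_rng(0)
        fwd, bwd = GRUParams.init(2, 3, rng), GRUParams.init(2, 3, rng)
        x = rng.normal(size=(1, 2))
        ann = bigru_encode(x, None, fwd, bwd)
        np.testing.assert_allclose(ann[0, :3], gru_oracle(x[0], np.zeros(3), fwd),
                                   atol=1e-12)
        np.testing.assert_allclose(ann[0, 3:], gru_oracle(x[0], np.zeros(3), bwd),
                                   atol=1e-12)

    def test_empty_sequence(self):
        rng = np.random.default_rng(0)
        fwd, bwd = GRUParams.init(2, 3, rng), GRUParams.init(2, 3, rng)
        assert bigru_encode(np.zeros((0, 2)), None, fwd, bwd).shape == (0, 6)

    def test_palindrome_with_tied_directions_is_mirror_symmetric(self):
        rng = np.random.default_rng(1)
        p = GRUParams.init(2, 3, rng)
        seq = rng.normal(size=(3, 2))
        pal = np.vstack([seq, seq[::-1][1:]])  # length 5 palindrome
        ann = bigru_encode(pal, None, p, p)
        T = pal.shape[0]
        for t in range(T):
            np.testing.assert_allclose(ann[t, :3], ann[T - 1 - t, 3:], atol=1e-10)

    def test_padding_does_not_change_real_annotations(self):
        rng = np.random.default_rng(2)
        fwd, bwd = GRUParams.init(2, 3, rng), GRUParams.init(2, 3, rng)
        seq = rng.normal(size=(4, 2))
        base = bigru_encode(seq, None, fwd, bwd)
        padded = np.vstack([seq, rng.normal(size=(3, 2))])  # garbage in padding
        mask = np.array([1, 1, 1, 1, 0, 0, 0])
        out = bigru_encode(padded, mask, fwd, bwd)
        np.testing.assert_allclose(out[:4], base, atol=1e-12)
        np.testing.assert_allclose(out[4:], 0.0)  # padded annotations zeroed


class TestAttentionPool:
    def test_identical_annotations_get_uniform_weights(self):
        rng = np.random.default_rng(0)
        params = AttentionParams.init(4, rng)
        ann = np.tile(rng.normal(size=4), (5, 1))
        pooled, alpha = attention_pool(ann, None, params)
        np.testing.assert_allclose(alpha, 0.2, atol=1e-12)
        np.testing.assert_allclose(pooled, ann[0], atol=1e-12)

    def test_single_unmasked_position(self):
        rng = np.random.default_rng(1)
        params = AttentionParams.init(3, rng)
        ann = rng.normal(size=(4, 3))
        pooled, alpha = attention_pool(ann, np.array([0, 0, 1, 0]), params)
        np.testing.assert_allclose(alpha, [0, 0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(pooled, ann[2], atol=1e-12)

    def test_matches_direct_tanh_softmax_evaluation(self):
        rng = np.random.default_rng(2)
        params = AttentionParams.init(3, rng)
        ann = rng.normal(size=(3, 3))
        pooled, alpha = attention_pool(ann, None, params)
        # independent evaluation
        u = np.tanh(ann @ params.W.data + params.b.data)
        scores = u @ params.u.data
        expected_alpha = np.exp(scores - scores.max())
        expected_alpha /= expected_alpha.sum()
        np.testing.assert_allclose(alpha, expected_alpha, atol=1e-12)
        np.testing.assert_allclose(pooled, expected_alpha @ ann, atol=1e-12)

    def test_all_masked_raises(self):
        rng = np.random.default_rng(3)
        params = AttentionParams.init(3, rng)
        with pytest.raises(ValueError, match="masked"):
            attention_pool(np.ones((2, 3)), np.array([0, 0]), params)


@pytest.fixture
def tiny_encoder():
    rng = np.random.default_rng(11)
    return EncoderParams.init(vocab_size=9, embedding_dim=4, hidden=3, rng=rng)


class TestEncodeDocument:
    def test_one_word_document_composes_from_primitives(self, tiny_encoder):
        p = tiny_encoder
        idx = np.array([[5]])
        mask = np.array([[1]])
        enc = encode_document(idx, mask, p)
        # manual composition: single word -> its annotation is the sentence
        # vector (attention over one position is 1), then one sentence step
        x = p.embedding.data[5]
        word_ann = np.concatenate([gru_oracle(x, np.zeros(3), p.word_fwd),
                                   gru_oracle(x, np.zeros(3), p.word_bwd)])
        sent_ann = np.concatenate([gru_oracle(word_ann, np.zeros(3), p.sent_fwd),
                                   gru_oracle(word_ann, np.zeros(3), p.sent_bwd)])
        np.testing.assert_allclose(enc.sentence_vectors[0], word_ann, atol=1e-10)
        np.testing.assert_allclose(enc.e, sent_ann, atol=1e-10)
        assert enc.word_attention[0, 0] == pytest.approx(1.0)
        assert enc.sentence_attention[0] == pytest.approx(1.0)

    def test_duplicated_sentence_yields_identical_sentence_vectors(self, tiny_encoder):
        # word-level encoding of identical sentences is identical; the
        # sentence-level Bi-GRU then sees the copies at different positions,
        # so their attention weights may differ slightly but both stay active
        idx = np.array([[2, 3, 0], [2, 3, 0]])
        mask = np.array([[1, 1, 0], [1, 1, 0]])
        enc = encode_document(idx, mask, tiny_encoder)
        np.testing.assert_allclose(enc.sentence_vectors[0],
                                   enc.sentence_vectors[1], atol=1e-12)
        assert enc.sentence_attention.sum() == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(enc.sentence_attention[0],
                                   enc.sentence_attention[1], atol=0.05)

    def test_invariant_to_amount_of_padding(self, tiny_encoder):
        idx = np.array([[2, 3], [4, 0]])
        mask = np.array([[1, 1], [1, 0]])
        enc = encode_document(idx, mask, tiny_encoder)
        idx_big = np.zeros((5, 7), dtype=int)
        mask_big = np.zeros((5, 7), dtype=int)
        idx_big[:2, :2] = idx
        mask_big[:2, :2] = mask
        idx_big[3:, 4:] = 8  # garbage token ids under zero mask
        enc_big = encode_document(idx_big, mask_big, tiny_encoder)
        np.testing.assert_allclose(enc.e, enc_big.e, atol=1e-10)
        np.testing.assert_allclose(enc_big.word_attention[mask_big == 0], 0.0)
        np.testing.assert_allclose(enc_big.sentence_attention[2:], 0.0)

    def test_attention_rows_sum_to_one(self, tiny_encoder):
        rng = np.random.default_rng(5)
        idx = rng.integers(1, 9, size=(4, 6))
        mask = np.ones((4, 6), dtype=int)
        mask[2, 3:] = 0
        mask[3, :] = 0
        idx[mask == 0] = 0
        enc = encode_document(idx, mask, tiny_encoder)
        for i in range(3):
            assert enc.word_attention[i].sum() == pytest.approx(1.0, abs=1e-6)
        assert enc.word_attention[3].sum() == pytest.approx(0.0)
        assert enc.sentence_attention.sum() == pytest.approx(1.0, abs=1e-6)

    def test_empty_document_raises(self, tiny_encoder):
        with pytest.raises(ValueError):
            encode_document(np.zeros((2, 2), dtype=int),
                            np.zeros((2, 2), dtype=int), tiny_encoder)

    def test_deterministic(self, tiny_encoder):
        idx = np.array([[2, 3], [4, 5]])
        mask = np.ones((2, 2), dtype=int)
        e1 = encode_document(idx, mask, tiny_encoder).e
        e2 = encode_document(idx, mask, tiny_encoder).e
        np.testing.assert_array_equal(e1, e2)


def test_gradient_check_through_full_encoder(tiny_encoder):
    """Finite-difference gradient of a scalar loss through encode_batch
    matches autodiff to 1e-4 on a tiny document."""
    p = tiny_encoder
    idx = np.array([[[2, 3], [4, 0]]])
    mask = np.array([[[1, 1], [1, 0]]])
    v = np.linspace(-1, 1, 6)

    def scalar_loss():
        e, _, _, _ = encode_batch(idx, mask, p)
        return (e.reshape(-1) * v).sum()

    loss = scalar_loss()
    for t in p.tensors():
        t.grad = None
    loss.backward()
    eps = 1e-5
    rng = np.random.default_rng(0)
    for tensor in [p.embedding, p.word_fwd.Wr, p.word_fwd.Uh, p.word_attn.u,
                   p.sent_fwd.Wz, p.sent_attn.W]:
        flat = tensor.data.reshape(-1)
        for idx_flat in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            orig = flat[idx_flat]
            flat[idx_flat] = orig + eps
            hi = float(scalar_loss().data)
            flat[idx_flat] = orig - eps
            lo = float(scalar_loss().data)
            flat[idx_flat] = orig
            fd = (hi - lo) / (2 * eps)
            ad = tensor.grad.reshape(-1)[idx_flat]
            assert ad == pytest.approx(fd, abs=1e-4)


def test_checkpoint_round_trip(tmp_path, tiny_encoder):
    path = tmp_path / "enc.npz"
    save_encoder(tiny_encoder, path)
    back = load_encoder(path)
    idx = np.array([[2, 3], [4, 5]])
    mask = np.ones((2, 2), dtype=int)
    np.testing.assert_array_equal(encode_document(idx, mask, tiny_encoder).e,
                                  encode_document(idx, mask, back).e)
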