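"""Hierarchical document encoder: word-level Bi-GRU + attention pooling into
sentence vectors, then sentence-level Bi-GRU + attention pooling into a single
document vector.

Both levels share the same structure.  The GRU follows the standard gating

    r_t = sigma(W_r x_t + U_r h_{t-1} + b_r)
    z_t = sigma(W_z x_t + U_z h_{t-1} + b_z)
    h~  = tanh(W_h x_t + U_h (r_t * h_{t-1}) + b_h)
    h_t = (1 - z_t) * h_{t-1} + z_t * h~

and the attention pooling is the HAN formulation: project each annotation
through tanh(W h + b), score it against a learned context vector, softmax
over non-padding positions, and return the weighted sum.  Padded positions
receive exactly zero attention (additive -inf masking), so annotations and
document vectors are invariant to the amount of padding.

All parameters are autodiff Tensors; forward passes run batched over
(batch, sentences, words) index arrays for speed, with per-sequence wrappers
for the individual operations.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

from .autodiff import (Tensor, concat, embedding, masked_softmax,
                       scatter_rows, stack)

__all__ = [
    "GRUParams",
    "AttentionParams",
    "EncoderParams",
    "EncodedDoc",
    "gru_step",
    "bigru_encode",
    "attention_pool",
    "encode_document",
    "encode_batch",
]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


@dataclass
class GRUParams:
    """Weights of one GRU direction (input, recurrent, bias per gate)."""

    Wr: Tensor
    Ur: Tensor
    br: Tensor
    Wz: Tensor
    Uz: Tensor
    bz: Tensor
    Wh: Tensor
    Uh: Tensor
    bh: Tensor

    @property
    def hidden_size(self) -> int:
        return self.Ur.shape[0]

    @classmethod
    def init(cls, input_dim: int, hidden: int, rng: np.random.Generator) -> "GRUParams":
        def w():
            return Tensor(_glorot(rng, input_dim, hidden), requires_grad=True)

        def u():
            return Tensor(_glorot(rng, hidden, hidden), requires_grad=True)

        def b():
            return Tensor(np.zeros(hidden), requires_grad=True)

        return cls(Wr=w(), Ur=u(), br=b(), Wz=w(), Uz=u(), bz=b(), Wh=w(), Uh=u(), bh=b())

    def tensors(self) -> list[Tensor]:
        return [getattr(self, f.name) for f in fields(self)]


@dataclass
class AttentionParams:
    """tanh projection + learned context vector for attention pooling."""

    W: Tensor
    b: Tensor
    u: Tensor  # context vector, randomly initialized and trained

    @classmethod
    def init(cls, dim: int, rng: np.random.Generator, proj: int | None = None) -> "AttentionParams":
        proj = proj or dim
        return cls(
            W=Tensor(_glorot(rng, dim, proj), requires_grad=True),
            b=Tensor(np.zeros(proj), requires_grad=True),
            u=Tensor(rng.normal(0.0, 0.1, size=proj), requires_grad=True),
        )

    def tensors(self) -> list[Tensor]:
        return [self.W, self.b, self.u]


@dataclass
class EncodedDoc:
    """Document vector plus the retained attention weights."""

    e: np.ndarray                       # (2H,)
    sentence_vectors: np.ndarray        # (L, 2H)
    word_attention: np.ndarray          # (L, T), zero on padding
    sentence_attention: np.ndarray      # (L,), zero on padding


# ---- GRU ----------------------------------------------------------------------

def _gru_cell(x: Tensor, h: Tensor, p: GRUParams) -> Tensor:
    r = (x @ p.Wr + h @ p.Ur + p.br).sigmoid()
    z = (x @ p.Wz + h @ p.Uz + p.bz).sigmoid()
    h_cand = (x @ p.Wh + (r * h) @ p.Uh + p.bh).tanh()
    return (1.0 - z) * h + z * h_cand


def gru_step(x_t: np.ndarray, h_prev: np.ndarray, params: GRUParams) -> np.ndarray:
    """One GRU step on a single input/hidden vector pair."""
    x = Tensor(np.asarray(x_t, dtype=float).reshape(1, -1))
    h = Tensor(np.asarray(h_prev, dtype=float).reshape(1, -1))
    if x.shape[1] != params.Wr.shape[0] or h.shape[1] != params.hidden_size:
        raise ValueError(
            f"shape mismatch: x has dim {x.shape[1]} (expected {params.Wr.shape[0]}), "
            f"h has dim {h.shape[1]} (expected {params.hidden_size})"
        )
    return _gru_cell(x, h, params).data[0]


def _gru_direction(
    x: Tensor, mask: np.ndarray, params: GRUParams, reverse: bool
) -> Tensor:
    """Run one direction over (B, T, E); padded steps carry the state through.

    Algebraically identical to iterating ``_gru_cell``, but the input
    projections of all time steps are computed in one matmul and the
    reset/update recurrent matrices are fused, which roughly halves the
    number of tape nodes per step.
    """
    B, T, _ = x.shape
    H = params.hidden_size
    xp_rz = x @ concat([params.Wr, params.Wz], axis=1) \
        + concat([params.br, params.bz], axis=0)          # (B, T, 2H)
    xp_h = x @ params.Wh + params.bh                       # (B, T, H)
    U_rz = concat([params.Ur, params.Uz], axis=1)          # (H, 2H)
    h = Tensor(np.zeros((B, H)))
    states: list[Tensor] = [None] * T  # type: ignore[list-item]
    steps = range(T - 1, -1, -1) if reverse else range(T)
    for t in steps:
        gates = (xp_rz[:, t, :] + h @ U_rz).sigmoid()
        r, z = gates[:, :H], gates[:, H:]
        h_cand = (xp_h[:, t, :] + (r * h) @ params.Uh).tanh()
        h_new = (1.0 - z) * h + z * h_cand
        m = mask[:, t : t + 1].astype(float)  # (B, 1)
        h = h_new if m.all() else h_new * m + h * (1.0 - m)
        states[t] = h
    return stack(states, axis=1)  # (B, T, H)


def bigru_batch(
    x: Tensor, mask: np.ndarray, fwd: GRUParams, bwd: GRUParams
) -> Tensor:
    """Bidirectional annotations [h_fwd; h_bwd], zeroed on padded positions."""
    h_f = _gru_direction(x, mask, fwd, reverse=False)
    h_b = _gru_direction(x, mask, bwd, reverse=True)
    ann = concat([h_f, h_b], axis=-1)
    return ann * mask[:, :, None].astype(float)


def bigru_encode(
    sequence: np.ndarray,
    mask: np.ndarray | None,
    fwd: GRUParams,
    bwd: GRUParams,
) -> np.ndarray:
    """Encode one sequence of input vectors into (T, 2H) annotations."""
    sequence = np.asarray(sequence, dtype=float)
    if sequence.size == 0:
        return np.zeros((0, 2 * fwd.hidden_size))
    if mask is None:
        mask = np.ones(sequence.shape[0], dtype=int)
    x = Tensor(sequence[None, :, :])
    return bigru_batch(x, np.asarray(mask)[None, :], fwd, bwd).data[0]


# ---- attention ----------------------------------------------------------------

def _attend(h: Tensor, mask: np.ndarray, params: AttentionParams) -> tuple[Tensor, Tensor]:
    """Batched attention pooling over axis 1 of (B, T, D).

    Rows whose mask is entirely zero pool to a zero vector with all-zero
    weights (used for padding-only sentences inside a document batch).
    """
    proj = (h @ params.W + params.b).tanh()            # (B, T, A)
    scores = (proj @ params.u.reshape(-1, 1)).reshape(h.shape[0], h.shape[1])
    alpha = masked_softmax(scores, mask, axis=-1)       # (B, T)
    pooled = (alpha.reshape(h.shape[0], h.shape[1], 1) * h).sum(axis=1)
    return pooled, alpha


def attention_pool(
    annotations: np.ndarray,
    mask: np.ndarray | None,
    params: AttentionParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool one annotation sequence; requires at least one unmasked position."""
    annotations = np.asarray(annotations, dtype=float)
    if mask is None:
        mask = np.ones(annotations.shape[0], dtype=int)
    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError("attention_pool: all positions are masked")
    pooled, alpha = _attend(Tensor(annotations[None]), mask[None, :], params)
    return pooled.data[0], alpha.data[0]


# ---- document encoder ---------------------------------------------------------

@dataclass
class EncoderParams:
    """Full hierarchical encoder: embeddings + two Bi-GRU/attention levels."""

    embedding: Tensor
    word_fwd: GRUParams
    word_bwd: GRUParams
    word_attn: AttentionParams
    sent_fwd: GRUParams
    sent_bwd: GRUParams
    sent_attn: AttentionParams

    @classmethod
    def init(
        cls,
        vocab_size: int,
        embedding_dim: int,
        hidden: int,
        rng: np.random.Generator,
        pretrained: np.ndarray | None = None,
    ) -> "EncoderParams":
        if pretrained is not None:
            emb = np.asarray(pretrained, dtype=float)
            if emb.shape != (vocab_size, embedding_dim):
                raise ValueError("pretrained embedding shape mismatch")
        else:
            emb = rng.normal(0.0, 0.1, size=(vocab_size, embedding_dim))
            emb[0] = 0.0  # padding row
        return cls(
            embedding=Tensor(emb, requires_grad=True),
            word_fwd=GRUParams.init(embedding_dim, hidden, rng),
            word_bwd=GRUParams.init(embedding_dim, hidden, rng),
            word_attn=AttentionParams.init(2 * hidden, rng),
            sent_fwd=GRUParams.init(2 * hidden, hidden, rng),
            sent_bwd=GRUParams.init(2 * hidden, hidden, rng),
            sent_attn=AttentionParams.init(2 * hidden, rng),
        )

    @property
    def hidden_size(self) -> int:
        return self.word_fwd.hidden_size

    def tensors(self) -> list[Tensor]:
        out = [self.embedding]
        for grp in (self.word_fwd, self.word_bwd, self.sent_fwd, self.sent_bwd):
            out.extend(grp.tensors())
        out.extend(self.word_attn.tensors())
        out.extend(self.sent_attn.tensors())
        return out


def encode_batch(
    idx: np.ndarray,
    mask: np.ndarray,
    params: EncoderParams,
) -> tuple[Tensor, Tensor, Tensor, Tensor]:
    """Encode a (B, S, T) index batch.

    Returns ``(e, sent_vecs, word_alpha, sent_alpha)`` where ``e`` is
    (B, 2H), ``sent_vecs`` (B, S, 2H), ``word_alpha`` (B, S, T) and
    ``sent_alpha`` (B, S); all are differentiable Tensors.
    """
    B, S, T = idx.shape
    H2 = 2 * params.hidden_size
    wmask = mask.reshape(B * S, T)
    real = np.flatnonzero(wmask.any(axis=1))  # skip padding-only sentences
    emb = embedding(params.embedding, idx.reshape(B * S, T)[real])
    ann = bigru_batch(emb, wmask[real], params.word_fwd, params.word_bwd)
    pooled, walpha_real = _attend(ann, wmask[real], params.word_attn)
    sent_flat = scatter_rows(pooled, real, B * S)                 # (B*S, 2H)
    walpha = scatter_rows(walpha_real, real, B * S)
    sent_vecs = sent_flat.reshape(B, S, H2)
    smask = mask.any(axis=2).astype(int)                          # (B, S)
    sann = bigru_batch(sent_vecs, smask, params.sent_fwd, params.sent_bwd)
    e, salpha = _attend(sann, smask, params.sent_attn)            # (B, 2H)
    return e, sent_vecs, walpha.reshape(B, S, T), salpha


def encode_document(
    idx: np.ndarray,
    mask: np.ndarray,
    params: EncoderParams,
) -> EncodedDoc:
    """Encode one padded (S, T) document into an EncodedDoc."""
    idx = np.asarray(idx)
    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError("cannot encode a document with no real tokens")
    e, sv, wa, sa = encode_batch(idx[None], mask[None], params)
    return EncodedDoc(
        e=e.data[0],
        sentence_vectors=sv.data[0],
        word_attention=wa.data[0],
        sentence_attention=sa.data[0],
    )


# ---- checkpointing ------------------------------------------------------------

def _flatten_params(params: EncoderParams, prefix: str = "enc") -> dict[str, np.ndarray]:
    out = {f"{prefix}.embedding": params.embedding.data}
    for gname in ("word_fwd", "word_bwd", "sent_fwd", "sent_bwd"):
        grp: GRUParams = getattr(params, gname)
        for f in fields(grp):
            out[f"{prefix}.{gname}.{f.name}"] = getattr(grp, f.name).data
    for aname in ("word_attn", "sent_attn"):
        att: AttentionParams = getattr(params, aname)
        for key in ("W", "b", "u"):
            out[f"{prefix}.{aname}.{key}"] = getattr(att, key).data
    return out


def _load_params(arrays: dict[str, np.ndarray], prefix: str = "enc") -> EncoderParams:
    def t(name):
        return Tensor(arrays[f"{prefix}.{name}"], requires_grad=True)

    def gru(gname):
        return GRUParams(**{f: t(f"{gname}.{f}") for f in
                            ("Wr", "Ur", "br", "Wz", "Uz", "bz", "Wh", "Uh", "bh")})

    def attn(aname):
        return AttentionParams(W=t(f"{aname}.W"), b=t(f"{aname}.b"), u=t(f"{aname}.u"))

    return EncoderParams(
        embedding=t("embedding"),
        word_fwd=gru("word_fwd"),
        word_bwd=gru("word_bwd"),
        word_attn=attn("word_attn"),
        sent_fwd=gru("sent_fwd"),
        sent_bwd=gru("sent_bwd"),
        sent_attn=attn("sent_attn"),
    )


def save_encoder(params: EncoderParams, path: str | Path) -> None:
    np.savez(path, **_flatten_params(params))


def load_encoder(path: str | Path) -> EncoderParams:
    with np.load(path) as data:
        return _load_params({k: data[k] for k in data.files})
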