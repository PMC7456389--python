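"""Pseudo-cascade head: auxiliary recognition softmax, fusion, and a
linear-chain CRF over normalization labels.

The auxiliary head turns each context vector h_i into a probability
distribution over recognition (BIO) tags; that *distribution* — not a
hard argmax — is concatenated onto h_i, keeping the cascade end-to-end
differentiable.  The CRF scores a labeling Y of a length-N sentence as

    score(Y) = Σ_i  e_i[y_i]  +  Σ_{i≥2} T[y_i, y_{i-1}],

with emissions e_i = W^T h^c_i.  There is no start/stop state: the first
position contributes its emission only.  The partition function is
computed by the forward algorithm in log space; decoding is Viterbi with
ties broken toward the lowest label index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NEG_INF = -1e30


@dataclass(frozen=True)
class TerHeadParams:
    """Linear + softmax recognition head: P_i = softmax(W_r h_i + b_r)."""

    W_r: np.ndarray  # (d_r, d_h)
    b_r: np.ndarray  # (d_r,)

    @property
    def d_r(self) -> int:
        return self.b_r.shape[0]


@dataclass(frozen=True)
class CrfParams:
    """Emission projection W (d_in × L) and transition matrix T (L × L).

    ``T[j, i]`` is the score of label j at position t following label i
    at position t-1.
    """

    W: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        L = self.T.shape[0]
        if self.T.shape != (L, L) or self.W.shape[1] != L or L < 2:
            raise ValueError("inconsistent CRF parameter shapes")
        if not (np.isfinite(self.W).all() and np.isfinite(self.T).all()):
            raise ValueError("CRF parameters must be finite")


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def ter_forward(H: np.ndarray, params: TerHeadParams, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-position recognition distributions, shape (..., d_r).

    Masked (padded) rows are emitted as uniform; they are excluded from
    every loss downstream.
    """
    P = softmax(H @ params.W_r.T + params.b_r, axis=-1)
    if mask is not None:
        uniform = np.full(params.d_r, 1.0 / params.d_r, dtype=P.dtype)
        P = np.where(mask[..., None] > 0, P, uniform)
    return P


def fuse(H: np.ndarray, P: np.ndarray) -> np.ndarray:
    """h^c_i = [h_i, p_i]: plain column-wise concatenation."""
    if H.shape[:-1] != P.shape[:-1]:
        raise ValueError("H and P must agree on every axis but the last")
    return np.concatenate([H, P], axis=-1)


def _logsumexp(x: np.ndarray, axis: int = -1) -> np.ndarray:
    m = x.max(axis=axis, keepdims=True)
    return (m + np.log(np.exp(x - m).sum(axis=axis, keepdims=True))).squeeze(axis)


def emissions(H_c: np.ndarray, params: CrfParams) -> np.ndarray:
    return H_c @ params.W


def crf_score_sequence(H_c: np.ndarray, labels: np.ndarray, params: CrfParams) -> float:
    """Unnormalized log-score of one labeling of one sentence (N × d)."""
    em = emissions(H_c, params)
    labels = np.asarray(labels)
    s = em[np.arange(len(labels)), labels].sum()
    if len(labels) > 1:
        s += params.T[labels[1:], labels[:-1]].sum()
    return float(s)


def crf_log_partition(H_c: np.ndarray, params: CrfParams) -> float:
    """log Σ_Y exp(score(Y)) over all L^N labelings, by the forward
    algorithm in log space."""
    em = emissions(H_c, params)
    alpha = em[0]
    for t in range(1, em.shape[0]):
        alpha = em[t] + _logsumexp(alpha[None, :] + params.T, axis=1)
    return float(_logsumexp(alpha, axis=0))


def viterbi_decode(H_c: np.ndarray, params: CrfParams) -> tuple[np.ndarray, float]:
    """Highest-scoring labeling and its score; ties go to the lowest
    label index (np.argmax picks the first maximum)."""
    em = emissions(H_c, params)
    N, L = em.shape
    delta = em[0].astype(np.float64)
    back = np.zeros((N, L), dtype=np.int64)
    for t in range(1, N):
        cand = delta[None, :] + params.T  # cand[j, i]: come from i into j
        back[t] = np.argmax(cand, axis=1)
        delta = em[t] + cand[np.arange(L), back[t]]
    labels = np.zeros(N, dtype=np.int64)
    labels[-1] = int(np.argmax(delta))
    for t in range(N - 1, 0, -1):
        labels[t - 1] = back[t, labels[t]]
    return labels, float(delta[labels[-1]])


def enumerate_log_partition(H_c: np.ndarray, params: CrfParams) -> float:
    """Brute-force log-partition by exhaustive enumeration (oracle; tiny N only)."""
    from itertools import product

    N = H_c.shape[0]
    L = params.T.shape[0]
    scores = [crf_score_sequence(H_c, np.array(y), params) for y in product(range(L), repeat=N)]
    return float(_logsumexp(np.array(scores), axis=0))


def enumerate_best_path(H_c: np.ndarray, params: CrfParams) -> tuple[np.ndarray, float]:
    """Brute-force argmax labeling (oracle; tiny N only).  First maximum in
    lexicographic enumeration order == lowest-label-index tie-break."""
    from itertools import product

    N = H_c.shape[0]
    L = params.T.shape[0]
    best, best_s = None, -np.inf
    for y in product(range(L), repeat=N):
        s = crf_score_sequence(H_c, np.array(y), params)
        if s > best_s:
            best, best_s = np.array(y), s
    return best, best_s


# ---------------------------------------------------------------------------
# Batched training-path CRF: loss and analytic gradients via forward-backward
# ---------------------------------------------------------------------------


def crf_nll_batch(
    em: np.ndarray, T: np.ndarray, gold: np.ndarray, mask: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean negative log-likelihood over a batch, with gradients.

    ``em`` is (B, N, L) emissions, ``gold`` (B, N) label indices, ``mask``
    (B, N) with contiguous 1-prefixes.  Returns (loss, d_em, d_T) where
    d_em = (marginals − one-hot gold)·mask / B and d_T is expected minus
    observed transition counts / B.
    """
    B, N, L = em.shape
    emf = em.astype(np.float64)
    Tf = T.astype(np.float64)
    mk = mask > 0

    # forward
    alpha = np.zeros((B, N, L))
    alpha[:, 0] = emf[:, 0]
    for t in range(1, N):
        m = alpha[:, t - 1][:, None, :] + Tf[None, :, :]  # (B, j, i)
        mmax = m.max(axis=2, keepdims=True)
        step = emf[:, t] + (mmax[:, :, 0] + np.log(np.exp(m - mmax).sum(axis=2)))
        alpha[:, t] = np.where(mk[:, t, None], step, alpha[:, t - 1])
    amax = alpha[:, -1].max(axis=1, keepdims=True)
    logZ = amax[:, 0] + np.log(np.exp(alpha[:, -1] - amax).sum(axis=1))

    # backward
    beta = np.zeros((B, N, L))
    for t in range(N - 2, -1, -1):
        m = (emf[:, t + 1] + beta[:, t + 1])[:, :, None] + Tf[None, :, :]  # (B, j, i)
        mmax = m.max(axis=1, keepdims=True)
        step = mmax[:, 0, :] + np.log(np.exp(m - mmax).sum(axis=1))
        beta[:, t] = np.where(mk[:, t + 1, None], step, beta[:, t + 1])

    # unary marginals and gold score
    marg = np.exp(alpha + beta - logZ[:, None, None]) * mask[..., None]
    rows = np.arange(B)[:, None]
    cols = np.arange(N)[None, :]
    gold_em = np.where(mk, emf[rows, cols, gold], 0.0).sum(axis=1)
    trans_valid = mk[:, 1:]  # padding is a suffix, so mask_t implies mask_{t-1}
    gold_tr = np.where(trans_valid, Tf[gold[:, 1:], gold[:, :-1]], 0.0).sum(axis=1)
    loss = float(np.mean(logZ - gold_em - gold_tr))

    d_em = marg.copy()
    onehot_idx = (rows, cols, gold)
    np.subtract.at(d_em, onehot_idx, mask)
    d_em /= B

    # pairwise expected counts for d_T
    d_T = np.zeros((L, L))
    for t in range(1, N):
        valid = mk[:, t]
        if not valid.any():
            break
        pair = (
            alpha[:, t - 1][:, None, :]
            + Tf[None, :, :]
            + (emf[:, t] + beta[:, t])[:, :, None]
            - logZ[:, None, None]
        )
        pp = np.exp(pair) * valid[:, None, None]
        d_T += pp.sum(axis=0)
        np.subtract.at(d_T, (gold[valid, t], gold[valid, t - 1]), 1.0)
    d_T /= B

    return loss, d_em.astype(em.dtype), d_T.astype(T.dtype)


def viterbi_decode_batch(em: np.ndarray, T: np.ndarray, mask: np.ndarray) -> list[np.ndarray]:
    """Viterbi over a padded batch; returns one label array per sentence."""
    lengths = mask.sum(axis=1).astype(int)
    out = []
    for b in range(em.shape[0]):
        n = lengths[b]
        labels, _ = _viterbi_em(em[b, :n], T)
        out.append(labels)
    return out


def _viterbi_em(em: np.ndarray, T: np.ndarray) -> tuple[np.ndarray, float]:
    N, L = em.shape
    delta = em[0].astype(np.float64)
    back = np.zeros((N, L), dtype=np.int64)
    for t in range(1, N):
        cand = delta[None, :] + T
        back[t] = np.argmax(cand, axis=1)
        delta = em[t] + cand[np.arange(L), back[t]]
    labels = np.zeros(N, dtype=np.int64)
    labels[-1] = int(np.argmax(delta))
    for t in range(N - 1, 0, -1):
        labels[t - 1] = back[t, labels[t]]
    return labels, float(delta[labels[-1]])
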