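"""Training objectives: auxiliary recognition loss, CRF negative
log-likelihood, and their biased convex combination.

The joint objective is  L_BL = γ·L_TEN + (1−γ)·L_TER  with 0 < γ < 1,
weighting the primary normalization task against the auxiliary
recognition regularizer.  Both component losses are written as sums over
positions but averaged over the sentences of a batch, so γ keeps the
same meaning at any batch size (a "sum" reduction is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .crf import CrfParams, crf_log_partition, crf_score_sequence

BCE_EPS = 1e-7


class ConfigError(ValueError):
    """Invalid training configuration value."""


@dataclass(frozen=True)
class LossBundle:
    """Per-step loss components; l_bl = γ·l_ten + (1−γ)·l_ter exactly."""

    l_ter: float
    l_ten: float
    l_bl: float


def ter_loss(
    gold_onehot: np.ndarray,
    P: np.ndarray,
    mask: np.ndarray,
    eps: float = BCE_EPS,
    reduction: str = "mean",
) -> float:
    """Element-wise binary cross-entropy between gold one-hot tags and the
    predicted distributions, summed over unmasked positions and (by
    default) averaged over batch sentences.

    Accepts (N, d_r) single sentences or (B, N, d_r) batches.
    """
    loss, _ = ter_loss_grad(gold_onehot, P, mask, eps=eps, reduction=reduction)
    return loss


def ter_loss_grad(
    gold_onehot: np.ndarray,
    P: np.ndarray,
    mask: np.ndarray,
    eps: float = BCE_EPS,
    reduction: str = "mean",
) -> tuple[float, np.ndarray]:
    """BCE loss plus its gradient with respect to the probabilities."""
    if P.min() < 0.0 or P.max() > 1.0:
        raise ValueError("predicted probabilities must lie in [0, 1]")
    squeeze = P.ndim == 2
    if squeeze:
        gold_onehot, P, mask = gold_onehot[None], P[None], mask[None]
    B = P.shape[0]
    Pc = np.clip(P, eps, 1.0 - eps)
    m = mask[..., None]
    elem = -(gold_onehot * np.log(Pc) + (1.0 - gold_onehot) * np.log1p(-Pc)) * m
    denom = B if reduction == "mean" else 1
    loss = float(elem.sum()) / denom
    inside = (P > eps) & (P < 1.0 - eps)  # clip is flat outside
    dP = np.where(inside, (Pc - gold_onehot) / (Pc * (1.0 - Pc)), 0.0) * m / denom
    if squeeze:
        dP = dP[0]
    return loss, dP.astype(P.dtype)


def ter_loss_categorical(
    gold_onehot: np.ndarray, P: np.ndarray, mask: np.ndarray, eps: float = BCE_EPS
) -> float:
    """Categorical cross-entropy alternative to the element-wise BCE."""
    if P.ndim == 2:
        gold_onehot, P, mask = gold_onehot[None], P[None], mask[None]
    Pc = np.clip(P, eps, 1.0)
    elem = -(gold_onehot * np.log(Pc)).sum(axis=-1) * mask
    return float(elem.sum()) / P.shape[0]


def ten_loss(
    batch: Sequence[tuple[np.ndarray, np.ndarray]],
    params: CrfParams,
    reduction: str = "mean",
) -> float:
    """Mean over sentences of (log-partition − gold-path score).

    ``batch`` holds (H_c, gold label index) pairs, one per sentence.
    Non-negative up to numerical tolerance; zero only when the gold path
    carries all probability mass.
    """
    if not batch:
        raise ValueError("empty batch")
    total = 0.0
    for H_c, labels in batch:
        total += crf_log_partition(H_c, params) - crf_score_sequence(H_c, labels, params)
    return total / (len(batch) if reduction == "mean" else 1)


def biased_loss(l_ten: float, l_ter: float, gamma: float) -> float:
    """γ·L_TEN + (1−γ)·L_TER with 0 < γ < 1 enforced."""
    check_gamma(gamma)
    return gamma * l_ten + (1.0 - gamma) * l_ter


def check_gamma(gamma: float) -> None:
    if not 0.0 < gamma < 1.0:
        raise ConfigError(f"bias parameter gamma must lie strictly in (0, 1), got {gamma}")


def bundle(l_ten: float, l_ter: float, gamma: float) -> LossBundle:
    return LossBundle(l_ter=l_ter, l_ten=l_ten, l_bl=biased_loss(l_ten, l_ter, gamma))
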