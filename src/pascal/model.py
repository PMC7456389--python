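"""The full pseudo-cascade model: encoder → auxiliary head → fusion → CRF.

Variants (matching the single-/multi-task ablation grid):

* ``multitask=True, decoder="crf"``   — the full cascade: the auxiliary
  recognition distribution is concatenated onto each context vector and a
  CRF labels the result (the default).
* ``multitask=False, decoder="crf"``  — single-task CRF on the context
  vectors alone.
* ``multitask=False, decoder="softmax"`` — single-task per-character
  softmax classifier (no label-transition modeling).

All forward/backward arithmetic is numpy; gradients are hand-derived and
verified against finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import crf as crf_ops
from .crf import CrfParams, TerHeadParams, fuse, softmax, ter_forward
from .encoder import EncoderConfig, encoder_backward, encoder_forward, init_encoder_params, xavier
from .losses import bundle, check_gamma, ter_loss_grad, LossBundle

CHECKPOINT_SCHEMA = 1


@dataclass(frozen=True)
class ModelConfig:
    encoder: EncoderConfig
    n_labels: int  # |C| + 1 normalization labels
    n_ter_tags: int = 3  # BIO
    multitask: bool = True
    decoder: str = "crf"  # "crf" | "softmax"
    fuse_hard: bool = False  # concatenate argmax one-hot instead of probabilities
    ter_loss: str = "bce"  # "bce" (element-wise) | "ce" (categorical)

    def __post_init__(self) -> None:
        if self.decoder not in ("crf", "softmax"):
            raise ValueError(f"unknown decoder: {self.decoder!r}")
        if self.ter_loss not in ("bce", "ce"):
            raise ValueError(f"unknown ter_loss: {self.ter_loss!r}")
        if self.n_labels < 2:
            raise ValueError("need at least two labels (one regimen plus O)")

    @property
    def fused_width(self) -> int:
        return self.encoder.d_h + (self.n_ter_tags if self.multitask else 0)


class PascalModel:
    """Parameter container with forward, loss/gradient and decode paths."""

    def __init__(self, cfg: ModelConfig, seed: int = 0, params: dict[str, np.ndarray] | None = None):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        dt = np.dtype(cfg.encoder.dtype)
        if params is not None:
            self.params = params
            return
        p = init_encoder_params(cfg.encoder, rng)
        d_h = cfg.encoder.d_h
        if cfg.multitask:
            p["ter.W"] = xavier(rng, (cfg.n_ter_tags, d_h), d_h, cfg.n_ter_tags, dt)
            p["ter.b"] = np.zeros(cfg.n_ter_tags, dtype=dt)
        d_in = cfg.fused_width
        if cfg.decoder == "crf":
            p["crf.W"] = xavier(rng, (d_in, cfg.n_labels), d_in, cfg.n_labels, dt)
            p["crf.T"] = np.zeros((cfg.n_labels, cfg.n_labels), dtype=dt)
        else:
            p["dec.W"] = xavier(rng, (d_in, cfg.n_labels), d_in, cfg.n_labels, dt)
            p["dec.b"] = np.zeros(cfg.n_labels, dtype=dt)
        self.params = p

    # -- public views ------------------------------------------------------

    @property
    def ter_head(self) -> TerHeadParams:
        return TerHeadParams(self.params["ter.W"], self.params["ter.b"])

    @property
    def crf_params(self) -> CrfParams:
        return CrfParams(self.params["crf.W"], self.params["crf.T"])

    # -- training path -----------------------------------------------------

    def loss_and_grads(
        self,
        char_idx: np.ndarray,
        mask: np.ndarray,
        ten_gold: np.ndarray,
        ter_gold: np.ndarray,
        gamma: float,
        train: bool = True,
        rng: np.random.Generator | None = None,
    ) -> tuple[LossBundle, dict[str, np.ndarray]]:
        """One joint forward/backward pass over a padded batch.

        Returns the loss components and a gradient for every parameter of
        the active variant.  Gradients of L_TEN are scaled by γ and of
        L_TER by (1−γ), so they sum to ∇L_BL.  For single-task variants
        l_ter is 0 and l_bl equals l_ten.
        """
        cfg = self.cfg
        p = self.params
        grads: dict[str, np.ndarray] = {}
        H, enc_cache = encoder_forward(p, cfg.encoder, char_idx, mask, train=train, rng=rng)
        B, N, d_h = H.shape

        if cfg.multitask:
            check_gamma(gamma)
            logits = H @ p["ter.W"].T + p["ter.b"]
            P = softmax(logits, axis=-1)
            if cfg.fuse_hard:
                Pf = np.eye(cfg.n_ter_tags, dtype=P.dtype)[P.argmax(axis=-1)]
            else:
                Pf = P
            Hc = fuse(H, Pf)
            ter_onehot = np.eye(cfg.n_ter_tags, dtype=P.dtype)[ter_gold]
            if cfg.ter_loss == "bce":
                l_ter, dP_ter = ter_loss_grad(ter_onehot, P, mask)
            else:  # categorical cross-entropy variant
                Pc = np.clip(P, 1e-7, None)
                l_ter = float((-(ter_onehot * np.log(Pc)).sum(-1) * mask).sum() / H.shape[0])
                dP_ter = np.where(P > 1e-7, -ter_onehot / Pc, 0.0) * mask[..., None] / H.shape[0]
        else:
            Hc = H
            l_ter, dP_ter = 0.0, None

        if cfg.decoder == "crf":
            em = Hc @ p["crf.W"]
            l_ten, d_em, d_T = crf_ops.crf_nll_batch(em, p["crf.T"], ten_gold, mask)
            w_ten = gamma if cfg.multitask else 1.0
            grads["crf.T"] = w_ten * d_T
            d_em = w_ten * d_em
            grads["crf.W"] = Hc.reshape(-1, Hc.shape[-1]).T @ d_em.reshape(-1, cfg.n_labels)
            dHc = d_em @ p["crf.W"].T
        else:
            logits_d = Hc @ p["dec.W"] + p["dec.b"]
            Q = softmax(logits_d, axis=-1)
            onehot = np.eye(cfg.n_labels, dtype=Q.dtype)[ten_gold]
            logQ = np.log(np.clip(Q, 1e-12, None))
            l_ten = float(-((onehot * logQ).sum(axis=-1) * mask).sum() / B)
            w_ten = gamma if cfg.multitask else 1.0
            dlogits_d = w_ten * (Q - onehot) * mask[..., None] / B
            grads["dec.W"] = Hc.reshape(-1, Hc.shape[-1]).T @ dlogits_d.reshape(-1, cfg.n_labels)
            grads["dec.b"] = dlogits_d.sum(axis=(0, 1))
            dHc = dlogits_d @ p["dec.W"].T

        if cfg.multitask:
            dH = dHc[..., :d_h].copy()
            dP = (1.0 - gamma) * dP_ter
            if not cfg.fuse_hard:
                dP = dP + dHc[..., d_h:]
            # softmax backward: dlogits = P ⊙ (dP − ⟨dP, P⟩)
            dlogits = P * (dP - (dP * P).sum(axis=-1, keepdims=True))
            dlogits *= mask[..., None]
            grads["ter.W"] = dlogits.reshape(-1, cfg.n_ter_tags).T @ H.reshape(-1, d_h)
            grads["ter.b"] = dlogits.sum(axis=(0, 1))
            dH += dlogits @ p["ter.W"]
        else:
            dH = dHc

        grads.update(encoder_backward(dH, enc_cache, p, cfg.encoder))
        if cfg.multitask:
            return bundle(l_ten, l_ter, gamma), grads
        return LossBundle(l_ter=0.0, l_ten=l_ten, l_bl=l_ten), grads

    # -- inference path ----------------------------------------------------

    def forward(self, char_idx: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        """Deterministic inference forward: returns (H_c, TER distributions)."""
        H, _ = encoder_forward(self.params, self.cfg.encoder, char_idx, mask, train=False)
        if not self.cfg.multitask:
            return H, None
        P = ter_forward(H, self.ter_head, mask)
        if self.cfg.fuse_hard:
            Pf = np.eye(self.cfg.n_ter_tags, dtype=P.dtype)[P.argmax(axis=-1)]
            return fuse(H, Pf), P
        return fuse(H, P), P

    def predict(
        self, char_idx: np.ndarray, mask: np.ndarray
    ) -> tuple[list[np.ndarray], list[np.ndarray] | None, list[float]]:
        """Decode a padded batch: (TEN label indices, TER tag indices, scores)."""
        Hc, P = self.forward(char_idx, mask)
        lengths = mask.sum(axis=1).astype(int)
        if self.cfg.decoder == "crf":
            em = Hc @ self.params["crf.W"]
            labels, scores = [], []
            for b in range(em.shape[0]):
                n = lengths[b]
                lab, s = crf_ops._viterbi_em(em[b, :n], self.params["crf.T"])
                labels.append(lab)
                scores.append(s)
        else:
            logits = Hc @ self.params["dec.W"] + self.params["dec.b"]
            labels = [logits[b, : lengths[b]].argmax(axis=-1) for b in range(logits.shape[0])]
            scores = [float(logits[b, : lengths[b]].max(axis=-1).sum()) for b in range(logits.shape[0])]
        ter = None
        if P is not None:
            ter = [P[b, : lengths[b]].argmax(axis=-1) for b in range(P.shape[0])]
        return labels, ter, scores

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "schema": CHECKPOINT_SCHEMA,
            "model": {
                "n_labels": self.cfg.n_labels,
                "n_ter_tags": self.cfg.n_ter_tags,
                "multitask": self.cfg.multitask,
                "decoder": self.cfg.decoder,
                "fuse_hard": self.cfg.fuse_hard,
                "ter_loss": self.cfg.ter_loss,
            },
            "encoder": asdict(self.cfg.encoder),
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path) -> "PascalModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta["schema"] != CHECKPOINT_SCHEMA:
                raise ValueError(f"unsupported checkpoint schema {meta['schema']}")
            params = {k: data[k] for k in data.files if k != "__meta__"}
        enc = EncoderConfig(**{**meta["encoder"], "filters": tuple(meta["encoder"]["filters"])})
        cfg = ModelConfig(encoder=enc, **meta["model"])
        return cls(cfg, params=params)
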