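"""Gated convolutional encoder over character embeddings.

Architecture: an embedding lookup feeds a stack of gated convolutional
(GLU) blocks.  Each block computes two parallel 1-d convolutions B = C*W+b
and G = C*M+g and gates them elementwise, h(C) = B ⊙ σ(G).  The first
block projects the embedding width down to the first filter width with no
residual path; a 1×1 projection then lifts to the working width, and the
remaining blocks are residual (output C + h(C)).  Convolutions use
symmetric zero "same" padding: the task is offline labeling, so context
from both directions is available.

Everything here is plain numpy with hand-written backward passes
(im2col convolutions); forward passes in inference mode are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .corpus import PAD_INDEX


@dataclass(frozen=True)
class EncoderConfig:
    """Hyperparameters of the encoder stack.

    Defaults follow the reference configuration: 200-dim character
    embeddings, kernel width 3, four convolutional layers with filter
    widths (128, 256, 256, 256), of which the last three are residual
    blocks, dropout 0.5 during training.
    """

    vocab_size: int
    d_e: int = 200
    kernel: int = 3
    n_conv_layers: int = 4
    filters: tuple[int, ...] = (128, 256, 256, 256)
    n_residual_blocks: int = 3
    dropout: float = 0.5
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.kernel % 2 != 1:
            raise ValueError("kernel width must be odd (symmetric context)")
        if len(self.filters) != self.n_conv_layers:
            raise ValueError("filters must list one width per convolutional layer")
        if self.n_residual_blocks != self.n_conv_layers - 1:
            raise ValueError(
                "wiring assumes layer 1 is non-residual and all later layers are "
                "residual blocks: n_residual_blocks must equal n_conv_layers - 1"
            )
        if len(set(self.filters[1:])) > 1:
            raise ValueError("residual blocks must share one width")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def d_h(self) -> int:
        """Width of the context vectors the encoder emits."""
        return self.filters[-1]

    @property
    def receptive_radius(self) -> int:
        """Characters farther than this from position i cannot affect h_i."""
        return self.n_conv_layers * (self.kernel - 1) // 2


def xavier(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def init_encoder_params(cfg: EncoderConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Xavier-initialized parameter dictionary; biases zero; PAD row zero."""
    dt = np.dtype(cfg.dtype)
    k = cfg.kernel
    p: dict[str, np.ndarray] = {}
    p["embed.W"] = xavier(rng, (cfg.vocab_size, cfg.d_e), cfg.vocab_size, cfg.d_e, dt)
    p["embed.W"][PAD_INDEX] = 0.0
    d_in = cfg.d_e
    for layer, d_out in enumerate(cfg.filters, start=1):
        for kern in ("W", "M"):
            p[f"conv{layer}.{kern}"] = xavier(rng, (k, d_in, d_out), k * d_in, k * d_out, dt)
        p[f"conv{layer}.b"] = np.zeros(d_out, dtype=dt)
        p[f"conv{layer}.g"] = np.zeros(d_out, dtype=dt)
        if layer == 1 and cfg.filters[0] != cfg.filters[1]:
            p["proj.W"] = xavier(rng, (cfg.filters[0], cfg.filters[1]), cfg.filters[0], cfg.filters[1], dt)
        d_in = cfg.filters[1] if layer == 1 else d_out
    return p


def embed(char_idx: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Row lookup: output row i is row char_idx[i] of the embedding table.

    The PAD row (index 0) is all zeros by construction, so padded
    positions embed to zero vectors.
    """
    char_idx = np.asarray(char_idx)
    if char_idx.max(initial=0) >= table.shape[0]:
        raise IndexError("character index out of embedding-table range")
    return table[char_idx]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, N, d) → (B, N, k*d) windows under symmetric zero padding."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    win = sliding_window_view(xp, k, axis=1)  # (B, N, d, k)
    B, N, d, _ = win.shape
    return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, N, k * d)


def conv1d_same(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Same-padded 1-d convolution; returns (output, im2col cache)."""
    k, d_in, d_out = W.shape
    cols = _im2col(x, k)
    y = cols @ W.reshape(k * d_in, d_out) + b
    return y, cols


def conv1d_same_backward(
    dy: np.ndarray, cols: np.ndarray, W: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dW, db) of a same-padded convolution."""
    k, d_in, d_out = W.shape
    B, N, _ = dy.shape
    # flush float32 denormals: they carry no signal but can push BLAS onto
    # a very slow scalar path
    np.copyto(dy, 0.0, where=np.abs(dy) < 1e-30)
    dW = (cols.reshape(-1, k * d_in).T @ dy.reshape(-1, d_out)).reshape(k, d_in, d_out)
    db = dy.sum(axis=(0, 1))
    dcols = (dy @ W.reshape(k * d_in, d_out).T).reshape(B, N, k, d_in)
    pad = k // 2
    dxp = np.zeros((B, N + 2 * pad, d_in), dtype=dy.dtype)
    for j in range(k):
        dxp[:, j : j + N] += dcols[:, :, j]
    return dxp[:, pad : pad + N], dW, db


def glu_forward(
    x: np.ndarray, params: dict[str, np.ndarray], prefix: str
) -> tuple[np.ndarray, dict]:
    """h = (x*W + b) ⊙ σ(x*M + g)."""
    Bc, cols = conv1d_same(x, params[f"{prefix}.W"], params[f"{prefix}.b"])
    Gc, _ = conv1d_same(x, params[f"{prefix}.M"], params[f"{prefix}.g"])
    # clipping the pre-activation keeps σ and σ(1−σ) out of the float32
    # denormal range (σ(±30) is exact to ~1e-13 anyway)
    sig = 1.0 / (1.0 + np.exp(-np.clip(Gc, -30.0, 30.0)))
    return Bc * sig, {"cols": cols, "Bc": Bc, "sig": sig, "prefix": prefix}


def glu_backward(
    dy: np.ndarray, cache: dict, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]
) -> np.ndarray:
    prefix = cache["prefix"]
    sig, Bc, cols = cache["sig"], cache["Bc"], cache["cols"]
    dBc = dy * sig
    dGc = dy * Bc * sig * (1.0 - sig)
    dx1, dW, db = conv1d_same_backward(dBc, cols, params[f"{prefix}.W"])
    dx2, dM, dg = conv1d_same_backward(dGc, cols, params[f"{prefix}.M"])
    grads[f"{prefix}.W"] = grads.get(f"{prefix}.W", 0) + dW
    grads[f"{prefix}.b"] = grads.get(f"{prefix}.b", 0) + db
    grads[f"{prefix}.M"] = grads.get(f"{prefix}.M", 0) + dM
    grads[f"{prefix}.g"] = grads.get(f"{prefix}.g", 0) + dg
    return dx1 + dx2


def encoder_forward(
    params: dict[str, np.ndarray],
    cfg: EncoderConfig,
    char_idx: np.ndarray,
    mask: np.ndarray,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Map (B, N) character indices to (B, N, d_h) context vectors.

    Inputs at padded positions are zeroed before every convolution, so
    valid positions never see padding garbage; the returned matrix is
    itself zero at padded positions.  Dropout (inverted, applied to each
    block's output) is active only when ``train`` is set.
    """
    m3 = mask[..., None].astype(params["embed.W"].dtype)
    cache: dict = {"idx": char_idx, "mask3": m3, "glu": [], "drop": [], "resid_in": []}

    def dropout(h: np.ndarray) -> np.ndarray:
        if train and cfg.dropout > 0.0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            keep = (rng.random(h.shape) >= cfg.dropout).astype(h.dtype) / (1.0 - cfg.dropout)
            cache["drop"].append(keep)
            return h * keep
        cache["drop"].append(None)
        return h

    x = params["embed.W"][char_idx] * m3
    h, c = glu_forward(x, params, "conv1")
    cache["glu"].append(c)
    h = dropout(h)
    if "proj.W" in params:
        cache["proj_in"] = h
        h = h @ params["proj.W"]
    for layer in range(2, cfg.n_conv_layers + 1):
        xin = h * m3
        cache["resid_in"].append(xin)
        z, c = glu_forward(xin, params, f"conv{layer}")
        cache["glu"].append(c)
        h = dropout(xin + z)
    H = h * m3
    cache["pre_mask"] = h
    return H, cache


def encoder_backward(
    dH: np.ndarray,
    cache: dict,
    params: dict[str, np.ndarray],
    cfg: EncoderConfig,
) -> dict[str, np.ndarray]:
    """Backpropagate through the encoder; returns parameter gradients."""
    grads: dict[str, np.ndarray] = {}
    m3 = cache["mask3"]
    dh = dH * m3
    for layer in range(cfg.n_conv_layers, 1, -1):
        i = layer - 1  # index into per-block caches (block 1 is index 0)
        keep = cache["drop"][i]
        if keep is not None:
            dh = dh * keep
        dz = glu_backward(dh, cache["glu"][i], params, grads)
        dh = (dh + dz) * m3  # gradient w.r.t. the block's (masked) input
    if "proj.W" in params:
        grads["proj.W"] = cache["proj_in"].reshape(-1, params["proj.W"].shape[0]).T @ dh.reshape(
            -1, params["proj.W"].shape[1]
        )
        dh = dh @ params["proj.W"].T
    keep = cache["drop"][0]
    if keep is not None:
        dh = dh * keep
    dx = glu_backward(dh, cache["glu"][0], params, grads) * m3
    dWe = np.zeros_like(params["embed.W"])
    np.add.at(dWe, cache["idx"], dx)
    dWe[PAD_INDEX] = 0.0
    grads["embed.W"] = dWe
    return grads


def encode(
    char_idx: np.ndarray,
    mask: np.ndarray,
    params: dict[str, np.ndarray],
    cfg: EncoderConfig,
) -> np.ndarray:
    """Inference-mode forward pass: deterministic, dropout off."""
    H, _ = encoder_forward(params, cfg, char_idx, mask, train=False)
    return H
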