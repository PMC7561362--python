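"""Omics-specific encoders into the shared regulatory latent space.

Three networks, one per feature block:

* **Histone encoder** — a CNN (100 full-height 7x7 kernels, batch
  normalization, ReLU, 1-D max-pooling of size 3 / stride 3 with one zero
  of padding on each side) over the 7 x 40 binned log-count matrix,
  followed by a bidirectional LSTM (40 hidden units per direction) with
  additive attention over the 12 pooled positions.  Output ``h_hm`` has
  length 80 (the attended BiLSTM context).
* **Methylation encoder** — a dynamic bidirectional LSTM (10 per
  direction) with additive attention over the gene's variable-length CpG
  track.  Output ``h_me`` has length 20 for any track length; an empty
  track maps to the zero vector.
* **TF encoder** — single-head scaled dot-product self-attention over the
  candidate TF positions of the 3 x 1016 matrix (each position's 3-vector
  projected to a small query/key/value space), masked mean-pooling, and a
  linear map to ``h_tf`` of length 5.  Masked columns are excluded before
  softmax, so the output is invariant to whatever values they hold; an
  all-masked gene maps to the zero vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autograd import Tensor, concat, relu, softmax
from .ingest import HistoneMatrix, MethylationTrack, TFMatrix, N_BINS, N_MARKS, N_TFS


@dataclass
class EncoderConfig:
    """Architecture hyperparameters; defaults reproduce every printed shape."""

    conv_kernels: int = 100
    conv_kernel_width: int = 7  # kernels span all 7 marks (full height)
    pool_size: int = 3
    pool_stride: int = 3
    pool_pad: int = 1  # zeros added on each side before pooling
    hm_lstm_hidden: int = 40  # per direction -> |h_hm| = 80
    me_lstm_hidden: int = 10  # per direction -> |h_me| = 20
    tf_latent: int = 5
    tf_qkv_dim: int = 8
    tf_input_scale: float = 5.0  # divisor bringing TF features to unit scale
    attn_hidden: int = 32  # additive-attention projection width
    seed: int = 0

    @property
    def hm_latent(self) -> int:
        return 2 * self.hm_lstm_hidden

    @property
    def me_latent(self) -> int:
        return 2 * self.me_lstm_hidden

    @property
    def conv_out_len(self) -> int:
        return N_BINS - self.conv_kernel_width + 1

    @property
    def pooled_len(self) -> int:
        return (self.conv_out_len + 2 * self.pool_pad - self.pool_size) // self.pool_stride + 1


@dataclass
class HistoneLatent:
    h_hm: np.ndarray
    bin_attention: np.ndarray


@dataclass
class MethylationLatent:
    h_me: np.ndarray
    cpg_attention: np.ndarray


@dataclass
class TFLatent:
    h_tf: np.ndarray
    tf_attention: np.ndarray  # (1016, 1016); nonzero only on candidate rows/cols


def _max_pool1d(x: Tensor, size: int, stride: int, pad: int) -> Tensor:
    """Max-pool the last axis of (B, C, L) with zero padding on both sides."""
    B, C, L = x.shape
    if pad:
        z = Tensor(np.zeros((B, C, pad)))
        x = concat([z, x, z], axis=2)
    Lp = L + 2 * pad
    pieces = [
        x[:, :, s : s + size].max(axis=2)
        for s in range(0, Lp - size + 1, stride)
    ]
    from .autograd import stack

    return stack(pieces, axis=2)


class HistoneEncoder(nn.Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        K, W = cfg.conv_kernels, cfg.conv_kernel_width
        self.conv_w = nn.Parameter(nn.glorot(rng, N_MARKS * W, K, (K, N_MARKS, W)))
        self.conv_b = nn.Parameter(np.zeros(K))
        self.bn = nn.BatchNorm1d(K)
        self.lstm = nn.BiLSTM(K, cfg.hm_lstm_hidden, rng)
        self.attn = nn.AdditiveAttention(cfg.hm_latent, cfg.attn_hidden, rng)

    def __call__(self, x: Tensor):
        """x: (B, 7, 40) -> (context (B, 80), bin attention (B, 12))."""
        if x.shape[1:] != (N_MARKS, N_BINS):
            raise ValueError(f"expected (B, {N_MARKS}, {N_BINS}) input, got {x.shape}")
        from .autograd import conv1d_full_height

        fm = conv1d_full_height(x, self.conv_w, self.conv_b)  # (B, K, 34)
        fm = relu(self.bn(fm))
        pooled = _max_pool1d(fm, self.cfg.pool_size, self.cfg.pool_stride, self.cfg.pool_pad)
        steps = pooled.swapaxes(1, 2)  # (B, 12, K)
        states = self.lstm(steps)
        return self.attn(states)


class MethylationEncoder(nn.Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.lstm = nn.BiLSTM(1, cfg.me_lstm_hidden, rng)
        self.attn = nn.AdditiveAttention(cfg.me_latent, cfg.attn_hidden, rng)

    def __call__(self, betas: list[np.ndarray] | np.ndarray):
        """Variable-length CpG beta tracks -> (context (B, 20), attention (B, Tmax)).

        Attention rows are zero beyond each track's length; a length-0 track
        yields the zero context vector.
        """
        if isinstance(betas, np.ndarray) and betas.ndim == 1:
            betas = [betas]
        lengths = np.array([len(b) for b in betas])
        T = max(1, int(lengths.max()) if len(lengths) else 1)
        B = len(betas)
        padded = np.zeros((B, T, 1))
        for i, b in enumerate(betas):
            padded[i, : len(b), 0] = b
        mask = np.arange(T)[None, :] < lengths[:, None]
        states = self.lstm(Tensor(padded), lengths=np.maximum(lengths, 1))
        return self.attn(states, mask=mask)


class TFEncoder(nn.Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d = cfg.tf_qkv_dim
        self.wq = nn.Linear(3, d, rng)
        self.wk = nn.Linear(3, d, rng)
        self.wv = nn.Linear(3, d, rng)
        self.out = nn.Linear(d, cfg.tf_latent, rng)

    def __call__(self, vals: np.ndarray, mask: np.ndarray):
        """Compact candidate features -> (h_tf (B, 5), attention (B, C, C)).

        ``vals``: (B, C, 3) per-candidate feature triples (padded);
        ``mask``: (B, C) validity.  Masked positions are excluded from the
        softmax and from the mean-pool; genes with no candidates map to the
        zero vector.  Inputs are divided by a fixed scale so the attention
        logits start in the soft (trainable) range.
        """
        x = Tensor(np.asarray(vals) / self.cfg.tf_input_scale)
        d = self.cfg.tf_qkv_dim
        q, k, v = self.wq(x), self.wk(x), self.wv(x)
        scores = (q @ k.swapaxes(1, 2)) * (1.0 / np.sqrt(d))  # (B, C, C)
        key_mask = np.broadcast_to(mask[:, None, :], scores.shape)
        attn = softmax(scores, axis=-1, mask=key_mask)
        ctx = attn @ v  # (B, C, d)
        m = mask.astype(np.float64)
        denom = np.maximum(m.sum(axis=1, keepdims=True), 1.0)
        pooled = (ctx * Tensor(m[:, :, None])).sum(axis=1) / Tensor(denom)
        h = self.out(pooled)
        any_valid = (mask.any(axis=1)).astype(np.float64)
        h = h * Tensor(any_valid[:, None])  # all-masked gene -> zero vector
        attn = attn * Tensor(m[:, :, None])  # zero out masked query rows
        return h, attn


# ---------------------------------------------------------------------------
# single-example functional wrappers
# ---------------------------------------------------------------------------


def _default(encoder_cls, cfg: EncoderConfig | None):
    cfg = cfg or EncoderConfig()
    rng = np.random.default_rng(cfg.seed)
    enc = encoder_cls(cfg, rng)
    enc.eval()
    return enc


def encode_histone(hm: HistoneMatrix, cfg: EncoderConfig | None = None,
                   encoder: HistoneEncoder | None = None) -> HistoneLatent:
    enc = encoder or _default(HistoneEncoder, cfg)
    h, w = enc(Tensor(hm.values[None]))
    return HistoneLatent(h_hm=h.data[0].copy(), bin_attention=w.data[0].copy())


def encode_methylation(me: MethylationTrack, cfg: EncoderConfig | None = None,
                       encoder: MethylationEncoder | None = None) -> MethylationLatent:
    enc = encoder or _default(MethylationEncoder, cfg)
    h, w = enc([me.betas])
    attn = w.data[0][: len(me)].copy()
    return MethylationLatent(h_me=h.data[0].copy(), cpg_attention=attn)


def encode_tf(tf: TFMatrix, cfg: EncoderConfig | None = None,
              encoder: TFEncoder | None = None) -> TFLatent:
    enc = encoder or _default(TFEncoder, cfg)
    cand = np.flatnonzero(tf.mask)
    full = np.zeros((N_TFS, N_TFS))
    if cand.size == 0:
        h = np.zeros(enc.cfg.tf_latent)
        return TFLatent(h_tf=h, tf_attention=full)
    vals = tf.values[:, cand].T[None]  # (1, C, 3)
    mask = np.ones((1, cand.size), dtype=bool)
    h, attn = enc(vals, mask)
    full[np.ix_(cand, cand)] = attn.data[0]
    return TFLatent(h_tf=h.data[0].copy(), tf_attention=full)
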