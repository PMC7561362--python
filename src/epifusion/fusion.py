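"""Multi-attention fusion of the omics latent vectors.

The three latent vectors ``h_hm`` (80), ``h_me`` (20) and ``h_tf`` (5) are
concatenated into ``h`` (length 105 under the default configuration).  One
affine map ``A`` produces ``k`` attention weightings over the joint vector:
its output is reshaped to ``k`` rows of length ``|h|`` and softmaxed per
row (across all coordinates, so heads can trade mass between omics blocks).
Each attended copy is the elementwise product ``h~_i = h * a_i``; their
concatenation feeds a final affine layer whose scalar score decides the
label: +1 (HEG) iff score > 0.

The per-head attention mass over an omics' coordinate range, divided by the
block's size (so the 5-dim TF block is not penalized for being small),
gives the per-omics importance used in the cross-cell-line comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor, softmax


@dataclass
class FusedLatent:
    h: np.ndarray  # concatenated latent vector
    block_attentions: np.ndarray  # (k, |h|), each row sums to 1
    attended: np.ndarray  # (k, |h|), h~_i = h * a_i


@dataclass
class Prediction:
    score: float
    label: int  # +1 iff score > 0


class MultiAttentionBlock(nn.Module):
    """k-head attention over a concatenated latent vector plus the output layer."""

    def __init__(self, in_dim: int, k: int, rng: np.random.Generator):
        super().__init__()
        if k < 1:
            raise ValueError("attention count k must be >= 1")
        self.k = k
        self.in_dim = in_dim
        self.attn_map = nn.Linear(in_dim, k * in_dim, rng)  # the affine map A
        self.out = nn.Linear(k * in_dim, 1, rng)

    def attend(self, h: Tensor):
        """h: (B, L) -> (attentions (B, k, L), attended copies (B, k, L))."""
        B, L = h.shape
        logits = self.attn_map(h).reshape(B, self.k, L)
        a = softmax(logits, axis=-1)
        attended = h.reshape(B, 1, L) * a
        return a, attended

    def __call__(self, h: Tensor):
        """h: (B, L) -> (scores (B,), attentions (B, k, L))."""
        a, attended = self.attend(h)
        B, L = h.shape
        scores = self.out(attended.reshape(B, self.k * L)).reshape(B)
        return scores, a


# ---------------------------------------------------------------------------
# functional wrappers over single examples
# ---------------------------------------------------------------------------


def fuse(h_hm: np.ndarray, h_me: np.ndarray, h_tf: np.ndarray,
         k: int = 4, block: MultiAttentionBlock | None = None,
         seed: int = 0) -> FusedLatent:
    """Concatenate the three latent vectors and apply the k attention heads."""
    h = np.concatenate([np.asarray(h_hm), np.asarray(h_me), np.asarray(h_tf)])
    if block is None:
        block = MultiAttentionBlock(h.size, k, np.random.default_rng(seed))
    if block.in_dim != h.size:
        raise ValueError(f"block expects dim {block.in_dim}, got {h.size}")
    a, attended = block.attend(Tensor(h[None]))
    return FusedLatent(h=h, block_attentions=a.data[0].copy(),
                       attended=attended.data[0].copy())


def predict(fused: FusedLatent, block: MultiAttentionBlock) -> Prediction:
    """Score the attended copies with the output layer; label = +1 iff score > 0."""
    flat = Tensor(fused.attended.reshape(1, -1))
    score = float(block.out(flat).data[0, 0])
    return Prediction(score=score, label=1 if score > 0 else -1)


def omics_block_importance(block_attentions: np.ndarray,
                           block_sizes: dict[str, int]) -> dict[str, float]:
    """Per-omics importance from fusion attention weights.

    ``block_attentions``: (..., k, L) attention rows (any leading axes are
    averaged, e.g. genes); ``block_sizes`` maps omics name -> its latent
    width, in concatenation order.  Importance is the mean attention mass
    on the omics' coordinate range, averaged over heads, divided by the
    block size (mean-per-dimension mass) and normalized to sum to 1.
    """
    a = np.asarray(block_attentions)
    L = a.shape[-1]
    if sum(block_sizes.values()) != L:
        raise ValueError("block sizes must sum to the attention length")
    mean_row = a.reshape(-1, L).mean(axis=0)  # average over genes and heads
    lo = 0
    per_dim = {}
    for name, size in block_sizes.items():
        per_dim[name] = mean_row[lo : lo + size].sum() / size
        lo += size
    total = sum(per_dim.values())
    if total == 0:
        return {name: 0.0 for name in per_dim}
    return {name: float(v / total) for name, v in per_dim.items()}
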