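"""Self-attention and collaborative (cross-phase) attention blocks.

Both blocks act on a flattened 3D feature map ``x`` of shape (B, C, N) with
N = D*H*W spatial positions.  Queries/keys are 1x1x1 (pointwise) projections
to a small key dimension, values a pointwise C -> C projection; attention is
the row-softmax of the scaled query-key scores, so every attention row sums
to one and coefficients lie in (0, 1).  The attended value sum enters through
a residual gate ``y = x + gamma * attend(x)`` with ``gamma`` a learnable
scalar; at ``gamma = 0`` the block is an exact identity, which stabilizes
early training and makes the block's contribution testable.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .autodiff import Tensor, softmax
from .layers import DTYPE, Module, _he_init


@dataclasses.dataclass
class AttentionBlockOutput:
    """Attended feature map plus the row-stochastic attention coefficients."""

    features: Tensor  # (B, C, N), same shape as input
    attention: Tensor  # (B, N, N), rows sum to 1


def _check_finite(x: Tensor, name: str) -> None:
    if not np.isfinite(x.data).all():
        raise ValueError(f"non-finite values in {name} input to attention block")


class _QKVProjections(Module):
    def __init__(self, channels: int, d_qk: int, rng: np.random.Generator, gamma_init: float):
        super().__init__()
        self.d_qk = d_qk
        self.wq = Tensor(_he_init(rng, (channels, d_qk), channels), requires_grad=True)
        self.wk = Tensor(_he_init(rng, (channels, d_qk), channels), requires_grad=True)
        self.wv = Tensor(_he_init(rng, (channels, channels), channels), requires_grad=True)
        self.gamma = Tensor(np.asarray(float(gamma_init), dtype=DTYPE), requires_grad=True)

    def qkv(self, x_t: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        return x_t @ self.wq, x_t @ self.wk, x_t @ self.wv


class SelfAttention3d(_QKVProjections):
    """Intra-phase attention: positions of one phase attend to each other."""

    def __call__(self, x: Tensor) -> AttentionBlockOutput:
        _check_finite(x, "self-attention")
        x_t = x.transpose(0, 2, 1)  # (B, N, C)
        q, k, v = self.qkv(x_t)
        scores = (q @ k.transpose(0, 2, 1)) / math.sqrt(self.d_qk)
        attn = softmax(scores, axis=-1)
        out = (attn @ v).transpose(0, 2, 1)  # back to (B, C, N)
        y = x + self.gamma * out
        return AttentionBlockOutput(features=y, attention=attn)


class CollaborativeAttention3d(_QKVProjections):
    """Inter-phase attention: one phase's queries against the other phases.

    Keys and values come from each other phase in turn; the per-pair attended
    outputs are averaged and residual-added to the phase's own map.  The
    reported attention matrix is the mean of the pair matrices (still
    row-stochastic).
    """

    def __call__(self, own: Tensor, others: Sequence[Tensor]) -> AttentionBlockOutput:
        if len(others) == 0:
            raise ValueError("collaborative attention needs at least one other phase")
        for o in others:
            if o.data.shape != own.data.shape:
                raise ValueError(f"phase feature shape mismatch: {o.data.shape} vs {own.data.shape}")
        _check_finite(own, "collaborative-attention")
        own_t = own.transpose(0, 2, 1)
        q = own_t @ self.wq
        outs, attns = [], []
        for other in others:
            _check_finite(other, "collaborative-attention")
            o_t = other.transpose(0, 2, 1)
            k = o_t @ self.wk
            v = o_t @ self.wv
            attn = softmax((q @ k.transpose(0, 2, 1)) / math.sqrt(self.d_qk), axis=-1)
            attns.append(attn)
            outs.append(attn @ v)
        inv = 1.0 / len(others)
        mean_out = outs[0] * inv
        mean_attn = attns[0] * inv
        for o, a in zip(outs[1:], attns[1:]):
            mean_out = mean_out + o * inv
            mean_attn = mean_attn + a * inv
        y = own + self.gamma * mean_out.transpose(0, 2, 1)
        return AttentionBlockOutput(features=y, attention=mean_attn)
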