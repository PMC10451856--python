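"""Deterministic micro-fixtures for fast, training-free verification.

Every fixture is regenerated from code (integer or fixed-constant
arithmetic), never stored, so it is bit-identical across runs and platforms.
The toy attention fixture hand-computes the expected softmax attention matrix
and block output with plain ``math`` arithmetic, independent of the network
code, and serves as the oracle in attention tests.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Any, Callable

import numpy as np


@dataclasses.dataclass
class Fixture:
    name: str
    params: dict[str, Any]
    data: dict[str, Any]
    expected: dict[str, Any]


def fixture_augmentation_counts() -> Fixture:
    """A 32^3 ramp cube and the sliding-cut count law for three geometries."""
    side = 32
    cube = np.arange(side**3, dtype=np.float64).reshape(side, side, side)

    def count(resample: int, cut: int, stride: int) -> int:
        return (math.floor((resample - cut) / stride) + 1) ** 3

    return Fixture(
        name="augmentation_counts",
        params={"resample": 32, "cut": 16},
        data={"cube": cube},
        expected={
            "per_axis_stride2": 9,
            "total_stride2": count(32, 16, 2),  # 729
            "total_stride4": count(32, 16, 4),  # 125
            "total_cut32": count(32, 32, 2),  # 1 (identity cut)
        },
    )


def fixture_toy_attention() -> Fixture:
    """N=2, C=1 attention toy with hand-set projections and exact expectations.

    x = (x1, x2); q_i = a*x_i, k_j = b*x_j, v_j = c*x_j; score s_ij =
    q_i*k_j / sqrt(1); A_ij = softmax over j; out_i = sum_j A_ij v_j;
    y_i = x_i + gamma*out_i.
    """
    x1, x2 = 1.0, -1.0
    a, b, c, gamma = 0.7, 0.5, 1.3, 0.9

    def row(i_val: float) -> tuple[float, float]:
        s1 = (a * i_val) * (b * x1)
        s2 = (a * i_val) * (b * x2)
        m = max(s1, s2)
        e1, e2 = math.exp(s1 - m), math.exp(s2 - m)
        z = e1 + e2
        return e1 / z, e2 / z

    attn = [row(x1), row(x2)]
    out = [attn[i][0] * c * x1 + attn[i][1] * c * x2 for i in range(2)]
    y = [x1 + gamma * out[0], x2 + gamma * out[1]]
    return Fixture(
        name="toy_attention",
        params={"wq": a, "wk": b, "wv": c, "gamma": gamma},
        data={"x": np.array([[[x1, x2]]])},  # (B=1, C=1, N=2)
        expected={"attention": np.array(attn), "output": np.array([[y]])[0]},
    )


REGISTRY: dict[str, Callable[[], Fixture]] = {
    "augmentation_counts": fixture_augmentation_counts,
    "toy_attention": fixture_toy_attention,
}


def get_fixture(name: str) -> Fixture:
    return REGISTRY[name]()
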