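"""Inference cost model: feature extraction vs a single 1-D convolution layer.

At test time the stored projection maps a beat of ``n`` samples to its
features in ``n * C * max_c(q_c)`` multiply-accumulate operations (``C``
classes, ``q_c`` components per class).  A 1-D convolution layer that keeps
the feature-map size costs ``Ch_in * Ch_out * k * D_f`` (bias omitted).  One
multiply-accumulate counts as one operation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence


def feature_op_count(n: int, C: int, q: Sequence[int]) -> int:
    """Operations for one beat's full feature vector: ``n * C * max(q)``."""
    if n < 1 or C < 1:
        raise ValueError("n and C must be >= 1")
    q = list(q)
    if not q:
        raise ValueError("q must be nonempty")
    if any(v < 0 for v in q):
        raise ValueError("component counts must be nonnegative")
    return int(n) * int(C) * int(max(q))


def conv1d_op_count(ch_in: int, ch_out: int, k: int, d_f: int) -> int:
    """Operations for one size-preserving 1-D convolution layer."""
    if min(ch_in, ch_out, k, d_f) < 1:
        raise ValueError("all convolution parameters must be >= 1")
    return int(ch_in) * int(ch_out) * int(k) * int(d_f)


@dataclass
class CostEstimate:
    """Side-by-side operation counts for the two inference paths."""

    n: int
    C: int
    q: tuple[int, ...]
    ch_in: int
    ch_out: int
    k: int
    d_f: int

    @property
    def feature_ops(self) -> int:
        return feature_op_count(self.n, self.C, self.q)

    @property
    def conv_ops(self) -> int:
        return conv1d_op_count(self.ch_in, self.ch_out, self.k, self.d_f)

    @property
    def cheaper(self) -> bool:
        return cheaper_than_conv(self)


def cheaper_than_conv(cost: CostEstimate) -> bool:
    """Strict inequality: fewer operations than the single conv layer."""
    return cost.feature_ops < cost.conv_ops
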