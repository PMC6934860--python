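"""Mask evaluation metrics."""

from __future__ import annotations

import numpy as np

from ..containers import SegMask


def dice(a: SegMask | np.ndarray, b: SegMask | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks score 1.0."""
    pa = a.pixels if isinstance(a, SegMask) else np.asarray(a)
    pb = b.pixels if isinstance(b, SegMask) else np.asarray(b)
    if pa.shape != pb.shape:
        raise ValueError("mask shapes differ")
    pa = pa.astype(bool)
    pb = pb.astype(bool)
    denom = pa.sum() + pb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pa, pb).sum() / denom)
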