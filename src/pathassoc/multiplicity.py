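"""Benjamini-Hochberg step-up FDR adjustment.

Supports an externally specified total test count ``m`` larger than the
number of supplied p-values, for the common reporting situation where only
the top k hits of an m-test scan are listed: the caller asserts the supplied
values are the k smallest of the m, and the step-up ranks run 1..k against
denominator weights m/j.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["bh_adjust"]


def bh_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """BH-adjusted p-values (q-values), returned in the input order.

    ``q_(i) = min_{i <= j <= k} min(1, m * p_(j) / j)`` over the ascending
    order statistics, with ``m`` defaulting to ``k = len(p_values)``.
    """
    p = np.asarray(p_values, dtype=float)
    k = p.size
    if k == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = k if m is None else int(m)
    if m < k:
        raise ValueError(f"total test count m={m} smaller than number of p-values k={k}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(k)
    q[order] = q_sorted
    return q
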