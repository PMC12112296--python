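"""Small shared descriptive-statistics helpers."""

from __future__ import annotations

import numpy as np


def proportion_pct(numerator: float, denominator: float, decimals: int = 2) -> float:
    """Percentage ``100 * numerator / denominator`` rounded for display.

    The single routine behind every reported percentage, so printed tables
    and headline ratios share one rounding convention.
    """
    if denominator == 0:
        return float("nan")
    return round(100.0 * numerator / denominator, decimals)


def median_and_hinges(values) -> tuple[float, float, float]:
    """Median and lower/upper hinges of a sample.

    The median of an even-sized sample is the midpoint of the two central
    order statistics.  Hinges are the medians of the lower and upper halves,
    excluding the overall median from both halves when n is odd (the
    median-exclusive convention; identical to fourths for even n).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    med = float(np.median(x))
    half = n // 2
    lower = x[:half]
    upper = x[n - half:]
    if half == 0:  # n == 1
        return med, med, med
    return float(np.median(lower)), med, float(np.median(upper))
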