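"""Histogram auto-thresholding: iterative intermeans (IsoData), its classic
trimmed variant ("Default"), and Kapur's two-class maximum-entropy split.

All three operate on a 256-bin intensity histogram and return an integer
threshold ``t`` in [0, 255] under one fixed convention: pixels with
intensity strictly greater than ``t`` are "positive".

IsoData seeks a fixed point of

    t_{k+1} = round( (mu_below(t_k) + mu_above(t_k)) / 2 )

where mu_below is the mean intensity of bins <= t and mu_above of bins > t.
The "Default" variant first zeroes the extreme bins 0 and 255 (the classic
guard against erased/saturated areas) and then runs the same iteration on
the trimmed histogram.  Kapur's method maximizes the sum of the Shannon
entropies (natural log) of the two class-conditional distributions over all
splits that leave both classes with positive probability; ties break toward
the smallest threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateHistogramError

__all__ = [
    "ThresholdResult",
    "histogram_from_image",
    "threshold_isodata",
    "threshold_default",
    "threshold_maxentropy",
    "THRESHOLD_ALGORITHMS",
]


@dataclass(frozen=True)
class ThresholdResult:
    """An integer threshold plus the algorithm that produced it.

    Pixels with intensity > ``threshold`` are positive.
    """

    threshold: int
    algorithm: str
    iterations: int | None = None


def histogram_from_image(image: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """256-bin intensity histogram of an 8-bit image, optionally ROI-masked."""
    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise ValueError("expected an 8-bit (uint8) image")
    values = img[np.asarray(mask, dtype=bool)] if mask is not None else img.ravel()
    return np.bincount(values, minlength=256).astype(np.int64)


def _validate(counts: np.ndarray) -> np.ndarray:
    h = np.asarray(counts, dtype=np.float64)
    if h.shape != (256,) or np.any(h < 0):
        raise ValueError("histogram must be 256 non-negative counts")
    if np.count_nonzero(h) < 2:
        raise DegenerateHistogramError(
            "degenerate histogram: mass in fewer than 2 distinct bins"
        )
    return h


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _intermeans_fixed_point(h: np.ndarray, algorithm: str) -> ThresholdResult:
    bins = np.arange(256, dtype=np.float64)
    occupied = np.nonzero(h)[0]
    lo, hi = int(occupied[0]), int(occupied[-1])
    csum = np.cumsum(h)
    cmoment = np.cumsum(h * bins)
    total, total_m = csum[-1], cmoment[-1]

    def update(t: int) -> int:
        mu_below = cmoment[t] / csum[t]
        mu_above = (total_m - cmoment[t]) / (total - csum[t])
        return _round_half_up((mu_below + mu_above) / 2.0)

    # start at the midpoint of occupied support, kept inside [lo, hi-1] so
    # both classes are non-empty throughout
    t = min(max((lo + hi) // 2, lo), hi - 1)
    prev: int | None = None
    iterations = 0
    for iterations in range(1, 257):
        t_new = min(max(update(t), lo), hi - 1)
        if t_new == t:
            break
        if prev is not None and t_new == prev:  # period-2 cycle: take smaller
            t = min(t, t_new)
            break
        prev, t = t, t_new
    return ThresholdResult(threshold=int(t), algorithm=algorithm, iterations=iterations)


def threshold_isodata(counts: np.ndarray) -> ThresholdResult:
    """Iterative intermeans (IsoData/Ridler-Calvard) threshold."""
    h = _validate(counts)
    return _intermeans_fixed_point(h, "IsoData")


def threshold_default(counts: np.ndarray) -> ThresholdResult:
    """Classic trimmed intermeans ("Default") threshold.

    Bins 0 and 255 are zeroed before iterating, so saturated or erased
    areas cannot drag the class means; on histograms with empty extreme
    bins this coincides with plain IsoData.  If trimming empties the
    histogram (all mass at 0 and/or 255) the midpoint 128 is returned,
    matching the classic fallback.
    """
    h = _validate(counts)
    trimmed = h.copy()
    trimmed[0] = 0.0
    trimmed[255] = 0.0
    n_left = np.count_nonzero(trimmed)
    if n_left == 0:
        # all mass sat at the extremes: classic midpoint fallback
        return ThresholdResult(threshold=128, algorithm="Default", iterations=0)
    if n_left == 1:
        raise DegenerateHistogramError("degenerate histogram after end-bin trimming")
    return _intermeans_fixed_point(trimmed, "Default")


def threshold_maxentropy(counts: np.ndarray) -> ThresholdResult:
    """Kapur's maximum-entropy threshold (natural-log entropies).

    Maximizes H_below(t) + H_above(t) where H_below is the entropy of the
    class-conditional distribution over bins <= t and H_above over bins > t.
    Zero-probability bins contribute nothing; candidate splits must leave
    both classes positive probability; ties break toward the smallest t.
    """
    h = _validate(counts)
    p = h / h.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    P = np.cumsum(p)  # P[t] = class probability of bins <= t
    S = np.cumsum(plogp)
    occupied = np.nonzero(h)[0]
    lo, hi = int(occupied[0]), int(occupied[-1])
    ts = np.arange(lo, hi)  # splits with both classes non-empty
    P_b = P[ts]
    P_a = 1.0 - P_b
    # H_class = ln(P) - S_class / P  (from -sum (p/P) ln(p/P))
    H_b = np.log(P_b) - S[ts] / P_b
    H_a = np.log(P_a) - (S[255] - S[ts]) / P_a
    total = H_b + H_a
    t = int(ts[int(np.argmax(total))])  # argmax takes first (smallest) maximizer
    return ThresholdResult(threshold=t, algorithm="MaxEntropy")


THRESHOLD_ALGORITHMS = {
    "IsoData": threshold_isodata,
    "Default": threshold_default,
    "MaxEntropy": threshold_maxentropy,
}
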