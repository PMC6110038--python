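"""Histograms, entropy, and entropy-balanced four-way segmentation.

A gray-level histogram is split into two subhistograms of (nearly) equal
Shannon entropy by the *half-entropy threshold*: the smallest level at which
the cumulative per-bin entropy reaches half the interval's total entropy.
Applying the rule once to the occupied range and once to each half yields
three thresholds and four entropy-balanced segments — the entry point of the
EASHE pipeline.

All entropies are in bits (log base 2) with the convention ``0·log 0 = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import L


class DegenerateHistogramError(Exception):
    """An intensity interval carries too little structure to be split.

    Raised when an operation needs positive entropy (or positive mass) on an
    interval that has none.  The top-level pipeline catches this and falls
    back to the identity mapping rather than failing.
    """


@dataclass(frozen=True)
class Histogram:
    """Per-level pixel counts with the occupied-range bounds.

    Attributes
    ----------
    counts : ndarray of int, shape (256,)
        Number of pixels at each gray level.
    total : int
        Total pixel count (``counts.sum()``).
    k_l, k_u : int
        Lowest and highest occupied gray levels.
    """

    counts: np.ndarray
    total: int
    k_l: int
    k_u: int


@dataclass(frozen=True)
class Segmentation:
    """Three entropy thresholds and the four-segment partition they induce.

    ``boundaries = (m0, m1, m2, m3, m4)`` delimit input segments
    ``[m0, m1], [m1+1, m2], [m2+1, m3], [m3+1, m4]``; ``segment_entropies``
    are their entropies in bits.  ``degenerate`` is set instead of raising
    when fewer than four non-empty segments can be formed.
    """

    thresholds: tuple[int, int, int]
    boundaries: tuple[int, int, int, int, int]
    segment_entropies: tuple[float, float, float, float]
    degenerate: bool

    @property
    def segment_bounds(self) -> tuple[tuple[int, int], ...]:
        """Input index ranges ``(a_r, b_r)`` of the four segments."""
        m0, m1, m2, m3, m4 = self.boundaries
        return ((m0, m1), (m1 + 1, m2), (m2 + 1, m3), (m3 + 1, m4))


def compute_histogram(image, channel_policy: str = "gray") -> Histogram:
    """Build the 256-bin histogram of an 8-bit image.

    Parameters
    ----------
    image : array_like
        ``(H, W)`` grayscale or ``(H, W, 3)`` RGB array of integers in
        ``[0, 255]``.
    channel_policy : {"gray", "value_channel"}
        For RGB input only ``"value_channel"`` is valid: the per-pixel
        maximum of R, G, B (the HSV value channel) is histogrammed.
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 3 and arr.shape[2] == 3:
        if channel_policy != "value_channel":
            raise ValueError(
                "RGB input requires channel_policy='value_channel'"
            )
        arr = arr.max(axis=2)
    elif arr.ndim != 2:
        raise ValueError(f"expected 2-D gray or (H, W, 3) RGB image, got shape {arr.shape}")
    flat = arr.ravel()
    if flat.min() < 0 or flat.max() > 255:
        raise ValueError("pixel values must lie in [0, 255]")
    counts = np.bincount(flat.astype(np.int64), minlength=L)
    occupied = np.flatnonzero(counts)
    return Histogram(
        counts=counts,
        total=int(counts.sum()),
        k_l=int(occupied[0]),
        k_u=int(occupied[-1]),
    )


def to_pdf(hist: Histogram) -> np.ndarray:
    """Normalize a histogram to a probability density over the 256 levels."""
    if hist.total <= 0:
        raise ValueError("histogram has zero total count")
    return hist.counts.astype(np.float64) / hist.total


def bin_entropies(pdf: np.ndarray) -> np.ndarray:
    """Per-bin entropy contributions ``-p·log2 p`` (0 where p = 0)."""
    p = np.asarray(pdf, dtype=np.float64)
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = -p[pos] * np.log2(p[pos])
    return out


def entropy(pdf: np.ndarray, lo: int = 0, hi: int = L - 1) -> float:
    """Shannon entropy of ``pdf`` restricted to levels ``[lo, hi]``, in bits."""
    if not 0 <= lo <= hi <= L - 1:
        raise ValueError(f"invalid interval [{lo}, {hi}]")
    return float(bin_entropies(pdf)[lo : hi + 1].sum())


def half_entropy_threshold(pdf: np.ndarray, lo: int, hi: int) -> int:
    """Smallest level splitting ``[lo, hi]`` at half its cumulative entropy.

    Returns the smallest ``k`` in ``[lo, hi-1]`` such that the entropy of
    ``[lo, k]`` is at least half the entropy of ``[lo, hi]``.  The half-way
    point generally falls between integer levels, so the lower side overshoots
    by at most the entropy contribution of bin ``k``.  The result is clamped
    to ``hi - 1`` so both sides are non-empty index ranges.
    """
    if hi <= lo:
        raise ValueError(f"need hi > lo, got [{lo}, {hi}]")
    e = bin_entropies(pdf)[lo : hi + 1]
    total = e.sum()
    if total <= 0.0:
        raise DegenerateHistogramError(
            f"zero entropy on [{lo}, {hi}]: nothing to split"
        )
    cum = np.cumsum(e)
    k = lo + int(np.argmax(cum >= total / 2.0))
    return min(k, hi - 1)


def segment_histogram(pdf: np.ndarray, k_l: int, k_u: int) -> Segmentation:
    """Partition the occupied range into four entropy-balanced segments.

    The half-entropy rule is applied to ``[k_l, k_u]`` giving the middle
    threshold, then recursively to the lower half (including its boundary)
    and to the upper half, giving the outer thresholds.  Degeneracy — zero
    entropy anywhere, or an interval too short to split — sets the
    ``degenerate`` flag rather than raising, so callers can fall back to an
    identity mapping.
    """
    try:
        ks2 = half_entropy_threshold(pdf, k_l, k_u)
        ks1 = half_entropy_threshold(pdf, k_l, ks2)
        ks3 = half_entropy_threshold(pdf, ks2 + 1, k_u)
    except (ValueError, DegenerateHistogramError):
        return Segmentation(
            thresholds=(k_l, k_l, k_l),
            boundaries=(k_l, k_l, k_l, k_l, k_u),
            segment_entropies=(0.0, 0.0, 0.0, 0.0),
            degenerate=True,
        )
    boundaries = (k_l, ks1, ks2, ks3, k_u)
    seg_entropies = (
        entropy(pdf, k_l, ks1),
        entropy(pdf, ks1 + 1, ks2),
        entropy(pdf, ks2 + 1, ks3),
        entropy(pdf, ks3 + 1, k_u),
    )
    return Segmentation(
        thresholds=(ks1, ks2, ks3),
        boundaries=boundaries,
        segment_entropies=seg_entropies,
        degenerate=False,
    )
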