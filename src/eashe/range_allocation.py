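"""Dynamic-range reallocation of the four subhistograms.

Equalizing each subhistogram strictly within its input boundaries keeps the
flaws of the input layout: narrow segments saturate, wide sparse ones expand
unevenly.  Each segment's output width is therefore blended between its
input span and the uniform share ``L / N_subs = 64`` with a weight derived
from the segment's entropy — low-entropy (detail-poor) segments are pulled
strongly toward the uniform share, high-entropy ones keep their span.  The
input histogram is then remapped level-by-level onto the new ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

from ._util import L, round_half_away
from .histogram_core import DegenerateHistogramError, Segmentation, entropy

N_SUBS = 4

WeightHook = Union[str, Callable[[float], float]]


def _weight_reciprocal_clamped(e_r: float) -> float:
    """Reciprocal-entropy weight clamped to [0, 1]; 1 for zero entropy."""
    if e_r <= 0.0:
        return 1.0
    return min(1.0, 1.0 / e_r)


def _weight_normalized_entropy(e_r: float) -> float:
    # complement of entropy relative to the 8-bit maximum
    return min(1.0, max(0.0, 1.0 - e_r / 8.0))


def _weight_uniform(e_r: float) -> float:
    return 1.0


_WEIGHT_HOOKS = {
    "reciprocal_clamped": _weight_reciprocal_clamped,
    "normalized_entropy": _weight_normalized_entropy,
    "uniform": _weight_uniform,
}


@dataclass(frozen=True)
class RangeAllocation:
    """Input spans, blended widths and output boundaries of the 4 segments.

    ``out_bounds`` are inclusive output intervals ``(l_r, u_r)`` that tile
    ``[0, 255]`` without gap or overlap: ``l_1 = 0``, ``l_{r+1} = u_r + 1``,
    ``u_4 = 255`` and ``u_r - l_r = range_r >= 1``.
    """

    spans: tuple[int, int, int, int]
    aspans: tuple[float, float, float, float]
    ranges: tuple[int, int, int, int]
    out_bounds: tuple[tuple[int, int], ...]
    n_subs: int = N_SUBS


@dataclass(frozen=True)
class AdjustedPDF:
    """The input PDF transported onto the reallocated dynamic range.

    Attributes
    ----------
    p_adj : ndarray, shape (256,)
        Probability mass at each output level; sums to 1.
    remap : ndarray of int, shape (256,)
        Output level for each occupied input level, -1 elsewhere.
        Non-decreasing on occupied levels.
    e_adj : float
        Total entropy of ``p_adj`` in bits.
    """

    p_adj: np.ndarray
    remap: np.ndarray
    e_adj: float


def allocate_ranges(
    seg: Segmentation,
    total_levels: int = L,
    weight: WeightHook = "reciprocal_clamped",
) -> RangeAllocation:
    """Blend each segment's span toward the uniform share and integerize.

    For segment ``r`` with boundaries ``m_{r-1}, m_r`` and entropy ``E_r``:

    - ``span_r = m_r - m_{r-1}`` (input width),
    - ``aspan_r = span_r + w(E_r) · (L/N_subs - span_r)`` with the weight
      ``w(E) = clamp(1/E, 0, 1)`` by default (``w = 1`` at zero entropy),
    - real output widths are ``aspan_r / Σ aspan · (L - N_subs)``, rounded
      by the largest-remainder method to integers summing to ``L - N_subs``
      with a minimum width of 1 (deficit taken from the largest width,
      lower index first on ties).

    The ``weight`` hook may be one of ``"reciprocal_clamped"``,
    ``"normalized_entropy"``, ``"uniform"`` or any callable ``E -> w``.
    """
    if seg.degenerate:
        raise DegenerateHistogramError("cannot allocate ranges for a degenerate segmentation")
    if total_levels != L:
        raise ValueError("only 8-bit images (256 levels) are supported")
    w_fn = _WEIGHT_HOOKS[weight] if isinstance(weight, str) else weight

    m = seg.boundaries
    spans = tuple(int(m[r] - m[r - 1]) for r in range(1, 5))
    share = L / N_SUBS
    aspans = tuple(
        span + w_fn(e_r) * (share - span)
        for span, e_r in zip(spans, seg.segment_entropies)
    )

    budget = L - N_SUBS  # 252: each segment also consumes one level for its lower bound
    rho = np.array(aspans, dtype=np.float64)
    rho = rho / rho.sum() * budget
    ranges = np.floor(rho).astype(np.int64)
    frac = rho - ranges
    # largest-remainder distribution of the leftover levels, lower index on ties
    leftover = budget - int(ranges.sum())
    order = np.argsort(-frac, kind="stable")
    ranges[order[:leftover]] += 1
    # enforce the minimum width of 1, taking the deficit from the largest
    while (ranges < 1).any():
        i = int(np.argmax(ranges < 1))
        ranges[int(np.argmax(ranges))] -= 1 - ranges[i]
        ranges[i] = 1

    out_bounds = []
    lo = 0
    for r in range(N_SUBS):
        hi = lo + int(ranges[r])
        out_bounds.append((lo, hi))
        lo = hi + 1
    return RangeAllocation(
        spans=spans,
        aspans=tuple(float(a) for a in aspans),
        ranges=tuple(int(r) for r in ranges),
        out_bounds=tuple(out_bounds),
    )


def remap_pdf(
    pdf: np.ndarray, seg: Segmentation, alloc: RangeAllocation
) -> AdjustedPDF:
    """Transport the input PDF onto the reallocated output ranges.

    Each occupied input level ``k`` in input segment ``r`` (input range
    ``[a_r, b_r]``, output range ``[l_r, u_r]``) moves to

    ``k' = round(l_r + (k - a_r) / max(b_r - a_r, 1) · range_r)``

    with round-half-away-from-zero.  Probability mass follows the levels;
    collisions sum, so total mass is conserved exactly up to float addition.
    """
    p = np.asarray(pdf, dtype=np.float64)
    p_adj = np.zeros(L)
    remap = np.full(L, -1, dtype=np.int64)
    for (a, b), (lo, hi) in zip(seg.segment_bounds, alloc.out_bounds):
        rng_out = hi - lo
        width = max(b - a, 1)
        ks = np.arange(a, b + 1)
        occ = ks[p[a : b + 1] > 0]
        if occ.size == 0:
            continue
        kp = (round_half_away(lo + (occ - a) / width * rng_out)).astype(np.int64)
        remap[occ] = kp
        np.add.at(p_adj, kp, p[occ])
    e_adj = entropy(p_adj, 0, L - 1)
    return AdjustedPDF(p_adj=p_adj, remap=remap, e_adj=e_adj)
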