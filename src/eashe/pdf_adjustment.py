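"""Adaptive reshaping of the range-adjusted PDF.

Plain equalization lets high-probability bins dominate the transfer function
(saturation) while a purely flat target erases contrast differences.  Here
the range-adjusted PDF is split once at its half-entropy level and each side
is pulled quadratically toward the midpoint of its own extreme densities:

- a bin below the midpoint moves up:   ``m - α (m - p)² / (m - p_min)``
- a bin above the midpoint moves down: ``m + α (p - m)² / (p_max - m)``

where ``m = (p_max + p_min) / 2`` over the side's occupied bins.  The control
factor ``α ∈ [0, 1]`` is data-derived from the asymmetry of the gray-level
means on the two sides: ``α = 0`` flattens the side completely (a near-linear
stretch), ``α = 1`` leaves the extremes fixed (full equalization behaviour).
The reshaped weights are then accumulated and normalized into a CDF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import L
from .histogram_core import DegenerateHistogramError, half_entropy_threshold
from .range_allocation import AdjustedPDF


@dataclass(frozen=True)
class SideStats:
    """Split level, side means, per-side density extremes and control factors.

    ``low``/``high`` extremes are ``(pdf_max, pdf_min, pdf_avgmm)`` taken over
    the side's *occupied* bins (``p_adj > 0``); ``pdf_avgmm`` is the midpoint
    ``(pdf_max + pdf_min) / 2``.  ``alpha_low`` applies to levels
    ``k <= i_ks``, ``alpha_high`` to ``k > i_ks``; both lie in ``[0, 1]``
    and sum to 1 before clamping.
    """

    i_ks: int
    i_avg_low: float
    i_avg_high: float
    low_extremes: tuple[float, float, float]
    high_extremes: tuple[float, float, float]
    alpha_low: float
    alpha_high: float


def split_adjusted(adj: AdjustedPDF) -> int:
    """Half-entropy split level of the range-adjusted PDF over [0, 255]."""
    if adj.e_adj <= 0.0:
        raise DegenerateHistogramError("adjusted PDF has zero entropy")
    return half_entropy_threshold(adj.p_adj, 0, L - 1)


def side_means(adj: AdjustedPDF, i_ks: int) -> tuple[float, float]:
    """Mean gray level on each side of the split (conditional means).

    Returns ``(I_avgsub1, I_avgsub2)`` with ``I_avgsub1`` the mass-weighted
    mean level over ``[0, i_ks]`` and ``I_avgsub2`` over ``[i_ks+1, 255]``.
    """
    p = adj.p_adj
    k = np.arange(L, dtype=np.float64)
    mass_lo = p[: i_ks + 1].sum()
    mass_hi = p[i_ks + 1 :].sum()
    if mass_lo <= 0.0 or mass_hi <= 0.0:
        raise DegenerateHistogramError("a side of the split carries no probability mass")
    avg_lo = float((k[: i_ks + 1] * p[: i_ks + 1]).sum() / mass_lo)
    avg_hi = float((k[i_ks + 1 :] * p[i_ks + 1 :]).sum() / mass_hi)
    return avg_lo, avg_hi


def control_factor(
    i_ks: int, i_avg_low: float, i_avg_high: float
) -> tuple[float, float]:
    """Adaptive enhancement-strength factors for the two sides.

    ``alpha_low = (i_ks - I_avgsub1) / (I_avgsub2 - I_avgsub1)`` and
    ``alpha_high = (I_avgsub2 - i_ks) / (I_avgsub2 - I_avgsub1)``, each
    clamped to ``[0, 1]``.  A side whose mean sits close to the split level
    gets a small α (strong flattening); the complementary side gets the
    rest.  Equal side means degenerate to ``(0, 0)`` — no reshaping.
    """
    denom = i_avg_high - i_avg_low
    if denom <= 0.0:
        return 0.0, 0.0
    a_low = (i_ks - i_avg_low) / denom
    a_high = (i_avg_high - i_ks) / denom
    clamp = lambda a: min(1.0, max(0.0, a))
    return clamp(a_low), clamp(a_high)


def _side_extremes(p: np.ndarray, lo: int, hi: int):
    occ = p[lo : hi + 1][p[lo : hi + 1] > 0]
    if occ.size == 0:
        return 0.0, 0.0, 0.0
    pmax = float(occ.max())
    pmin = float(occ.min())
    return pmax, pmin, (pmax + pmin) / 2.0


def compute_side_stats(
    adj: AdjustedPDF, alpha_override: tuple[float, float] | None = None
) -> SideStats:
    """Split the adjusted PDF and gather everything the reshaping needs.

    ``alpha_override`` replaces the data-derived control factors with fixed
    values (debugging aid; not part of the standard pipeline).
    """
    i_ks = split_adjusted(adj)
    avg_lo, avg_hi = side_means(adj, i_ks)
    if alpha_override is not None:
        a_low, a_high = alpha_override
    else:
        a_low, a_high = control_factor(i_ks, avg_lo, avg_hi)
    return SideStats(
        i_ks=i_ks,
        i_avg_low=avg_lo,
        i_avg_high=avg_hi,
        low_extremes=_side_extremes(adj.p_adj, 0, i_ks),
        high_extremes=_side_extremes(adj.p_adj, i_ks + 1, L - 1),
        alpha_low=a_low,
        alpha_high=a_high,
    )


def adjust_pdf(adj: AdjustedPDF, stats: SideStats) -> np.ndarray:
    """Pull each side's occupied bins quadratically toward its midpoint.

    Returns the modified per-level weights (not renormalized; the subsequent
    CDF normalization absorbs the change of total mass).  Unoccupied bins
    stay at zero — no mass is invented at levels absent from the image.  A
    side whose occupied bins all share one density is copied unchanged.
    """
    p = adj.p_adj
    p_mod = p.copy()
    sides = (
        (0, stats.i_ks, stats.alpha_low, stats.low_extremes),
        (stats.i_ks + 1, L - 1, stats.alpha_high, stats.high_extremes),
    )
    for lo, hi, alpha, (pmax, pmin, avgmm) in sides:
        if pmax <= pmin:  # constant or empty side: nothing to reshape
            continue
        sl = slice(lo, hi + 1)
        ps = p[sl]
        out = p_mod[sl]
        below = (ps > 0) & (ps < avgmm)
        above = ps > avgmm
        out[below] = avgmm - alpha * (avgmm - ps[below]) ** 2 / (avgmm - pmin)
        out[above] = avgmm + alpha * (ps[above] - avgmm) ** 2 / (pmax - avgmm)
    return p_mod


def normalized_cdf(p_mod: np.ndarray) -> np.ndarray:
    """Cumulative sum of the modified weights, normalized to end at 1."""
    total = float(np.sum(p_mod))
    if total <= 0.0:
        raise DegenerateHistogramError("modified PDF has zero total weight")
    c = np.cumsum(np.asarray(p_mod, dtype=np.float64)) / total
    # rounding can push interior entries a ulp past 1; keep c monotone with c[255] = 1
    np.minimum(c, 1.0, out=c)
    c[-1] = 1.0
    return c
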