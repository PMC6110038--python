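"""Transfer functions, lookup-table composition, and the full pipeline.

Each output segment is equalized independently: the normalized CDF is
re-normalized within the segment so its transfer function spans exactly the
segment's allocated range, and the enhanced image is the union of the four
independently equalized subimages.  A classical global histogram
equalization transfer is provided as the comparison baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._util import L, round_half_away
from .histogram_core import (
    DegenerateHistogramError,
    compute_histogram,
    segment_histogram,
    to_pdf,
)
from .pdf_adjustment import adjust_pdf, compute_side_stats, normalized_cdf
from .range_allocation import RangeAllocation, allocate_ranges, remap_pdf


@dataclass(frozen=True)
class EnhanceConfig:
    """Knobs of the enhancement pipeline.

    color_policy : {"value_channel", "per_channel", "luminance"}
        How RGB images are handled.  ``value_channel`` (default) enhances
        the per-pixel max of R, G, B and rescales the channels
        proportionally, preserving hue.  ``per_channel`` equalizes each
        channel independently.  ``luminance`` drives the scaling from the
        Rec. 601 luma instead of the value channel.
    weight_hook : {"reciprocal_clamped", "normalized_entropy", "uniform"}
        Entropy-to-blend-weight rule of the range allocation.
    emit_diagnostics : bool
        Attach thresholds, ranges and α values to the result.
    alpha_override : (float, float) or None
        Fixed control factors replacing the data-derived ones (debug only).
    """

    color_policy: str = "value_channel"
    weight_hook: str = "reciprocal_clamped"
    emit_diagnostics: bool = False
    alpha_override: tuple[float, float] | None = None


@dataclass
class EnhancementResult:
    """Enhanced image, the lookup table that produced it, and diagnostics."""

    image: np.ndarray
    lut: np.ndarray
    fallback: bool
    diagnostics: dict[str, Any] = field(default_factory=dict)


def classical_he_transfer(pdf: np.ndarray, k_lo: int = 0, k_hi: int = L - 1) -> np.ndarray:
    """Classical histogram-equalization transfer over ``[k_lo, k_hi]``.

    ``f[k] = round(k_lo + (k_hi - k_lo) · cdf(k))`` — the textbook CDF
    remapping, used as the built-in baseline for brightness-shift
    comparisons.
    """
    if k_hi < k_lo:
        raise ValueError("need k_hi >= k_lo")
    cdf = np.cumsum(np.asarray(pdf, dtype=np.float64))
    f = round_half_away(k_lo + (k_hi - k_lo) * cdf)
    return np.clip(f, 0, L - 1).astype(np.int64)


def segment_transfer(cdf: np.ndarray, alloc: RangeAllocation) -> np.ndarray:
    """Per-segment equalization transfer from the normalized CDF.

    Within each output segment ``[l_r, u_r]`` the CDF is re-normalized to
    the segment's own mass (``c_r(k) = (c[k] - C_{r-1}) / (C_r - C_{r-1})``
    with ``C_r = c[u_r]``, ``C_0 = 0``) so the mapping spans exactly
    ``[l_r, u_r]``; a segment with no mass inherits a linear ramp, keeping
    the table total and monotone.
    """
    c = np.asarray(cdf, dtype=np.float64)
    f = np.zeros(L, dtype=np.int64)
    c_prev = 0.0
    for lo, hi in alloc.out_bounds:
        c_seg = c[hi]
        width = hi - lo
        ks = np.arange(lo, hi + 1)
        if c_seg > c_prev:
            local = (c[lo : hi + 1] - c_prev) / (c_seg - c_prev)
        else:
            local = (ks - lo) / max(width, 1)
        f[lo : hi + 1] = round_half_away(lo + width * local).astype(np.int64)
        c_prev = c_seg
    return f


def compose_lut(remap: np.ndarray, transfer: np.ndarray) -> np.ndarray:
    """Compose the grayscale remap with the transfer into one total LUT.

    Occupied input levels go through ``transfer[remap[k]]``; unoccupied
    levels copy their nearest occupied neighbour (lower neighbour on ties)
    so the table is defined on all 256 levels and stays monotone.
    """
    occupied = np.flatnonzero(remap >= 0)
    if occupied.size == 0:
        return np.arange(L, dtype=np.int64)
    final = np.empty(L, dtype=np.int64)
    final[occupied] = transfer[remap[occupied]]
    gaps = np.setdiff1d(np.arange(L), occupied, assume_unique=True)
    if gaps.size:
        pos = np.searchsorted(occupied, gaps)
        lo_n = occupied[np.clip(pos - 1, 0, occupied.size - 1)]
        hi_n = occupied[np.clip(pos, 0, occupied.size - 1)]
        # nearest occupied neighbour, lower on ties
        nearest = np.where((gaps - lo_n) <= (hi_n - gaps), lo_n, hi_n)
        nearest[gaps < occupied[0]] = occupied[0]
        nearest[gaps > occupied[-1]] = occupied[-1]
        final[gaps] = final[nearest]
    return final


def _identity_result(image: np.ndarray, diag: dict) -> EnhancementResult:
    return EnhancementResult(
        image=image.copy(),
        lut=np.arange(L, dtype=np.int64),
        fallback=True,
        diagnostics=diag,
    )


def _enhance_gray_lut(gray: np.ndarray, config: EnhanceConfig):
    """Run the pipeline on a 2-D gray array; return (lut, fallback, diag)."""
    hist = compute_histogram(gray)
    pdf = to_pdf(hist)
    seg = segment_histogram(pdf, hist.k_l, hist.k_u)
    diag: dict[str, Any] = {}
    if seg.degenerate:
        return np.arange(L, dtype=np.int64), True, diag
    try:
        alloc = allocate_ranges(seg, weight=config.weight_hook)
        adj = remap_pdf(pdf, seg, alloc)
        stats = compute_side_stats(adj, alpha_override=config.alpha_override)
        p_mod = adjust_pdf(adj, stats)
        cdf = normalized_cdf(p_mod)
        transfer = segment_transfer(cdf, alloc)
        lut = compose_lut(adj.remap, transfer)
    except DegenerateHistogramError:
        return np.arange(L, dtype=np.int64), True, diag
    if config.emit_diagnostics:
        diag = {
            "thresholds": seg.thresholds,
            "boundaries": seg.boundaries,
            "segment_entropies": seg.segment_entropies,
            "spans": alloc.spans,
            "aspans": alloc.aspans,
            "ranges": alloc.ranges,
            "out_bounds": alloc.out_bounds,
            "split_level": stats.i_ks,
            "side_means": (stats.i_avg_low, stats.i_avg_high),
            "alpha": (stats.alpha_low, stats.alpha_high),
        }
    return lut, False, diag


def _scale_channels(rgb: np.ndarray, base: np.ndarray, new_base: np.ndarray) -> np.ndarray:
    """Scale R, G, B by new_base/base per pixel, preserving hue."""
    base_f = base.astype(np.float64)
    new_f = new_base.astype(np.float64)
    out = np.empty_like(rgb, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(base_f > 0, new_f / np.where(base_f > 0, base_f, 1.0), 0.0)
    for ch in range(3):
        out[..., ch] = rgb[..., ch] * ratio
    # a zero base pixel has no hue: set all channels to the new base value
    zero = base_f == 0
    out[zero, :] = new_f[zero, None]
    return np.clip(round_half_away(out), 0, L - 1).astype(np.uint8)


def enhance(image, config: EnhanceConfig | None = None) -> EnhancementResult:
    """Run the full entropy-based adaptive subhistogram equalization.

    Pipeline: histogram → entropy-balanced four-way segmentation →
    dynamic-range reallocation → PDF remapping → adaptive PDF reshaping →
    per-segment equalization → LUT application.  Degenerate inputs
    (constant images, fewer than four usable segments) return the original
    pixels with ``fallback=True`` instead of raising.

    RGB images are enhanced on a single base channel (per ``config``) and
    the colour channels are scaled proportionally.
    """
    config = config or EnhanceConfig()
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 2:
        lut, fallback, diag = _enhance_gray_lut(arr, config)
        out = lut[arr.astype(np.int64)].astype(np.uint8)
        return EnhancementResult(image=out, lut=lut, fallback=fallback, diagnostics=diag)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected gray or RGB image, got shape {arr.shape}")

    if config.color_policy == "per_channel":
        outs, luts, fb = [], [], False
        for ch in range(3):
            lut, f_ch, _ = _enhance_gray_lut(arr[..., ch], config)
            outs.append(lut[arr[..., ch].astype(np.int64)])
            luts.append(lut)
            fb = fb or f_ch
        out = np.stack(outs, axis=-1).astype(np.uint8)
        return EnhancementResult(image=out, lut=np.stack(luts), fallback=fb, diagnostics={})
    if config.color_policy == "luminance":
        base = round_half_away(
            0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
        ).astype(np.int64)
        base = np.clip(base, 0, L - 1)
    elif config.color_policy == "value_channel":
        base = arr.max(axis=2).astype(np.int64)
    else:
        raise ValueError(f"unknown color policy {config.color_policy!r}")
    lut, fallback, diag = _enhance_gray_lut(base.astype(np.uint8), config)
    if fallback:
        return _identity_result(arr, diag)
    new_base = lut[base]
    out = _scale_channels(arr, base, new_base)
    return EnhancementResult(image=out, lut=lut, fallback=False, diagnostics=diag)


def classical_he(image) -> np.ndarray:
    """Global histogram equalization over [0, 255] (comparison baseline)."""
    arr = np.asarray(image)
    if arr.ndim == 3:
        gray = arr.max(axis=2)
    else:
        gray = arr
    hist = compute_histogram(gray)
    lut = classical_he_transfer(to_pdf(hist), 0, L - 1)
    if arr.ndim == 3:
        return _scale_channels(arr, gray.astype(np.int64), lut[gray.astype(np.int64)])
    return lut[arr.astype(np.int64)].astype(np.uint8)
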