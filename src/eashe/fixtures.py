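"""Deterministic synthetic test images and histograms.

The public benchmark imagery this kind of method is usually evaluated on is
external; these generators emulate its salient histogram regimes — constant,
exact-uniform, low-contrast narrow-band, bimodal/multimodal Gaussian
mixtures, and isolated spikes — so every code path can be exercised without
any download.  All randomness flows through an explicit integer seed; the
same spec always yields a bit-identical image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from ._util import L

KINDS = ("constant", "ramp", "uniform_exact", "low_contrast", "gaussian_mixture", "spikes")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic image: kind, shape, seed, kind parameters."""

    kind: str
    shape: tuple[int, int] = (64, 64)
    seed: int = 0
    params: dict[str, Any] = field(default_factory=dict)


def _check_shape(shape) -> tuple[int, int]:
    h, w = shape
    if h < 1 or w < 1:
        raise ValueError(f"invalid shape {shape}")
    return int(h), int(w)


def constant_image(shape=(64, 64), level: int = 128) -> np.ndarray:
    """Single-level image; the canonical degenerate input."""
    h, w = _check_shape(shape)
    if not 0 <= level <= 255:
        raise ValueError(f"level {level} outside [0, 255]")
    return np.full((h, w), level, dtype=np.uint8)


def ramp_image(shape=(64, 64)) -> np.ndarray:
    """Row-wise linear ramp from 0 to 255."""
    h, w = _check_shape(shape)
    row = np.floor(np.linspace(0, 255, w) + 0.5).astype(np.uint8) if w > 1 else np.zeros(1, np.uint8)
    return np.tile(row, (h, 1))


def uniform_exact_image(shape=(16, 16)) -> np.ndarray:
    """Every level appears exactly H·W/256 times (H·W must divide by 256)."""
    h, w = _check_shape(shape)
    if (h * w) % L != 0:
        raise ValueError(f"{h}x{w} pixels not divisible by {L}")
    reps = (h * w) // L
    return np.repeat(np.arange(L, dtype=np.uint8), reps).reshape(h, w)


def low_contrast_image(shape=(64, 64), seed: int = 0, band=(100, 139)) -> np.ndarray:
    """Gaussian noise clipped into a narrow intensity band (default width 40)."""
    h, w = _check_shape(shape)
    lo, hi = band
    if not 0 <= lo < hi <= 255:
        raise ValueError(f"invalid band {band}")
    rng = np.random.default_rng(seed)
    mid = (lo + hi) / 2.0
    sigma = max((hi - lo) / 4.0, 1.0)
    vals = rng.normal(mid, sigma, size=(h, w))
    return np.clip(np.floor(vals + 0.5), lo, hi).astype(np.uint8)


def gaussian_mixture_image(
    shape=(64, 64),
    seed: int = 0,
    means: Sequence[float] = (60.0, 190.0),
    sigmas: Sequence[float] = (10.0, 10.0),
    weights: Sequence[float] = (0.5, 0.5),
) -> np.ndarray:
    """Per-pixel draws from a seeded Gaussian mixture, clipped to [0, 255]."""
    h, w = _check_shape(shape)
    means = np.asarray(means, dtype=np.float64)
    sigmas = np.asarray(sigmas, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if not (means.shape == sigmas.shape == weights.shape) or means.ndim != 1:
        raise ValueError("means, sigmas, weights must be 1-D and equal length")
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    comp = rng.choice(means.size, size=h * w, p=weights)
    vals = rng.normal(means[comp], sigmas[comp])
    return np.clip(np.floor(vals + 0.5), 0, 255).astype(np.uint8).reshape(h, w)


def spikes_image(
    shape=(64, 64),
    seed: int = 0,
    levels: Sequence[int] = (60, 190),
    weights: Sequence[float] = (0.5, 0.5),
) -> np.ndarray:
    """Mass only at the listed levels, drawn with the listed proportions."""
    h, w = _check_shape(shape)
    levels = np.asarray(levels, dtype=np.int64)
    weights = np.asarray(weights, dtype=np.float64)
    if levels.ndim != 1 or levels.shape != weights.shape:
        raise ValueError("levels and weights must be 1-D and equal length")
    if (levels < 0).any() or (levels > 255).any():
        raise ValueError("levels must lie in [0, 255]")
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    rng = np.random.default_rng(seed)
    vals = rng.choice(levels, size=(h, w), p=weights / weights.sum())
    return vals.astype(np.uint8)


_GENERATORS = {
    "constant": lambda s: constant_image(s.shape, **s.params),
    "ramp": lambda s: ramp_image(s.shape),
    "uniform_exact": lambda s: uniform_exact_image(s.shape),
    "low_contrast": lambda s: low_contrast_image(s.shape, s.seed, **s.params),
    "gaussian_mixture": lambda s: gaussian_mixture_image(s.shape, s.seed, **s.params),
    "spikes": lambda s: spikes_image(s.shape, s.seed, **s.params),
}


def generate(spec: FixtureSpec) -> np.ndarray:
    """Materialize a fixture image from its spec (deterministic)."""
    if spec.kind not in _GENERATORS:
        raise ValueError(f"unknown fixture kind {spec.kind!r}; choose from {KINDS}")
    return _GENERATORS[spec.kind](spec)


def random_histogram(seed: int, occupied: int = 64) -> np.ndarray:
    """Seeded random PDF with positive mass on `occupied` distinct levels.

    The workhorse input for oracle tests of the entropy-split machinery.
    """
    if not 1 <= occupied <= L:
        raise ValueError(f"occupied must be in [1, {L}], got {occupied}")
    rng = np.random.default_rng(seed)
    levels = rng.choice(L, size=occupied, replace=False)
    masses = rng.random(occupied) + 1e-3
    pdf = np.zeros(L)
    pdf[levels] = masses / masses.sum()
    return pdf
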