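"""Shared fixtures and independent brute-force oracles.

The oracles re-derive the entropy-split machinery with plain Python loops
and :mod:`math`, independent of the numpy implementation they check.
"""

import math

import numpy as np
import pytest

from eashe import FixtureSpec, generate


def per_bin_entropy(p: float) -> float:
    return -p * math.log2(p) if p > 0 else 0.0


def brute_half_entropy_threshold(pdf, lo: int, hi: int):
    """Plain-loop version of the half-entropy stopping rule."""
    total = sum(per_bin_entropy(pdf[k]) for k in range(lo, hi + 1))
    if total <= 0:
        return None
    cum = 0.0
    for k in range(lo, hi + 1):
        cum += per_bin_entropy(pdf[k])
        if cum >= total / 2.0:
            return min(k, hi - 1)
    return hi - 1


def brute_segment_thresholds(pdf, k_l: int, k_u: int):
    """Brute-force four-way segmentation; None when degenerate."""
    if k_u <= k_l:
        return None
    ks2 = brute_half_entropy_threshold(pdf, k_l, k_u)
    if ks2 is None or ks2 <= k_l:
        return None
    ks1 = brute_half_entropy_threshold(pdf, k_l, ks2)
    if ks2 + 1 >= k_u:
        return None
    ks3 = brute_half_entropy_threshold(pdf, ks2 + 1, k_u)
    if ks1 is None or ks3 is None:
        return None
    return ks1, ks2, ks3


@pytest.fixture
def uniform_image():
    """16x16 image where every gray level appears exactly once."""
    return generate(FixtureSpec("uniform_exact", (16, 16)))


@pytest.fixture
def uniform_pdf():
    return np.full(256, 1.0 / 256)


def mixture_image(seed: int, shape=(64, 64)):
    """Seeded Gaussian-mixture image with seed-derived component layout."""
    rng = np.random.default_rng(seed)
    ncomp = int(rng.integers(2, 5))
    means = tuple(rng.uniform(20, 235, ncomp))
    sigmas = tuple(rng.uniform(5, 30, ncomp))
    weights = tuple(rng.dirichlet(np.ones(ncomp)))
    return generate(
        FixtureSpec(
            "gaussian_mixture",
            shape,
            seed,
            {"means": means, "sigmas": sigmas, "weights": weights},
        )
    )


def bimodal_image(seed: int, shape=(64, 64)):
    """Seeded bimodal fixture: dark and bright modes of random balance."""
    rng = np.random.default_rng(seed)
    m_dark = rng.uniform(40, 90)
    m_bright = rng.uniform(160, 220)
    w = rng.uniform(0.3, 0.7)
    return generate(
        FixtureSpec(
            "gaussian_mixture",
            shape,
            seed,
            {"means": (m_dark, m_bright), "sigmas": (12.0, 12.0), "weights": (w, 1 - w)},
        )
    )
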