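"""Objective quality measures: discrete entropy, PSNR and AMBE.

- Discrete entropy (DE, bits): entropy of the intensity distribution;
  higher means richer detail, with the maximum of 8 bits reached only by
  the exactly uniform histogram.
- PSNR (dB): ``10·log10(255² / MSE)`` against the input image; higher
  means less deviation / noise amplification.  Identical images yield an
  infinite PSNR, reported as ``math.inf``.
- AMBE (gray levels): ``|mean(X) - mean(Y)|``; lower means better
  brightness preservation.

For RGB images DE is computed on the value channel (consistent with the
enhancement policy) while MSE/PSNR/AMBE run over all channel samples.
"""

from __future__ import annotations

import csv
import io as _io
import json
import math
from dataclasses import dataclass

import numpy as np

from .histogram_core import compute_histogram, entropy, to_pdf

_PEAK = 255.0


def _as_array(image) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty image")
    return arr


def discrete_entropy(image) -> float:
    """Entropy of the image's normalized intensity histogram, in bits."""
    arr = np.asarray(image)
    hist = compute_histogram(
        arr, channel_policy="value_channel" if arr.ndim == 3 else "gray"
    )
    return entropy(to_pdf(hist))


def mse(x, y) -> float:
    """Mean squared error between two same-shaped images."""
    ax, ay = _as_array(x), _as_array(y)
    if ax.shape != ay.shape:
        raise ValueError(f"shape mismatch: {ax.shape} vs {ay.shape}")
    return float(np.mean((ax - ay) ** 2))


def psnr(x, y) -> float:
    """Peak signal-to-noise ratio in dB; ``math.inf`` for identical images."""
    err = mse(x, y)
    if err == 0.0:
        return math.inf
    return float(10.0 * math.log10(_PEAK**2 / err))


def ambe(x, y) -> float:
    """Absolute mean brightness error, in gray levels."""
    ax, ay = _as_array(x), _as_array(y)
    if ax.shape != ay.shape:
        raise ValueError(f"shape mismatch: {ax.shape} vs {ay.shape}")
    return float(abs(ax.mean() - ay.mean()))


@dataclass(frozen=True)
class QualityReport:
    """The three quality scores of an enhancement, plus the raw MSE."""

    de_input: float
    de_output: float
    psnr: float
    ambe: float
    mse: float

    def to_dict(self) -> dict:
        """Flat dict with JSON-safe values (infinite PSNR becomes "inf")."""
        d = {
            "de_input": self.de_input,
            "de_output": self.de_output,
            "psnr": self.psnr,
            "ambe": self.ambe,
            "mse": self.mse,
        }
        if math.isinf(self.psnr):
            d["psnr"] = "inf"
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def to_csv_row(self) -> str:
        """One CSV line: de_input, de_output, psnr, ambe, mse."""
        buf = _io.StringIO()
        w = csv.writer(buf)
        d = self.to_dict()
        w.writerow([d["de_input"], d["de_output"], d["psnr"], d["ambe"], d["mse"]])
        return buf.getvalue().strip()


def quality_report(original, enhanced) -> QualityReport:
    """Score an enhanced image against its original."""
    return QualityReport(
        de_input=discrete_entropy(original),
        de_output=discrete_entropy(enhanced),
        psnr=psnr(original, enhanced),
        ambe=ambe(original, enhanced),
        mse=mse(original, enhanced),
    )
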