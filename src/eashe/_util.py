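"""Shared numeric helpers."""

import numpy as np

#: Number of gray levels of an 8-bit image.
L = 256


def round_half_away(x):
    """Round half away from zero, elementwise.

    Used at every quantization site instead of :func:`numpy.round` (banker's
    rounding) so results are bit-exact across platforms and match the usual
    image-processing convention.  All quantities rounded in this package are
    non-negative, but the symmetric form is kept for safety.
    """
    x = np.asarray(x, dtype=np.float64)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)
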