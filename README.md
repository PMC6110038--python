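# eashe — entropy-based adaptive subhistogram equalization

Contrast enhancement for 8-bit grayscale and RGB images, aimed at
preprocessing in microscopy, medical imaging and general photography
pipelines.  Classical histogram equalization (HE) remaps gray levels
through the image's cumulative distribution; it stretches contrast
effectively but saturates dense intensity regions and shifts the mean
brightness, which is unacceptable when downstream analysis depends on
stable intensities.

`eashe` implements an entropy-based adaptive subhistogram equalization
scheme that enhances contrast while preserving mean brightness and detail:

1. **Entropy-balanced segmentation.**  The occupied histogram range
   `[k_l, k_u]` is split at the *half-entropy threshold* — the smallest
   level `k_s` with `−Σ_{k≤k_s} p(k) log₂ p(k) ≥ E/2` where
   `E = −Σ p log₂ p` — once globally and once per half, giving four
   subhistograms of (nearly) equal entropy.
2. **Dynamic-range reallocation.**  Each segment's output width is a blend
   `aspan_r = span_r + w(E_r)·(L/4 − span_r)` of its input span and the
   uniform share (`L = 256`), with weight `w(E) = clamp(1/E, 0, 1)`:
   detail-poor segments are pulled toward the uniform share, detail-rich
   ones keep their span.  The widths are integerized to tile `[0, 255]`
   exactly and the PDF is remapped onto the new ranges.
3. **Adaptive PDF reshaping.**  The remapped PDF is split at its
   half-entropy level and each side is pulled quadratically toward the
   midpoint `m = (pdf_max + pdf_min)/2` of its occupied-bin densities,
   controlled by a data-derived factor `α ∈ [0, 1]` computed from the
   asymmetry of the side means: `α = 0` flattens the side (gentle linear
   stretch), `α = 1` keeps the extremes fixed (full HE behaviour).
4. **Per-segment equalization.**  Each output segment is equalized with
   its own normalized CDF, `f(k) = l_r + (u_r − l_r)·c_r(k)`, and the four
   transfer functions compose into a single monotone 256-entry lookup
   table applied per pixel.

Results are scored with discrete entropy (DE, bits — detail), PSNR (dB —
deviation from the input) and AMBE (gray levels — brightness shift).

## Worked example

```python
import numpy as np
from eashe import EnhanceConfig, FixtureSpec, enhance, generate, quality_report

image = generate(FixtureSpec(
    "gaussian_mixture", shape=(64, 64), seed=42,
    params={"means": (60, 190), "sigmas": (10, 10), "weights": (0.5, 0.5)},
))
result = enhance(image, EnhanceConfig(emit_diagnostics=True))
print("thresholds:", result.diagnostics["thresholds"])
print("output ranges:", result.diagnostics["ranges"])
print("alpha:", tuple(round(a, 4) for a in result.diagnostics["alpha"]))
report = quality_report(image, result.image)
print(f"DE  {report.de_input:.4f} -> {report.de_output:.4f} bits")
print(f"PSNR {report.psnr:.4f} dB   AMBE {report.ambe:.4f}")
```

prints

```
thresholds: (60, 87, 190)
output ranges: (54, 55, 85, 58)
alpha: (0.3083, 0.6917)
DE  6.3478 -> 6.2590 bits
PSNR 23.9281 dB   AMBE 0.4004
```

The bimodal image is split at levels 60/87/190 (the dark mode carries half
the entropy, so two thresholds fall inside it), the four segments receive
output widths 54/55/85/58, and the reshaping factors (0.31, 0.69) reflect
the split sitting closer to the dark mean.  Contrast is stretched across
the full range while the mean brightness moves by only 0.40 gray levels —
the brightness-preservation property the method is designed for.

The same pipeline is available from a shell:

```sh
eashe fixture gaussian_mixture mix.png --seed 42
eashe enhance mix.png out.png --report report.json --diagnostics
eashe metrics mix.png out.png
```

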