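# Methods

This note records the model implemented by `eashe`, the choices made where
the design was genuinely open, and what the synthetic test conditions do
and do not establish about real imagery.

## Model

The input is an 8-bit image `I` with `L = 256` gray levels, occupied range
`[k_l, k_u]`, histogram `H(k)` and PDF `p(k) = H(k)/N`.  All entropies are
Shannon entropies in bits (log base 2) with `0·log 0 = 0`.  Base 2 is fixed
globally: the segmentation thresholds are base-invariant, but the
range-allocation weight `1/E` is not, so one base must hold everywhere and
bits is the natural choice for 8-bit data.

### 1. Entropy-balanced segmentation

The *half-entropy threshold* of an interval `[lo, hi]` is the smallest
`k_s ∈ [lo, hi−1]` with cumulative entropy `≥ E([lo,hi])/2`.  The exact
half-way point generally falls between integer levels, so the rule is
stated with `≥` and the smallest satisfying level; the lower side then
overshoots `E/2` by less than the entropy contribution of bin `k_s`.  The
result is clamped to `hi − 1` so both sides are non-empty index ranges.

Applying the rule to `[k_l, k_u]` yields the middle threshold `k_s2`;
re-applying it to `[k_l, k_s2]` and `[k_s2+1, k_u]` yields `k_s1` and
`k_s3`.  The four input segments are `[m0,m1], [m1+1,m2], [m2+1,m3],
[m3+1,m4]` with `(m0..m4) = (k_l, k_s1, k_s2, k_s3, k_u)`.  Because
entropy is a per-bin sum, the four segment entropies partition the total
exactly, and each deviates from `E/4` by at most its own split's
threshold-bin entropy plus half the middle split's — the bound the
acceptance suite checks.

Degeneracy (a single occupied level, or a zero-entropy sub-interval) sets
a flag instead of raising; the pipeline then returns the identity mapping.

### 2. Dynamic-range reallocation

For segment `r` with span `span_r = m_r − m_{r−1}` and entropy `E_r`:

    aspan_r = span_r + w(E_r) · (L/4 − span_r),   w(E) = clamp(1/E, 0, 1)

with `w = 1` at zero entropy.  The clamp keeps `aspan_r` between `span_r`
and the uniform share 64, so blending can only move a segment *toward*
the uniform share — the shrink-toward-uniform invariant.  The reciprocal
weight means segments whose content is detail-poor (low entropy, e.g. a
flat background occupying a wide band) surrender width, while detail-rich
segments keep theirs.  Two alternative hooks are exposed
(`normalized_entropy`: `w = 1 − E/8`; `uniform`: `w = 1`) because the
best weighting is application-dependent; `reciprocal_clamped` is the
default.

Integer output widths must tile `[0, 255]` with four inclusive intervals,
which consumes `L − 4 = 252` levels of width plus one level per lower
bound.  Real widths `aspan_r/Σaspan · 252` are integerized by
largest-remainder rounding (deterministic, lower index first on ties) with
a minimum width of 1, the deficit taken from the largest width.  Bounds
follow as `l_1 = 0`, `u_r = l_r + range_r`, `l_{r+1} = u_r + 1`,
`u_4 = 255`.

Each occupied input level is then moved affinely onto its segment's output
range, `k' = round(l_r + (k − a_r)/max(b_r − a_r, 1) · range_r)`, with
probability mass following the levels (collisions sum, mass is conserved).
Unoccupied output levels stay at zero probability: interpolating mass into
them would invent intensities absent from the image.

### 3. Adaptive PDF reshaping

The remapped PDF is split once at its own half-entropy level `I_ks`.  Per
side, with `pdf_max/pdf_min` the extreme densities over the side's
*occupied* bins and `m = (pdf_max + pdf_min)/2`:

    p(k) < m:  p'(k) = m − α (m − p(k))² / (m − pdf_min)
    p(k) > m:  p'(k) = m + α (p(k) − m)² / (pdf_max − m)

The quadratic pull never overshoots: for `α ∈ [0, 1]` every value stays
between `p(k)` and `m`, extremes are fixed points at `α = 1`, and all
occupied bins collapse to `m` at `α = 0`.  Taking extremes over occupied
bins only is essential — a global `pdf_min = 0` would make the lower
branch inject mass at empty levels.  The extremes, like the factors, are
per-side: the split exists precisely to treat the two halves differently,
and a global extreme would make one side's branch guard vacuous.

The control factors derive from the asymmetry of the conditional mean
levels `μ₁ = E[k | k ≤ I_ks]`, `μ₂ = E[k | k > I_ks]`:

    α_low = (I_ks − μ₁)/(μ₂ − μ₁),   α_high = (μ₂ − I_ks)/(μ₂ − μ₁)

clamped to `[0, 1]` (they sum to 1 before clamping).  A side whose mean
hugs the split is strongly flattened; equal means degrade to
`α = (0, 0)` — no reshaping.  A fixed `α` override exists for debugging
only.

The reshaped weights need not sum to 1; the cumulative sum is normalized
by its final value (clipped to 1 against one-ulp overshoot), giving a
non-decreasing CDF with `c(255) = 1`.

### 4. Per-segment equalization

Within each output segment the CDF is re-normalized to the segment's own
mass, `c_r(k) = (c(k) − C_{r−1})/(C_r − C_{r−1})` with `C_r = c(u_r)`,
`C_0 = 0`, and the transfer is `f(k) = round(l_r + (u_r − l_r)·c_r(k))`.
The segment-local normalization is what makes each mapping span exactly
its allocated range — with the global CDF a segment's outputs would
overrun its boundaries and the union-of-subimages construction would
break.  A segment with no mass inherits a linear ramp so the table stays
total and monotone.  The remap and the transfer compose into one LUT;
unoccupied input levels copy their nearest occupied neighbour (lower on
ties), keeping the table total and monotone on all 256 levels.

Rounding is half-away-from-zero at every quantization site, for
bit-identical results across platforms (`numpy.round` banker's rounding
would differ at exact halves).

### Color

The method is defined on one intensity channel.  For RGB the default
policy enhances the value channel (per-pixel max of R, G, B) and scales
the three channels by `V'/V`, which preserves hue; a pixel with `V = 0`
has no hue and receives `V'` on all channels.  `per_channel`
(independent equalization, strongest but hue-shifting) and `luminance`
(Rec. 601 luma as the base channel) are selectable alternatives.

### Metrics

DE is the entropy of the intensity histogram (value channel for RGB),
maximal at 8 bits for the exactly uniform histogram.  MSE/PSNR use peak
255, with infinite PSNR for identical images reported as `math.inf`
(serialized as the string `"inf"`).  AMBE is the absolute difference of
*mean* brightness — per-pixel means, not sums, since the quantity is on
the 0–255 scale.

## Synthetic study conditions

The generators produce the histogram regimes that drive the method's
behaviour: `constant` and two-level spikes (degeneracy), `uniform_exact`
(the analytic fixed point: thresholds 63/127/191, equal ranges, output
within ±1 level), `low_contrast` (Gaussian noise clipped into a ≤ 40-level
band, default band 100–139 — the stretch case), `gaussian_mixture`
(2–4 seeded modes, means 20–235, σ 5–30, Dirichlet weights — the
general case, including bright-dominant and bimodal layouts typical of
benchmark photographs), and `spikes` (exact sparse histograms for oracle
tests).  Default image size is 64×64 (4096 pixels), enough for mixture
weights to concentrate within ±0.05 while keeping the 500-image invariant
sweep under a few seconds.  All randomness flows through explicit integer
seeds; identical specs are bit-identical.

What passing these conditions does **not** show: performance on natural
images with spatial structure (the generators draw pixels i.i.d., so no
texture, gradients or noise correlation), on other bit depths, or on
color distributions with saturated hues.  The quantitative scores
reported by `scripts/acceptance.py` characterize the synthetic suite
only; on asymmetric multi-modal mixtures the absolute AMBE is larger than
on typical photographs, though consistently below the classical-HE
baseline's.

## Numerical choices and limitations

- Thresholds: smallest-level-`≥` tie-break, clamped so neither side is an
  empty index range.
- Integerization: largest-remainder with minimum width 1; ties broken by
  lower segment index.
- Degenerate inputs never raise from `enhance`; they return the original
  pixels, the identity LUT and `fallback=True`.
- Fixed at four subhistograms; 8-bit only; no local/tile-based variant.
- The entropy weight `w(E)` below 1 bit of segment entropy saturates at 1,
  so very sparse segments are always pulled fully to the uniform share —
  intentional, but it makes the allocation insensitive to differences
  among near-empty segments.
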