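"""Transfer functions, LUT composition, and the end-to-end pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis.extra import numpy as hnp

from conftest import mixture_image
from eashe import (
    EnhanceConfig,
    FixtureSpec,
    allocate_ranges,
    classical_he_transfer,
    compose_lut,
    compute_histogram,
    enhance,
    generate,
    normalized_cdf,
    random_histogram,
    segment_histogram,
    segment_transfer,
    to_pdf,
)
from eashe.equalization import classical_he


def _spike_pdf(levels_masses):
    p = np.zeros(256)
    for level, mass in levels_masses.items():
        p[level] = mass
    return p


class TestClassicalHeTransfer:
    def test_uniform_is_near_identity(self, uniform_pdf):
        f = classical_he_transfer(uniform_pdf, 0, 255)
        assert np.abs(f - np.arange(256)).max() <= 1

    def test_single_spike_saturates(self):
        f = classical_he_transfer(_spike_pdf({0: 1.0}), 0, 255)
        assert f[0] == 255

    def test_two_bin_cdf_values(self):
        f = classical_he_transfer(_spike_pdf({0: 0.25, 128: 0.75}), 0, 255)
        assert f[0] == 64  # round(255 * 0.25)
        assert f[128] == 255

    def test_monotone(self):
        f = classical_he_transfer(random_histogram(3, 100), 0, 255)
        assert (np.diff(f) >= 0).all()


class TestSegmentTransfer:
    def _alloc(self, pdf):
        nz = np.flatnonzero(pdf)
        seg = segment_histogram(pdf, int(nz[0]), int(nz[-1]))
        return seg, allocate_ranges(seg)

    def test_linear_cdf_is_near_identity(self, uniform_pdf):
        _, alloc = self._alloc(uniform_pdf)
        c = (np.arange(256) + 1) / 256
        f = segment_transfer(c, alloc)
        assert np.abs(f - np.arange(256)).max() <= 1

    def test_saturated_segment_maps_to_upper_bound(self, uniform_pdf):
        """All of a segment's mass at its first level drives its outputs to the top."""
        _, alloc = self._alloc(uniform_pdf)  # bounds (64,127) for segment 2
        c = np.zeros(256)
        c[0:64] = 0.25
        c[64:] = 0.5  # jump at 64: segment 2's local cdf saturates immediately
        c[128:] = 0.75
        c[192:] = 1.0
        f = segment_transfer(c, alloc)
        assert (f[64:128] == 127).all()

    @pytest.mark.parametrize("seed", range(30))
    def test_monotone_within_bounds_and_tops_out(self, seed):
        pdf = random_histogram(seed, occupied=int(np.random.default_rng(seed).integers(8, 257)))
        nz = np.flatnonzero(pdf)
        seg = segment_histogram(pdf, int(nz[0]), int(nz[-1]))
        if seg.degenerate:
            return
        alloc = allocate_ranges(seg)
        c = normalized_cdf(pdf)
        f = segment_transfer(c, alloc)
        assert (np.diff(f) >= 0).all()
        for lo, hi in alloc.out_bounds:
            assert f[lo : hi + 1].min() >= lo and f[lo : hi + 1].max() <= hi
        assert f[255] == 255


class TestComposeLut:
    def test_identity_composition(self):
        identity = np.arange(256)
        assert (compose_lut(identity.copy(), identity.copy()) == identity).all()

    def test_sparse_composition_and_gap_fill(self):
        remap = np.full(256, -1)
        remap[100], remap[120] = 0, 63
        transfer = np.arange(256)
        transfer[63] = 255
        final = compose_lut(remap, transfer)
        assert final[100] == 0 and final[120] == 255
        # gaps copy the nearest occupied neighbour, lower on ties
        assert final[99] == 0 and final[110] == 0 and final[111] == 255

    @pytest.mark.parametrize("seed", range(30))
    def test_final_lut_total_and_monotone(self, seed):
        pdf = random_histogram(seed, occupied=int(np.random.default_rng(seed).integers(8, 257)))
        nz = np.flatnonzero(pdf)
        seg = segment_histogram(pdf, int(nz[0]), int(nz[-1]))
        if seg.degenerate:
            return
        alloc = allocate_ranges(seg)
        from eashe import remap_pdf

        adj = remap_pdf(pdf, seg, alloc)
        c = normalized_cdf(adj.p_adj)
        f = segment_transfer(c, alloc)
        final = compose_lut(adj.remap, f)
        assert final.shape == (256,)
        assert (np.diff(final) >= 0).all()
        assert final.min() >= 0 and final.max() <= 255


class TestEnhance:
    def test_constant_image_falls_back(self):
        img = generate(FixtureSpec("constant", (8, 8)))
        result = enhance(img)
        assert result.fallback
        assert (result.image == img).all()

    def test_uniform_image_is_near_identity(self, uniform_image):
        result = enhance(uniform_image)
        assert not result.fallback
        diff = np.abs(result.image.astype(int) - uniform_image.astype(int))
        assert diff.max() <= 1

    @pytest.mark.parametrize("seed", range(25))
    def test_output_range_and_monotone_lut(self, seed):
        img = mixture_image(seed)
        result = enhance(img)
        if result.fallback:
            return
        assert result.image.shape == img.shape
        assert result.image.max() == 255
        assert (np.diff(result.lut) >= 0).all()
        # equal inputs get equal outputs through the single LUT
        assert (result.image == result.lut[img.astype(int)]).all()

    def test_low_contrast_gets_stretched(self):
        img = generate(FixtureSpec("low_contrast", (64, 64), seed=2))
        result = enhance(img)
        out_range = int(result.image.max()) - int(result.image.min())
        in_range = int(img.max()) - int(img.min())
        assert out_range > in_range

    def test_rgb_value_channel_policy(self):
        rng = np.random.default_rng(0)
        rgb = np.clip(rng.normal(120, 30, (32, 32, 3)), 0, 255).astype(np.uint8)
        result = enhance(rgb)
        assert result.image.shape == rgb.shape
        assert not result.fallback
        # value channel of the output equals the LUT applied to the input value channel
        v_in = rgb.max(axis=2).astype(int)
        v_out = result.image.max(axis=2).astype(int)
        assert np.abs(v_out - result.lut[v_in]).max() <= 1  # channel rounding slack

    @pytest.mark.parametrize("policy", ["per_channel", "luminance"])
    def test_alternate_color_policies_run(self, policy):
        rng = np.random.default_rng(1)
        rgb = np.clip(rng.normal(120, 40, (32, 32, 3)), 0, 255).astype(np.uint8)
        result = enhance(rgb, EnhanceConfig(color_policy=policy))
        assert result.image.shape == rgb.shape
        assert result.image.dtype == np.uint8

    def test_diagnostics_emitted_on_request(self):
        img = mixture_image(3)
        result = enhance(img, EnhanceConfig(emit_diagnostics=True))
        assert {"thresholds", "ranges", "alpha", "out_bounds"} <= result.diagnostics.keys()
        a_low, a_high = result.diagnostics["alpha"]
        assert 0.0 <= a_low <= 1.0 and 0.0 <= a_high <= 1.0

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            enhance(np.zeros((0, 3), dtype=np.uint8))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        hnp.arrays(
            np.uint8,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=1, max_side=24),
        )
    )
    def test_any_image_enhances_safely(self, pixels):
        """No input crashes; outputs stay 8-bit with the shape preserved and
        the intensity ordering of pixels never inverted."""
        result = enhance(pixels)
        assert result.image.shape == pixels.shape
        assert result.image.dtype == np.uint8
        assert (np.diff(result.lut) >= 0).all()
        assert (result.image == result.lut[pixels.astype(int)]).all()


class TestClassicalHeBaseline:
    def test_stretches_full_range(self):
        img = generate(FixtureSpec("low_contrast", (64, 64), seed=4))
        out = classical_he(img)
        assert out.max() == 255
        assert out.shape == img.shape
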