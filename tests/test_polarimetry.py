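"""DoFP demosaicking, Stokes computation and DoP/AoP map properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polcrab.polarimetry import (
    DEFAULT_LAYOUT,
    MASK_OVEREXPOSED,
    MASK_UNDEREXPOSED,
    MASK_VALID,
    DimensionError,
    LayoutError,
    PolarizationMaps,
    RawMosaic,
    StokesImage,
    compute_stokes,
    demosaic,
    dop_aop,
    render_false_colour,
)
from polcrab.synthdata import make_disc_scene, render_mosaic


def interleave(I0, I45, I90, I135, layout=DEFAULT_LAYOUT):
    channels = {0: I0, 45: I45, 90: I90, 135: I135}
    h, w = I0.shape
    out = np.empty((2 * h, 2 * w), dtype=I0.dtype)
    for dr in range(2):
        for dc in range(2):
            out[dr::2, dc::2] = channels[layout[dr][dc]]
    return out


class TestDemosaic:
    def test_single_superpixel_lookup(self):
        mosaic = RawMosaic(np.array([[7, 5], [3, 9]]), bit_depth=8)
        I0, I45, I90, I135 = demosaic(mosaic)
        assert (I0[0, 0], I45[0, 0], I90[0, 0], I135[0, 0]) == (9, 5, 7, 3)

    def test_constant_mosaic(self):
        mosaic = RawMosaic(np.full((4, 4), 42), bit_depth=8)
        for ch in demosaic(mosaic):
            assert ch.shape == (2, 2)
            assert np.all(ch == 42)

    def test_reinterleave_roundtrip(self, rng):
        pixels = rng.integers(0, 256, size=(8, 8))
        mosaic = RawMosaic(pixels, bit_depth=8)
        np.testing.assert_array_equal(interleave(*demosaic(mosaic)), pixels)

    def test_odd_dimensions_rejected(self):
        with pytest.raises(DimensionError):
            RawMosaic(np.zeros((3, 4)), bit_depth=8)

    def test_bad_layout_rejected(self):
        with pytest.raises(LayoutError):
            RawMosaic(np.zeros((4, 4)), bit_depth=8, layout=((0, 0), (45, 90)))

    def test_out_of_range_pixels_rejected(self):
        with pytest.raises(ValueError):
            RawMosaic(np.full((2, 2), 300), bit_depth=8)


class TestComputeStokes:
    @pytest.mark.parametrize(
        "I,expected",
        [
            ((100, 100, 100, 100), (200, 0, 0)),  # unpolarized
            ((200, 100, 0, 100), (200, 200, 0)),  # fully horizontal
            ((100, 200, 100, 0), (200, 0, 200)),  # fully 45 degrees
        ],
    )
    def test_canonical_inputs(self, I, expected):
        arrays = [np.full((2, 2), float(v)) for v in I]
        s = compute_stokes(*arrays)
        for got, want in zip((s.S0, s.S1, s.S2), expected):
            assert np.all(got == want)

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            compute_stokes(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 3)), np.zeros((2, 2)))


class TestDopAop:
    def test_horizontal_full_polarization(self):
        maps = dop_aop(StokesImage(np.full((1, 1), 200.0), np.full((1, 1), 200.0), np.zeros((1, 1))))
        assert maps.dop[0, 0] == pytest.approx(1.0)
        assert maps.aop[0, 0] == pytest.approx(0.0)

    def test_unpolarized_aop_convention(self):
        maps = dop_aop(StokesImage(np.full((1, 1), 200.0), np.zeros((1, 1)), np.zeros((1, 1))))
        assert maps.dop[0, 0] == 0.0
        assert maps.aop[0, 0] == 0.0  # undefined angle reported as 0

    def test_noise_clipping_counted(self):
        # S1 slightly exceeding S0 (unphysical, noise-like)
        maps = dop_aop(StokesImage(np.full((1, 1), 100.0), np.full((1, 1), 110.0), np.zeros((1, 1))))
        assert maps.dop[0, 0] == 1.0
        assert maps.n_clipped == 1

    def test_underexposure_masked(self):
        s = StokesImage(np.array([[0.5, 300.0]]), np.zeros((1, 2)), np.zeros((1, 2)))
        maps = dop_aop(s, floor_threshold=1.0)
        assert maps.mask[0, 0] == MASK_UNDEREXPOSED
        assert maps.mask[0, 1] == MASK_VALID

    def test_overexposure_per_superpixel(self):
        pixels = np.zeros((4, 4), dtype=int)
        pixels[0, 0] = 255  # one saturated subpixel in superpixel (0, 0)
        mosaic = RawMosaic(pixels, bit_depth=8)
        s = StokesImage(np.full((2, 2), 100.0), np.zeros((2, 2)), np.zeros((2, 2)))
        maps = dop_aop(s, mosaic, saturation_margin=0)
        assert maps.mask[0, 0] == MASK_OVEREXPOSED
        assert np.all(maps.mask.ravel()[1:] == MASK_VALID)

    def test_mask_monotone_in_saturation_margin(self, rng):
        pixels = rng.integers(0, 256, size=(8, 8))
        mosaic = RawMosaic(pixels, bit_depth=8)
        s = compute_stokes(*demosaic(mosaic))
        over = [
            (dop_aop(s, mosaic, saturation_margin=m).mask == MASK_OVEREXPOSED)
            for m in (0, 5, 20, 80)
        ]
        for smaller, larger in zip(over, over[1:]):
            assert np.all(larger | ~smaller)  # raising the margin never unmarks


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    dop=st.floats(0.02, 1.0),
    aop=st.floats(-89.9, 89.9),
    s0=st.floats(10.0, 4000.0),
)
def test_float_roundtrip_exact(dop, aop, s0):
    """Forward Malus-law rendering then inversion recovers the Stokes scene."""
    phis = np.radians(np.array([0.0, 45.0, 90.0, 135.0]))
    S1 = s0 * dop * np.cos(2 * np.radians(aop))
    S2 = s0 * dop * np.sin(2 * np.radians(aop))
    I = [np.full((1, 1), 0.5 * (s0 + S1 * np.cos(2 * p) + S2 * np.sin(2 * p))) for p in phis]
    s = compute_stokes(*I)
    assert s.S0[0, 0] == pytest.approx(s0, rel=1e-12)
    maps = dop_aop(s, floor_threshold=0.0)
    assert maps.dop[0, 0] == pytest.approx(dop, abs=1e-9)
    assert maps.aop[0, 0] == pytest.approx(aop, abs=1e-7)


def test_dop_invariant_under_intensity_scaling(rng):
    scene = make_disc_scene(0.3, 0.8, 4, 12, s0=1000.0, aop=20.0)
    maps = []
    for scale in (1.0, 3.7):
        s = StokesImage(scene.S0 * scale, scene.S1 * scale, scene.S2 * scale)
        maps.append(dop_aop(s))
    np.testing.assert_allclose(maps[0].dop, maps[1].dop, atol=1e-12)


def test_rotating_polarization_plane_shifts_aop(rng):
    delta = 37.0
    base = make_disc_scene(0.6, 0.6, 3, 8, s0=1000.0, aop=10.0)
    rotated = make_disc_scene(0.6, 0.6, 3, 8, s0=1000.0, aop=10.0 + delta)
    m0 = dop_aop(StokesImage(base.S0, base.S1, base.S2))
    m1 = dop_aop(StokesImage(rotated.S0, rotated.S1, rotated.S2))
    shift = (m1.aop - m0.aop) % 180.0
    np.testing.assert_allclose(shift, delta, atol=1e-9)
    np.testing.assert_allclose(m0.dop, m1.dop, atol=1e-12)


class TestFalseColour:
    @staticmethod
    def uniform_maps(dop=0.0, aop=0.0, mask_value=MASK_VALID):
        shape = (2, 2)
        return PolarizationMaps(
            dop=np.full(shape, dop),
            aop=np.full(shape, aop),
            intensity=np.full(shape, 100.0),
            mask=np.full(shape, mask_value, dtype=np.uint8),
        )

    def test_zero_dop_uniform_at_colormap_origin(self):
        import matplotlib

        img = render_false_colour(self.uniform_maps(dop=0.0), "dop")
        origin = (np.array(matplotlib.colormaps["viridis"](0.0)[:3]) * 255).round()
        assert np.all(img == origin.astype(np.uint8))

    def test_overexposed_white_underexposed_black(self):
        assert np.all(render_false_colour(self.uniform_maps(mask_value=MASK_OVEREXPOSED), "dop") == 255)
        assert np.all(render_false_colour(self.uniform_maps(mask_value=MASK_UNDEREXPOSED), "aop") == 0)

    def test_aop_colormap_is_cyclic(self):
        lo = render_false_colour(self.uniform_maps(aop=-90.0), "aop")
        hi = render_false_colour(self.uniform_maps(aop=89.999), "aop")
        assert np.abs(lo.astype(int) - hi.astype(int)).max() <= 2

    def test_unknown_channel(self):
        with pytest.raises(ValueError):
            render_false_colour(self.uniform_maps(), "s3")


def test_quantized_roundtrip_within_two_counts():
    scene = make_disc_scene(0.5, 0.9, 4, 12, s0=3000.0, aop=-25.0)
    mosaic = render_mosaic(scene, bit_depth=12, noise_sd=0.0)
    s = compute_stokes(*demosaic(mosaic))
    assert np.abs(s.S0 - scene.S0).max() <= 2.0
    assert np.abs(s.S1 - scene.S1).max() <= 2.0
    assert np.abs(s.S2 - scene.S2).max() <= 2.0
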