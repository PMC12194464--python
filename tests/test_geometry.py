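"""Detector geometry, masks, frame arithmetic and azimuthal integration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from waxstrace import (
    DetectorGeometry,
    Frame,
    PixelMask,
    average_frames,
    azimuthal_integrate,
    build_mask,
    dilate_mask,
    energy_to_wavelength,
    normalize_frame,
    pixel_to_q,
    q_to_radius,
)
from waxstrace.geometry import BEAMSTOP, DEAD

from conftest import brute_force_integrate

GEOM = DetectorGeometry()  # 170.21 mm, 12.4 keV, 0.172 mm pixels


class TestWavelength:
    def test_hc_over_e(self):
        assert energy_to_wavelength(12.4) == pytest.approx(0.0999873, abs=1e-7)

    def test_conversion_constant_identity(self):
        assert energy_to_wavelength(1.2398420) == pytest.approx(1.0, rel=1e-12)

    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_doubling_energy_halves_wavelength(self, energy):
        assert energy_to_wavelength(2 * energy) == pytest.approx(
            energy_to_wavelength(energy) / 2, rel=1e-12
        )

    def test_rejects_non_positive_energy(self):
        with pytest.raises(ValueError):
            energy_to_wavelength(0.0)


class TestPixelToQ:
    def test_forward_beam_is_zero(self):
        assert pixel_to_q(0.0, GEOM) == 0.0

    def test_printed_geometry_value(self):
        # tan(2θ) = 17.021/170.21 = 0.1 → q = 4π sin(θ)/λ ≈ 6.2606 nm⁻¹
        assert pixel_to_q(17.021, GEOM) == pytest.approx(6.2606, abs=1e-3)

    def test_small_angle_limit(self):
        # exact series: q = q_lin * (1 - 3x^2/8 + O(x^4)) with x = r/L
        for x in (0.005, 0.01, 0.02):
            r = x * GEOM.sample_detector_distance_mm
            q = pixel_to_q(r, GEOM)
            q_lin = 2 * np.pi * r / (
                GEOM.sample_detector_distance_mm * GEOM.wavelength_nm
            )
            assert abs(q - q_lin) / q < 0.4 * x * x

    def test_strictly_monotone(self):
        r = np.linspace(0.0, 120.0, 500)
        q = pixel_to_q(r, GEOM)
        assert np.all(np.diff(q) > 0)

    @given(st.floats(min_value=1e-3, max_value=150.0))
    def test_roundtrip(self, r):
        q = pixel_to_q(r, GEOM)
        assert q_to_radius(q, GEOM) == pytest.approx(r, rel=1e-9)

    def test_rejects_negative_distance(self):
        with pytest.raises(ValueError):
            pixel_to_q(-1.0, GEOM)


class TestMasks:
    def test_zero_radius_no_dead_is_empty(self):
        mask = build_mask((16, 16), (8.0, 8.0), 0.0, [], GEOM)
        assert mask.excluded.sum() == 0

    def test_beamstop_count_matches_brute_force(self):
        shape, center, radius = (32, 32), (15.3, 16.7), 0.9
        mask = build_mask(shape, center, radius, [], GEOM)
        count = 0
        for i in range(shape[0]):
            for j in range(shape[1]):
                r = GEOM.pixel_pitch_mm * np.hypot(i - center[0], j - center[1])
                count += r <= radius
        assert (mask.provenance & BEAMSTOP != 0).sum() == count
        assert mask.excluded.sum() == count

    def test_duplicate_dead_pixels_idempotent(self):
        a = build_mask((8, 8), (4, 4), 0.0, [(1, 2), (1, 2), (3, 3)], GEOM)
        b = build_mask((8, 8), (4, 4), 0.0, [(1, 2), (3, 3)], GEOM)
        assert np.array_equal(a.excluded, b.excluded)
        assert (a.provenance & DEAD != 0).sum() == 2

    def test_out_of_bounds_dead_pixel_rejected(self):
        with pytest.raises(ValueError):
            build_mask((8, 8), (4, 4), 0.0, [(9, 0)], GEOM)

    def test_dilate_zero_radius_is_identity(self):
        mask = build_mask((8, 8), (4, 4), 0.0, [(2, 2)], GEOM)
        out = dilate_mask(mask, 0)
        assert np.array_equal(out.excluded, mask.excluded)

    def test_dilate_single_pixel_unit_disk(self):
        excluded = np.zeros((9, 9), dtype=bool)
        excluded[4, 4] = True
        out = dilate_mask(PixelMask(excluded), 1)
        assert out.excluded.sum() == 5  # 4-connected unit disk

    def test_dilate_monotone(self):
        excluded = np.zeros((16, 16), dtype=bool)
        excluded[3, 12] = excluded[10, 2] = True
        mask = PixelMask(excluded)
        once = dilate_mask(mask, 2)
        twice = dilate_mask(dilate_mask(mask, 2), 2)
        assert np.all(once.excluded >= mask.excluded)
        assert np.all(twice.excluded >= once.excluded)


class TestFrameArithmetic:
    def test_normalize_identity(self):
        f = Frame(np.arange(12.0).reshape(3, 4), exposure_time=1.0, monitor=2.0)
        out = normalize_frame(f, reference_monitor=2.0)
        assert np.array_equal(out.counts, f.counts)

    def test_normalize_monitor_and_exposure_scaling(self):
        f = Frame(np.ones((2, 2)), exposure_time=0.5, monitor=1.0)
        out = normalize_frame(f, reference_monitor=2.0)
        # (2/1) / 0.5 = 4
        assert np.allclose(out.counts, 4.0)
        assert out.applied_scale == pytest.approx(4.0)

    def test_normalize_preserves_zeros_and_rejects_bad_monitor(self):
        f = Frame(np.zeros((2, 2)), exposure_time=1.0, monitor=1.0)
        assert np.all(normalize_frame(f, 5.0).counts == 0.0)
        with pytest.raises(ValueError):
            normalize_frame(Frame(np.ones((2, 2)), monitor=-1.0), 1.0)

    def test_average_single_and_identical(self):
        a = Frame(np.random.default_rng(0).poisson(5, (4, 4)).astype(float))
        assert np.array_equal(average_frames([a]).counts, a.counts)
        out = average_frames([a, a])
        assert np.array_equal(out.counts, a.counts)
        assert out.exposure_time == pytest.approx(2 * a.exposure_time)

    def test_average_constants(self):
        c1, c2 = Frame(np.full((3, 3), 2.0)), Frame(np.full((3, 3), 6.0))
        assert np.allclose(average_frames([c1, c2]).counts, 4.0)

    def test_average_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            average_frames([Frame(np.ones((2, 2))), Frame(np.ones((3, 3)))])


def _small_geom():
    return DetectorGeometry(beam_center=(31.5, 32.5))


class TestAzimuthalIntegration:
    def test_constant_frame_gives_constant_profile(self):
        geom = _small_geom()
        frame = Frame(np.full((64, 64), 7.0))
        edges = np.linspace(0.1, 8.0, 40)
        prof = azimuthal_integrate(frame, geom, None, edges)
        finite = np.isfinite(prof.intensity)
        assert finite.any()
        assert np.allclose(prof.intensity[finite], 7.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        geom = _small_geom()
        counts = rng.poisson(20, (64, 64)).astype(float)
        excluded = rng.random((64, 64)) < 0.05
        edges = np.linspace(0.2, 7.5, 25)
        prof = azimuthal_integrate(frame := Frame(counts), geom, PixelMask(excluded), edges)
        oi, osig, on = brute_force_integrate(counts, excluded, geom.q_map((64, 64)), edges)
        assert np.array_equal(prof.n_pixels, on)
        np.testing.assert_array_equal(prof.intensity, oi)
        np.testing.assert_array_equal(prof.sigma, osig)

    def test_single_pixel_poisson_sigma(self):
        geom = _small_geom()
        counts = np.zeros((64, 64))
        counts[10, 10] = 9.0
        excluded = np.ones((64, 64), dtype=bool)
        excluded[10, 10] = False
        edges = np.linspace(0.0, 10.0, 11)
        prof = azimuthal_integrate(Frame(counts), geom, PixelMask(excluded), edges)
        b = np.nanargmax(np.where(prof.n_pixels > 0, prof.intensity, -1))
        assert prof.intensity[b] == pytest.approx(9.0)
        assert prof.sigma[b] == pytest.approx(3.0)

    def test_masked_pixels_never_influence_profile(self):
        rng = np.random.default_rng(7)
        geom = _small_geom()
        counts = rng.poisson(10, (64, 64)).astype(float)
        excluded = rng.random((64, 64)) < 0.2
        edges = np.linspace(0.2, 7.5, 20)
        a = azimuthal_integrate(Frame(counts.copy()), geom, PixelMask(excluded), edges)
        counts[excluded] += 1e6
        b = azimuthal_integrate(Frame(counts), geom, PixelMask(excluded), edges)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_linearity_in_counts(self):
        rng = np.random.default_rng(3)
        geom = _small_geom()
        counts = rng.poisson(15, (64, 64)).astype(float)
        edges = np.linspace(0.2, 7.5, 20)
        a = azimuthal_integrate(Frame(counts), geom, None, edges)
        b = azimuthal_integrate(Frame(3.0 * counts), geom, None, edges)
        finite = np.isfinite(a.intensity)
        np.testing.assert_allclose(b.intensity[finite], 3.0 * a.intensity[finite])

    def test_all_masked_rejected(self):
        geom = _small_geom()
        with pytest.raises(ValueError):
            azimuthal_integrate(
                Frame(np.ones((8, 8))), geom,
                PixelMask(np.ones((8, 8), dtype=bool)),
                np.linspace(0, 5, 6),
            )

    def test_non_increasing_edges_rejected(self):
        with pytest.raises(ValueError):
            azimuthal_integrate(
                Frame(np.ones((8, 8))), _small_geom(), None, np.array([1.0, 1.0, 2.0])
            )
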