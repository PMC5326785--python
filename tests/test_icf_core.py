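"""Unit and property tests for the per-slice cylindrical fit."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import dense_ellipse_pv, disk_section, mixture_slice
from veinicf.icf_core import (
    CrossSection,
    DegenerateFitError,
    MaskError,
    NoSignalError,
    SegmentPair,
    VeinGeometry,
    chord_fit,
    combine_radius,
    estimate_background,
    estimate_chi_vein,
    fit_error,
    fit_slice,
    fit_vein_segment,
    invert_segment_area,
    rasterize_ellipse_pv,
    segment_area,
    segment_fractions,
    vein_only_image,
)

TWO_PI = 2.0 * math.pi


def _section(pixels, init=None):
    pixels = np.asarray(pixels, dtype=float)
    if init is None:
        init = np.zeros_like(pixels, dtype=bool)
        init[pixels.shape[0] // 2, pixels.shape[1] // 2] = True
    return CrossSection(pixels=pixels, init_mask=init, background_roi=~init)


class TestBackgroundAndVeinOnly:
    def test_constant_slice(self):
        sec = _section(np.full((7, 7), 0.02))
        assert estimate_background(sec) == pytest.approx(0.02)

    def test_mean_of_roi(self):
        pixels = np.zeros((3, 3))
        init = np.zeros((3, 3), bool)
        init[1, 1] = True
        roi = np.zeros((3, 3), bool)
        roi[0, 0] = roi[0, 1] = roi[0, 2] = True
        pixels[0] = [0.0, 0.1, 0.2]
        sec = CrossSection(pixels=pixels, init_mask=init, background_roi=roi)
        assert estimate_background(sec) == pytest.approx(0.1)

    def test_empty_roi_raises(self):
        init = np.ones((3, 3), bool)
        sec = CrossSection(
            pixels=np.zeros((3, 3)), init_mask=init, background_roi=~init
        )
        with pytest.raises(MaskError):
            estimate_background(sec)

    def test_zero_background_is_identity(self):
        pixels = np.random.default_rng(0).normal(size=(5, 5))
        pv = np.random.default_rng(1).uniform(size=(5, 5))
        np.testing.assert_array_equal(vein_only_image(pixels, pv, 0.0), pixels)

    def test_pure_vein_keeps_intensity(self):
        pixels = np.full((4, 4), 0.3)
        assert np.allclose(vein_only_image(pixels, np.ones((4, 4)), 0.1), 0.3)

    def test_hand_arithmetic(self):
        out = vein_only_image(np.array([[0.5]]), np.array([[0.4]]), 0.1)
        assert out[0, 0] == pytest.approx(0.5 - 0.1 * 0.6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            vein_only_image(np.zeros((3, 3)), np.zeros((2, 2)), 0.0)


class TestSegmentFractions:
    def test_disk_inside_one_line_gives_zero_fractions(self):
        img = np.zeros((9, 9))
        img[4, 3:6] = 1.0  # all signal in line 4 of axis 0
        seg = segment_fractions(img, axis=0)
        assert seg.A1 == 0.0 and seg.A2 == 0.0
        assert (seg.chord_lo, seg.chord_hi) == (3.5, 4.5)

    def test_centered_disk_matches_analytic_segment_area(self):
        # chord at distance 0.5 from a disk of radius 1.3
        R = 1.3
        pv = dense_ellipse_pv((4.0, 4.0), R, R, 0.0, (9, 9), n=512)
        seg = segment_fractions(pv, axis=0)
        theta = 2.0 * math.acos(0.5 / R)
        expected = (theta - math.sin(theta)) / TWO_PI
        assert seg.A1 == pytest.approx(expected, abs=1e-4)
        assert seg.A2 == pytest.approx(expected, abs=1e-4)

    def test_offset_disk_asymmetry(self):
        pv = dense_ellipse_pv((4.3, 4.0), 1.3, 1.3, 0.0, (9, 9), n=128)
        seg = segment_fractions(pv, axis=0)
        assert seg.A2 > seg.A1  # more area beyond the high-index chord

    def test_no_signal_raises(self):
        with pytest.raises(NoSignalError):
            segment_fractions(np.zeros((5, 5)), axis=0)

    def test_tie_broken_toward_center(self):
        img = np.zeros((7, 7))
        img[1, :] = 1.0
        img[3, :] = 1.0  # tie; 3 is the central line
        seg = segment_fractions(img, axis=0)
        assert (seg.chord_lo, seg.chord_hi) == (2.5, 3.5)


class TestInvertSegmentArea:
    @pytest.mark.parametrize(
        "area,theta",
        [(0.0, 0.0), (0.5, math.pi), (1.0, TWO_PI)],
    )
    def test_exact_points(self, area, theta):
        assert invert_segment_area(area) == pytest.approx(theta, abs=1e-10)

    def test_quarter_area_bisection_oracle(self):
        # independent bisection on [0, 2*pi]
        lo, hi = 0.0, TWO_PI
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if (mid - math.sin(mid)) / TWO_PI < 0.25:
                lo = mid
            else:
                hi = mid
        assert invert_segment_area(0.25) == pytest.approx(lo, abs=1e-10)
        assert invert_segment_area(0.25) == pytest.approx(2.3099, abs=1e-3)

    def test_round_trip_accuracy(self):
        areas = np.linspace(0.0, 1.0, 1000)
        back = np.array([segment_area(invert_segment_area(a)) for a in areas])
        assert np.max(np.abs(back - areas)) < 1e-8

    def test_monotone_in_area(self):
        thetas = [invert_segment_area(a) for a in np.linspace(0, 1, 101)]
        assert np.all(np.diff(thetas) > 0)

    @pytest.mark.parametrize("bad", [-0.01, 1.01])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            invert_segment_area(bad)


def _analytic_pair(radius, offset):
    """True segment areas of a circle around the unit-spaced chords +-0.5."""
    d1 = offset + 0.5  # distance from center to the low chord
    d2 = 0.5 - offset
    thetas = []
    for d in (d1, d2):
        if d >= radius:
            thetas.append(0.0)
        else:
            thetas.append(2.0 * math.acos(d / radius))
    a1, a2 = [(t - math.sin(t)) / TWO_PI for t in thetas]
    return SegmentPair(A1=a1, A2=a2, chord_lo=-0.5, chord_hi=0.5)


class TestChordFit:
    def test_symmetric_center_at_midpoint(self):
        seg = _analytic_pair(1.3, 0.0)
        p, r = chord_fit(seg)
        assert p == pytest.approx(0.0, abs=1e-12)
        assert r == pytest.approx(1.3, abs=1e-9)

    @pytest.mark.parametrize("radius", [0.8, 1.3, 2.0])
    def test_centered_radius_recovery(self, radius):
        _, r = chord_fit(_analytic_pair(radius, 0.0))
        assert r == pytest.approx(radius, abs=1e-9)

    def test_zero_areas_give_inscribed_disk(self):
        seg = SegmentPair(A1=0.0, A2=0.0, chord_lo=-0.5, chord_hi=0.5)
        p, r = chord_fit(seg)
        assert p == pytest.approx(0.0)
        assert r == pytest.approx(0.5)

    @given(
        radius=st.floats(0.6, 3.0),
        offset=st.floats(-0.5, 0.5),
    )
    def test_exact_recovery_property(self, radius, offset):
        # both chords must genuinely cut the disk for exact recovery
        if offset + 0.5 >= radius * 0.999 or 0.5 - offset >= radius * 0.999:
            return
        p, r = chord_fit(_analytic_pair(radius, offset))
        assert abs(p - offset) < 1e-6
        assert abs(r - radius) < 1e-6

    def test_degenerate_raises(self):
        seg = SegmentPair(A1=0.5, A2=0.5, chord_lo=-0.5, chord_hi=0.5)
        with pytest.raises(DegenerateFitError):
            chord_fit(seg)


class TestCombineRadius:
    def test_untilted_circle(self):
        assert combine_radius(1.3, 1.3) == pytest.approx(1.3)

    def test_untilted_plain_average(self):
        assert combine_radius(1.0, 2.0) == pytest.approx(1.5)

    def test_tilted_ellipse_extents_recover_radius(self):
        # a cylinder of radius R tilted by t has in-slice extents
        # wx, wy; the combination should return ~R (1% bias at 30 deg)
        R, t = 1.3, math.radians(30)
        for phi in (0.0, math.radians(20), math.radians(45)):
            a, b = R / math.cos(t), R
            wx = math.sqrt((a * math.cos(phi)) ** 2 + (b * math.sin(phi)) ** 2)
            wy = math.sqrt((a * math.sin(phi)) ** 2 + (b * math.cos(phi)) ** 2)
            assert combine_radius(wx, wy, t, phi) == pytest.approx(R, rel=0.02)

    def test_bias_at_45_degrees_matches_formula(self):
        # the averaged correction carries a known (cos t + sec t)/2 factor
        R, t = 1.0, math.radians(45)
        a, b = R / math.cos(t), R
        got = combine_radius(a, b, t, 0.0)
        assert got == pytest.approx(0.5 * (math.cos(t) + 1 / math.cos(t)), rel=1e-9)


class TestRasterizePV:
    def test_containment_in_one_voxel(self):
        geom = VeinGeometry((3.0, 3.0), (0.2, 0.3), 0.25)
        pv = rasterize_ellipse_pv(geom, (7, 7))
        assert pv[3, 3] == pytest.approx(math.pi * 0.2 * 0.3, abs=5e-3)
        pv[3, 3] = 0.0
        assert pv.sum() == 0.0

    def test_interior_saturation(self):
        geom = VeinGeometry((5.0, 5.0), (4.0, 4.0), 4.0)
        pv = rasterize_ellipse_pv(geom, (11, 11))
        assert pv[5, 5] == 1.0 and pv[4, 5] == 1.0

    def test_corner_centered_symmetry_and_oracle(self):
        geom = VeinGeometry((3.5, 3.5), (1.3, 1.3), 1.3)
        pv = rasterize_ellipse_pv(geom, (8, 8))
        # 4-fold symmetry about the corner
        np.testing.assert_allclose(pv, pv[::-1, :][:, ::-1], atol=1e-12)
        oracle = dense_ellipse_pv((3.5, 3.5), 1.3, 1.3, 0.0, (8, 8), n=512)
        # midpoint sub-sampling error scales as 1/subsample along the rim
        assert np.max(np.abs(pv - oracle)) < 2e-3
        fine = rasterize_ellipse_pv(geom, (8, 8), subsample=64)
        assert np.max(np.abs(fine - oracle)) < 1e-3

    def test_area_sum(self):
        geom = VeinGeometry((4.2, 3.7), (1.7, 1.1), 1.4, inplane=0.4)
        pv = rasterize_ellipse_pv(geom, (9, 9))
        assert pv.sum() == pytest.approx(math.pi * 1.7 * 1.1, rel=0.01)
        assert pv.min() >= 0.0 and pv.max() <= 1.0


class TestChiVeinAndFitError:
    def test_exact_model_inversion(self):
        pv = dense_ellipse_pv((4.1, 3.8), 1.4, 1.4, 0.0, (9, 9), n=128)
        pixels = mixture_slice(pv, 0.30, 0.0)
        assert estimate_chi_vein(pixels, pv, 0.0) == pytest.approx(0.30, abs=1e-12)

    def test_single_voxel(self):
        pv = np.zeros((3, 3))
        pv[1, 1] = 1.0
        pixels = np.zeros((3, 3))
        pixels[1, 1] = 0.42
        assert estimate_chi_vein(pixels, pv, 0.0) == pytest.approx(0.42)

    def test_zero_pv_raises(self):
        with pytest.raises(MaskError):
            estimate_chi_vein(np.zeros((3, 3)), np.zeros((3, 3)), 0.0)

    def test_monte_carlo_unbiasedness(self):
        pv = dense_ellipse_pv((4.0, 4.0), 1.3, 1.3, 0.0, (9, 9), n=64)
        clean = mixture_slice(pv, 0.30, 0.05)
        rng = np.random.default_rng(123)
        n_rep, sigma = 10_000, 0.02
        noise = rng.normal(scale=sigma, size=(n_rep,) + pv.shape)
        denom = (pv * pv).sum()
        ests = ((pv * (clean + noise - 0.05 * (1 - pv))).sum(axis=(1, 2))) / denom
        se = ests.std(ddof=1) / math.sqrt(n_rep)
        assert abs(ests.mean() - 0.30) < 2 * se + 1e-12

    def test_perfect_reconstruction_zero_error(self):
        pv = dense_ellipse_pv((4.0, 4.0), 1.2, 1.2, 0.0, (9, 9), n=64)
        pixels = mixture_slice(pv, 0.3, 0.1)
        assert fit_error(pixels, pv, 0.3, 0.1) == pytest.approx(0.0, abs=1e-24)

    def test_single_voxel_residual(self):
        pv = np.zeros((1, 1))
        pv[0, 0] = 1.0
        assert fit_error(np.array([[0.4]]), pv, 0.3, 0.0) == pytest.approx(0.01)

    def test_direct_loop_oracle(self):
        rng = np.random.default_rng(5)
        pv = rng.uniform(size=(6, 6))
        pv[pv < 0.3] = 0.0
        pixels = rng.normal(size=(6, 6))
        got = fit_error(pixels, pv, 0.27, 0.03)
        acc, n = 0.0, 0
        for i in range(6):
            for j in range(6):
                if pv[i, j] > 0:
                    model = 0.27 * pv[i, j] + 0.03 * (1 - pv[i, j])
                    acc += (pixels[i, j] - model) ** 2
                    n += 1
        assert got == pytest.approx(acc / n, rel=1e-12)


class TestFitSlice:
    @pytest.mark.parametrize("center", [(7.0, 7.0), (7.31, 6.78), (6.62, 7.45)])
    def test_noiseless_disk_recovery(self, center):
        sec, _ = disk_section(center, 1.3, (15, 15), chi_bg=0.02)
        res = fit_slice(sec)
        assert res.valid
        assert res.geometry.radius == pytest.approx(1.3, rel=0.03)
        assert math.hypot(
            res.geometry.center[0] - center[0], res.geometry.center[1] - center[1]
        ) < 0.05
        assert res.chi_vein == pytest.approx(0.30, abs=0.01)

    def test_small_vein_no_crash(self):
        sec, _ = disk_section((7.2, 7.1), 0.5, (15, 15))
        res = fit_slice(sec)  # sub-grid-crossing regime: flagged, not fatal
        assert isinstance(res.converged, bool)

    def test_tilted_ellipse_recovery(self):
        R, t, phi = 1.3, math.radians(30), math.radians(20)
        pv = dense_ellipse_pv(
            (7.2, 6.9), R / math.cos(t), R, phi, (15, 15), n=256
        )
        from scipy.ndimage import binary_dilation

        init = binary_dilation(pv > 0, iterations=2)
        sec = CrossSection(
            pixels=mixture_slice(pv, 0.30, 0.0),
            init_mask=init,
            background_roi=~init,
        )
        res = fit_slice(sec, tilt=t, inplane=phi)
        assert res.geometry.radius == pytest.approx(R, rel=0.05)

    def test_deterministic(self):
        sec, _ = disk_section((7.1, 7.3), 1.4, (15, 15), chi_bg=0.03)
        r1 = fit_slice(sec)
        r2 = fit_slice(sec)
        assert r1.chi_vein == r2.chi_vein
        np.testing.assert_array_equal(r1.pv_map, r2.pv_map)
        assert r1.geometry == r2.geometry


def _cylinder_volume(n, nz, center, radius, tilt, inplane, chi_v=0.30, chi_bg=0.02):
    """Analytic mixture volume of a straight tilted cylinder (no recon)."""
    vol = np.zeros((n, n, nz))
    mask = np.zeros((n, n, nz), bool)
    zmid = nz // 2
    a, b = radius / math.cos(tilt), radius
    for k in range(nz):
        cx = center[0] + math.tan(tilt) * math.cos(inplane) * (k - zmid)
        cy = center[1] + math.tan(tilt) * math.sin(inplane) * (k - zmid)
        pv = dense_ellipse_pv((cx, cy), a, b, inplane, (n, n), n=64)
        vol[:, :, k] = mixture_slice(pv, chi_v, chi_bg)
        mask[:, :, k] = pv > 0.5
        if not mask[:, :, k].any():
            mask[int(round(cx)), int(round(cy)), k] = True
    return vol, mask


class TestFitVeinSegment:
    def test_straight_tilted_cylinder(self):
        tilt = math.radians(30)
        vol, mask = _cylinder_volume(21, 5, (10.2, 9.8), 1.3, tilt, math.radians(15))
        seg = fit_vein_segment(vol, mask, dilate=2, mode="simulation")
        assert abs(seg.radius - 1.3) / 1.3 < 0.03
        assert abs(math.degrees(seg.tilt) - 30.0) < 3.0
        assert seg.chi_vein == pytest.approx(0.30, abs=0.02)

    def test_identical_slices_weighted_mean(self):
        vol, mask = _cylinder_volume(17, 5, (8.0, 8.0), 1.3, 0.0, 0.0)
        seg = fit_vein_segment(vol, mask, dilate=2, mode="simulation")
        radii = [fr.geometry.radius for fr in seg.per_slice if fr.valid]
        assert seg.radius == pytest.approx(radii[0], rel=1e-6)

    def test_inverse_error_weighting_discounts_bad_slice(self):
        vol, mask = _cylinder_volume(17, 5, (8.1, 8.2), 1.3, 0.0, 0.0)
        rng = np.random.default_rng(9)
        vol[:, :, 0] += rng.normal(scale=0.2, size=(17, 17))  # ruin one slice
        seg = fit_vein_segment(vol, mask, dilate=2, mode="simulation")
        good = [
            fr.geometry.radius
            for fr in seg.per_slice[1:]
            if fr.valid and fr.geometry is not None
        ]
        assert seg.radius == pytest.approx(np.mean(good), rel=0.02)

    def test_to_frame_columns(self):
        vol, mask = _cylinder_volume(17, 3, (8.0, 8.0), 1.3, 0.0, 0.0)
        seg = fit_vein_segment(vol, mask, dilate=2)
        df = seg.to_frame()
        for col in ("slice_index", "px", "py", "Rx", "Ry", "R", "chi_vein",
                    "chi_background", "eps_fit", "iterations", "converged"):
            assert col in df.columns
        assert len(df) == 3
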