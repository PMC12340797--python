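"""Radial-profile reduction: centering, binning, normalization, ratio, band."""

import numpy as np
import pytest

from capsheet.diffraction import (
    DiffractionFrame,
    EmptyBandError,
    IncompatibleProfilesError,
    NoSignalError,
    background_ratio,
    detect_band,
    find_center,
    full_partial_background_run,
    normalize_band,
    radial_average,
)
from capsheet.phantoms import DiffractionPhantomSpec, generate_diffraction_frame

from conftest import OCP_BAND


def flat_frame(value=5.0, size=64, q_nyq=1.75):
    return DiffractionFrame(np.full((size, size), value), q_nyquist_invA=q_nyq)


class TestFindCenter:
    def test_all_zero_raises(self):
        with pytest.raises(NoSignalError, match="no signal"):
            find_center(DiffractionFrame(np.zeros((64, 64)), 1.75))

    def test_uniform_frame_gives_geometric_center(self):
        assert find_center(flat_frame()) == pytest.approx((31.5, 31.5))

    def test_centered_phantom(self):
        frame, truth = generate_diffraction_frame(DiffractionPhantomSpec(seed=0))
        est = find_center(frame)
        assert est == pytest.approx(truth.true_center_px, abs=0.5)

    def test_offset_phantom(self, diffraction_pair):
        (target, t_truth), _ = diffraction_pair
        est = find_center(target)
        assert est == pytest.approx(t_truth.true_center_px, abs=0.5)


class TestRadialAverage:
    def test_uniform_frame_flat_profile(self):
        prof = radial_average(flat_frame(value=3.0), center=(31.5, 31.5))
        occupied = prof.n_pixels > 0
        assert np.allclose(prof.mean_intensity[occupied], 3.0)

    def test_pixel_conservation(self):
        frame = flat_frame(size=48)
        center = (23.5, 23.5)
        prof = radial_average(frame, center)
        rr, cc = np.mgrid[0:48, 0:48]
        q = np.hypot(rr - center[0], cc - center[1]) * 1.75 / 24.0
        assert prof.n_pixels.sum() == (q <= 1.75).sum()

    def test_matches_brute_force_accumulation(self):
        rng = np.random.default_rng(3)
        img = rng.random((32, 32))
        frame = DiffractionFrame(img, q_nyquist_invA=1.75)
        center = (15.0, 16.0)
        n_bins = 16
        prof = radial_average(frame, center, n_bins=n_bins)
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins, dtype=int)
        dq = 1.75 / n_bins
        for r in range(32):
            for c in range(32):
                q = np.hypot(r - center[0], c - center[1]) * 1.75 / 16.0
                if q > 1.75:
                    continue
                b = min(int(q / dq), n_bins - 1)
                sums[b] += img[r, c]
                counts[b] += 1
        assert np.array_equal(prof.n_pixels, counts)
        occ = counts > 0
        assert np.allclose(prof.mean_intensity[occ], sums[occ] / counts[occ])

    def test_rotation_invariance(self):
        frame, truth = generate_diffraction_frame(
            DiffractionPhantomSpec(bands=(OCP_BAND,), seed=4)
        )
        center = truth.true_center_px
        p1 = radial_average(frame, center)
        rotated = DiffractionFrame(np.rot90(frame.intensities, 2), 1.75)
        h, w = frame.intensities.shape
        rot_center = (h - 1 - center[0], w - 1 - center[1])
        p2 = radial_average(rotated, rot_center)
        assert np.array_equal(p1.n_pixels, p2.n_pixels)
        occ = p1.n_pixels > 0
        assert np.allclose(p1.mean_intensity[occ], p2.mean_intensity[occ])

    def test_band_argmax_at_injected_q(self):
        frame, truth = generate_diffraction_frame(
            DiffractionPhantomSpec(bands=(OCP_BAND,), ice_peaks=(), seed=0)
        )
        prof = radial_average(frame, truth.true_center_px)
        occ = prof.n_pixels > 0
        excess = np.where(occ, prof.mean_intensity - 100.0, -np.inf)
        q_peak = prof.q_bin_centers[np.argmax(excess)]
        dq = prof.q_bin_centers[1] - prof.q_bin_centers[0]
        assert abs(q_peak - 1 / 2.85) <= dq

    def test_calibration_q_to_d(self):
        prof = radial_average(flat_frame(q_nyq=1.75), center=(31.5, 31.5))
        q_target = 0.75 * 1.75
        i = np.argmin(np.abs(prof.q_bin_centers - q_target))
        dq = prof.q_bin_centers[1] - prof.q_bin_centers[0]
        assert 1.0 / prof.q_bin_centers[i] == pytest.approx(
            1.0 / (0.75 * 1.75), abs=1.0 / q_target**2 * dq
        )


class TestNormalizeBand:
    def test_band_mean_becomes_one_and_idempotent(self):
        frame, truth = generate_diffraction_frame(DiffractionPhantomSpec(seed=5))
        prof = radial_average(frame, truth.true_center_px)
        norm = normalize_band(prof)
        in_band = (
            (norm.q_bin_centers >= 0.094)
            & (norm.q_bin_centers <= 0.113)
            & (norm.n_pixels > 0)
        )
        assert np.nanmean(norm.mean_intensity[in_band]) == pytest.approx(1.0, abs=1e-9)
        again = normalize_band(norm)
        assert np.allclose(
            again.mean_intensity[norm.n_pixels > 0],
            norm.mean_intensity[norm.n_pixels > 0],
        )

    def test_scale_invariance(self):
        frame, truth = generate_diffraction_frame(DiffractionPhantomSpec(seed=6))
        prof = radial_average(frame, truth.true_center_px)
        scaled = radial_average(
            DiffractionFrame(frame.intensities * 7.3, 1.75), truth.true_center_px
        )
        occ = prof.n_pixels > 0
        assert np.allclose(
            normalize_band(prof).mean_intensity[occ],
            normalize_band(scaled).mean_intensity[occ],
        )

    def test_background_only_band_normalizes_background_to_one(self):
        frame, truth = generate_diffraction_frame(
            DiffractionPhantomSpec(background_level=42.0, seed=7)
        )
        prof = normalize_band(radial_average(frame, truth.true_center_px))
        # the 0.094-0.113 1/A band contains only flat background here, so
        # background bins away from any peak normalize to ~1
        occ = prof.n_pixels > 0
        q = prof.q_bin_centers
        far = occ & (q > 1.0)  # many sigma beyond both ice halos
        assert np.nanmedian(prof.mean_intensity[far]) == pytest.approx(1.0, rel=1e-3)

    def test_empty_band_raises(self):
        prof = radial_average(flat_frame(), center=(31.5, 31.5))
        with pytest.raises(EmptyBandError, match="unoccupied"):
            normalize_band(prof, 1.7401, 1.7402)


class TestBackgroundRatioAndBand:
    def test_identity_ratio(self):
        frame, truth = generate_diffraction_frame(DiffractionPhantomSpec(seed=8))
        prof = normalize_band(radial_average(frame, truth.true_center_px))
        ratio = background_ratio(prof, prof)
        assert np.allclose(ratio.ratio[~ratio.mask], 1.0)
        assert np.allclose(ratio.d_A[~ratio.mask], 1.0 / ratio.q_invA[~ratio.mask])

    def test_binning_mismatch_rejected(self):
        frame, truth = generate_diffraction_frame(DiffractionPhantomSpec(seed=8))
        p1 = normalize_band(radial_average(frame, truth.true_center_px, n_bins=64))
        p2 = normalize_band(radial_average(frame, truth.true_center_px, n_bins=128))
        with pytest.raises(IncompatibleProfilesError):
            background_ratio(p1, p2)

    def test_ice_suppressed_band_detected(self, diffraction_pair):
        (target, t_truth), (background, b_truth) = diffraction_pair
        pt = normalize_band(radial_average(target, t_truth.true_center_px))
        pb = normalize_band(radial_average(background, b_truth.true_center_px))
        ratio = background_ratio(pt, pb)
        for d_ice in (3.71, 2.15):
            i = np.argmin(np.abs(ratio.d_A - d_ice))
            assert ratio.ratio[i] == pytest.approx(1.0, abs=0.05)
        band = detect_band(ratio)
        assert band.band_present
        dq = ratio.q_invA[1] - ratio.q_invA[0]
        assert abs(1 / band.peak_d_A - 1 / 2.85) <= dq

    def test_flat_ratio_reports_no_band(self):
        frame, truth = generate_diffraction_frame(DiffractionPhantomSpec(seed=9))
        prof = normalize_band(radial_average(frame, truth.true_center_px))
        band = detect_band(background_ratio(prof, prof))
        assert not band.band_present

    def test_ice_only_target_reports_no_band_in_window(self):
        """Matched ice halos in target and background cancel: nothing in
        the 2.5-3.2 A window should be called a band."""
        t, tt = generate_diffraction_frame(DiffractionPhantomSpec(seed=10))
        b, bt = generate_diffraction_frame(DiffractionPhantomSpec(seed=11))
        pt = normalize_band(radial_average(t, tt.true_center_px))
        pb = normalize_band(radial_average(b, bt.true_center_px))
        band = detect_band(background_ratio(pt, pb))
        assert not band.band_present

    def test_masked_bins_never_enter_detection(self):
        frame, truth = generate_diffraction_frame(DiffractionPhantomSpec(seed=12))
        prof = normalize_band(radial_average(frame, truth.true_center_px))
        # zero the background over the whole detection window -> all masked
        broken = background_ratio(
            prof,
            type(prof)(
                q_bin_centers=prof.q_bin_centers,
                mean_intensity=np.where(
                    (prof.q_bin_centers > 1 / 3.2) & (prof.q_bin_centers < 1 / 2.5),
                    0.0,
                    prof.mean_intensity,
                ),
                n_pixels=prof.n_pixels,
                normalization_band=prof.normalization_band,
            ),
        )
        with pytest.raises(EmptyBandError, match="window unoccupied"):
            detect_band(broken)


class TestFullPartialBackgroundRun:
    def test_identical_frames_give_unit_ratios(self):
        frame, _ = generate_diffraction_frame(DiffractionPhantomSpec(seed=13))
        result = full_partial_background_run(frame, frame, frame)
        assert np.allclose(result.full_ratio.ratio[~result.full_ratio.mask], 1.0)
        assert not result.full_band.band_present

    def test_full_stronger_than_partial(self):
        d, w, a = 2.85, 0.15, 40.0
        full, _ = generate_diffraction_frame(
            DiffractionPhantomSpec(bands=((d, w, a),), seed=14)
        )
        partial, _ = generate_diffraction_frame(
            DiffractionPhantomSpec(bands=((d, w, a / 4),), seed=15)
        )
        background, _ = generate_diffraction_frame(DiffractionPhantomSpec(seed=16))
        result = full_partial_background_run(full, partial, background)
        i = np.argmin(np.abs(result.full_ratio.d_A - d))
        assert result.full_ratio.ratio[i] > result.partial_ratio.ratio[i] > 1.0

    def test_d_axis_decreasing(self, diffraction_pair):
        (target, _), (background, _) = diffraction_pair
        result = full_partial_background_run(target, target, background)
        d = result.full_ratio.d_A
        finite = np.isfinite(d)
        assert np.all(np.diff(d[finite]) < 0)
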