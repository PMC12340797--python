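"""LDSAED radial-profile analysis.

Reduces 2D low-dose selected-area electron diffraction frames to calibrated
radial profiles and summarizes the diagnostic calcium-phosphate band:

1. beam-center estimation (intensity centroid refined by 180-degree
   rotational-symmetry correlation),
2. azimuthal (radial) averaging on a linear q axis anchored to the Nyquist
   spatial frequency at half the image width,
3. normalization on a reference q band (default 0.094-0.113 1/A) so frames
   of different exposure are mutually comparable,
4. division of a target profile by a nearby background profile, which
   dampens non-specific structure shared by both — notably the vitreous-ice
   halos near d = 3.71 and 2.15 A,
5. conversion to d-spacing (d = 1/q) and detection of a broad band in a
   d window (default 2.5-3.2 A, where OCP-like plates diffract).

No crystallographic indexing or structure-factor modeling is attempted: the
module detects and localizes bands only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

DEFAULT_NORM_BAND = (0.094, 0.113)
DEFAULT_BAND_WINDOW_D = (2.5, 3.2)
DEFAULT_CENTRAL_EXCLUSION_Q = 0.03
DEFAULT_SMOOTH_WIDTH_BINS = 3
DEFAULT_BAND_MARGIN = 0.05


class NoSignalError(ValueError):
    """Frame carries no intensity to center on."""


class IncompatibleProfilesError(ValueError):
    """Two profiles do not share binning / normalization."""


class EmptyBandError(ValueError):
    """A required q band or d window contains no occupied bins."""


@dataclass
class DiffractionFrame:
    """A 2D diffraction frame with q calibration.

    ``q_nyquist_invA`` is the spatial frequency (1/A) reached at half the
    image width; q is linear in pixel radius. ``center_px`` optionally
    carries a known beam center (row, col).
    """

    intensities: np.ndarray
    q_nyquist_invA: float
    camera_length_mm: float | None = None
    center_px: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2 or self.intensities.size == 0:
            raise ValueError("intensities must be a non-empty 2D grid")
        if not self.q_nyquist_invA > 0:
            raise ValueError("q_nyquist_invA must be positive")
        if self.center_px is not None:
            r, c = self.center_px
            h, w = self.intensities.shape
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError("center_px lies outside the grid")


@dataclass
class RadialProfile:
    """Azimuthal average: mean intensity per q bin with bin occupancy."""

    q_bin_centers: np.ndarray
    mean_intensity: np.ndarray
    n_pixels: np.ndarray
    normalization_band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.q_bin_centers = np.asarray(self.q_bin_centers, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        self.n_pixels = np.asarray(self.n_pixels, dtype=int)
        if not np.all(np.diff(self.q_bin_centers) > 0):
            raise ValueError("q_bin_centers must be strictly increasing")


@dataclass
class RatioProfile:
    """Target/background intensity ratio on a shared q (and d = 1/q) axis.

    ``mask`` flags bins excluded because either profile was unoccupied or
    the background fell below the division floor; masked bins carry NaN and
    never enter band detection.
    """

    q_invA: np.ndarray
    d_A: np.ndarray
    ratio: np.ndarray
    mask: np.ndarray
    normalization_band: tuple[float, float] | None = None


@dataclass
class BandSummary:
    """Location and strength of the strongest band in a d window."""

    window_d_A: tuple[float, float]
    peak_d_A: float
    peak_ratio: float
    band_present: bool


def find_center(
    frame: DiffractionFrame,
    search_radius_px: float = 5.0,
    search_step_px: float = 0.5,
) -> tuple[float, float]:
    """Estimate the beam center of a diffraction frame.

    A first guess is the intensity-weighted centroid over the central
    quarter of the image (half extent in each dimension). It is refined by
    maximizing the Pearson correlation between the frame and its
    180-degree rotation about the candidate center, over a +/-5 px grid at
    0.5 px steps — a diffraction pattern of a (quasi-)powder is symmetric
    under inversion through the beam center.

    Raises :class:`NoSignalError` on an all-zero frame. On a degenerate
    (constant) frame the centroid is returned unrefined.
    """
    img = frame.intensities
    h, w = img.shape
    if not np.any(img):
        raise NoSignalError("no signal")

    r0, r1 = h // 4, h - h // 4
    c0, c1 = w // 4, w - w // 4
    crop = img[r0:r1, c0:c1]
    total = crop.sum()
    if total <= 0:
        cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    else:
        rr, cc_idx = np.mgrid[r0:r1, c0:c1]
        cr = float((rr * crop).sum() / total)
        cc = float((cc_idx * crop).sum() / total)

    rr_full, cc_full = np.mgrid[0:h, 0:w]
    flat = img.ravel()
    offsets = np.arange(-search_radius_px, search_radius_px + search_step_px / 2,
                        search_step_px)
    best = (-np.inf, (cr, cc))
    for dr in offsets:
        for dc in offsets:
            cand_r, cand_c = cr + dr, cc + dc
            rot_r = 2.0 * cand_r - rr_full
            rot_c = 2.0 * cand_c - cc_full
            inside = (
                (rot_r >= 0) & (rot_r <= h - 1) & (rot_c >= 0) & (rot_c <= w - 1)
            )
            if inside.sum() < 16:
                continue
            rot = ndimage.map_coordinates(
                img, [rot_r[inside], rot_c[inside]], order=1
            )
            orig = flat[inside.ravel()]
            so, sr = orig.std(), rot.std()
            if so == 0 or sr == 0:
                continue
            score = float(np.mean((orig - orig.mean()) * (rot - rot.mean())) / (so * sr))
            if score > best[0]:
                best = (score, (cand_r, cand_c))
    return best[1]


def radial_average(
    frame: DiffractionFrame,
    center: tuple[float, float],
    n_bins: int | None = None,
) -> RadialProfile:
    """Azimuthally average a frame into equal-width q bins from 0 to Nyquist.

    A pixel at Euclidean radius r (px, from pixel centers) maps to
    ``q = r * q_nyquist_invA / (image_width / 2)``; pixels beyond the
    Nyquist frequency are dropped. Default bin count is one bin per pixel
    of radial extent (half the image width).
    """
    img = frame.intensities
    h, w = img.shape
    cr, cc = center
    if not (0 <= cr < h and 0 <= cc < w):
        raise ValueError("center lies outside the grid")
    if n_bins is None:
        n_bins = w // 2
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    rr, ccol = np.mgrid[0:h, 0:w]
    q = np.hypot(rr - cr, ccol - cc) * frame.q_nyquist_invA / (w / 2.0)
    keep = q <= frame.q_nyquist_invA
    dq = frame.q_nyquist_invA / n_bins
    idx = np.minimum((q[keep] / dq).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=img[keep], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) * dq
    return RadialProfile(q_bin_centers=centers, mean_intensity=means, n_pixels=counts)


def normalize_band(
    profile: RadialProfile,
    q_lo: float = DEFAULT_NORM_BAND[0],
    q_hi: float = DEFAULT_NORM_BAND[1],
) -> RadialProfile:
    """Divide a profile by its mean intensity over the [q_lo, q_hi] band.

    After normalization the mean of ``mean_intensity`` over occupied bins in
    the band equals 1, making separately exposed frames comparable. Scale
    invariant: profiles differing by a positive factor normalize
    identically.
    """
    in_band = (
        (profile.q_bin_centers >= q_lo)
        & (profile.q_bin_centers <= q_hi)
        & (profile.n_pixels > 0)
    )
    if not in_band.any():
        raise EmptyBandError("normalization band unoccupied")
    band_mean = float(np.nanmean(profile.mean_intensity[in_band]))
    if band_mean == 0:
        raise EmptyBandError("degenerate normalization")
    return replace(
        profile,
        mean_intensity=profile.mean_intensity / band_mean,
        normalization_band=(q_lo, q_hi),
    )


def background_ratio(
    target: RadialProfile,
    background: RadialProfile,
    background_floor_frac: float = 1e-6,
) -> RatioProfile:
    """Divide a target profile by a background profile, bin by bin.

    Both profiles must share q binning and normalization band. Bins
    unoccupied in either profile, or where the background falls below
    ``background_floor_frac`` times the background's normalization-band
    mean, are masked rather than fabricated. The d axis (d = 1/q) is
    attached for band detection.
    """
    if (
        target.q_bin_centers.shape != background.q_bin_centers.shape
        or not np.allclose(target.q_bin_centers, background.q_bin_centers)
        or target.normalization_band != background.normalization_band
    ):
        raise IncompatibleProfilesError("incompatible profiles")

    q = target.q_bin_centers
    band = target.normalization_band
    if band is not None:
        in_band = (q >= band[0]) & (q <= band[1]) & (background.n_pixels > 0)
        band_mean = float(np.nanmean(background.mean_intensity[in_band]))
    else:
        band_mean = float(np.nanmean(background.mean_intensity))
    floor = background_floor_frac * band_mean

    bad = (
        (target.n_pixels == 0)
        | (background.n_pixels == 0)
        | ~np.isfinite(target.mean_intensity)
        | ~np.isfinite(background.mean_intensity)
        | (background.mean_intensity < floor)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(bad, np.nan, target.mean_intensity / background.mean_intensity)
        d = np.where(q > 0, 1.0 / q, np.inf)
    return RatioProfile(
        q_invA=q, d_A=d, ratio=ratio, mask=bad, normalization_band=band
    )


def detect_band(
    ratio: RatioProfile,
    window_d_A: tuple[float, float] = DEFAULT_BAND_WINDOW_D,
    smooth_width_bins: int = DEFAULT_SMOOTH_WIDTH_BINS,
    margin: float = DEFAULT_BAND_MARGIN,
    central_exclusion_q: float = DEFAULT_CENTRAL_EXCLUSION_Q,
) -> BandSummary:
    """Locate the strongest band of a ratio profile inside a d window.

    The ratio is smoothed with a centered moving average over unmasked bins
    (masked bins are skipped, not zero-filled) before peak-picking: the
    bands of poorly ordered material are broad, so a single-bin argmax would
    be noise-dominated. The peak is the smoothed maximum within the window;
    ties resolve to the lowest-d bin. ``band_present`` requires the peak
    ratio to exceed ``1 + margin``.
    """
    lo_d, hi_d = window_d_A
    if not lo_d < hi_d:
        raise ValueError("window lo must be < hi")
    valid = ~ratio.mask & np.isfinite(ratio.ratio) & (ratio.q_invA >= central_exclusion_q)

    # moving average over valid bins only
    half = smooth_width_bins // 2
    n = len(ratio.ratio)
    smoothed = np.full(n, np.nan)
    vals = np.where(valid, ratio.ratio, 0.0)
    cnt = valid.astype(float)
    kernel = np.ones(2 * half + 1)
    ssum = np.convolve(vals, kernel, mode="same")
    scnt = np.convolve(cnt, kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = np.where(scnt > 0, ssum / scnt, np.nan)

    in_window = valid & (ratio.d_A >= lo_d) & (ratio.d_A <= hi_d)
    if not in_window.any():
        raise EmptyBandError("window unoccupied")
    cand = np.where(in_window, smoothed, -np.inf)
    peak_val = np.nanmax(cand[in_window])
    # ties: lowest d = highest q = highest index
    peak_idx = int(np.flatnonzero(cand == peak_val)[-1])
    return BandSummary(
        window_d_A=window_d_A,
        peak_d_A=float(ratio.d_A[peak_idx]),
        peak_ratio=float(peak_val),
        band_present=bool(peak_val > 1.0 + margin),
    )


@dataclass
class FullPartialResult:
    """Output of :func:`full_partial_background_run`."""

    full_ratio: RatioProfile
    partial_ratio: RatioProfile
    full_band: BandSummary
    centers: dict = field(default_factory=dict)


def full_partial_background_run(
    full: DiffractionFrame,
    partial: DiffractionFrame,
    background: DiffractionFrame,
    n_bins: int | None = None,
    norm_band: tuple[float, float] = DEFAULT_NORM_BAND,
    window_d_A: tuple[float, float] = DEFAULT_BAND_WINDOW_D,
) -> FullPartialResult:
    """Run the full/partial/background LDSAED comparison.

    Centers, radially averages, and band-normalizes each frame; divides the
    full and partial profiles by the background profile; detects the band
    in the full-frame ratio. ``full`` is a frame with an aggregate centered
    in the aperture, ``partial`` one with only a little aggregate visible,
    ``background`` a nearby control region.
    """
    if not (
        full.q_nyquist_invA == partial.q_nyquist_invA == background.q_nyquist_invA
    ):
        raise IncompatibleProfilesError("frames do not share calibration")
    profiles = {}
    centers = {}
    for name, frame in (("full", full), ("partial", partial), ("background", background)):
        center = frame.center_px if frame.center_px is not None else find_center(frame)
        centers[name] = center
        prof = radial_average(frame, center, n_bins=n_bins)
        profiles[name] = normalize_band(prof, *norm_band)
    full_ratio = background_ratio(profiles["full"], profiles["background"])
    partial_ratio = background_ratio(profiles["partial"], profiles["background"])
    full_band = detect_band(full_ratio, window_d_A=window_d_A)
    return FullPartialResult(
        full_ratio=full_ratio,
        partial_ratio=partial_ratio,
        full_band=full_band,
        centers=centers,
    )
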