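"""Synthetic phantoms with exact ground truth.

Three generators emulate the data the analysis stages consume:

* micrographs with dark sheet-like aggregates — thin calcium-phosphate
  plates seen edge-on project as curvilinear fiber-like strokes — placed
  inside elliptical membrane-bounded regions on a noisy background;
* radially symmetric electron diffraction frames with Gaussian bands at
  chosen d-spacings plus the vitreous-ice halos near 3.71 and 2.15 Angstrom;
* per-condition aggregate-area tables drawn from log-normal laws with
  requested medians.

Every generator is a pure function of (spec, seed): identical inputs yield
bit-identical outputs. No image physics is simulated (no CTF, no multislice
scattering); the phantoms exist to give each downstream stage a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from capsheet.area_quant import RegionMask


class PlacementError(RuntimeError):
    """Requested aggregates could not be placed without overlap."""


class BandBeyondNyquistError(ValueError):
    """A requested diffraction band lies outside the resolvable q range."""


@dataclass
class SheetPhantomSpec:
    """Parameters of a synthetic sheet-aggregate micrograph.

    Defaults mirror the acquisition this emulates: 3.21 A/px pixel size and
    ~1.85 nm true plate thickness. ``apparent_width_nm`` widens the drawn
    strokes (tilted or defocus-blurred plates can appear up to ~7 nm wide).
    ``aggregate_contrast`` is the intensity depression of sheet pixels below
    ``background_level``; ``noise_sigma`` is additive Gaussian noise, with the
    default at 10% of the contrast. ``rect_stroke_px`` replaces the random
    curvilinear strokes with a single axis-aligned rectangle of the given
    (height, width) in px per aggregate, for exact-area tests.
    """

    image_size_px: tuple[int, int] = (256, 256)
    pixel_size_A: float = 3.21
    n_aggregates: int = 3
    sheet_thickness_nm: float = 1.85
    apparent_width_nm: float | None = None
    aggregate_contrast: float = 40.0
    background_level: float = 100.0
    noise_sigma: float = 4.0
    blur_sigma_px: float = 0.0
    rect_stroke_px: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        if h < 32 or w < 32:
            raise ValueError("image_size_px must be >= 32 in each dimension")
        if not (self.pixel_size_A > 0 and self.sheet_thickness_nm > 0):
            raise ValueError("pixel_size_A and sheet_thickness_nm must be positive")
        if self.n_aggregates < 0:
            raise ValueError("n_aggregates must be non-negative")
        if self.noise_sigma < 0 or self.blur_sigma_px < 0:
            raise ValueError("noise_sigma and blur_sigma_px must be >= 0")

    @property
    def stroke_width_px(self) -> float:
        width_nm = (
            self.apparent_width_nm
            if self.apparent_width_nm is not None
            else self.sheet_thickness_nm
        )
        return width_nm / (self.pixel_size_A / 10.0)


@dataclass
class DiffractionPhantomSpec:
    """Parameters of a synthetic radially symmetric diffraction frame.

    Bands and ice peaks are ``(center_d_A, width_d_A, amplitude)`` triples;
    widths are Gaussian sigmas in d-space, converted to q-space at the band
    center. ``q_nyquist_invA`` is the spatial frequency reached at half the
    image width (default 1.75 1/A, the 670 mm camera-length calibration).
    Default ice peaks sit at the vitreous-ice halos, 3.71 and 2.15 A.
    """

    image_size_px: tuple[int, int] = (256, 256)
    q_nyquist_invA: float = 1.75
    bands: tuple[tuple[float, float, float], ...] = ()
    ice_peaks: tuple[tuple[float, float, float], ...] = (
        (3.71, 0.35, 60.0),
        (2.15, 0.12, 35.0),
    )
    center_offset_px: tuple[float, float] = (0.0, 0.0)
    background_level: float = 100.0
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        if h < 32 or w < 32:
            raise ValueError("image_size_px must be >= 32 in each dimension")
        if not self.q_nyquist_invA > 0:
            raise ValueError("q_nyquist_invA must be positive")
        if self.background_level < 0:
            raise ValueError("background_level must be non-negative")
        for center_d, width_d, amp in tuple(self.bands) + tuple(self.ice_peaks):
            if not center_d > 0 or not width_d > 0:
                raise ValueError("band centers and widths must be positive")
            if amp < 0:
                raise ValueError("band amplitudes must be >= 0")
            if not 0 < 1.0 / center_d < self.q_nyquist_invA:
                raise BandBeyondNyquistError(
                    f"band beyond Nyquist: d={center_d} A gives "
                    f"q={1.0 / center_d:.3f} >= {self.q_nyquist_invA} 1/A"
                )


@dataclass
class GroundTruth:
    """Exact answers recorded by a generator for downstream comparison."""

    masks: list[RegionMask] = field(default_factory=list)
    true_area_px: list[int] = field(default_factory=list)
    true_area_nm2: list[float] = field(default_factory=list)
    true_band_centers_d_A: list[float] = field(default_factory=list)
    true_center_px: tuple[float, float] | None = None
    label_image: np.ndarray | None = None


def _ellipse_mask(shape, center, semi_axes, angle):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / semi_axes[0]) ** 2 + (v / semi_axes[1]) ** 2 <= 1.0


def _random_walk_strokes(rng, inner, width_px, target_fraction=0.35):
    """Draw curvilinear strokes inside ``inner`` until they fill roughly
    ``target_fraction`` of it; returns the stroke boolean image."""
    stroke_pts = np.zeros_like(inner)
    area_target = target_fraction * inner.sum()
    radius = max(width_px / 2.0, 0.5)
    # structuring element for dilation to stroke width
    r_int = int(np.ceil(radius))
    yy, xx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    disk = yy**2 + xx**2 <= radius**2
    rows, cols = np.nonzero(inner)
    per_point = disk.sum()  # rough area contribution of one walk step
    max_steps = int(area_target / max(per_point, 1) * 8) + 50
    for _ in range(12):  # up to 12 strokes per aggregate
        start = rng.integers(0, len(rows))
        r, c = float(rows[start]), float(cols[start])
        heading = rng.uniform(0, 2 * np.pi)
        for _ in range(max_steps):
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < inner.shape[0] and 0 <= ci < inner.shape[1]):
                break
            if not inner[ri, ci]:
                break
            stroke_pts[ri, ci] = True
            heading += rng.normal(0.0, 0.18)
            r += np.sin(heading)
            c += np.cos(heading)
        stroke = ndimage.binary_dilation(stroke_pts, structure=disk)
        if (stroke & inner).sum() >= area_target:
            break
    return ndimage.binary_dilation(stroke_pts, structure=disk) & inner


def generate_sheet_micrograph(spec: SheetPhantomSpec):
    """Render a sheet-aggregate micrograph and its exact ground truth.

    Each aggregate is a set of dark curvilinear strokes of width
    ``spec.stroke_width_px`` inside an elliptical membrane-bounded region;
    ellipses do not overlap each other or the image border. The ground truth
    records, per aggregate, the elliptical region mask and the exact set of
    pixels depressed below background *before* blur and noise.

    Returns
    -------
    (Micrograph, GroundTruth)

    Raises
    ------
    PlacementError
        If the requested number of aggregates cannot be placed without
        overlap after bounded retries ("placement failure").
    """
    from capsheet.area_quant import Micrograph  # local import avoids cycle at init

    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    img = np.full((h, w), float(spec.background_level))
    occupied = np.zeros((h, w), dtype=bool)
    label_image = np.zeros((h, w), dtype=np.int32)
    truth = GroundTruth(label_image=label_image)
    pixel_area_nm2 = (spec.pixel_size_A / 10.0) ** 2

    min_dim = min(h, w)
    for i in range(spec.n_aggregates):
        placed = False
        for _ in range(200):
            a = rng.uniform(0.08, 0.16) * min_dim
            b = rng.uniform(0.08, 0.16) * min_dim
            margin = max(a, b) + 2
            center = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
            angle = rng.uniform(0, np.pi)
            ellipse = _ellipse_mask((h, w), center, (a, b), angle)
            if not (ellipse & occupied).any():
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"placement failure: could not place aggregate {i + 1} "
                f"of {spec.n_aggregates}"
            )
        occupied |= ellipse
        # keep strokes off the ellipse boundary so the mask has a background rim
        inner = _ellipse_mask((h, w), center, (a * 0.8, b * 0.8), angle)
        if spec.rect_stroke_px is not None:
            sh, sw = spec.rect_stroke_px
            r0 = int(round(center[0] - sh / 2))
            c0 = int(round(center[1] - sw / 2))
            stroke = np.zeros((h, w), dtype=bool)
            stroke[r0 : r0 + sh, c0 : c0 + sw] = True
        else:
            stroke = _random_walk_strokes(rng, inner, spec.stroke_width_px)
        img[stroke] -= spec.aggregate_contrast
        label_image[stroke] = i + 1
        area_px = int(stroke.sum())
        truth.masks.append(RegionMask(label=i + 1, pixels=ellipse))
        truth.true_area_px.append(area_px)
        truth.true_area_nm2.append(area_px * pixel_area_nm2)

    if spec.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma_px)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)

    micrograph = Micrograph(
        intensities=img,
        pixel_size_A=spec.pixel_size_A,
        metadata={"phantom": "sheet", "seed": spec.seed},
    )
    return micrograph, truth


def generate_diffraction_frame(spec: DiffractionPhantomSpec):
    """Render a radially symmetric diffraction frame and its ground truth.

    Intensity at pixel radius r from the true center is
    ``background_level + sum_i A_i * exp(-(q(r) - 1/d_i)**2 / (2 sigma_q_i**2))``
    where ``q(r) = r * q_nyquist_invA / (image_width / 2)`` and
    ``sigma_q_i = width_d_i / d_i**2`` (first-order q<->d conversion).
    Optional Poisson noise is applied last.

    Returns ``(DiffractionFrame, GroundTruth)``.
    """
    from capsheet.diffraction import DiffractionFrame  # avoid import cycle

    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    center = ((h - 1) / 2.0 + spec.center_offset_px[0],
              (w - 1) / 2.0 + spec.center_offset_px[1])
    rr, cc = np.mgrid[0:h, 0:w]
    r = np.hypot(rr - center[0], cc - center[1])
    q = r * spec.q_nyquist_invA / (w / 2.0)

    img = np.full((h, w), float(spec.background_level))
    for center_d, width_d, amp in tuple(spec.bands) + tuple(spec.ice_peaks):
        q0 = 1.0 / center_d
        sigma_q = width_d / center_d**2
        img += amp * np.exp(-((q - q0) ** 2) / (2.0 * sigma_q**2))

    if spec.poisson_noise:
        img = rng.poisson(img).astype(float)

    frame = DiffractionFrame(
        intensities=img,
        q_nyquist_invA=spec.q_nyquist_invA,
        center_px=None,
    )
    truth = GroundTruth(
        true_band_centers_d_A=[b[0] for b in spec.bands],
        true_center_px=center,
    )
    return frame, truth


def generate_group_areas(
    group_specs: list[tuple[str, float, float, int]],
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-group aggregate areas from log-normal laws.

    ``group_specs`` is a list of ``(label, median_nm2, spread, n)`` where
    ``spread`` is the standard deviation of log-area (dimensionless). The
    log-normal median equals ``exp(mu)``, so areas are
    ``median * exp(spread * z)`` with standard-normal z. ``spread = 0``
    degenerates to all areas equal to the median.

    Returns a DataFrame with columns ``group`` and ``area_nm2``.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for label, median_nm2, spread, n in group_specs:
        if not median_nm2 > 0:
            raise ValueError(f"group {label!r}: median must be positive")
        if n < 1:
            raise ValueError(f"group {label!r}: n must be >= 1")
        if spread < 0:
            raise ValueError(f"group {label!r}: spread must be >= 0")
        z = rng.standard_normal(n)
        areas = median_nm2 * np.exp(spread * z)
        frames.append(pd.DataFrame({"group": label, "area_nm2": areas}))
    if not frames:
        return pd.DataFrame(columns=["group", "area_nm2"])
    return pd.concat(frames, ignore_index=True)
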