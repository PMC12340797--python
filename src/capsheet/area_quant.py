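"""Aggregate area measurement with a per-region adaptive threshold.

Each candidate aggregate is delimited by a hand-drawn (or phantom-generated)
binary region mask. Within the mask the pixel intensities are reduced to a
per-region threshold

    t = (max - min) - k * sigma,        k = 1.5 by default,

with ``sigma`` the population standard deviation of the masked intensities.
Aggregate material is hyper-electron-dense and therefore *darker* than
background in a bright-field micrograph, so intensities are first flipped to
positive contrast (``v' = max - v``) and anchored at zero
(``v'' = v' - min(v')``); pixels with ``v'' >= t`` are counted as aggregate.
The pixel count is converted to nm**2 using the calibrated pixel size.

The threshold sits in the upper part of the intensity range for bimodal
regions, so it selects the dense phase while rejecting background, without
assuming anything about the absolute intensity scale: the measured area is
invariant under any affine rescaling ``v -> a*v + b`` with ``a > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_STD_MULTIPLIER = 1.5


class IncongruentMaskError(ValueError):
    """Mask and micrograph shapes differ."""


class EmptyRegionError(ValueError):
    """A region mask selects no pixels."""


@dataclass
class Micrograph:
    """A calibrated 2D electron micrograph.

    Parameters
    ----------
    intensities
        2D array of pixel intensities (any real dtype).
    pixel_size_A
        Pixel size in Angstrom per pixel; must be positive.
    metadata
        Free-form acquisition metadata (defocus, dose, source file, ...).
    """

    intensities: np.ndarray
    pixel_size_A: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2 or self.intensities.size == 0:
            raise ValueError("intensities must be a non-empty 2D grid")
        if not self.pixel_size_A > 0:
            raise ValueError("pixel_size_A must be positive")

    @property
    def pixel_area_nm2(self) -> float:
        """Area of one pixel in nm**2 (pixel_size_A is Angstrom; 1 nm = 10 A)."""
        return (self.pixel_size_A / 10.0) ** 2


@dataclass
class RegionMask:
    """Binary mask marking one candidate aggregate region."""

    label: int
    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be a 2D grid")
        if not self.pixels.any():
            raise EmptyRegionError(f"mask {self.label}: empty region")


@dataclass
class AggregateMeasurement:
    """Per-region threshold and area result."""

    label: int
    n_masked_px: int
    min_intensity: float
    max_intensity: float
    std_intensity: float
    threshold: float
    area_px: int
    area_nm2: float


@dataclass
class BatchResult:
    """Outcome of :func:`measure_batch`: a table plus any per-pair failures."""

    table: pd.DataFrame
    failures: list[tuple[int, str]] = field(default_factory=list)

    @property
    def partial_failure(self) -> bool:
        return len(self.failures) > 0


def _check_congruent(micrograph: Micrograph, mask: RegionMask) -> None:
    if micrograph.intensities.shape != mask.pixels.shape:
        raise IncongruentMaskError(
            f"incongruent mask: image {micrograph.intensities.shape} "
            f"vs mask {mask.pixels.shape}"
        )


def masked_pixels(micrograph: Micrograph, mask: RegionMask) -> np.ndarray:
    """Intensities at the mask's true positions, in row-major order.

    Out-of-mask pixels are excluded entirely (they are *not* returned as
    zeros): multiplying the mask into the image would poison the region
    minimum with background zeros.
    """
    _check_congruent(micrograph, mask)
    return micrograph.intensities[mask.pixels]


def compute_threshold(
    values: Sequence[float] | np.ndarray,
    std_multiplier: float = DEFAULT_STD_MULTIPLIER,
) -> float:
    """Adaptive threshold t = (max - min) - k * sigma over a value list.

    ``sigma`` is the population standard deviation (ddof=0): it is a
    descriptive statistic of all pixels in the region, not a sample
    estimate. The result may be negative (then every pixel passes).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EmptyRegionError("empty region")
    return float(
        (values.max() - values.min()) - std_multiplier * values.std(ddof=0)
    )


def foreground_mask(
    micrograph: Micrograph,
    mask: RegionMask,
    std_multiplier: float = DEFAULT_STD_MULTIPLIER,
) -> np.ndarray:
    """Boolean image of aggregate pixels inside the mask.

    Masked intensities are flipped so aggregate (dark) material is
    high-valued, anchored at zero, and thresholded with ``>=``. A constant
    region yields t = 0 and all v'' = 0, so the whole region is foreground.
    """
    _check_congruent(micrograph, mask)
    values = micrograph.intensities[mask.pixels]
    flipped = values.max() - values
    anchored = flipped - flipped.min()
    t = compute_threshold(anchored, std_multiplier)
    out = np.zeros_like(mask.pixels)
    out[mask.pixels] = anchored >= t
    return out


def binarize_and_measure(
    micrograph: Micrograph,
    mask: RegionMask,
    std_multiplier: float = DEFAULT_STD_MULTIPLIER,
) -> AggregateMeasurement:
    """Threshold one masked region and measure its aggregate area.

    ``area_px`` counts every foreground pixel within the mask (no
    connected-component filtering: the measurement is the total aggregate
    pixel area per drawn mask). ``area_nm2 = area_px * (pixel_size_A/10)**2``.
    """
    values = masked_pixels(micrograph, mask)
    fg = foreground_mask(micrograph, mask, std_multiplier)
    area_px = int(fg.sum())
    return AggregateMeasurement(
        label=mask.label,
        n_masked_px=int(values.size),
        min_intensity=float(values.min()),
        max_intensity=float(values.max()),
        std_intensity=float(values.std(ddof=0)),
        threshold=compute_threshold(
            (values.max() - values) - (values.max() - values).min(),
            std_multiplier,
        ),
        area_px=area_px,
        area_nm2=area_px * micrograph.pixel_area_nm2,
    )


def measure_batch(
    micrographs_with_masks: Iterable[tuple],
    pixel_size_A: float | None = None,
    std_multiplier: float = DEFAULT_STD_MULTIPLIER,
) -> BatchResult:
    """Measure many (micrograph, mask[, condition]) pairs into one table.

    Parameters
    ----------
    micrographs_with_masks
        Iterable of ``(Micrograph, RegionMask)`` or
        ``(Micrograph, RegionMask, condition_label)`` tuples.
    pixel_size_A
        Optional override applied to every micrograph; by default each
        micrograph's own calibration is used.

    Any failing pair is recorded in ``failures`` with its error message and
    skipped; the batch result flags partial failure rather than aborting.
    """
    rows = []
    failures: list[tuple[int, str]] = []
    for i, item in enumerate(micrographs_with_masks):
        if len(item) == 3:
            micrograph, mask, condition = item
        else:
            micrograph, mask = item
            condition = ""
        try:
            if pixel_size_A is not None:
                micrograph = Micrograph(
                    micrograph.intensities, pixel_size_A, micrograph.metadata
                )
            m = binarize_and_measure(micrograph, mask, std_multiplier)
        except (ValueError, IncongruentMaskError) as exc:
            failures.append((i, str(exc)))
            continue
        rows.append(
            {
                "label": m.label,
                "condition": condition,
                "n_masked_px": m.n_masked_px,
                "threshold": m.threshold,
                "area_px": m.area_px,
                "area_nm2": m.area_nm2,
            }
        )
    columns = ["label", "condition", "n_masked_px", "threshold", "area_px", "area_nm2"]
    table = pd.DataFrame(rows, columns=columns)
    return BatchResult(table=table, failures=failures)
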