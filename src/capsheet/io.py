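"""File formats, run configuration, and run manifests.

Micrographs and diffraction frames travel as MRC (pixel size in the header)
or TIFF (uncalibrated unless a calibration is supplied); region masks as
label-image TIFF/PNG; tabular results as UTF-8 comma-separated CSV with a
header row; summaries and manifests as JSON. Calibration is never silently
defaulted: a missing pixel size raises, and a header/flag conflict beyond
1% logs a warning and lets the explicit flag win.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from capsheet import mrc
from capsheet.area_quant import Micrograph, RegionMask
from capsheet.diffraction import (
    DEFAULT_BAND_WINDOW_D,
    DEFAULT_CENTRAL_EXCLUSION_Q,
    DEFAULT_NORM_BAND,
    BandSummary,
    DiffractionFrame,
    RadialProfile,
    RatioProfile,
)

logger = logging.getLogger("capsheet")


class UncalibratedError(ValueError):
    """No pixel size / q calibration available from header, sidecar or flag."""


@dataclass
class RunConfig:
    """Configuration shared by the CLI pipelines."""

    pixel_size_A: float | None = None
    std_multiplier: float = 1.5
    q_nyquist_invA: float | None = None
    normalization_band: tuple[float, float] = DEFAULT_NORM_BAND
    band_window_d_A: tuple[float, float] = DEFAULT_BAND_WINDOW_D
    central_exclusion_q: float = DEFAULT_CENTRAL_EXCLUSION_Q
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        for name in ("pixel_size_A", "q_nyquist_invA"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("normalization_band", "band_window_d_A"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lo must be < hi")


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI run's outputs."""

    command: str
    config: dict
    inputs: dict = field(default_factory=dict)    # path -> sha256
    outputs: dict = field(default_factory=dict)   # path -> sha256
    timings_s: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    package_version: str = ""

    def add_input(self, path) -> None:
        self.inputs[str(path)] = sha256_file(path)

    def add_output(self, path) -> None:
        self.outputs[str(path)] = sha256_file(path)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def sha256_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class StageTimer:
    """Context manager recording a stage's wall time into a manifest."""

    def __init__(self, manifest: RunManifest, stage: str):
        self.manifest, self.stage = manifest, stage

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.manifest.timings_s[self.stage] = round(time.perf_counter() - self.t0, 4)
        return False


def _resolve_pixel_size(header_px: float | None, flag_px: float | None, path) -> float:
    if flag_px is not None and header_px is not None:
        if abs(flag_px - header_px) / header_px > 0.01:
            logger.warning(
                "pixel size conflict for %s: header %.4g vs flag %.4g A/px; "
                "flag wins",
                path, header_px, flag_px,
            )
        return flag_px
    if flag_px is not None:
        return flag_px
    if header_px is not None:
        return header_px
    raise UncalibratedError(f"uncalibrated micrograph: {path}")


def read_micrograph(path, pixel_size_A: float | None = None) -> Micrograph:
    """Read an MRC or TIFF micrograph with calibration resolution.

    MRC headers carry the pixel size; TIFF files are treated as
    uncalibrated, so ``pixel_size_A`` is then required. A >1% conflict
    between MRC header and flag emits a warning and the flag wins.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".mrc":
        data, header_px = mrc.read_mrc(path)
    elif suffix in (".tif", ".tiff"):
        try:
            data = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001 - tifffile raises various types
            raise IOError(f"corrupt input: {path}: {exc}") from exc
        header_px = None
    else:
        raise ValueError(f"unsupported micrograph format: {path}")
    px = _resolve_pixel_size(header_px, pixel_size_A, path)
    return Micrograph(
        intensities=np.asarray(data, dtype=float),
        pixel_size_A=px,
        metadata={"source": str(path)},
    )


def read_frame(path, q_nyquist_invA: float | None = None) -> DiffractionFrame:
    """Read a diffraction frame; q calibration from flag or sidecar JSON.

    A sidecar ``<frame>.json`` with key ``q_nyquist_invA`` supplies the
    calibration when no flag is given.
    """
    path = Path(path)
    if q_nyquist_invA is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            q_nyquist_invA = json.loads(sidecar.read_text()).get("q_nyquist_invA")
    if q_nyquist_invA is None:
        raise UncalibratedError(f"uncalibrated micrograph: {path} (no q_nyquist_invA)")
    suffix = path.suffix.lower()
    if suffix == ".mrc":
        data, _ = mrc.read_mrc(path)
    elif suffix in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        raise ValueError(f"unsupported frame format: {path}")
    return DiffractionFrame(
        intensities=np.asarray(data, dtype=float), q_nyquist_invA=q_nyquist_invA
    )


def read_label_masks(path) -> list[RegionMask]:
    """Read a label image (TIFF/PNG) into one RegionMask per label > 0."""
    import imageio.v3 as iio

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        labels = tifffile.imread(path)
    else:
        labels = iio.imread(path)
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError(f"label image must be 2D: {path}")
    return [
        RegionMask(label=int(lab), pixels=labels == lab)
        for lab in np.unique(labels)
        if lab > 0
    ]


def write_micrograph(path, micrograph: Micrograph) -> None:
    """Write MRC (float32, pixel size in header) or 16-bit TIFF."""
    path = Path(path)
    if path.suffix.lower() == ".mrc":
        mrc.write_mrc(path, micrograph.intensities, micrograph.pixel_size_A)
    else:
        data = micrograph.intensities
        lo, hi = data.min(), data.max()
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        tifffile.imwrite(path, ((data - lo) * scale).astype(np.uint16))


def write_label_image(path, label_image: np.ndarray) -> None:
    tifffile.imwrite(path, label_image.astype(np.int32))


def profile_to_csv(path, profile: RadialProfile) -> None:
    import pandas as pd

    with np.errstate(divide="ignore"):
        d = np.where(profile.q_bin_centers > 0, 1.0 / profile.q_bin_centers, np.inf)
    pd.DataFrame(
        {
            "q_invA": profile.q_bin_centers,
            "d_A": d,
            "intensity": profile.mean_intensity,
            "n_pixels": profile.n_pixels,
        }
    ).to_csv(path, index=False)


def ratio_to_csv(path, ratio: RatioProfile) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "q_invA": ratio.q_invA,
            "d_A": ratio.d_A,
            "ratio": ratio.ratio,
            "masked": ratio.mask.astype(int),
        }
    ).to_csv(path, index=False)


def band_summary_to_json(path, band: BandSummary) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "window_d_A": list(band.window_d_A),
                "peak_d_A": band.peak_d_A,
                "peak_ratio": band.peak_ratio,
                "band_present": band.band_present,
            },
            indent=2,
        )
    )
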