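"""Minimal MRC2014 reader/writer for 2D images.

Handles the subset of the MRC2014 format the pipelines need: single-section
(nz = 1) images in modes 0 (int8), 1 (int16), 2 (float32) and 6 (uint16),
little-endian, with the pixel size carried in the standard ``cella``/``mx``
header fields. Writing always emits mode 2 (float32).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

HEADER_SIZE = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


class CorruptMRCError(IOError):
    """File is not a readable single-section MRC."""


def write_mrc(path, data: np.ndarray, pixel_size_A: float) -> None:
    """Write a 2D array as a little-endian mode-2 (float32) MRC file.

    The pixel size is stored via ``cella = pixel_size * (mx, my, mz)``.
    Data layout follows the convention ``data[row, col]`` with the column
    (x) axis fastest, matching standard EM software.
    """
    data = np.asarray(data)
    if data.ndim != 2:
        raise ValueError("only 2D images are written")
    ny, nx = data.shape
    arr = np.ascontiguousarray(data, dtype="<f4")
    header = bytearray(HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, 1)          # nx, ny, nz
    struct.pack_into("<i", header, 12, 2)                  # mode 2 = float32
    struct.pack_into("<3i", header, 28, nx, ny, 1)         # mx, my, mz
    struct.pack_into(
        "<3f", header, 40, nx * pixel_size_A, ny * pixel_size_A, pixel_size_A
    )                                                      # cella (Angstrom)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)           # mapc, mapr, maps
    struct.pack_into(
        "<3f", header, 76, float(arr.min()), float(arr.max()), float(arr.mean())
    )                                                      # dmin, dmax, dmean
    struct.pack_into("<i", header, 88, 0)                  # ispg
    struct.pack_into("<i", header, 92, 0)                  # nsymbt
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"                  # little-endian stamp
    struct.pack_into("<f", header, 216, float(arr.std()))  # rms
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(arr.tobytes())


def read_mrc(path) -> tuple[np.ndarray, float | None]:
    """Read a single-section MRC file.

    Returns ``(data, pixel_size_A)``; the pixel size is ``cella_x / mx``
    when both are positive, else ``None`` (uncalibrated). Multi-section
    files yield their first section.
    """
    raw = Path(path).read_bytes()
    if len(raw) < HEADER_SIZE:
        raise CorruptMRCError(f"corrupt input: {path} shorter than MRC header")
    nx, ny, nz = struct.unpack_from("<3i", raw, 0)
    (mode,) = struct.unpack_from("<i", raw, 12)
    mx, _, _ = struct.unpack_from("<3i", raw, 28)
    cella_x, _, _ = struct.unpack_from("<3f", raw, 40)
    (nsymbt,) = struct.unpack_from("<i", raw, 92)
    if raw[208:212] not in (b"MAP ", b"MAP\x00"):
        raise CorruptMRCError(f"corrupt input: {path} missing MAP stamp")
    if mode not in _MODE_DTYPES:
        raise CorruptMRCError(f"corrupt input: unsupported MRC mode {mode}")
    if nx <= 0 or ny <= 0 or nz <= 0:
        raise CorruptMRCError(f"corrupt input: bad dimensions {(nx, ny, nz)}")
    dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
    start = HEADER_SIZE + nsymbt
    need = start + nx * ny * dtype.itemsize
    if len(raw) < need:
        raise CorruptMRCError(f"corrupt input: {path} truncated data block")
    data = np.frombuffer(raw[start : start + nx * ny * dtype.itemsize], dtype=dtype)
    data = data.reshape(ny, nx).copy()
    pixel = cella_x / mx if (mx > 0 and cella_x > 0) else None
    return data, pixel
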