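"""ENVI-format hypercube I/O and single-frame image export.

ENVI stores a hyperspectral cube as a plain text header (``.hdr``,
``key = value`` lines, multi-valued entries in braces) next to a raw
binary file.  All three interleaves are read (BSQ: band-sequential,
BIL: band-interleaved-by-line, BIP: band-interleaved-by-pixel); cubes
are written as BSQ float64 so round trips are lossless bit-for-bit.
"""

from __future__ import annotations

import os
import re
from pathlib import Path

import numpy as np
import tifffile

from .hypercube import ABSORBANCE, REFLECTANCE, Hypercube

_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
    14: np.int64,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}


def _header_path(path: Path) -> Path:
    return path if path.suffix == ".hdr" else path.with_suffix(path.suffix + ".hdr")


def _data_path(path: Path) -> Path:
    if path.suffix == ".hdr":
        stem = path.with_suffix("")
        for cand in (stem, stem.with_suffix(".img"), stem.with_suffix(".dat")):
            if cand.exists():
                return cand
        return stem
    return path


def _parse_header(text: str) -> dict:
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic line)")
    body = text.split("\n", 1)[1] if "\n" in text else ""
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values before splitting into lines
    body = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), body)
    for line in body.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(path: str | os.PathLike) -> Hypercube:
    """Read an ENVI header/binary pair into a :class:`Hypercube`.

    Bands are reordered to ascending wavelength.  A header without
    wavelength metadata, or a binary whose size disagrees with the header
    dimensions, is an explicit error.
    """
    path = Path(path)
    hdr = _header_path(path)
    if not hdr.exists():
        raise FileNotFoundError(f"missing ENVI header {hdr}")
    fields = _parse_header(hdr.read_text())

    try:
        rows = int(fields["lines"])
        cols = int(fields["samples"])
        bands = int(fields["bands"])
    except KeyError as exc:
        raise ValueError(f"ENVI header missing required field {exc}") from exc
    dtype = _DTYPES.get(int(fields.get("data type", 4)))
    if dtype is None:
        raise ValueError(f"unsupported ENVI data type {fields.get('data type')}")
    interleave = fields.get("interleave", "bsq").lower()
    offset = int(fields.get("header offset", 0))
    byte_order = int(fields.get("byte order", 0))

    if "wavelength" not in fields:
        raise ValueError("ENVI header has no wavelength metadata")
    wl_text = fields["wavelength"].strip().strip("{}")
    wavelengths = np.array(
        [float(tok) for tok in wl_text.replace(",", " ").split() if tok],
        dtype=np.float64,
    )
    if wavelengths.size != bands:
        raise ValueError(
            f"header lists {bands} bands but {wavelengths.size} wavelengths"
        )

    data_file = _data_path(path)
    if not data_file.exists():
        raise FileNotFoundError(f"missing ENVI binary {data_file}")
    raw = np.fromfile(data_file, dtype=dtype, offset=offset)
    if byte_order == 1:
        raw = raw.byteswap()
    expected = rows * cols * bands
    if raw.size != expected:
        raise ValueError(
            f"ENVI binary holds {raw.size} values, header implies {expected}"
        )
    if interleave == "bsq":
        cube = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(rows, cols, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")

    order = np.argsort(wavelengths, kind="stable")
    cube = np.ascontiguousarray(cube[:, :, order])
    wavelengths = wavelengths[order]

    mode = fields.get("mcidetect mode", REFLECTANCE).lower()
    if mode not in (REFLECTANCE, ABSORBANCE):
        mode = REFLECTANCE
    pixel_size = fields.get("mcidetect pixel size mm")
    return Hypercube(
        values=cube.astype(np.float64),
        wavelengths_nm=wavelengths,
        mode=mode,
        pixel_size_mm=float(pixel_size) if pixel_size else None,
        field_of_view_id=fields.get("mcidetect fov id", path.stem),
    )


def write_envi(cube: Hypercube, path: str | os.PathLike) -> Path:
    """Write a hypercube as an ENVI BSQ float64 pair; returns the data path."""
    if cube.n_bands == 0 or cube.values.size == 0:
        raise ValueError("refusing to write an empty hypercube")
    path = Path(path)
    if path.suffix == ".hdr":
        path = path.with_suffix("")
    path.parent.mkdir(parents=True, exist_ok=True)

    rows, cols = cube.spatial_shape
    wl = ", ".join(repr(float(w)) for w in cube.wavelengths_nm)
    header_lines = [
        "ENVI",
        "description = {mcidetect hypercube}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {cube.n_bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[np.dtype(np.float64)]}",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = Nanometers",
        "wavelength = {" + wl + "}",
        f"mcidetect mode = {cube.mode}",
        f"mcidetect fov id = {cube.field_of_view_id}",
    ]
    if cube.pixel_size_mm is not None:
        header_lines.append(f"mcidetect pixel size mm = {cube.pixel_size_mm!r}")
    _header_path(path).write_text("\n".join(header_lines) + "\n")

    bsq = np.ascontiguousarray(cube.values.transpose(2, 0, 1), dtype=np.float64)
    bsq.tofile(path)
    return path


def export_frame(cube: Hypercube, nm: float, path: str | os.PathLike) -> Path:
    """Export one wavelength frame as a min–max stretched 16-bit TIFF/PNG."""
    frame = cube.frame(nm).astype(np.float64)
    lo, hi = float(frame.min()), float(frame.max())
    if hi > lo:
        scaled = (frame - lo) / (hi - lo)
    else:
        scaled = np.zeros_like(frame)
    img = np.round(scaled * 65535).astype(np.uint16)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, img)
    else:
        tifffile.imwrite(path, img)
    return path
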