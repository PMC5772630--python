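"""Readers and writers for height images and run artifacts.

Accepted inputs are single-channel float TIFF (the pixel size is read from
a JSON ImageDescription written by this package, or from X/YResolution
tags, or passed explicitly) and whitespace-delimited text matrices (pixel
size always explicit). Native instrument formats are out of scope; export
to TIFF or text first.
"""
from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path

import numpy as np
import tifffile

from .image import HeightImage

__all__ = ["read_image", "write_image", "write_text_image"]

_TIFF_SUFFIXES = {".tif", ".tiff"}

# TIFF ResolutionUnit -> size of that unit in nm (2 = inch, 3 = cm)
_RESUNIT_NM = {2: 2.54e7, 3: 1.0e7}


def _pixel_size_from_tiff(page) -> tuple[float | None, str]:
    tags = page.tags
    desc = tags.get("ImageDescription")
    if desc is not None:
        try:
            meta = json.loads(desc.value)
            if isinstance(meta, dict) and "pixel_size" in meta:
                return float(meta["pixel_size"]), str(meta.get("unit", "nm"))
        except (json.JSONDecodeError, TypeError, ValueError):
            pass
    xres = tags.get("XResolution")
    unit = tags.get("ResolutionUnit")
    if xres is not None and unit is not None and unit.value in _RESUNIT_NM:
        num, den = xres.value
        if num:
            per_unit = Fraction(int(num), int(den))  # pixels per unit
            return float(_RESUNIT_NM[unit.value] / per_unit), "nm"
    return None, "nm"


def read_image(
    path: str | Path,
    pixel_size: float | None = None,
    height_scale: float | None = None,
    unit_label: str = "nm",
) -> HeightImage:
    """Load a height image from float TIFF or a text matrix.

    ``pixel_size`` (physical units per pixel) overrides any metadata; text
    matrices always require it. Integer TIFF data requires ``height_scale``
    (physical height per count) and is converted to float heights.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        with tifffile.TiffFile(path) as tif:
            data = tif.pages[0].asarray()
            meta_px, meta_unit = _pixel_size_from_tiff(tif.pages[0])
        if data.ndim != 2:
            raise ValueError(
                f"expected a single-channel image, got shape {data.shape}"
            )
        if np.issubdtype(data.dtype, np.integer):
            if height_scale is None:
                raise ValueError(
                    "integer TIFF input requires a height scale factor "
                    "(physical height per count)"
                )
            data = data.astype(float) * height_scale
        else:
            data = data.astype(float)
            if height_scale is not None:
                data = data * height_scale
        if pixel_size is None:
            pixel_size = meta_px
            unit_label = meta_unit
        if pixel_size is None:
            raise ValueError(
                f"no pixel size metadata in {path.name}; pass pixel_size"
            )
    else:
        if pixel_size is None:
            raise ValueError("text matrix input requires an explicit pixel size")
        data = np.loadtxt(path, dtype=float)
        if data.ndim != 2:
            raise ValueError(f"text matrix must be 2D, got shape {data.shape}")
        if height_scale is not None:
            data = data * height_scale
    return HeightImage(data, pixel_size_x=float(pixel_size), unit_label=unit_label)


def write_image(path: str | Path, img: HeightImage) -> None:
    """Write a float32 TIFF with the pixel size in the ImageDescription."""
    meta = {"pixel_size": img.pixel_size_x, "unit": img.unit_label}
    tifffile.imwrite(
        Path(path),
        img.heights.astype(np.float32),
        description=json.dumps(meta),
    )


def write_text_image(path: str | Path, img: HeightImage) -> None:
    """Write the height matrix as whitespace-delimited text."""
    np.savetxt(Path(path), img.heights, fmt="%.9g")
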