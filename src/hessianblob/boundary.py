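"""Blob support regions and closed boundary contours.

A blob's spatial support at its selected scale is the 8-connected component
of strictly positive ``det H_norm L`` containing the seed: because the
Gaussian curvature shares its sign with the Hessian determinant, this is
exactly the locally convex patch around the center, and its rim is a zero
crossing of the detector. Contours are traced on the detector layer:

* ``subpixel_factor == 1`` returns the exact pixel-boundary (staircase)
  polygon of the region footprint — vertices on pixel corners, area equal
  to the pixel count, perimeter the edge count;
* ``subpixel_factor >= 2`` interpolates the detector on a grid refined by
  that factor (bilinear or bicubic) and traces the ``detH = 0`` level set
  with marching squares, yielding a smooth subpixel boundary.

Zero crossings always close around a positive region, so outer contours are
closed polygons unless the region runs into the image border.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union
from skimage import measure

from .detection import BlobSeed
from .scalespace import DetectorVolume

__all__ = ["BlobRegion", "Contour", "extract_region", "trace_contour"]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class BlobRegion:
    """Connected positive-detH component supporting one blob."""

    k: int
    pixels: np.ndarray          # (N, 2) array of (row, col) indices
    seed: tuple[int, int]       # (row, col) of the seed pixel
    shape: tuple[int, int]      # full image shape
    connectivity: int = 8

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(row_min, row_max, col_min, col_max), inclusive."""
        r = self.pixels[:, 0]
        c = self.pixels[:, 1]
        return int(r.min()), int(r.max()), int(c.min()), int(c.max())

    def touches_border(self, band: int = 0) -> bool:
        r0, r1, c0, c1 = self.bbox
        rows, cols = self.shape
        return (
            r0 <= band or c0 <= band or r1 >= rows - 1 - band or c1 >= cols - 1 - band
        )


@dataclass
class Contour:
    """Closed polygonal boundary (or hole) of one blob.

    Vertices are stored in pixel coordinates (x = col, y = row, origin at
    the top-left pixel center); physical coordinates are the same scaled by
    ``pixel_size``. The first vertex is repeated as the last for closed
    rings. ``trusted`` is False when the region intersects the per-scale
    untrusted border band.
    """

    xy: np.ndarray
    pixel_size: float
    closed: bool
    subpixel_factor: int
    role: str = "outer"        # "outer" | "hole"
    trusted: bool = True

    @property
    def xy_phys(self) -> np.ndarray:
        return self.xy * self.pixel_size

    @property
    def perimeter(self) -> float:
        """Polygon length in physical units (0 for open contours)."""
        if not self.closed:
            return float("nan")
        d = np.diff(self.xy_phys, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    @property
    def area(self) -> float:
        """Shoelace area in physical units (NaN for open contours)."""
        if not self.closed:
            return float("nan")
        p = self.xy_phys
        x, y = p[:, 0], p[:, 1]
        return float(0.5 * abs(np.dot(x[:-1], y[1:]) - np.dot(x[1:], y[:-1])))


def extract_region(vol: DetectorVolume, seed: BlobSeed) -> BlobRegion:
    """8-connected flood fill of positive detH from the seed, at its scale."""
    layer = vol.detH[seed.k]
    if layer[seed.i, seed.j] <= 0:
        raise ValueError(
            f"inconsistent seed: detH <= 0 at (k={seed.k}, i={seed.i}, j={seed.j})"
        )
    labels, _ = ndimage.label(layer > 0, structure=_EIGHT)
    comp = labels == labels[seed.i, seed.j]
    return BlobRegion(
        k=seed.k,
        pixels=np.argwhere(comp),
        seed=(seed.i, seed.j),
        shape=layer.shape,
    )


def _ring_to_xy(ring) -> np.ndarray:
    return np.asarray(ring.coords, dtype=float)


def _staircase_contours(
    region: BlobRegion, pixel_size: float, trusted: bool
) -> list[Contour]:
    """Exact pixel-boundary polygon(s) of the region footprint."""
    boxes = [
        box(c - 0.5, r - 0.5, c + 0.5, r + 0.5) for r, c in region.pixels
    ]
    merged = unary_union(boxes)
    polys = list(merged.geoms) if merged.geom_type == "MultiPolygon" else [merged]
    seed_pt = Point(region.seed[1], region.seed[0])
    polys.sort(key=lambda p: p.distance(seed_pt))
    outer_poly = polys[0]
    contours = [
        Contour(
            xy=_ring_to_xy(outer_poly.exterior),
            pixel_size=pixel_size,
            closed=True,
            subpixel_factor=1,
            role="outer",
            trusted=trusted,
        )
    ]
    for hole in outer_poly.interiors:
        contours.append(
            Contour(
                xy=_ring_to_xy(hole),
                pixel_size=pixel_size,
                closed=True,
                subpixel_factor=1,
                role="hole",
                trusted=trusted,
            )
        )
    return contours


def _level_contours(
    region: BlobRegion,
    vol: DetectorVolume,
    factor: int,
    interp: str,
    trusted: bool,
) -> list[Contour]:
    order = {"bilinear": 1, "bicubic": 3}[interp]
    layer = vol.detH[region.k]
    rows, cols = layer.shape
    pad = 4
    r0, r1, c0, c1 = region.bbox
    r0 = max(r0 - pad, 0)
    c0 = max(c0 - pad, 0)
    r1 = min(r1 + pad, rows - 1)
    c1 = min(c1 + pad, cols - 1)
    rr = np.linspace(r0, r1, (r1 - r0) * factor + 1)
    cc = np.linspace(c0, c1, (c1 - c0) * factor + 1)
    R, C = np.meshgrid(rr, cc, indexing="ij")
    fine = ndimage.map_coordinates(
        layer, [R.ravel(), C.ravel()], order=order, mode="nearest"
    ).reshape(R.shape)
    raw = measure.find_contours(fine, 0.0)
    px = vol.source.pixel_size
    step = 1.0 / factor
    traced: list[tuple[np.ndarray, bool]] = []
    for c in raw:
        xy = np.column_stack([c0 + c[:, 1] * step, r0 + c[:, 0] * step])  # (x, y)
        closed = bool(np.allclose(xy[0], xy[-1]))
        if closed and not np.array_equal(xy[0], xy[-1]):
            xy = np.vstack([xy, xy[:1]])
        traced.append((xy, closed))

    seed_pt = Point(region.seed[1], region.seed[0])
    enclosing = []
    for idx, (xy, closed) in enumerate(traced):
        if closed and len(xy) >= 4:
            poly = Polygon(xy)
            if poly.is_valid and poly.contains(seed_pt):
                enclosing.append((poly.area, idx, poly))
    if not enclosing:
        # region touches the border (or the crop): report what was traced,
        # flagged open/invalid
        if not traced:
            return []
        xy, closed = max(traced, key=lambda t: len(t[0]))
        return [
            Contour(
                xy=xy,
                pixel_size=px,
                closed=False,
                subpixel_factor=factor,
                role="outer",
                trusted=trusted,
            )
        ]
    enclosing.sort(key=lambda e: (e[0], e[1]))
    _, outer_idx, outer_poly = enclosing[0]
    contours = [
        Contour(
            xy=traced[outer_idx][0],
            pixel_size=px,
            closed=True,
            subpixel_factor=factor,
            role="outer",
            trusted=trusted,
        )
    ]
    # holes: closed rings inside the outer ring that do not enclose the seed
    holes = []
    for idx, (xy, closed) in enumerate(traced):
        if idx == outer_idx or not closed or len(xy) < 4:
            continue
        poly = Polygon(xy)
        if not poly.is_valid:
            continue
        if outer_poly.contains(poly) and not poly.contains(seed_pt):
            holes.append((poly.area, idx, poly))
    holes.sort(key=lambda h: (-h[0], h[1]))
    kept: list[Polygon] = []
    for _, idx, poly in holes:
        if any(other.contains(poly) for other in kept):
            continue  # nested ring inside an already-kept hole
        kept.append(poly)
        contours.append(
            Contour(
                xy=traced[idx][0],
                pixel_size=px,
                closed=True,
                subpixel_factor=factor,
                role="hole",
                trusted=trusted,
            )
        )
    return contours


def trace_contour(
    region: BlobRegion,
    vol: DetectorVolume,
    subpixel_factor: int = 1,
    interp: str = "bilinear",
) -> list[Contour]:
    """Trace the closed ``detH = 0`` boundary of a blob region.

    Returns the outer contour first, holes after. ``subpixel_factor = 1``
    gives the pixel-resolution (staircase) boundary; larger factors trace
    the interpolated zero level set (``interp`` in {"bilinear",
    "bicubic"}). Contours of regions intersecting the untrusted border band
    carry ``trusted=False``; contours that cannot close (region running
    into the image border) carry ``closed=False``.
    """
    if region.n_pixels == 0:
        raise ValueError("empty region")
    factor = int(subpixel_factor)
    if factor < 1:
        raise ValueError("subpixel_factor must be >= 1")
    if interp not in ("bilinear", "bicubic"):
        raise ValueError(f"unknown interpolation {interp!r}")
    band = int(vol.border[region.k])
    trusted = not region.touches_border(band)
    if factor == 1:
        return _staircase_contours(region, vol.source.pixel_size, trusted)
    return _level_contours(region, vol, factor, interp, trusted)
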