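"""Particle assembly: overlap resolution, culling and measurements.

A Hessian blob bundles everything the detector knows about one particle:
the integer seed, the refined subpixel center and scale, the blob strength
(the detector value at the seed — the single significant culling
parameter), the positive-curvature support region and its closed boundary
contours, and the geometric measurements taken from them.

Overlapping blobs are resolved greedily by strength: when two blobs share
support pixels in the image plane, only the stronger survives. Culling by
minimum strength or minimum scale only selects which blobs are reported —
it never recomputes or deforms the survivors. The automatic strength
threshold applies Otsu's method to log10 blob strengths (strengths span
many decades, so a linear-scale histogram collapses onto one bin).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .boundary import BlobRegion, Contour
from .detection import BlobSeed, RefinedCenter
from .image import HeightImage

__all__ = [
    "HessianBlob",
    "ParticleMeasurements",
    "resolve_overlaps",
    "filter_min_scale",
    "filter_min_strength",
    "otsu_strength_threshold",
    "kmeans_strength_threshold",
    "measure_blob",
]


@dataclass
class ParticleMeasurements:
    """Geometric measurements of one particle, in physical units.

    ``projected_area`` and ``perimeter`` come from the polygon
    approximation (shoelace area of the outer contour minus holes, outer
    polygon length). ``relative_height`` subtracts the mean raw height
    along the outer contour from the peak height — an explicit provisional
    stand-in for a local background estimate, as is the boundary-referenced
    ``volume_provisional``.
    """

    projected_area: float
    perimeter: float
    max_height: float
    relative_height: float
    equivalent_radius: float
    volume_provisional: float
    n_pixels: int
    valid: bool = True

    @classmethod
    def invalid(cls, n_pixels: int = 0) -> "ParticleMeasurements":
        nan = float("nan")
        return cls(nan, nan, nan, nan, nan, nan, n_pixels, valid=False)


@dataclass
class HessianBlob:
    """One detected particle."""

    id: int
    seed: BlobSeed
    center: RefinedCenter
    strength: float
    sign: str
    region: BlobRegion
    contours: list[Contour] = field(default_factory=list)
    measurements: ParticleMeasurements | None = None

    @property
    def t_hat_px2(self) -> float:
        return self.center.t_hat_px2

    @property
    def t_hat_phys(self) -> float:
        return self.center.t_hat_phys

    @property
    def flags(self) -> str:
        out = []
        if not self.center.converged:
            out.append("unconverged_center")
        if self.contours and not self.contours[0].closed:
            out.append("open_contour")
        if self.contours and not self.contours[0].trusted:
            out.append("near_border")
        return "+".join(out) if out else "ok"


def resolve_overlaps(blobs: list[HessianBlob]) -> list[HessianBlob]:
    """Keep only the stronger blob wherever support regions overlap.

    Greedy by descending strength (ties broken by ascending seed
    (k, i, j)): a blob is accepted iff its region shares no pixel with any
    already-accepted blob's region, in the image plane regardless of scale.
    """
    if not blobs:
        return []
    ordered = sorted(
        blobs, key=lambda b: (-b.strength, b.seed.k, b.seed.i, b.seed.j)
    )
    shape = ordered[0].region.shape
    occupied = np.zeros(shape[0] * shape[1], dtype=bool)
    kept = []
    for b in ordered:
        flat = b.region.pixels[:, 0] * shape[1] + b.region.pixels[:, 1]
        if occupied[flat].any():
            continue
        occupied[flat] = True
        kept.append(b)
    return kept


def filter_min_scale(blobs: list[HessianBlob], t0: float) -> list[HessianBlob]:
    """Keep blobs with refined scale ``t_hat >= t0`` (pixel^2); no reshaping."""
    if t0 < 0:
        raise ValueError("minimum scale must be >= 0")
    return [b for b in blobs if b.t_hat_px2 >= t0]


def filter_min_strength(blobs: list[HessianBlob], s_min: float) -> list[HessianBlob]:
    """Keep blobs with ``strength >= s_min``; no reshaping. ``s_min = 0``
    keeps everything (the zero-parameter limit)."""
    if s_min < 0:
        raise ValueError("minimum strength must be >= 0")
    return [b for b in blobs if b.strength >= s_min]


def _log_hist(strengths: np.ndarray, bins: int):
    x = np.log10(strengths)
    hist, edges = np.histogram(x, bins=bins)
    return x, hist.astype(float), edges


def otsu_strength_threshold(strengths, bins: int = 256) -> float:
    """Otsu threshold on log10 blob strengths, mapped back to linear scale.

    Builds a 256-bin histogram of ``log10(strengths)`` and returns
    ``10**edge`` for the bin edge that minimizes the weighted intra-class
    variance (equivalently maximizes the inter-class variance). Degenerate
    input (all values equal) returns that value with a warning.
    """
    s = np.asarray(list(strengths), dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 strength values")
    if np.any(s <= 0):
        raise ValueError("blob strengths must be positive")
    if np.ptp(s) == 0:
        warnings.warn(
            "degenerate strength distribution (all values equal)", stacklevel=2
        )
        return float(s[0])
    _, hist, edges = _log_hist(s, bins)
    w = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * centers)
    mean_total = cum_m[-1]
    w0 = cum_w[:-1]
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(valid, cum_m[:-1] / np.where(w0 > 0, w0, 1.0), 0.0)
    mu1 = np.where(valid, (mean_total - cum_m[:-1]) / np.where(w1 > 0, w1, 1.0), 0.0)
    between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    cut = int(np.argmax(between))
    return float(10.0 ** edges[cut + 1])


def kmeans_strength_threshold(strengths) -> float:
    """Exact 1D two-cluster split of log10 strengths (k-means, k=2).

    Scans every split of the sorted log-strengths for the minimum total
    within-cluster sum of squares — the global optimum of 1D 2-means —
    and returns the midpoint between the two cluster means, mapped back to
    linear scale.
    """
    s = np.asarray(list(strengths), dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 strength values")
    if np.any(s <= 0):
        raise ValueError("blob strengths must be positive")
    x = np.sort(np.log10(s))
    n = len(x)
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)

    def sse(lo_sum, lo_sq, m):
        return lo_sq - lo_sum * lo_sum / m

    best, best_split = np.inf, 1
    for m in range(1, n):
        left = sse(c1[m - 1], c2[m - 1], m)
        right = sse(c1[-1] - c1[m - 1], c2[-1] - c2[m - 1], n - m)
        total = left + right
        if total < best - 1e-15:
            best, best_split = total, m
    mu0 = c1[best_split - 1] / best_split
    mu1 = (c1[-1] - c1[best_split - 1]) / (n - best_split)
    return float(10.0 ** (0.5 * (mu0 + mu1)))


def measure_blob(img: HeightImage, blob: HessianBlob) -> ParticleMeasurements:
    """Polygon-approximation measurements of one blob.

    Projected area = shoelace area of the outer contour minus hole areas;
    perimeter = outer polygon length; max height = peak raw height inside
    the region; relative height = max height minus the mean raw height
    sampled (bilinearly) along the outer contour. Open contours yield
    invalid measurements.
    """
    if not blob.contours or not blob.contours[0].closed:
        return ParticleMeasurements.invalid(blob.region.n_pixels)
    outer = blob.contours[0]
    area = outer.area
    for c in blob.contours[1:]:
        if c.role == "hole" and c.closed:
            area -= c.area
    perimeter = outer.perimeter

    rows = blob.region.pixels[:, 0]
    cols = blob.region.pixels[:, 1]
    region_heights = img.heights[rows, cols]
    max_height = float(region_heights.max())

    verts = outer.xy[:-1]  # drop closing vertex
    boundary_heights = ndimage.map_coordinates(
        img.heights, [verts[:, 1], verts[:, 0]], order=1, mode="nearest"
    )
    baseline = float(boundary_heights.mean())
    relative_height = max_height - baseline
    volume = float((region_heights - baseline).sum() * img.pixel_area)

    return ParticleMeasurements(
        projected_area=float(area),
        perimeter=float(perimeter),
        max_height=max_height,
        relative_height=relative_height,
        equivalent_radius=float(np.sqrt(max(area, 0.0) / np.pi)),
        volume_provisional=volume,
        n_pixels=blob.region.n_pixels,
        valid=True,
    )
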