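"""Ground-truth synthetic AFM-like images.

The generator renders Gaussian bumps — the canonical blob model — on a flat
background, optionally arranged as hexagonal lattices of three-bump
clusters (mimicking bacteriorhodopsin trimers), and applies the standard
AFM perturbation battery: constant offset, fault-line discontinuity,
planar tilt, per-scanline parabolic bow, per-scanline random offsets and
per-pixel Gaussian noise. A bump with planted scale ``t0`` (pixel^2) and
amplitude ``A`` contributes ``A * exp(-r^2 / (2 t0))``, so the full
detection pipeline has closed-form oracles: the detector response at the
center is ``A^2 t0^2 t^2 / (t0 + t)^4`` (maximal at ``t = t0``) and the
positive-curvature boundary at the selected scale is the circle
``r = sqrt(2 t0)``.

What this emulates — isolated protrusions of known size and position on a
flat or smoothly perturbed background, with raster-scan artifacts. What it
does not emulate — tip convolution, structured membrane backgrounds, and
height-dependent imaging noise of real AFM data.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image import HeightImage

__all__ = [
    "PlantedBlob",
    "GroundTruth",
    "gaussian_blob_image",
    "random_blob_image",
    "trimer_lattice_image",
    "perturb",
]

PERTURBATION_KINDS = (
    "offset",
    "fault",
    "tilt",
    "parabolic",
    "scanline_noise",
    "gaussian_noise",
)


@dataclass(frozen=True)
class PlantedBlob:
    """One planted Gaussian bump: center (pixel coords), amplitude, scale."""

    x: float
    y: float
    amplitude: float
    t0_px2: float
    sign: int = 1


@dataclass
class GroundTruth:
    """Planted-blob parameters emitted alongside every generated image."""

    blobs: list[PlantedBlob]
    pixel_size: float
    background: str = "flat"
    noise: str = "none"
    seed: int | None = None
    trimer_centers: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.blobs)

    @property
    def centers(self) -> np.ndarray:
        """(N, 2) array of (x, y) centers in pixel coordinates."""
        return np.array([[b.x, b.y] for b in self.blobs]).reshape(-1, 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_px": [b.x for b in self.blobs],
                "y_px": [b.y for b in self.blobs],
                "amplitude": [b.amplitude for b in self.blobs],
                "t0_px2": [b.t0_px2 for b in self.blobs],
                "sign": [b.sign for b in self.blobs],
            }
        )


def _render(shape: tuple[int, int], blobs: list[PlantedBlob]) -> np.ndarray:
    rows, cols = shape
    R, C = np.mgrid[0:rows, 0:cols].astype(float)
    heights = np.zeros(shape, dtype=float)
    for b in blobs:
        r2 = (C - b.x) ** 2 + (R - b.y) ** 2
        heights += b.sign * b.amplitude * np.exp(-r2 / (2.0 * b.t0_px2))
    return heights


def gaussian_blob_image(
    shape: tuple[int, int],
    pixel_size: float,
    blobs,
    seed: int | None = None,
    allow_overlap: bool = False,
) -> tuple[HeightImage, GroundTruth]:
    """Render Gaussian bumps at pixel centers; return image + ground truth.

    ``blobs`` is an iterable of ``(x, y, amplitude, t0_px2)`` tuples (or
    :class:`PlantedBlob`). Unless ``allow_overlap`` is set, centers must
    keep ``3 sqrt(2 t0)`` pixels from the border and pairwise distances of
    at least ``4 sqrt(2 max(t0))``, which guarantees well-separated,
    individually recoverable particles.
    """
    planted = [
        b if isinstance(b, PlantedBlob) else PlantedBlob(*b) for b in blobs
    ]
    rows, cols = shape
    for b in planted:
        if b.amplitude <= 0 or b.t0_px2 <= 0:
            raise ValueError("blob amplitude and scale must be positive")
        if not (0 <= b.x <= cols - 1 and 0 <= b.y <= rows - 1):
            raise ValueError(f"blob center ({b.x}, {b.y}) outside the image")
        if not allow_overlap:
            margin = 3.0 * np.sqrt(2.0 * b.t0_px2)
            if (
                b.x < margin
                or b.y < margin
                or b.x > cols - 1 - margin
                or b.y > rows - 1 - margin
            ):
                raise ValueError(
                    f"blob at ({b.x}, {b.y}) closer than 3*sqrt(2 t0) to border"
                )
    if not allow_overlap:
        for a_i, a in enumerate(planted):
            for b in planted[a_i + 1 :]:
                min_sep = 4.0 * np.sqrt(2.0 * max(a.t0_px2, b.t0_px2))
                if np.hypot(a.x - b.x, a.y - b.y) < min_sep:
                    raise ValueError(
                        "overlapping blobs; pass allow_overlap=True if intended"
                    )
    img = HeightImage(_render(shape, planted), pixel_size)
    gt = GroundTruth(blobs=planted, pixel_size=pixel_size, seed=seed)
    return img, gt


def random_blob_image(
    shape: tuple[int, int],
    pixel_size: float,
    n_blobs: int,
    amplitude: float = 3.0,
    t0_px2: float = 8.0,
    seed: int = 0,
    subpixel: bool = True,
) -> tuple[HeightImage, GroundTruth]:
    """Jittered-grid layout of ``n_blobs`` identical bumps (reproducible).

    Blobs are placed on a regular grid inside the safe margin, each
    jittered uniformly by an amount that preserves the non-overlap
    separation; with ``subpixel`` the centers keep their fractional parts.
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    margin = 3.0 * np.sqrt(2.0 * t0_px2) + 1.0
    min_sep = 4.0 * np.sqrt(2.0 * t0_px2)
    nc = int(np.ceil(np.sqrt(n_blobs * cols / rows)))
    nr = int(np.ceil(n_blobs / nc))
    cell_w = (cols - 1 - 2 * margin) / nc
    cell_h = (rows - 1 - 2 * margin) / nr
    if min(cell_w, cell_h) < min_sep:
        raise ValueError("image too small for that many non-overlapping blobs")
    jitter = max(0.0, (min(cell_w, cell_h) - min_sep) / 2.0 - 0.5)
    blobs = []
    for idx in range(n_blobs):
        gi, gj = divmod(idx, nc)
        y = margin + (gi + 0.5) * cell_h + rng.uniform(-jitter, jitter)
        x = margin + (gj + 0.5) * cell_w + rng.uniform(-jitter, jitter)
        if not subpixel:
            x, y = round(x), round(y)
        blobs.append(PlantedBlob(x=float(x), y=float(y), amplitude=amplitude,
                                 t0_px2=t0_px2))
    img, gt = gaussian_blob_image(shape, pixel_size, blobs, seed=seed)
    return img, gt


def trimer_lattice_image(
    shape: tuple[int, int] = (192, 192),
    pixel_size: float = 0.25,
    monomer_t0: float = 4.0,
    trimer_spacing: float = 3.6,
    lattice_constant: float = 25.0,
    amplitude: float = 1.5,
    seed: int | None = None,
) -> tuple[HeightImage, GroundTruth]:
    """Hexagonal lattice of three-bump clusters (trimer units).

    Trimer centroids sit on a hexagonal lattice with the given lattice
    constant (pixels); each trimer holds three monomer bumps of scale
    ``monomer_t0`` at distance ``trimer_spacing`` from the centroid. The
    ground truth lists every monomer center as a planted blob and the
    trimer centroids separately. Clusters that would overflow the safe
    margin are clipped (with a warning when nothing fits).

    The defaults emulate the bacteriorhodopsin purple-membrane lattice at
    0.25 nm/px: 6.25 nm lattice constant, monomer bumps of width
    sigma = 0.5 nm separated by ~1.6 nm within a trimer — close enough to
    merge into one coarse-scale unit while staying individually resolvable
    at fine scales, so the fixture exhibits genuine nested structure.
    """
    if trimer_spacing <= 0 or lattice_constant <= 0 or monomer_t0 <= 0:
        raise ValueError("lattice geometry parameters must be positive")
    rows, cols = shape
    margin = 3.0 * np.sqrt(2.0 * monomer_t0) + trimer_spacing
    dy = lattice_constant * np.sqrt(3.0) / 2.0
    angles = np.deg2rad([90.0, 210.0, 330.0])
    monomers: list[PlantedBlob] = []
    centroids = []
    row_idx = 0
    y = margin
    while y <= rows - 1 - margin:
        x = margin + (lattice_constant / 2.0 if row_idx % 2 else 0.0)
        while x <= cols - 1 - margin:
            centroids.append((x, y))
            for a in angles:
                monomers.append(
                    PlantedBlob(
                        x=float(x + trimer_spacing * np.cos(a)),
                        y=float(y + trimer_spacing * np.sin(a)),
                        amplitude=amplitude,
                        t0_px2=monomer_t0,
                    )
                )
            x += lattice_constant
        y += dy
        row_idx += 1
    if not centroids:
        warnings.warn("lattice does not fit in the image; empty ground truth",
                      stacklevel=2)
    img = HeightImage(_render(shape, monomers), pixel_size)
    gt = GroundTruth(
        blobs=monomers,
        pixel_size=pixel_size,
        background="flat",
        seed=seed,
        trimer_centers=np.array(centroids).reshape(-1, 2),
    )
    return img, gt


def perturb(
    img: HeightImage,
    kind: str,
    magnitude: float,
    seed: int | None = None,
    fault_row: int | None = None,
) -> HeightImage:
    """Apply one AFM-style image perturbation; stochastic kinds are
    reproducible under ``seed``.

    offset          add ``magnitude`` everywhere
    fault           add ``magnitude`` to every scanline above ``fault_row``
                    (default: image mid-height)
    tilt            plane rising to ``magnitude`` corner-to-corner
    parabolic       per-scanline parabola, zero at the line ends and
                    peaking at ``magnitude`` mid-line (bowing artifact)
    scanline_noise  per-scanline offsets ~ N(0, magnitude^2)
    gaussian_noise  per-pixel noise ~ N(0, magnitude^2)
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if kind not in PERTURBATION_KINDS:
        raise ValueError(
            f"unknown perturbation {kind!r}; expected one of {PERTURBATION_KINDS}"
        )
    h = img.heights
    rows, cols = h.shape
    if kind == "offset":
        add = np.full_like(h, magnitude)
    elif kind == "fault":
        cut = rows // 2 if fault_row is None else int(fault_row)
        add = np.zeros_like(h)
        add[:cut, :] = magnitude
    elif kind == "tilt":
        R, C = np.mgrid[0:rows, 0:cols].astype(float)
        add = magnitude * (R + C) / float(rows - 1 + cols - 1)
    elif kind == "parabolic":
        u = 2.0 * np.arange(cols) / (cols - 1) - 1.0  # -1 .. 1 along each line
        add = np.tile(magnitude * (1.0 - u * u), (rows, 1))
    elif kind == "scanline_noise":
        rng = np.random.default_rng(seed)
        add = np.repeat(rng.normal(0.0, magnitude, size=(rows, 1)), cols, axis=1)
    else:  # gaussian_noise
        rng = np.random.default_rng(seed)
        add = rng.normal(0.0, magnitude, size=h.shape)
    return img.copy_with(h + add)
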