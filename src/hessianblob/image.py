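"""Height-image container for AFM-style topographic data.

Coordinate convention used throughout the package: images are stored
row-major with the origin at the top-left *pixel center*; ``x`` runs along
columns and ``y`` along rows, so a pixel at index ``(i, j)`` sits at the
physical position ``(x, y) = (j * pixel_size_x, i * pixel_size_y)``.
Heights are in length units (typically nm).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HeightImage"]


@dataclass
class HeightImage:
    """A single-channel height map with physical pixel spacing.

    Parameters
    ----------
    heights : ndarray
        2D array of heights (length units, e.g. nm). Must be finite.
    pixel_size_x, pixel_size_y : float
        Lateral pixel spacing along columns / rows (same length unit as the
        heights). ``pixel_size_y`` defaults to ``pixel_size_x``.
    unit_label : str
        Name of the length unit, used in output headers.
    """

    heights: np.ndarray
    pixel_size_x: float
    pixel_size_y: float | None = None
    unit_label: str = "nm"

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError(
                f"heights must be a 2D array, got ndim={self.heights.ndim}"
            )
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights contain non-finite values")
        if self.pixel_size_y is None:
            self.pixel_size_y = self.pixel_size_x
        self.pixel_size_x = float(self.pixel_size_x)
        self.pixel_size_y = float(self.pixel_size_y)
        if self.pixel_size_x <= 0 or self.pixel_size_y <= 0:
            raise ValueError("pixel sizes must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def pixel_size(self) -> float:
        """Isotropic pixel size; raises for anisotropic grids (>1% off)."""
        px, py = self.pixel_size_x, self.pixel_size_y
        if abs(px - py) > 0.01 * max(px, py):
            raise ValueError(
                f"anisotropic pixels (dx={px}, dy={py}); the detector "
                "requires square pixels within 1%"
            )
        return 0.5 * (px + py)

    @property
    def pixel_area(self) -> float:
        return self.pixel_size_x * self.pixel_size_y

    def copy_with(self, heights: np.ndarray) -> "HeightImage":
        """New image sharing this image's metadata."""
        return HeightImage(
            heights=np.array(heights, dtype=float),
            pixel_size_x=self.pixel_size_x,
            pixel_size_y=self.pixel_size_y,
            unit_label=self.unit_label,
        )
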