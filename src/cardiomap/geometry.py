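"""Dish geometries and pixel/mm calibration.

A monolayer sits either in a circular culture dish (35 mm by default) or in a
rectangular strip (PDMS channel on a slide).  The camera sees a
``grid_rows x grid_cols`` superpixel grid; ``pixel_pitch_mm`` converts pixel
indices to physical distance.  All coordinates are 0-based ``(row, col)`` with
the origin at the top-left; physical positions refer to pixel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DishGeometry", "make_geometry"]


@dataclass
class DishGeometry:
    """Dish footprint on the camera grid.

    Attributes
    ----------
    shape : {"circle", "rectangle"}
    pixel_pitch_mm : float
        Physical size of one superpixel (mm).
    grid_rows, grid_cols : int
        Camera grid dimensions.
    mask : ndarray of bool, shape (grid_rows, grid_cols)
        True where the pixel center lies inside the dish footprint.
    diameter_mm : float or None
        Circle diameter (mm); None for rectangles.
    width_mm, length_mm : float or None
        Rectangle extents (width along rows, length along columns).
    """

    shape: str
    pixel_pitch_mm: float
    grid_rows: int
    grid_cols: int
    mask: np.ndarray = field(repr=False)
    diameter_mm: float | None = None
    width_mm: float | None = None
    length_mm: float | None = None

    @property
    def center_mm(self) -> tuple[float, float]:
        """Grid center in (y, x) mm."""
        return (self.grid_rows * self.pixel_pitch_mm / 2.0,
                self.grid_cols * self.pixel_pitch_mm / 2.0)

    def pixel_coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(y, x) coordinates of every pixel center in mm, each (rows, cols)."""
        p = self.pixel_pitch_mm
        y = (np.arange(self.grid_rows)[:, None] + 0.5) * p
        x = (np.arange(self.grid_cols)[None, :] + 0.5) * p
        return np.broadcast_to(y, (self.grid_rows, self.grid_cols)), \
            np.broadcast_to(x, (self.grid_rows, self.grid_cols))

    def distance_mm(self, origin_rc: tuple[int, int]) -> np.ndarray:
        """Euclidean distance (mm) of every pixel center from ``origin_rc``."""
        y, x = self.pixel_coords_mm()
        oy = (origin_rc[0] + 0.5) * self.pixel_pitch_mm
        ox = (origin_rc[1] + 0.5) * self.pixel_pitch_mm
        return np.hypot(y - oy, x - ox)

    def contains(self, rc: tuple[int, int]) -> bool:
        r, c = rc
        if not (0 <= r < self.grid_rows and 0 <= c < self.grid_cols):
            return False
        return bool(self.mask[r, c])

    def to_dict(self) -> dict:
        d = {
            "shape": self.shape,
            "pixel_pitch_mm": self.pixel_pitch_mm,
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
        }
        for k in ("diameter_mm", "width_mm", "length_mm"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DishGeometry":
        return make_geometry(
            d["shape"],
            diameter_mm=d.get("diameter_mm"),
            width_mm=d.get("width_mm"),
            length_mm=d.get("length_mm"),
            pixel_pitch_mm=d["pixel_pitch_mm"],
            grid_rows=d["grid_rows"],
            grid_cols=d["grid_cols"],
        )


def make_geometry(
    shape: str = "circle",
    *,
    diameter_mm: float | None = 35.0,
    width_mm: float | None = None,
    length_mm: float | None = None,
    pixel_pitch_mm: float = 0.2,
    grid_rows: int = 180,
    grid_cols: int = 180,
) -> DishGeometry:
    """Build a dish geometry and its pixel mask.

    The default is a 35 mm circular dish on a 180x180 superpixel grid at
    0.2 mm/superpixel, so the dish spans ~175 of the 180 superpixels.

    Raises
    ------
    ValueError
        If the dish footprint does not fit on the grid, or dimensions are
        not positive.
    """
    if pixel_pitch_mm <= 0:
        raise ValueError("pixel_pitch_mm must be positive")
    if grid_rows < 1 or grid_cols < 1:
        raise ValueError("grid dimensions must be positive")

    p = pixel_pitch_mm
    if shape == "circle":
        if diameter_mm is None or diameter_mm <= 0:
            raise ValueError("circle requires a positive diameter_mm")
        needed = diameter_mm / p
        if needed > min(grid_rows, grid_cols):
            raise ValueError(
                f"dish footprint exceeds grid: diameter {diameter_mm} mm needs "
                f"{needed:.0f} px at {p} mm/px but grid is "
                f"{grid_rows}x{grid_cols}"
            )
        cy = grid_rows * p / 2.0
        cx = grid_cols * p / 2.0
        y = (np.arange(grid_rows)[:, None] + 0.5) * p
        x = (np.arange(grid_cols)[None, :] + 0.5) * p
        mask = (y - cy) ** 2 + (x - cx) ** 2 < (diameter_mm / 2.0) ** 2
        return DishGeometry(
            shape="circle", pixel_pitch_mm=p, grid_rows=grid_rows,
            grid_cols=grid_cols, mask=mask, diameter_mm=diameter_mm,
        )

    if shape == "rectangle":
        if not width_mm or not length_mm or width_mm <= 0 or length_mm <= 0:
            raise ValueError("rectangle requires positive width_mm and length_mm")
        nr = int(round(width_mm / p))
        nc = int(round(length_mm / p))
        if nr > grid_rows or nc > grid_cols:
            raise ValueError(
                f"dish footprint exceeds grid: {width_mm}x{length_mm} mm needs "
                f"{nr}x{nc} px but grid is {grid_rows}x{grid_cols}"
            )
        mask = np.zeros((grid_rows, grid_cols), dtype=bool)
        r0 = (grid_rows - nr) // 2
        c0 = (grid_cols - nc) // 2
        mask[r0:r0 + nr, c0:c0 + nc] = True
        return DishGeometry(
            shape="rectangle", pixel_pitch_mm=p, grid_rows=grid_rows,
            grid_cols=grid_cols, mask=mask, width_mm=width_mm,
            length_mm=length_mm,
        )

    raise ValueError(f"unknown shape {shape!r}; expected 'circle' or 'rectangle'")
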