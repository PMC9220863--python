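"""Image-grid geometry and the package-wide coordinate convention.

Convention (fixed everywhere in this package):

* the origin is the top-left corner of pixel ``(row=0, col=0)``;
* ``x_nm`` increases with column index, ``y_nm`` with row index;
* a physical point maps to the pixel ``(floor(y/p), floor(x/p))`` where
  ``p`` is the x-y pixel pitch — half-open pixel ownership, so a point
  sitting exactly on a pixel boundary belongs to the higher-index pixel;
* the physical position of a pixel *center* is ``(index + 0.5) * p``.

All distances handed to the statistics modules are 2D (x, y): the inputs
are maximum-intensity projections, and any z coordinate carried by a spot
table is preserved on load but never enters a distance computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default x-y pixel pitch of the widefield setup the defaults emulate (nm).
DEFAULT_PIXEL_SIZE_NM = 107.5
#: Default z-step between optical planes (nm); carried for provenance only.
DEFAULT_Z_STEP_NM = 200.0


@dataclass(frozen=True)
class GridGeometry:
    """Physical geometry of one field of view.

    Parameters
    ----------
    height, width:
        Image shape in pixels.
    pixel_size_xy:
        Lateral pixel pitch in nm (> 0).
    z_step:
        Axial step in nm (> 0); informational, 2D analysis never uses it.
    """

    height: int
    width: int
    pixel_size_xy: float = DEFAULT_PIXEL_SIZE_NM
    z_step: float = DEFAULT_Z_STEP_NM

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError(f"image shape must be >= 1x1, got {self.height}x{self.width}")
        if self.pixel_size_xy <= 0:
            raise ValueError(f"pixel_size_xy must be > 0, got {self.pixel_size_xy}")
        if self.z_step <= 0:
            raise ValueError(f"z_step must be > 0, got {self.z_step}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def extent_x_nm(self) -> float:
        """Physical width of the field of view in nm (exclusive upper bound)."""
        return self.width * self.pixel_size_xy

    @property
    def extent_y_nm(self) -> float:
        return self.height * self.pixel_size_xy

    def to_pixel(self, x_nm, y_nm) -> tuple[np.ndarray, np.ndarray]:
        """Rasterize physical coordinates to ``(row, col)`` indices (floor)."""
        col = np.floor(np.asarray(x_nm, dtype=float) / self.pixel_size_xy).astype(np.int64)
        row = np.floor(np.asarray(y_nm, dtype=float) / self.pixel_size_xy).astype(np.int64)
        return row, col

    def pixel_center_nm(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x_nm, y_nm) of pixel centers."""
        x = (np.asarray(col, dtype=float) + 0.5) * self.pixel_size_xy
        y = (np.asarray(row, dtype=float) + 0.5) * self.pixel_size_xy
        return x, y

    def in_bounds(self, x_nm, y_nm) -> np.ndarray:
        """Vectorized bounds check for the half-open extent ``[0, n*p)``."""
        x = np.asarray(x_nm, dtype=float)
        y = np.asarray(y_nm, dtype=float)
        return (x >= 0) & (x < self.extent_x_nm) & (y >= 0) & (y < self.extent_y_nm)
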