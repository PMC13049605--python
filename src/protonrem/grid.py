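"""Regular volumetric grids with world-space metadata.

All volumes in the package live on axis-aligned regular grids indexed
``(ix, iy, iz)`` with patient-like LPS axes: +x left, +y posterior,
+z superior.  Positions are in mm, voxel centers at
``origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DoseGrid", "centered_origin"]


def centered_origin(shape, spacing) -> tuple[float, float, float]:
    """Origin that centers the grid on the world origin (voxel-center convention)."""
    return tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))


@dataclass
class DoseGrid:
    """A 3D scalar field (dose in Gy(RBE), density, ...) on a regular grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
    spacing : triple of mm
    origin : world coordinates (mm) of the center of voxel (0, 0, 0)
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("DoseGrid values must be a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def voxel_centers(self):
        """1D world-coordinate arrays (x, y, z) of voxel centers."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )

    def same_geometry(self, other: "DoseGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )

    def copy_with(self, values: np.ndarray) -> "DoseGrid":
        return DoseGrid(values, self.spacing, self.origin)
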