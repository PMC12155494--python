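"""The common 3D voxel-grid currency.

Every volume in the package — tracer activity, 511 keV linear attenuation,
non-AC and attenuation-corrected PET — is a :class:`VoxelGrid`: a 3D scalar
field plus its physical voxel spacing in millimetres.  The default spacing
(4.07, 4.07, 3.0) mm matches a whole-body PET reconstruction grid.

Coordinate convention: 0-based voxel indices; the physical position of voxel
``(i, j, k)`` is ``((i + 0.5) * sx, (j + 0.5) * sy, (k + 0.5) * sz)`` mm.
Grids are written to NIfTI in RAS orientation with an identity rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Default voxel spacing in mm for all synthetic volumes.
DEFAULT_SPACING_MM = (4.07, 4.07, 3.0)


@dataclass
class VoxelGrid:
    """A 3D scalar field with physical spacing.

    Parameters
    ----------
    data:
        3D array of finite reals.  Activity-like grids must be >= 0
        everywhere; attenuation grids hold cm^-1 values at 511 keV.
    spacing_mm:
        Positive voxel edge lengths ``(sx, sy, sz)`` in millimetres.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = field(default=DEFAULT_SPACING_MM)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VoxelGrid data must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("VoxelGrid data contains non-finite values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be 3 positive reals, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        """A new grid with the same spacing but different voxel values."""
        return replace(self, data=np.asarray(data))

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical center coordinates of every voxel along each axis (1D arrays)."""
        return tuple(
            (np.arange(n) + 0.5) * s for n, s in zip(self.shape, self.spacing_mm)
        )

    def index_to_mm(self, index) -> np.ndarray:
        """Physical position (mm) of a (possibly fractional) voxel index."""
        return (np.asarray(index, dtype=float) + 0.5) * np.asarray(self.spacing_mm)

    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing_mm, other.spacing_mm, atol=atol
        )


def require_same_geometry(*grids: VoxelGrid) -> None:
    """Raise if the grids do not share shape and spacing."""
    first = grids[0]
    for g in grids[1:]:
        if not first.same_geometry(g):
            raise ValueError(
                f"grids disagree in geometry: {first.shape}@{first.spacing_mm} "
                f"vs {g.shape}@{g.spacing_mm}"
            )


def require_activity(grid: VoxelGrid) -> None:
    """Activity-like grids must be non-negative everywhere."""
    if np.any(grid.data < 0):
        raise ValueError("activity grid has negative voxels")
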