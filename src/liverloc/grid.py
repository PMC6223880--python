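"""Volumetric image containers with world (mm, LPS) geometry.

A :class:`Volume` is a 3D scalar grid — CT intensities in Hounsfield units
for images, {0,1} for masks — together with voxel spacing, world origin and
axis direction matrix. World coordinates follow the LPS convention used by
ITK/DICOM; voxel indices are 0-based and refer to voxel centres, with the
array indexed ``data[i, j, k]`` along the (x, y, z) world axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = ["Volume", "Mask", "GeometryError"]


class GeometryError(ValueError):
    """Raised when two volumes that must share a grid do not."""


@dataclass
class Volume:
    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.direction is None:
            self.direction = np.eye(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (N,3) 0-based voxel indices (voxel centres) to world mm."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return (self.direction @ (idx * self.spacing).T).T + self.origin

    def world_to_voxel(self, pts_mm: np.ndarray) -> np.ndarray:
        pts_mm = np.atleast_2d(np.asarray(pts_mm, dtype=float))
        return (np.linalg.inv(self.direction) @ (pts_mm - self.origin).T).T / self.spacing

    def grid_world_coords(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (nx, ny, nz, 3)."""
        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return self.voxel_to_world(idx).reshape(nx, ny, nz, 3)

    def centre_mm(self) -> np.ndarray:
        """World coordinates of the grid centre."""
        return self.voxel_to_world((np.array(self.shape, dtype=float) - 1) / 2.0)[0]

    def same_grid(self, other: "Volume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )

    def require_same_grid(self, other: "Volume", what: str = "volumes") -> None:
        if not self.same_grid(other):
            raise GeometryError(f"{what} are not on the same grid")

    def copy(self, data: np.ndarray | None = None) -> "Volume":
        cls = type(self)
        return cls(
            data=self.data.copy() if data is None else data,
            spacing=self.spacing.copy(),
            origin=self.origin.copy(),
            direction=self.direction.copy(),
        )

    # -- SimpleITK bridge --------------------------------------------------
    def to_sitk(self, dtype=None) -> sitk.Image:
        arr = self.data if dtype is None else self.data.astype(dtype)
        img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(arr, (2, 1, 0))))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        img.SetDirection(tuple(self.direction.flatten()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "Volume":
        arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        return cls(
            data=arr,
            spacing=np.array(img.GetSpacing()),
            origin=np.array(img.GetOrigin()),
            direction=np.array(img.GetDirection()).reshape(3, 3),
        )


class Mask(Volume):
    """Binary volume on the same grid as its parent image."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def is_empty(self) -> bool:
        return not bool(self.data.any())

    def to_sitk(self, dtype=np.uint8) -> sitk.Image:
        return super().to_sitk(dtype=dtype)
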