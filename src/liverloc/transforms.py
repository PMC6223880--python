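"""World-coordinate spatial transforms: rigid motion and B-spline free-form
deformation.

All transforms map world points (mm, LPS) to world points. Registration
results and phantom ground truths are stored in the *resampling* direction
(fixed/intraprocedural space → moving/diagnostic space), the convention used
by ITK-family tools: resampling the moving image onto the fixed grid samples
``moving(T(x_fixed))``.

The cubic B-spline free-form deformation follows the ITK lattice convention:
a regular grid of coefficient vectors, displacement at ``x`` given by the
tensor-product cubic B-spline expansion of the surrounding 4×4×4
coefficients. ``BSplineDeformation.displacement_at`` is an explicit numpy
implementation of that summation; it agrees with
``sitk.BSplineTransform.TransformPoint`` and serves the rest of the package,
while the SimpleITK object is used for fast dense resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import gaussian_filter
from scipy.spatial.transform import Rotation

from .grid import Volume

__all__ = [
    "RigidTransform",
    "BSplineDeformation",
    "ComposedTransform",
    "random_bspline_field",
    "cubic_bspline_weights",
]


@dataclass
class RigidTransform:
    """6-DOF rigid map ``p -> R (p - c) + c + t`` about centre ``c`` (mm)."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    centre_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation_mm = np.asarray(self.translation_mm, dtype=float).reshape(3)
        self.centre_mm = np.asarray(self.centre_mm, dtype=float).reshape(3)
        if not np.allclose(self.matrix @ self.matrix.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation part must be orthonormal")
        if np.linalg.det(self.matrix) < 0:
            raise ValueError("rotation part must have determinant +1 (no reflection)")

    # -- constructors -------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_euler_deg(
        cls, angles_deg, translation_mm=(0.0, 0.0, 0.0), centre_mm=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        """Rigid transform from extrinsic x-y-z Euler angles in degrees."""
        mat = Rotation.from_euler("xyz", np.asarray(angles_deg, float), degrees=True).as_matrix()
        return cls(matrix=mat, translation_mm=translation_mm, centre_mm=centre_mm)

    @classmethod
    def z_rotation(cls, angle_deg: float, centre_mm, translation_mm=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """In-plane rotation about the cranio-caudal (z) axis."""
        return cls.from_euler_deg((0.0, 0.0, angle_deg), translation_mm, centre_mm)

    # -- algebra -------------------------------------------------------------
    def apply(self, pts_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_mm, dtype=float))
        return (self.matrix @ (pts - self.centre_mm).T).T + self.centre_mm + self.translation_mm

    def inverse(self) -> "RigidTransform":
        return RigidTransform(
            matrix=self.matrix.T,
            translation_mm=-self.matrix.T @ self.translation_mm,
            centre_mm=self.centre_mm,
        )

    def euler_deg(self) -> np.ndarray:
        return Rotation.from_matrix(self.matrix).as_euler("xyz", degrees=True)

    def rotation_angle_deg(self) -> float:
        """Total rotation magnitude (angle of the axis-angle form), degrees."""
        return float(np.degrees(np.linalg.norm(Rotation.from_matrix(self.matrix).as_rotvec())))

    # -- interop / io --------------------------------------------------------
    def to_sitk(self) -> sitk.Euler3DTransform:
        t = sitk.Euler3DTransform()
        t.SetCenter(tuple(self.centre_mm))
        t.SetMatrix(tuple(self.matrix.flatten()))
        t.SetTranslation(tuple(self.translation_mm))
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Transform) -> "RigidTransform":
        if not isinstance(t, sitk.Euler3DTransform):
            t = t.Downcast() if hasattr(t, "Downcast") else t
            while isinstance(t, sitk.CompositeTransform):
                if t.GetNumberOfTransforms() != 1:
                    raise ValueError("cannot flatten a multi-part composite to a rigid transform")
                t = t.GetNthTransform(0).Downcast()
            t = sitk.Euler3DTransform(t)
        return cls(
            matrix=np.array(t.GetMatrix()).reshape(3, 3),
            translation_mm=np.array(t.GetTranslation()),
            centre_mm=np.array(t.GetCenter()),
        )

    def to_dict(self) -> dict:
        return {
            "type": "rigid",
            "matrix": self.matrix.tolist(),
            "translation_mm": self.translation_mm.tolist(),
            "centre_mm": self.centre_mm.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            matrix=np.array(d["matrix"]),
            translation_mm=np.array(d["translation_mm"]),
            centre_mm=np.array(d["centre_mm"]),
        )


def cubic_bspline_weights(u: np.ndarray) -> np.ndarray:
    """The four cubic B-spline basis values at fractional offset ``u`` in [0,1).

    Returns shape ``u.shape + (4,)`` with weights for control points at
    relative indices -1, 0, 1, 2; the weights sum to 1.
    """
    u = np.asarray(u, dtype=float)
    u2, u3 = u * u, u**3
    w = np.empty(u.shape + (4,))
    w[..., 0] = (1 - u) ** 3 / 6.0
    w[..., 1] = (3 * u3 - 6 * u2 + 4) / 6.0
    w[..., 2] = (-3 * u3 + 3 * u2 + 3 * u + 1) / 6.0
    w[..., 3] = u3 / 6.0
    return w


@dataclass
class BSplineDeformation:
    """Cubic B-spline free-form deformation on a regular control lattice.

    ``coefficients`` has shape (nx, ny, nz, 3): a displacement coefficient
    vector (mm) per control point. The deformation is defined where a full
    4-point support exists, i.e. for lattice coordinates in [1, n-2] per
    axis; outside that domain the displacement is zero (the map falls back
    to the identity / the rigid part of a composition).
    """

    grid_origin_mm: np.ndarray
    grid_spacing_mm: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.grid_origin_mm = np.asarray(self.grid_origin_mm, dtype=float).reshape(3)
        self.grid_spacing_mm = np.asarray(self.grid_spacing_mm, dtype=float).reshape(3)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 4 or self.coefficients.shape[-1] != 3:
            raise ValueError("coefficients must have shape (nx, ny, nz, 3)")
        if min(self.coefficients.shape[:3]) < 4:
            raise ValueError("control lattice needs at least 4 points per axis")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.coefficients.shape[:3]  # type: ignore[return-value]

    def lattice_coords(self, pts_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_mm, dtype=float))
        return (pts - self.grid_origin_mm) / self.grid_spacing_mm

    def in_domain(self, pts_mm: np.ndarray) -> np.ndarray:
        s = self.lattice_coords(pts_mm)
        n = np.array(self.grid_shape, dtype=float)
        return np.all((s >= 1.0) & (s <= n - 2.0 - 1e-12), axis=1)

    def displacement_at(self, pts_mm: np.ndarray) -> np.ndarray:
        """Displacement vectors (mm) at world points, via direct tensor-product
        summation of the 4x4x4 surrounding coefficients. Zero outside the
        lattice's valid domain."""
        pts = np.atleast_2d(np.asarray(pts_mm, dtype=float))
        s = self.lattice_coords(pts)
        inside = self.in_domain(pts)
        out = np.zeros((len(pts), 3))
        if not inside.any():
            return out
        s_in = s[inside]
        base = np.floor(s_in).astype(int)  # support: base-1 .. base+2
        frac = s_in - base
        wx = cubic_bspline_weights(frac[:, 0])
        wy = cubic_bspline_weights(frac[:, 1])
        wz = cubic_bspline_weights(frac[:, 2])
        disp = np.zeros((len(s_in), 3))
        for a in range(4):
            ix = base[:, 0] + a - 1
            for b in range(4):
                iy = base[:, 1] + b - 1
                wab = wx[:, a] * wy[:, b]
                for c in range(4):
                    iz = base[:, 2] + c - 1
                    disp += (wab * wz[:, c])[:, None] * self.coefficients[ix, iy, iz]
        out[inside] = disp
        return out

    def apply(self, pts_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_mm, dtype=float))
        return pts + self.displacement_at(pts)

    def max_coefficient_mm(self) -> float:
        return float(np.abs(self.coefficients).max())

    # -- interop / io --------------------------------------------------------
    def to_sitk(self) -> sitk.BSplineTransform:
        imgs = []
        for axis in range(3):
            arr = np.ascontiguousarray(np.transpose(self.coefficients[..., axis], (2, 1, 0)))
            img = sitk.GetImageFromArray(arr.astype(np.float64))
            img.SetSpacing(tuple(self.grid_spacing_mm))
            img.SetOrigin(tuple(self.grid_origin_mm))
            imgs.append(img)
        return sitk.BSplineTransform(imgs, 3)

    @classmethod
    def from_sitk(cls, t: sitk.BSplineTransform) -> "BSplineDeformation":
        fixed = np.array(t.GetFixedParameters())
        size = fixed[:3].astype(int)
        origin = fixed[3:6]
        spacing = fixed[6:9]
        params = np.array(t.GetParameters())
        coeffs = np.stack(
            [
                np.transpose(axis_block.reshape(size[2], size[1], size[0]), (2, 1, 0))
                for axis_block in params.reshape(3, -1)
            ],
            axis=-1,
        )
        return cls(grid_origin_mm=origin, grid_spacing_mm=spacing, coefficients=coeffs)

    def to_dict(self) -> dict:
        return {
            "type": "bspline",
            "grid_origin_mm": self.grid_origin_mm.tolist(),
            "grid_spacing_mm": self.grid_spacing_mm.tolist(),
            "grid_shape": list(self.grid_shape),
            "coefficients": self.coefficients.ravel().tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BSplineDeformation":
        shape = tuple(d["grid_shape"]) + (3,)
        return cls(
            grid_origin_mm=np.array(d["grid_origin_mm"]),
            grid_spacing_mm=np.array(d["grid_spacing_mm"]),
            coefficients=np.array(d["coefficients"]).reshape(shape),
        )


@dataclass
class ComposedTransform:
    """Rigid motion composed with a B-spline warp: ``x -> R(x + u(x))``.

    This is the shape of a registration result where the rigid stage
    initialises the non-rigid stage: the warp acts in the fixed image's
    world frame, the rigid part then carries the point into the moving
    image's frame.
    """

    rigid: RigidTransform
    deformation: BSplineDeformation | None = None

    def apply(self, pts_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_mm, dtype=float))
        if self.deformation is not None:
            pts = self.deformation.apply(pts)
        return self.rigid.apply(pts)

    def to_sitk(self) -> sitk.Transform:
        if self.deformation is None:
            return self.rigid.to_sitk()
        comp = sitk.CompositeTransform(3)
        # CompositeTransform applies the most recently added transform first.
        comp.AddTransform(self.rigid.to_sitk())
        comp.AddTransform(self.deformation.to_sitk())
        return comp

    def to_dict(self) -> dict:
        return {
            "type": "composed",
            "rigid": self.rigid.to_dict(),
            "deformation": None if self.deformation is None else self.deformation.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ComposedTransform":
        return cls(
            rigid=RigidTransform.from_dict(d["rigid"]),
            deformation=None
            if d.get("deformation") is None
            else BSplineDeformation.from_dict(d["deformation"]),
        )


def random_bspline_field(
    grid_spacing_mm: float,
    amplitude_mm: float,
    domain: Volume,
    seed: int,
    smooth_sigma_cp: float = 0.5,
) -> BSplineDeformation:
    """Random smooth deformation covering a volume's world extent.

    Control coefficients are drawn i.i.d. uniform in [-amplitude, amplitude]
    per axis and then smoothed across the lattice with a (normalised)
    Gaussian. Because cubic B-spline basis weights are non-negative and sum
    to one, the dense displacement magnitude per axis is bounded by the
    largest coefficient, hence by ``amplitude_mm``.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude_mm must be >= 0")
    if grid_spacing_mm < 2.0 * float(np.min(domain.spacing)):
        raise ValueError(
            f"control spacing {grid_spacing_mm} mm is a degenerate lattice for "
            f"voxel spacing {domain.spacing} mm (needs >= 2 voxels)"
        )
    extent = (np.array(domain.shape) - 1) * domain.spacing
    lo = domain.origin - 2.0 * grid_spacing_mm
    n = np.ceil(extent / grid_spacing_mm).astype(int) + 5
    rng = np.random.default_rng(seed)
    coeffs = rng.uniform(-amplitude_mm, amplitude_mm, size=tuple(n) + (3,))
    if smooth_sigma_cp > 0 and amplitude_mm > 0:
        for axis in range(3):
            coeffs[..., axis] = gaussian_filter(
                coeffs[..., axis], sigma=smooth_sigma_cp, mode="nearest"
            )
        # restore the drawn scale (smoothing shrinks iid draws) without
        # breaking the bound: max |coefficient| is exactly amplitude_mm again
        coeffs *= amplitude_mm / np.abs(coeffs).max()
    return BSplineDeformation(
        grid_origin_mm=lo,
        grid_spacing_mm=np.full(3, float(grid_spacing_mm)),
        coefficients=coeffs,
    )
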