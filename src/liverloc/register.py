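"""Liver-masked rigid and B-spline non-rigid registration.

Aligns a diagnostic CECT (moving) to an intraprocedural virtually
unenhanced CT (fixed): an initial rigid alignment from liver-mask centroids
(optionally orienting an anteroposterior axis to handle extreme patient
rotation), a masked rigid refinement, then a coarse-to-fine cubic B-spline
free-form deformation restricted to the liver region. The recovered
transforms map fixed-space world points to moving-space world points (the
resampling convention), so transferring the outlined diagnostic tumour onto
the intraprocedural grid is a direct inverse-mapping resample.

The intensity relationship between a contrast-enhanced liver and its
virtually unenhanced counterpart is non-linear, so the rigid stage measures
similarity with mutual information over the (dilated) fixed liver mask,
optimised with Powell's method via SimpleITK's registration framework. The
non-rigid stage estimates a dense liver displacement with multi-resolution
symmetric-forces Demons between intensity-comparable (de-enhanced) volumes
— the Gaussian field smoothing acting as the regulariser — and projects it
onto the cubic B-spline lattice. This module owns the initialisation,
masking, transform model, lattice projection, similarity reporting and the
failure check.

A registration that converges to a solution where the livers do not overlap
is detected by the Dice coefficient of the fixed liver mask and the warped
moving liver mask: below ``failure_dice_threshold`` the result is flagged
failed rather than raising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import distance_transform_edt, gaussian_filter, map_coordinates, spline_filter

from .grid import Mask, Volume
from .transforms import BSplineDeformation, ComposedTransform, RigidTransform

__all__ = [
    "RegistrationParams",
    "RegistrationResult",
    "RegistrationError",
    "initial_alignment",
    "similarity",
    "register_rigid",
    "register_bspline",
    "transform_point",
    "transform_mask",
    "check_failure",
    "dilate_mask",
]


class RegistrationError(RuntimeError):
    """Optimisation diverged (non-finite metric) or inputs are unusable."""


@dataclass
class RegistrationParams:
    """Numeric settings of the registration.

    The multi-resolution pyramid and the control-point spacing schedule are
    coarse-to-fine; ``control_spacing_schedule_mm`` must be decreasing and
    its refinement factors power-of-two (the lattice is refined by grid
    doubling between levels).
    """

    metric_bins: int = 32
    pyramid_shrink: tuple[int, ...] = (4, 2, 1)
    pyramid_smoothing_vox: tuple[float, ...] = (2.0, 1.0, 0.0)
    rigid_iterations: int = 10
    rigid_line_iterations: int = 10
    demons_shrink: tuple[int, ...] = (4, 2)
    demons_iterations: tuple[int, ...] = (60, 40)
    demons_update_sigma_vox: float = 2.0
    demons_field_sigma_vox: float = 2.0
    demons_mask_dilation_mm: float = 10.0
    control_spacing_schedule_mm: tuple[float, ...] = (64.0, 32.0, 16.0)
    mask_dilation_mm: float = 5.0
    sampling_fraction: float = 0.25
    sampling_seed: int = 12345
    step_length: float = 1.0
    step_tolerance: float = 1e-3
    failure_dice_threshold: float = 0.3

    def __post_init__(self) -> None:
        if len(self.pyramid_shrink) < 1:
            raise ValueError("need at least one pyramid level")
        if len(self.pyramid_shrink) != len(self.pyramid_smoothing_vox):
            raise ValueError("pyramid shrink/smoothing schedules must match in length")
        sched = self.control_spacing_schedule_mm
        if any(a <= b for a, b in zip(sched, sched[1:])):
            raise ValueError("control spacing schedule must be strictly decreasing")
        if len(self.demons_shrink) != len(self.demons_iterations):
            raise ValueError("demons shrink/iteration schedules must match in length")


@dataclass
class RegistrationResult:
    rigid: RigidTransform
    deformation: BSplineDeformation | None
    final_metric: float
    liver_overlap_dice: float | None
    failed: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def transform(self) -> ComposedTransform:
        return ComposedTransform(rigid=self.rigid, deformation=self.deformation)

    def apply(self, pts_mm: np.ndarray) -> np.ndarray:
        return self.transform.apply(pts_mm)

    def to_sitk(self) -> sitk.Transform:
        return self.transform.to_sitk()


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def _mask_centroid_mm(mask: Mask) -> np.ndarray:
    if mask.is_empty():
        raise ValueError("mask is empty")
    return mask.voxel_to_world(np.argwhere(mask.data)).mean(axis=0)


def dilate_mask(mask: Mask, dilation_mm: float) -> Mask:
    """Isotropic world-distance dilation of a binary mask."""
    if dilation_mm <= 0:
        return mask.copy()
    dist = distance_transform_edt(~mask.data, sampling=mask.spacing)
    return mask.copy(data=dist <= dilation_mm)


def initial_alignment(
    fixed_liver: Mask,
    moving_liver: Mask,
    fixed_axis: np.ndarray | None = None,
    moving_axis: np.ndarray | None = None,
) -> RigidTransform:
    """Initial rigid estimate from liver-mask centroids.

    Translation maps the fixed liver centroid onto the moving one. When
    anteroposterior axes are supplied (two world points each, e.g. spinous
    process → sternum), an in-plane rotation about the cranio-caudal axis
    aligns them first — this recovers even extremely rotated patients before
    the intensity-based refinement.
    """
    c_f = _mask_centroid_mm(fixed_liver)
    c_m = _mask_centroid_mm(moving_liver)
    angle = 0.0
    if fixed_axis is not None and moving_axis is not None:
        d_f = np.asarray(fixed_axis, float)[1] - np.asarray(fixed_axis, float)[0]
        d_m = np.asarray(moving_axis, float)[1] - np.asarray(moving_axis, float)[0]
        angle = np.degrees(np.arctan2(d_m[1], d_m[0]) - np.arctan2(d_f[1], d_f[0]))
    return RigidTransform.z_rotation(angle, centre_mm=c_f, translation_mm=c_m - c_f)


def similarity(fixed: Volume, moving_resampled: Volume, mask: Mask, bins: int = 32) -> float:
    """Normalised mutual information NMI = (H(A)+H(B)) / H(A,B) over masked
    voxels, from a ``bins``×``bins`` joint histogram. Ranges from 1
    (independent) to 2 (identical up to an intensity bijection); a constant
    image inside the mask has zero entropy and the metric is defined as 2.
    """
    fixed.require_same_grid(moving_resampled, "fixed and resampled moving volumes")
    fixed.require_same_grid(mask, "volume and mask")
    if mask.is_empty():
        raise ValueError("mask is empty")
    a = fixed.data[mask.data].astype(float)
    b = moving_resampled.data[mask.data].astype(float)
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()

    def entropy(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    h_ab = entropy(p.ravel())
    if h_ab == 0.0:
        return 2.0
    return (entropy(p.sum(axis=1)) + entropy(p.sum(axis=0))) / h_ab


def check_failure(
    transformed_moving_liver: Mask, fixed_liver: Mask, threshold: float = 0.3
) -> tuple[float, bool]:
    """Dice overlap of the warped moving liver with the fixed liver; a value
    below ``threshold`` declares the registration failed ("the livers do not
    overlap")."""
    transformed_moving_liver.require_same_grid(fixed_liver, "liver masks")
    a, b = transformed_moving_liver.data, fixed_liver.data
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        raise ValueError("both liver masks are empty")
    dice = 2.0 * float(np.logical_and(a, b).sum()) / denom
    return dice, dice < threshold


def transform_point(transform, pts_mm: np.ndarray) -> np.ndarray:
    """Map world points through a transform (rigid part, then the B-spline
    displacement where defined). Points outside the control-lattice support
    are mapped by the rigid part alone, with a warning."""
    obj = transform.transform if isinstance(transform, RegistrationResult) else transform
    if isinstance(obj, ComposedTransform) and obj.deformation is not None:
        pts = np.atleast_2d(np.asarray(pts_mm, float))
        if not np.all(obj.deformation.in_domain(pts)):
            warnings.warn(
                "point(s) outside the B-spline lattice support: rigid-only extrapolation",
                stacklevel=2,
            )
    return obj.apply(pts_mm)


def transform_mask(transform, mask: Mask, target_geometry: Volume) -> Mask:
    """Resample a (moving-space) mask onto the fixed grid by inverse mapping
    with linear interpolation thresholded at 0.5."""
    if mask.is_empty():
        raise ValueError("mask is empty")
    obj = transform.transform if isinstance(transform, RegistrationResult) else transform
    t = obj.to_sitk()
    ref = target_geometry.to_sitk(dtype=np.float32)
    src = mask.to_sitk(dtype=np.float32)
    res = sitk.Resample(src, ref, t, sitk.sitkLinear, 0.0, sitk.sitkFloat32)
    arr = np.transpose(sitk.GetArrayFromImage(res), (2, 1, 0))
    out = Mask(
        data=arr >= 0.5,
        spacing=target_geometry.spacing,
        origin=target_geometry.origin,
        direction=target_geometry.direction,
    )
    if out.is_empty():
        warnings.warn("mask mapped entirely outside the target field of view", stacklevel=2)
    return out


def resample_volume(transform, moving: Volume, target_geometry: Volume, default_value: float = -1000.0) -> Volume:
    """Resample a moving volume onto the fixed grid through a transform."""
    obj = transform.transform if isinstance(transform, RegistrationResult) else transform
    res = sitk.Resample(
        moving.to_sitk(dtype=np.float32),
        target_geometry.to_sitk(dtype=np.float32),
        obj.to_sitk(),
        sitk.sitkLinear,
        default_value,
        sitk.sitkFloat32,
    )
    out = Volume.from_sitk(res)
    out.data = out.data.astype(moving.data.dtype)
    return out


# ---------------------------------------------------------------------------
# intensity-based optimisation (SimpleITK engine)
# ---------------------------------------------------------------------------


def _setup_method(
    fixed: Volume, fixed_liver: Mask, params: RegistrationParams
) -> sitk.ImageRegistrationMethod:
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=params.metric_bins)
    reg.SetMetricFixedMask(dilate_mask(fixed_liver, params.mask_dilation_mm).to_sitk())
    if params.sampling_fraction < 1.0:
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(params.sampling_fraction, params.sampling_seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetShrinkFactorsPerLevel(list(params.pyramid_shrink))
    reg.SetSmoothingSigmasPerLevel(list(params.pyramid_smoothing_vox))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    return reg


def register_rigid(
    fixed: Volume,
    moving: Volume,
    fixed_liver: Mask,
    init: RigidTransform | None = None,
    params: RegistrationParams | None = None,
) -> RigidTransform:
    """Refine a rigid transform by maximising masked mutual information with
    a multi-resolution gradient descent. Deterministic for fixed inputs and
    parameters (the metric sampling seed is part of the parameters)."""
    params = params or RegistrationParams()
    init = init or RigidTransform(centre_mm=fixed.centre_mm())
    reg = _setup_method(fixed, fixed_liver, params)
    # Powell's direction-set method: derivative-free line searches are robust
    # to the sampling noise of the metric and land well inside a voxel
    reg.SetOptimizerAsPowell(
        numberOfIterations=params.rigid_iterations,
        maximumLineIterations=params.rigid_line_iterations,
        stepLength=params.step_length,
        stepTolerance=params.step_tolerance,
        valueTolerance=1e-7,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(init.to_sitk(), inPlace=False)
    out = reg.Execute(fixed.to_sitk(dtype=np.float32), moving.to_sitk(dtype=np.float32))
    metric = reg.GetMetricValue()
    if not np.isfinite(metric):
        raise RegistrationError(
            f"rigid optimisation diverged: metric={metric}, "
            f"stop='{reg.GetOptimizerStopConditionDescription()}'"
        )
    return RigidTransform.from_sitk(out)


def _zero_bspline(fixed: Volume, final_spacing_mm: float) -> BSplineDeformation:
    extent = (np.asarray(fixed.shape) - 1) * fixed.spacing
    n = np.ceil(extent / final_spacing_mm).astype(int) + 5
    return BSplineDeformation(
        grid_origin_mm=fixed.origin - 2.0 * final_spacing_mm,
        grid_spacing_mm=np.full(3, float(final_spacing_mm)),
        coefficients=np.zeros(tuple(n) + (3,)),
    )


def _multires_demons(
    fixed_img: sitk.Image, moving_img: sitk.Image, params: RegistrationParams
) -> sitk.Image:
    """Coarse-to-fine symmetric-forces Demons; returns the displacement
    field (mm) on the fixed grid. The Gaussian smoothing of update and total
    field is the deformation regulariser."""
    field = None
    for shrink, iters in zip(params.demons_shrink, params.demons_iterations):
        if shrink > 1:
            sig = [shrink * 0.7 * s for s in fixed_img.GetSpacing()]
            f = sitk.Shrink(sitk.SmoothingRecursiveGaussian(fixed_img, sig), [shrink] * 3)
            m = sitk.Shrink(sitk.SmoothingRecursiveGaussian(moving_img, sig), [shrink] * 3)
        else:
            f, m = fixed_img, moving_img
        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(int(iters))
        demons.SetSmoothUpdateField(True)
        demons.SetUpdateFieldStandardDeviations(params.demons_update_sigma_vox)
        demons.SetSmoothDisplacementField(True)
        demons.SetStandardDeviations(params.demons_field_sigma_vox)
        if field is not None:
            field = sitk.Cast(
                sitk.Resample(field, f, sitk.Transform(), sitk.sitkLinear), sitk.sitkVectorFloat64
            )
            field = demons.Execute(f, m, field)
        else:
            field = demons.Execute(f, m)
    if field.GetSize() != fixed_img.GetSize():
        field = sitk.Resample(field, fixed_img, sitk.Transform(), sitk.sitkLinear)
    return field


def _fit_bspline_to_field(field: sitk.Image, fixed: Volume, spacing_mm: float) -> BSplineDeformation:
    """Project a dense displacement field onto a cubic B-spline control
    lattice: low-pass at the lattice scale, sample at the control points,
    then prefilter to interpolating coefficients."""
    arr = np.transpose(sitk.GetArrayFromImage(field), (2, 1, 0, 3))
    extent = (np.asarray(fixed.shape) - 1) * fixed.spacing
    origin = fixed.origin - 2.0 * spacing_mm
    n = np.ceil(extent / spacing_mm).astype(int) + 5
    grids = np.meshgrid(*[origin[a] + spacing_mm * np.arange(n[a]) for a in range(3)], indexing="ij")
    cp_vox = ((np.stack(grids, axis=-1) - fixed.origin) / fixed.spacing).reshape(-1, 3).T
    coeffs = np.empty(tuple(n) + (3,))
    for a in range(3):
        smoothed = gaussian_filter(arr[..., a], sigma=0.5 * spacing_mm / fixed.spacing)
        vals = map_coordinates(smoothed, cp_vox, order=1, mode="nearest").reshape(tuple(n))
        coeffs[..., a] = spline_filter(vals, order=3, mode="nearest")
    return BSplineDeformation(
        grid_origin_mm=origin, grid_spacing_mm=np.full(3, float(spacing_mm)), coefficients=coeffs
    )


def register_bspline(
    fixed: Volume,
    moving: Volume,
    fixed_liver: Mask,
    init: RigidTransform,
    params: RegistrationParams | None = None,
    moving_liver: Mask | None = None,
) -> RegistrationResult:
    """Liver-restricted non-rigid registration on top of a rigid
    initialisation; the deformation is modelled as a cubic B-spline
    free-form deformation on a regular control lattice (final spacing =
    last entry of ``control_spacing_schedule_mm``).

    The displacement estimation runs multi-resolution symmetric-forces
    Demons between the fixed image and the moving image resampled through
    ``init``; both images should be intensity-comparable (the pipeline
    passes the two virtually unenhanced volumes). Outside the dilated fixed
    liver the moving values are replaced by the fixed values, so no forces
    arise there and the alignment is restricted to the liver region. The
    dense field is then projected onto the B-spline lattice, which acts as a
    final smoothness constraint and gives a compact, composable transform.

    ``final_metric`` is the normalised mutual information between the fixed
    image and the moving image resampled through the composed result, over
    the dilated fixed liver. When ``moving_liver`` is supplied, the Dice
    overlap of the warped moving liver with the fixed liver decides the
    failure flag ("the livers do not overlap"). Setting all Demons
    iterations to zero yields the identity deformation (used to probe the
    failure path).
    """
    params = params or RegistrationParams()
    final_spacing = params.control_spacing_schedule_mm[-1]
    if fixed_liver.is_empty():
        raise ValueError("fixed liver mask is empty")
    fixed.require_same_grid(fixed_liver, "fixed volume and liver mask")

    if all(it <= 0 for it in params.demons_iterations):
        deformation = _zero_bspline(fixed, final_spacing)
    else:
        moving_res = resample_volume(ComposedTransform(init), moving, fixed)
        dilated = dilate_mask(fixed_liver, params.demons_mask_dilation_mm)
        clamped = np.where(dilated.data, moving_res.data, fixed.data).astype(np.float32)
        field = _multires_demons(
            fixed.to_sitk(dtype=np.float32),
            fixed.copy(data=clamped).to_sitk(dtype=np.float32),
            params,
        )
        deformation = _fit_bspline_to_field(field, fixed, final_spacing)
        if not np.all(np.isfinite(deformation.coefficients)):
            raise RegistrationError("non-rigid optimisation produced non-finite displacements")

    result = RegistrationResult(
        rigid=init,
        deformation=deformation,
        final_metric=np.nan,
        liver_overlap_dice=None,
        failed=False,
    )
    metric_mask = dilate_mask(fixed_liver, params.mask_dilation_mm)
    result.final_metric = similarity(
        fixed, resample_volume(result, moving, fixed), metric_mask, params.metric_bins
    )
    if moving_liver is not None:
        warped = transform_mask(result, moving_liver, fixed_liver)
        dice, failed = check_failure(warped, fixed_liver, params.failure_dice_threshold)
        result.liver_overlap_dice = dice
        result.failed = failed
    return result
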