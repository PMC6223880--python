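"""Synthetic abdominal CT phantom with paired diagnostic / intraprocedural
contrast-enhanced scans and known ground truth.

The generator emulates the structure of a clinical ablation-guidance cohort:
a diagnostic contrast-enhanced CT (CECT) of an abdomen containing a liver
with enhancing vessels, hypervascular (HCC-like) and hypovascular
(metastasis-like) tumours, plus an intraprocedural CECT of the same anatomy
acquired after patient rotation/translation and smooth non-rigid liver
deformation, each with independent acquisition noise. Tumour diameters
follow the clinical cohort statistics (mean 20.4 mm, sd 9.4 mm, range
6.1-60.0 mm) by default.

Anatomy is defined by analytic implicit surfaces in the diagnostic world
frame and sampled at arbitrary world points, so the intraprocedural volume
is rendered by pulling each of its voxel centres back through the ground
truth transform — the two volumes contain exactly the same anatomy, warped,
and every tumour centre is known exactly.

The ground-truth transform maps intraprocedural world points to diagnostic
world points (the resampling convention): a rigid patient motion composed
with a B-spline displacement that is windowed to vanish away from the liver,
keeping the spine rigid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .grid import Mask, Volume
from .transforms import BSplineDeformation, RigidTransform, random_bspline_field

__all__ = [
    "HU",
    "PhantomConfig",
    "PhantomCase",
    "ObserverErrorModel",
    "ObserverAnnotationSet",
    "LiverWindow",
    "TruthTransform",
    "TumourPlacementError",
    "generate_phantom",
    "simulate_observers",
]


class TumourPlacementError(RuntimeError):
    """Rejection sampling could not place a tumour inside the liver."""


#: Hounsfield values of the phantom tissue classes. CT does not prescribe
#: exact organ values; these are physiologically plausible and chosen so the
#: classes are separable: clips sit far above everything else, enhanced
#: parenchyma sits in a narrow band, vessels and hypervascular lesions are
#: hyper-attenuating relative to parenchyma, hypovascular lesions are darker.
HU = {
    "air": -1000.0,
    "fat": -50.0,
    "soft": 40.0,
    "spine": 700.0,
    "liver_cect": 110.0,
    "vessel": 160.0,
    "hyper_delta": 30.0,
    "hypo_delta": -35.0,
    "clip": 1000.0,
}


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_tumours: int = 3
    tumour_diameter_range_mm: tuple[float, float] = (6.1, 60.0)
    tumour_diameter_mean_mm: float = 20.4
    tumour_diameter_sd_mm: float = 9.4
    hyper_fraction: float = 35.0 / 56.0  # clinical mix: 35 HCC of 56 tumours
    rotation_deg: float = 0.0  # about the cranio-caudal (z) axis
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    deformation_amplitude_mm: float = 0.0
    deformation_grid_spacing_mm: float = 24.0
    noise_sd_hu: float = 10.0
    texture_amplitude_hu: float = 6.0  # smooth parenchymal texture (sd, HU)
    n_clips: int = 2
    clip_radius_mm: float = 3.0
    edge_mm: float = 2.0  # smooth partial-volume edge width
    seed: int = 0

    def __post_init__(self) -> None:
        shape = np.asarray(self.grid_shape, dtype=int)
        if shape.shape != (3,) or np.any(shape < 32):
            raise ValueError("grid_shape must have 3 axes with >= 32 voxels each")
        if np.any(np.asarray(self.spacing_mm, float) <= 0):
            raise ValueError("spacing_mm must be positive on every axis")
        lo, hi = self.tumour_diameter_range_mm
        if not (0 < lo < hi):
            raise ValueError("tumour_diameter_range_mm must be an increasing positive pair")
        if self.n_tumours < 0 or self.n_clips < 0:
            raise ValueError("counts must be non-negative")
        if self.deformation_amplitude_mm < 0 or self.noise_sd_hu < 0:
            raise ValueError("amplitudes must be non-negative")

    def to_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "spacing_mm": list(self.spacing_mm),
            "n_tumours": self.n_tumours,
            "tumour_diameter_range_mm": list(self.tumour_diameter_range_mm),
            "tumour_diameter_mean_mm": self.tumour_diameter_mean_mm,
            "tumour_diameter_sd_mm": self.tumour_diameter_sd_mm,
            "hyper_fraction": self.hyper_fraction,
            "rotation_deg": self.rotation_deg,
            "translation_mm": list(self.translation_mm),
            "deformation_amplitude_mm": self.deformation_amplitude_mm,
            "deformation_grid_spacing_mm": self.deformation_grid_spacing_mm,
            "noise_sd_hu": self.noise_sd_hu,
            "texture_amplitude_hu": self.texture_amplitude_hu,
            "n_clips": self.n_clips,
            "clip_radius_mm": self.clip_radius_mm,
            "edge_mm": self.edge_mm,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        for key in ("grid_shape", "spacing_mm", "tumour_diameter_range_mm", "translation_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# implicit-surface primitives (signed, ~mm scale, negative inside)
# ---------------------------------------------------------------------------


@dataclass
class _Ellipsoid:
    centre: np.ndarray
    semiaxes: np.ndarray

    def implicit(self, pts: np.ndarray) -> np.ndarray:
        rho = np.linalg.norm((pts - self.centre) / self.semiaxes, axis=-1)
        return (rho - 1.0) * float(np.min(self.semiaxes))


@dataclass
class _Sphere:
    centre: np.ndarray
    radius: float

    def implicit(self, pts: np.ndarray) -> np.ndarray:
        return np.linalg.norm(pts - self.centre, axis=-1) - self.radius


@dataclass
class _Capsule:
    a: np.ndarray
    b: np.ndarray
    radius: float

    def implicit(self, pts: np.ndarray) -> np.ndarray:
        ab = self.b - self.a
        t = np.clip(((pts - self.a) @ ab) / (ab @ ab), 0.0, 1.0)
        closest = self.a + t[..., None] * ab
        return np.linalg.norm(pts - closest, axis=-1) - self.radius


@dataclass
class LiverWindow:
    """Smooth weight that is 1 inside the liver and decays to 0 within
    ``falloff_mm`` of its surface, evaluated in diagnostic world space.
    Confines the ground-truth deformation so the spine stays rigid."""

    ellipsoids: list
    falloff_mm: float = 25.0

    def weights(self, pts_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_mm, dtype=float))
        f = np.min([e.implicit(pts) for e in self.ellipsoids], axis=0)
        u = np.clip(f, 0.0, self.falloff_mm) / self.falloff_mm
        return 0.5 * (1.0 + np.cos(np.pi * u))

    def to_dict(self) -> dict:
        return {
            "falloff_mm": self.falloff_mm,
            "ellipsoids": [
                {"centre": e.centre.tolist(), "semiaxes": e.semiaxes.tolist()}
                for e in self.ellipsoids
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LiverWindow":
        return cls(
            ellipsoids=[
                _Ellipsoid(np.array(e["centre"]), np.array(e["semiaxes"]))
                for e in d["ellipsoids"]
            ],
            falloff_mm=d["falloff_mm"],
        )


@dataclass
class TruthTransform:
    """Ground-truth intraprocedural→diagnostic map
    ``x -> R(x) + w(R(x)) * u(x)`` with rigid ``R``, B-spline displacement
    ``u`` on the intraprocedural domain and liver window ``w``."""

    rigid: RigidTransform
    deformation: BSplineDeformation | None = None
    window: LiverWindow | None = None

    def apply(self, pts_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_mm, dtype=float))
        y = self.rigid.apply(pts)
        if self.deformation is None:
            return y
        u = self.deformation.displacement_at(pts)
        w = self.window.weights(y)[:, None] if self.window is not None else 1.0
        return y + w * u

    def apply_dense(self, y_rigid: np.ndarray, u_dense: np.ndarray) -> np.ndarray:
        """Vectorised apply given precomputed rigid images and displacements."""
        if self.deformation is None:
            return y_rigid
        w = self.window.weights(y_rigid)[:, None] if self.window is not None else 1.0
        return y_rigid + w * u_dense

    def forward_point(self, p_diag_mm, tol: float = 1e-8, max_iter: int = 100) -> np.ndarray:
        """Invert the map for a single diagnostic-space point (fixed-point
        iteration; the windowed displacement is small and smooth)."""
        p = np.asarray(p_diag_mm, dtype=float).reshape(3)
        inv = self.rigid.inverse()
        x = inv.apply(p)[0]
        if self.deformation is None:
            return x
        for _ in range(max_iter):
            u = self.deformation.displacement_at(x[None])[0]
            w = self.window.weights(self.rigid.apply(x[None]))[0] if self.window else 1.0
            x_new = inv.apply(p - w * u)[0]
            if np.linalg.norm(x_new - x) < tol:
                return x_new
            x = x_new
        return x

    def is_identity(self) -> bool:
        rigid_id = np.allclose(self.rigid.matrix, np.eye(3)) and np.allclose(
            self.rigid.translation_mm, 0.0
        )
        return rigid_id and (
            self.deformation is None or self.deformation.max_coefficient_mm() == 0.0
        )

    def to_dict(self) -> dict:
        return {
            "rigid": self.rigid.to_dict(),
            "deformation": None if self.deformation is None else self.deformation.to_dict(),
            "window": None if self.window is None else self.window.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthTransform":
        return cls(
            rigid=RigidTransform.from_dict(d["rigid"]),
            deformation=None
            if d.get("deformation") is None
            else BSplineDeformation.from_dict(d["deformation"]),
            window=None if d.get("window") is None else LiverWindow.from_dict(d["window"]),
        )


# ---------------------------------------------------------------------------
# anatomy model
# ---------------------------------------------------------------------------


class _Anatomy:
    """Analytic abdomen: layered implicit primitives painted in order with a
    smooth (partial-volume-like) edge of width ``edge_mm``."""

    def __init__(self, config: PhantomConfig, rng: np.random.Generator):
        shape = np.asarray(config.grid_shape, dtype=float)
        spacing = np.asarray(config.spacing_mm, dtype=float)
        extent = (shape - 1) * spacing
        c = extent / 2.0  # volume centre in world mm (origin at 0)
        s = extent / 190.0  # layout scale relative to the reference field of view
        self.centre = c
        self.edge_mm = config.edge_mm

        self.body = _Ellipsoid(c, np.array([80, 62, 94]) * s)
        self.soft = _Ellipsoid(c, np.array([72, 54, 94]) * s)
        self.spine = _Capsule(
            c + np.array([0, 45 * s[1], -c[2]]),
            c + np.array([0, 45 * s[1], c[2]]),
            12.0 * min(s[0], s[1]),
        )
        self.liver_parts = [
            _Ellipsoid(c + np.array([-35, -20, 0]) * s, np.array([34, 28, 36]) * s),
            _Ellipsoid(c + np.array([-10, -27, -20]) * s, np.array([24, 20, 26]) * s),
            _Ellipsoid(c + np.array([-45, -5, -25]) * s, np.array([20, 18, 22]) * s),
        ]
        # portal-vein-like branches anchored to the liver ellipsoids
        l0, l1, l2 = (e.centre for e in self.liver_parts)
        self.vessels = [
            _Capsule(l0, l1, 4.0 * min(s)),
            _Capsule(l0, l2, 3.0 * min(s)),
            _Capsule(l0, l0 + np.array([-15, -12, 18]) * s, 3.0 * min(s)),
        ]
        self.tumours: list[_Sphere] = []
        self.tumour_types: list[str] = []
        self.clips: list[_Sphere] = []

        # smooth low-frequency soft-tissue texture: sum of random plane waves,
        # zero mean, sd = texture_amplitude_hu. Tied to the anatomy frame, so
        # it warps with the patient and carries orientation information the
        # way real parenchymal texture does.
        n_waves = 10
        wavelength = rng.uniform(25.0, 60.0, size=n_waves)
        direction = rng.normal(size=(n_waves, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        self.texture_k = 2 * np.pi * direction / wavelength[:, None]
        self.texture_phase = rng.uniform(0, 2 * np.pi, size=n_waves)
        self.texture_amp = config.texture_amplitude_hu

    def texture(self, pts: np.ndarray) -> np.ndarray:
        if self.texture_amp == 0:
            return np.zeros(len(pts))
        waves = np.cos(pts @ self.texture_k.T + self.texture_phase)
        return self.texture_amp * np.sqrt(2.0 / waves.shape[1]) * waves.sum(axis=1)

    def liver_implicit(self, pts: np.ndarray) -> np.ndarray:
        return np.min([e.implicit(pts) for e in self.liver_parts], axis=0)

    def place_tumours_and_clips(self, config: PhantomConfig, rng: np.random.Generator) -> None:
        lo, hi = config.tumour_diameter_range_mm
        n_hyper = int(round(config.n_tumours * config.hyper_fraction))
        for i in range(config.n_tumours):
            sphere = self._place_sphere(
                rng,
                radius_sampler=lambda: self._sample_diameter(rng, lo, hi, config) / 2.0,
                margin_mm=2.0,
                avoid=self.tumours,
                what=f"tumour {i}",
            )
            self.tumours.append(sphere)
            self.tumour_types.append("hyper" if i < n_hyper else "hypo")
        for i in range(config.n_clips):
            clip = self._place_sphere(
                rng,
                radius_sampler=lambda: config.clip_radius_mm,
                margin_mm=1.0,
                avoid=self.tumours + self.clips,
                what=f"clip {i}",
            )
            self.clips.append(clip)

    @staticmethod
    def _sample_diameter(rng, lo, hi, config) -> float:
        for _ in range(1000):
            d = rng.normal(config.tumour_diameter_mean_mm, config.tumour_diameter_sd_mm)
            if lo <= d <= hi:
                return d
        return float(np.clip(config.tumour_diameter_mean_mm, lo, hi))

    def _place_sphere(self, rng, radius_sampler, margin_mm, avoid, what) -> _Sphere:
        bbox_lo = np.min([e.centre - e.semiaxes for e in self.liver_parts], axis=0)
        bbox_hi = np.max([e.centre + e.semiaxes for e in self.liver_parts], axis=0)
        for _ in range(1000):
            r = radius_sampler()
            centre = rng.uniform(bbox_lo, bbox_hi)
            if self.liver_implicit(centre[None])[0] > -(r + margin_mm):
                continue
            if any(
                np.linalg.norm(centre - other.centre) < r + other.radius + 2.0
                for other in avoid
            ):
                continue
            return _Sphere(centre, r)
        raise TumourPlacementError(
            f"could not place {what} inside the liver after 1000 attempts "
            "(liver too small for the requested diameters)"
        )

    def hu_at(self, pts: np.ndarray, enhanced: bool = True) -> np.ndarray:
        """Hounsfield value at world points; ``enhanced=False`` renders the
        de-enhanced reference anatomy (flat liver, clips kept)."""
        pts = np.atleast_2d(pts)
        val = np.full(len(pts), HU["air"])

        def paint(f, v):
            alpha = np.clip(0.5 - f / self.edge_mm, 0.0, 1.0)
            return alpha * v + (1.0 - alpha) * val

        val = paint(self.body.implicit(pts), HU["fat"])
        val = paint(self.soft.implicit(pts), HU["soft"])
        val = paint(self.spine.implicit(pts), HU["spine"])
        val = paint(self.liver_implicit(pts), HU["liver_cect"])
        if enhanced:
            for v in self.vessels:
                val = paint(v.implicit(pts), HU["vessel"])
            for t, kind in zip(self.tumours, self.tumour_types):
                delta = HU["hyper_delta"] if kind == "hyper" else HU["hypo_delta"]
                val = paint(t.implicit(pts), HU["liver_cect"] + delta)
        soft_alpha = np.clip(0.5 - self.soft.implicit(pts) / self.edge_mm, 0.0, 1.0)
        val = val + soft_alpha * self.texture(pts)
        for clip in self.clips:
            val = paint(clip.implicit(pts), HU["clip"])
        return val


# ---------------------------------------------------------------------------
# phantom case
# ---------------------------------------------------------------------------


@dataclass
class PhantomCase:
    config: PhantomConfig
    diagnostic_cect: Volume
    intraproc_cect: Volume
    intraproc_vuct_reference: Volume
    liver_mask_diag: Mask
    liver_mask_intra: Mask
    tumour_masks_diag: list
    tumour_masks_intra: list
    clip_mask_intra: Mask
    tumour_types: list
    true_transform: TruthTransform
    true_centres_intra_mm: np.ndarray
    ap_axis_diag_mm: np.ndarray  # (2, 3): spinous process -> sternum
    ap_axis_intra_mm: np.ndarray


def _mask_centroid_mm(mask: Mask) -> np.ndarray:
    idx = np.argwhere(mask.data)
    if len(idx) == 0:
        raise ValueError("empty mask has no centroid")
    return mask.voxel_to_world(idx).mean(axis=0)


def generate_phantom(config: PhantomConfig) -> PhantomCase:
    """Generate a paired diagnostic/intraprocedural phantom case.

    Deterministic for a fixed config (one seed stream per component, derived
    from ``config.seed``). Raises :class:`TumourPlacementError` when the
    liver cannot host the requested tumours.
    """
    ss = np.random.SeedSequence(config.seed)
    s_geom, s_field, s_noise_d, s_noise_i = ss.spawn(4)
    rng_geom = np.random.default_rng(s_geom)

    template = Volume(
        data=np.zeros(config.grid_shape, dtype=np.float32),
        spacing=config.spacing_mm,
        origin=(0.0, 0.0, 0.0),
    )
    anatomy = _Anatomy(config, rng_geom)
    anatomy.place_tumours_and_clips(config, rng_geom)

    centre = anatomy.centre
    rigid = RigidTransform.z_rotation(
        config.rotation_deg, centre_mm=centre, translation_mm=config.translation_mm
    )
    deformation = None
    window = None
    if config.deformation_amplitude_mm > 0:
        deformation = random_bspline_field(
            grid_spacing_mm=config.deformation_grid_spacing_mm,
            amplitude_mm=config.deformation_amplitude_mm,
            domain=template,
            seed=int(s_field.generate_state(1)[0] % (2**31)),
        )
        scale = float(np.min((np.asarray(config.grid_shape) - 1) * config.spacing_mm) / 190.0)
        window = LiverWindow(ellipsoids=anatomy.liver_parts, falloff_mm=25.0 * min(scale, 1.0))
    truth = TruthTransform(rigid=rigid, deformation=deformation, window=window)

    grid_pts = template.grid_world_coords().reshape(-1, 3)
    shape = tuple(config.grid_shape)

    # diagnostic volume: anatomy at rest
    rng_d = np.random.default_rng(s_noise_d)
    diag_data = anatomy.hu_at(grid_pts, enhanced=True).reshape(shape)
    if config.noise_sd_hu > 0:
        diag_data = diag_data + rng_d.normal(0.0, config.noise_sd_hu, size=shape)
    diag = template.copy(data=diag_data.astype(np.float32))

    # intraprocedural volume: anatomy pulled back through the ground truth
    if deformation is not None:
        u_dense = _dense_displacement(deformation, template)
        pulled = truth.apply_dense(rigid.apply(grid_pts), u_dense)
    else:
        pulled = rigid.apply(grid_pts)
    rng_i = np.random.default_rng(s_noise_i)
    noise_i = (
        rng_i.normal(0.0, config.noise_sd_hu, size=shape) if config.noise_sd_hu > 0 else 0.0
    )
    intra = template.copy(
        data=(anatomy.hu_at(pulled, enhanced=True).reshape(shape) + noise_i).astype(np.float32)
    )
    # reference de-enhanced anatomy shares the intraprocedural noise so the
    # two differ only inside contrast-revealed structures
    vuct_ref = template.copy(
        data=(anatomy.hu_at(pulled, enhanced=False).reshape(shape) + noise_i).astype(np.float32)
    )

    def as_mask(values_neg_inside: np.ndarray) -> Mask:
        return Mask(
            data=(values_neg_inside <= 0.0).reshape(shape),
            spacing=template.spacing,
            origin=template.origin,
            direction=template.direction,
        )

    liver_diag = as_mask(anatomy.liver_implicit(grid_pts))
    liver_intra = as_mask(anatomy.liver_implicit(pulled))
    tumours_diag = [as_mask(t.implicit(grid_pts)) for t in anatomy.tumours]
    tumours_intra = [as_mask(t.implicit(pulled)) for t in anatomy.tumours]
    if anatomy.clips:
        clip_intra = as_mask(np.min([cl.implicit(pulled) for cl in anatomy.clips], axis=0))
    else:
        clip_intra = as_mask(np.full(len(grid_pts), 1.0))

    true_centres = np.array([_mask_centroid_mm(m) for m in tumours_intra])

    # anteroposterior axis landmarks (spinous process -> sternum), for the
    # axis-based initialisation of extremely rotated cases
    s = ((np.asarray(config.grid_shape) - 1) * np.asarray(config.spacing_mm)) / 190.0
    ap_diag = np.array(
        [centre + np.array([0, 58 * s[1], 0]), centre + np.array([0, -50 * s[1], 0])]
    )
    ap_intra = np.array([truth.forward_point(p) for p in ap_diag])

    case = PhantomCase(
        config=config,
        diagnostic_cect=diag,
        intraproc_cect=intra,
        intraproc_vuct_reference=vuct_ref,
        liver_mask_diag=liver_diag,
        liver_mask_intra=liver_intra,
        tumour_masks_diag=tumours_diag,
        tumour_masks_intra=tumours_intra,
        clip_mask_intra=clip_intra,
        tumour_types=list(anatomy.tumour_types),
        true_transform=truth,
        true_centres_intra_mm=true_centres,
        ap_axis_diag_mm=ap_diag,
        ap_axis_intra_mm=ap_intra,
    )
    _validate_case(case)
    return case


def _dense_displacement(deformation: BSplineDeformation, template: Volume) -> np.ndarray:
    """B-spline displacement at every voxel centre, via SimpleITK (fast);
    agrees with ``BSplineDeformation.displacement_at`` by construction."""
    filt = sitk.TransformToDisplacementFieldFilter()
    filt.SetReferenceImage(template.to_sitk(dtype=np.float32))
    filt.SetOutputPixelType(sitk.sitkVectorFloat64)
    field = sitk.GetArrayFromImage(filt.Execute(deformation.to_sitk()))
    # array comes back (z, y, x, 3)
    return np.transpose(field, (2, 1, 0, 3)).reshape(-1, 3)


def _validate_case(case: PhantomCase) -> None:
    """Construction invariants, asserted on every generated case."""
    for i, (td, ti) in enumerate(zip(case.tumour_masks_diag, case.tumour_masks_intra)):
        if td.is_empty() or ti.is_empty():
            raise AssertionError(f"tumour {i} rasterised to an empty mask")
        if not np.all(case.liver_mask_diag.data[td.data]):
            raise AssertionError(f"diagnostic tumour {i} escapes the liver mask")
        if not np.all(case.liver_mask_intra.data[ti.data]):
            raise AssertionError(f"intraprocedural tumour {i} escapes the liver mask")
    if not case.clip_mask_intra.is_empty():
        clip_vals = case.intraproc_cect.data[case.clip_mask_intra.data]
        if clip_vals.min() < 500.0 + 1:  # separable from everything below clip threshold
            raise AssertionError("clip voxels are not separable from soft tissue")
    liver_vals = case.intraproc_cect.data[case.liver_mask_intra.data]
    band = (HU["liver_cect"] + HU["hypo_delta"] - 5 * case.config.noise_sd_hu - case.config.edge_mm * 50,
            HU["clip"] + 5 * case.config.noise_sd_hu)
    if liver_vals.min() < band[0] - 200 or liver_vals.max() > band[1]:
        raise AssertionError("liver intensities outside the expected band")


# ---------------------------------------------------------------------------
# observer simulation (mental registration)
# ---------------------------------------------------------------------------


@dataclass
class ObserverErrorModel:
    """Per-observer annotation error: fixed bias plus zero-mean Gaussian
    noise per axis (mm). ``in_plane`` snaps the cranio-caudal coordinate to
    the nearest slice centre, mimicking annotation on axial slices."""

    bias_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sd_mm: tuple[float, float, float] = (12.0, 12.0, 12.0)
    in_plane: bool = False

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sd_mm, float) < 0):
            raise ValueError("sd_mm must be non-negative")


@dataclass
class ObserverAnnotationSet:
    annotations_mm: np.ndarray  # (n_observers, n_tumours, 3)
    error_model: ObserverErrorModel

    @property
    def n_observers(self) -> int:
        return self.annotations_mm.shape[0]

    @property
    def n_tumours(self) -> int:
        return self.annotations_mm.shape[1]


def simulate_observers(
    true_centres_mm: np.ndarray,
    error_model: ObserverErrorModel,
    n_observers: int = 4,
    seed: int = 0,
    volume: Volume | None = None,
) -> ObserverAnnotationSet:
    """Simulate mental-registration annotations of the tumour centres.

    Each observer annotates every tumour once: true centre + bias + noise.
    With ``error_model.in_plane`` and a reference volume, the z coordinate is
    snapped to the nearest slice centre (in-plane annotation only).
    """
    if n_observers < 1:
        raise ValueError("n_observers must be >= 1")
    centres = np.atleast_2d(np.asarray(true_centres_mm, dtype=float))
    rng = np.random.default_rng(seed)
    bias = np.asarray(error_model.bias_mm, dtype=float)
    sd = np.asarray(error_model.sd_mm, dtype=float)
    ann = centres[None] + bias + rng.normal(0.0, 1.0, size=(n_observers,) + centres.shape) * sd
    if error_model.in_plane:
        if volume is None:
            raise ValueError("in_plane snapping needs a reference volume")
        k = np.round(volume.world_to_voxel(ann.reshape(-1, 3))[:, 2])
        k = np.clip(k, 0, volume.shape[2] - 1)
        idx = volume.world_to_voxel(ann.reshape(-1, 3))
        idx[:, 2] = k
        ann = volume.voxel_to_world(idx).reshape(ann.shape)
    if volume is not None:
        lo = volume.voxel_to_world([0, 0, 0])[0] - volume.spacing / 2
        hi = volume.voxel_to_world(np.asarray(volume.shape) - 1)[0] + volume.spacing / 2
        ann = np.clip(ann, np.minimum(lo, hi), np.maximum(lo, hi))
    return ObserverAnnotationSet(annotations_mm=ann, error_model=error_model)
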