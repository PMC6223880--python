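"""File formats: NIfTI volumes, JSON truth/annotations/transforms, YAML
configuration, CSV tables.

World coordinates are millimetres in the LPS convention throughout (the
native convention of ITK; NIfTI's RAS affine is converted on read/write by
SimpleITK). Geometry round-trips to 1e-6.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import yaml

from .grid import GeometryError, Mask, Volume
from .phantom import PhantomCase, PhantomConfig, TruthTransform

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "read_annotations",
    "write_annotations",
    "read_truth",
    "write_truth",
    "write_case",
    "read_config",
    "write_config",
]

ANNOTATION_SCHEMA = "liverloc-annotations-1"
TRUTH_SCHEMA = "liverloc-truth-1"


def read_volume(path: str | Path) -> Volume:
    return Volume.from_sitk(sitk.ReadImage(str(path), sitk.sitkFloat32))


def write_volume(volume: Volume, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(volume.to_sitk(dtype=np.float32), str(path))


def read_mask(path: str | Path, parent: Volume | None = None) -> Mask:
    img = sitk.ReadImage(str(path), sitk.sitkUInt8)
    vol = Volume.from_sitk(img)
    mask = Mask(data=vol.data > 0, spacing=vol.spacing, origin=vol.origin, direction=vol.direction)
    if parent is not None and not mask.same_grid(parent):
        raise GeometryError(f"mask {path} is not on the same grid as its parent volume")
    return mask


def write_mask(mask: Mask, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(mask.to_sitk(), str(path))


# -- annotations -------------------------------------------------------------


def write_annotations(points_mm: dict, method: str, path: str | Path) -> None:
    """Write per-tumour annotated centres: {tumour_id: (x, y, z) world mm}."""
    payload = {
        "schema": ANNOTATION_SCHEMA,
        "method": method,
        "coordinate_convention": "LPS mm",
        "points": {str(k): [float(x) for x in v] for k, v in points_mm.items()},
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotations(path: str | Path, truth_ids: list | None = None) -> tuple[str, dict]:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != ANNOTATION_SCHEMA:
        raise ValueError(f"{path}: unknown annotation schema {payload.get('schema')!r}")
    points = {str(k): np.asarray(v, dtype=float) for k, v in payload["points"].items()}
    if truth_ids is not None:
        unknown = sorted(set(points) - set(map(str, truth_ids)))
        if unknown:
            raise ValueError(f"{path}: annotations for tumour ids absent from truth: {unknown}")
    return payload.get("method", "unknown"), points


# -- ground truth -------------------------------------------------------------


def write_truth(case: PhantomCase, path: str | Path) -> None:
    payload = {
        "schema": TRUTH_SCHEMA,
        "coordinate_convention": "LPS mm",
        "transform_direction": "intraprocedural -> diagnostic (resampling convention)",
        "true_transform": case.true_transform.to_dict(),
        "true_centres_intra_mm": case.true_centres_intra_mm.tolist(),
        "tumour_ids": [f"t{i}" for i in range(len(case.true_centres_intra_mm))],
        "tumour_types": list(case.tumour_types),
        "ap_axis_diag_mm": case.ap_axis_diag_mm.tolist(),
        "ap_axis_intra_mm": case.ap_axis_intra_mm.tolist(),
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != TRUTH_SCHEMA:
        raise ValueError(f"{path}: unknown truth schema {payload.get('schema')!r}")
    payload["true_transform"] = TruthTransform.from_dict(payload["true_transform"])
    payload["true_centres_intra_mm"] = np.asarray(payload["true_centres_intra_mm"], dtype=float)
    return payload


# -- case directories ----------------------------------------------------------


def write_case(case: PhantomCase, out_dir: str | Path) -> Path:
    """Write a phantom case directory: volumes and masks as NIfTI,
    ``truth.json`` and ``config.yaml``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(case.diagnostic_cect, out / "diag_cect.nii.gz")
    write_volume(case.intraproc_cect, out / "intra_cect.nii.gz")
    write_volume(case.intraproc_vuct_reference, out / "intra_vuct_reference.nii.gz")
    write_mask(case.liver_mask_diag, out / "liver_diag.nii.gz")
    write_mask(case.liver_mask_intra, out / "liver_intra.nii.gz")
    for i, (md, mi) in enumerate(zip(case.tumour_masks_diag, case.tumour_masks_intra)):
        write_mask(md, out / f"tumour_t{i}_diag.nii.gz")
        write_mask(mi, out / f"tumour_t{i}_intra.nii.gz")
    write_mask(case.clip_mask_intra, out / "clips_intra.nii.gz")
    write_truth(case, out / "truth.json")
    write_config(case.config, out / "config.yaml")
    return out


# -- config -------------------------------------------------------------------


def write_config(config: PhantomConfig, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def read_config(path: str | Path) -> PhantomConfig:
    return PhantomConfig.from_dict(yaml.safe_load(Path(path).read_text()))
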