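"""Virtual contrast de-enhancement of the liver.

A contrast-enhanced CT (CECT) reveals hypervascular tumours and vessels as
hyper-attenuating structures and hypovascular metastases as darker regions
inside the enhanced liver parenchyma. This module builds a *virtually
unenhanced CT* (VUCT): hyper-attenuating liver voxels (found by an adaptive
intensity threshold) and explicitly segmented hypo-attenuating regions are
replaced with values representative of normal parenchyma, so the tumour
becomes inconspicuous. Very high intensity voxels — surgical clips and
calcifications — are preserved, as is everything outside the liver.

Parenchyma statistics are estimated robustly (median / MAD) from liver
voxels inside a plausibility band, so vessels and lesions do not bias the
estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import Mask, Volume

__all__ = ["DeenhanceParams", "ParenchymaEstimationError", "estimate_parenchyma_stats", "deenhance"]

_MAD_TO_SD = 1.4826  # normal-consistency factor for the median absolute deviation


class ParenchymaEstimationError(RuntimeError):
    """Too few in-band liver voxels to estimate parenchyma statistics."""


@dataclass
class DeenhanceParams:
    """Replacement thresholds and texture parameters.

    ``hyper_threshold_hu`` may be left ``None``: it is then set adaptively to
    ``mean + hyper_nsigma * sd`` of the estimated parenchyma. Clips and
    calcifications above ``clip_threshold_hu`` are never replaced.
    """

    hyper_threshold_hu: float | None = None
    hyper_nsigma: float = 1.5
    clip_threshold_hu: float = 500.0
    parenchyma_band_hu: tuple[float, float] = (0.0, 300.0)
    fill_noise: bool = True
    smoothing_sigma_mm: float = 2.0
    min_band_voxels: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.parenchyma_band_hu
        if not lo < hi:
            raise ValueError("parenchyma_band_hu must be an increasing pair")
        if self.hyper_threshold_hu is not None and self.hyper_threshold_hu >= self.clip_threshold_hu:
            raise ValueError("clip_threshold_hu must exceed hyper_threshold_hu")


def estimate_parenchyma_stats(
    cect: Volume, liver_mask: Mask, params: DeenhanceParams | None = None
) -> tuple[float, float]:
    """Robust (median, MAD-based sd) of liver voxels inside the parenchyma band."""
    params = params or DeenhanceParams()
    if liver_mask.is_empty():
        raise ValueError("liver mask is empty")
    cect.require_same_grid(liver_mask, "CECT and liver mask")
    vals = cect.data[liver_mask.data]
    lo, hi = params.parenchyma_band_hu
    vals = vals[(vals >= lo) & (vals <= hi)]
    if vals.size < params.min_band_voxels:
        raise ParenchymaEstimationError(
            f"only {vals.size} liver voxels inside band {params.parenchyma_band_hu} "
            f"(need >= {params.min_band_voxels}); pass explicit statistics instead"
        )
    mean = float(np.median(vals))
    sd = float(_MAD_TO_SD * np.median(np.abs(vals - mean)))
    return mean, sd


def deenhance(
    cect: Volume,
    liver_mask: Mask,
    hypo_masks: list | None = None,
    params: DeenhanceParams | None = None,
    exclude_mask: Mask | None = None,
    parenchyma_stats: tuple[float, float] | None = None,
) -> Volume:
    """Create a virtually unenhanced CT from a contrast-enhanced CT.

    Replaced: liver voxels in ``(hyper_threshold, clip_threshold)`` and all
    voxels of ``hypo_masks`` (clipped to the liver). Preserved exactly:
    everything outside the liver, voxels at/above ``clip_threshold_hu``, and
    an optional exclusion mask (e.g. hilar vessel silhouettes). Replacement
    values are parenchyma-statistics draws (truncated so no replaced voxel
    re-exceeds the hyper threshold), feathered outward into the surrounding
    parenchyma over ``smoothing_sigma_mm`` to avoid step artefacts.
    Deterministic for a fixed seed.
    """
    params = params or DeenhanceParams()
    hypo_masks = hypo_masks or []
    if liver_mask.is_empty():
        raise ValueError("liver mask is empty")
    cect.require_same_grid(liver_mask, "CECT and liver mask")
    for m in hypo_masks:
        cect.require_same_grid(m, "CECT and hypo mask")

    if parenchyma_stats is None:
        mean, sd = estimate_parenchyma_stats(cect, liver_mask, params)
    else:
        mean, sd = parenchyma_stats
    hyper_thr = (
        params.hyper_threshold_hu
        if params.hyper_threshold_hu is not None
        else mean + params.hyper_nsigma * sd
    )
    if hyper_thr >= params.clip_threshold_hu:
        raise ValueError("adaptive hyper threshold reached the clip threshold")

    liver = liver_mask.data
    preserved = (cect.data >= params.clip_threshold_hu)
    if exclude_mask is not None:
        cect.require_same_grid(exclude_mask, "CECT and exclusion mask")
        preserved |= exclude_mask.data

    region = liver & (cect.data > hyper_thr) & ~preserved
    for m in hypo_masks:
        outside = m.data & ~liver
        if outside.any():
            warnings.warn(
                f"hypo mask extends {int(outside.sum())} voxels outside the liver; clipping",
                stacklevel=2,
            )
        region |= m.data & liver & ~preserved

    if not region.any():
        return cect.copy()

    if params.fill_noise and sd > 0:
        rng = np.random.default_rng(params.seed)
        draw = rng.normal(mean, sd, size=cect.shape)
        span = params.hyper_nsigma * sd
        fill = np.clip(draw, mean - span, mean + span)
    else:
        fill = np.full(cect.shape, mean)

    # feather outward only: alpha is 1 on the whole replacement region and
    # decays into the neighbouring parenchyma, never below 1 inside, so the
    # replaced structures are fully suppressed
    if params.smoothing_sigma_mm > 0:
        sigma_vox = params.smoothing_sigma_mm / cect.spacing
        alpha = gaussian_filter(region.astype(float), sigma=sigma_vox)
        alpha = np.maximum(alpha, region.astype(float))
    else:
        alpha = region.astype(float)
    alpha[~liver] = 0.0
    alpha[preserved] = 0.0

    out = cect.data.astype(np.float64) * (1.0 - alpha) + fill * alpha
    return cect.copy(data=out.astype(cect.data.dtype))
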