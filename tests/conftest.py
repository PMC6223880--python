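"""Shared fixtures: small, fast phantom configurations for unit tests and
session-cached generated cases (generation is deterministic, so caching is
purely a speed matter)."""

from __future__ import annotations

import numpy as np
import pytest

from liverloc import DeenhanceParams, PhantomConfig, deenhance, generate_phantom
from liverloc.grid import Mask, Volume


SMALL = dict(
    grid_shape=(48, 48, 48),
    spacing_mm=(2.0, 2.0, 2.0),
    n_tumours=2,
    tumour_diameter_range_mm=(6.1, 14.0),
    tumour_diameter_mean_mm=10.0,
    tumour_diameter_sd_mm=3.0,
    n_clips=1,
)


def small_config(**overrides) -> PhantomConfig:
    return PhantomConfig(**{**SMALL, **overrides})


@pytest.fixture(scope="session")
def identity_case():
    """No motion, no deformation, no noise: the two volumes coincide."""
    return generate_phantom(small_config(noise_sd_hu=0.0, seed=11))


@pytest.fixture(scope="session")
def moved_case():
    """Rigid motion + deformation + noise on the small grid."""
    return generate_phantom(
        small_config(
            rotation_deg=9.0,
            translation_mm=(6.0, -4.0, 3.0),
            deformation_amplitude_mm=6.0,
            seed=12,
        )
    )


@pytest.fixture(scope="session")
def full_case():
    """Default-sized (96^3, 2 mm) case with the study's motion conditions."""
    return generate_phantom(
        PhantomConfig(
            rotation_deg=10.0,
            translation_mm=(8.0, -5.0, 4.0),
            deformation_amplitude_mm=10.0,
            seed=21,
        )
    )


@pytest.fixture(scope="session")
def full_case_vuct(full_case):
    hypo = [
        m
        for m, k in zip(full_case.tumour_masks_intra, full_case.tumour_types)
        if k == "hypo"
    ]
    return deenhance(
        full_case.intraproc_cect,
        full_case.liver_mask_intra,
        hypo,
        DeenhanceParams(seed=21),
    )


def make_volume(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), direction=None):
    return Volume(data=np.asarray(data), spacing=spacing, origin=origin, direction=direction)


def make_mask(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), direction=None):
    return Mask(data=np.asarray(data), spacing=spacing, origin=origin, direction=direction)
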