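"""Shared fixtures: synthetic volumes and (expensive) full pipeline runs.

Everything is generated programmatically; heavyweight phantoms and
pipeline executions are session-scoped so the whole suite pays for them
once.
"""

from __future__ import annotations

import numpy as np
import pytest

from bonemicrokit import phantoms, pipeline, skeleton
from bonemicrokit.volume import DensityVolume, Units

TIBIAL_LENGTH_MM = 100.0


def make_rod_volume(diameter_vox: float = 5.0, length: int = 31, width: int = 9,
                    offset: float = 0.0, spacing: float = 0.15) -> DensityVolume:
    """Straight rod along z with circular cross-section, bone on marrow."""
    zz, yy, xx = np.mgrid[0:length, 0:width, 0:width].astype(float)
    c = width // 2 + offset
    vals = np.where((yy - c) ** 2 + (xx - c) ** 2 <= (diameter_vox / 2) ** 2, 800.0, 100.0)
    return DensityVolume(vals, (spacing,) * 3, units=Units.MG_CC)


def make_slab_volume(thickness_vox: int = 5, lateral: int = 21, spacing: float = 0.15,
                     pad: int = 10) -> DensityVolume:
    """Single slab normal to z, bone on marrow."""
    nz = thickness_vox + 2 * pad
    vals = np.full((nz, lateral, lateral), 100.0)
    vals[pad : pad + thickness_vox] = 800.0
    return DensityVolume(vals, (spacing,) * 3, units=Units.MG_CC)


@pytest.fixture(scope="session")
def rod_skeleton():
    vol = make_rod_volume()
    m = skeleton.bone_membership(vol)
    return m, skeleton.fuzzy_skeletonize(m)


@pytest.fixture(scope="session")
def plate_skeleton():
    vol = make_slab_volume()
    m = skeleton.bone_membership(vol)
    return m, skeleton.fuzzy_skeletonize(m)


@pytest.fixture(scope="session")
def tibia_untilted():
    """Default tibia phantom with cortical pores, plus its ground truth."""
    vol, gt = phantoms.make_tibia_phantom(tilt_deg=0.0, wall_porosity=0.15, seed=0)
    return vol, gt


@pytest.fixture(scope="session")
def tibia_run_pair(tibia_untilted):
    """Full pipeline on matched untilted and 10°-tilted tibia phantoms."""
    cfg = pipeline.PipelineConfig(tibial_length_mm=TIBIAL_LENGTH_MM)
    vol0, gt0 = tibia_untilted
    out0 = pipeline.run_pipeline(vol0, cfg)
    vol1, gt1 = phantoms.make_tibia_phantom(tilt_deg=10.0, wall_porosity=0.15, seed=0)
    out1 = pipeline.run_pipeline(vol1, cfg)
    return {"untilted": (out0, gt0), "tilted": (out1, gt1)}
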