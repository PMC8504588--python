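"""Shared fixtures: one default adult phantom pipeline (session-scoped,
since plan assembly is the expensive step) plus small analytic phantoms."""

from __future__ import annotations

import numpy as np
import pytest

import tbiplan as tp
from tbiplan.planning import build_whole_body_plan
from tbiplan.volumes import Grid, ImageVolume

RX_GY = 13.2
FRACTIONS = 8


@pytest.fixture(scope="session")
def adult_case():
    """Default 180 cm adult phantom, segmented and planned at 5 mm."""
    spec = tp.PhantomSpec.default_adult(180.0, seed=1, voxel_spacing=(5, 5, 5))
    volume, structures = tp.generate_phantom(spec)
    params = tp.SegmentationParams()
    ptv = tp.build_ptv(structures, params)
    subtargets = tp.divide_ptv(ptv, structures.grid, structures.landmarks, params)
    plan = build_whole_body_plan(
        volume, structures, subtargets, ptv, rx_gy=RX_GY, fractions=FRACTIONS
    )
    return {
        "spec": spec,
        "volume": volume,
        "structures": structures,
        "params": params,
        "ptv": ptv,
        "subtargets": subtargets,
        "plan": plan,
    }


@pytest.fixture(scope="session")
def water_slab():
    """Homogeneous water block: 30 x 20 x 60 cm on a 5 mm grid."""
    g = Grid.covering((-150, -100, -300), (150, 100, 300), (5.0, 5.0, 5.0))
    return ImageVolume(g, np.zeros(g.shape, dtype=np.float32))


@pytest.fixture(scope="session")
def water_cylinder():
    """Water cylinder (r = 10 cm) along z, mimicking adducted legs."""
    g = Grid.covering((-150, -150, -400), (150, 150, 400), (5.0, 5.0, 5.0))
    hu = np.full(g.shape, -1000.0, dtype=np.float32)
    X = g.axis_coords(0)[:, None, None]
    Y = g.axis_coords(1)[None, :, None]
    inside = np.broadcast_to((X**2 + Y**2) <= 100.0**2, g.shape)
    hu[inside] = 0.0
    return ImageVolume(g, hu)
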