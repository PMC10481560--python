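"""Shared fixtures: tiny grids for unit tests and one session-scoped
full-pipeline run reused by all end-to-end checks."""

from __future__ import annotations

import numpy as np
import pytest

from rectarc import (
    AutoPlanConfig,
    GridGeometry,
    PhantomSpec,
    ROIMask,
    VoxelGrid,
    default_goals,
    generate_phantom,
    run_autoplan,
)


def small_geometry(n=16, spacing=2.0):
    return GridGeometry.centered((n, n, n), (spacing, spacing, spacing))


@pytest.fixture
def geom16():
    return small_geometry(16, 2.0)


@pytest.fixture
def water_cylinder():
    """Uniform water cylinder (density 1) on a 40³ grid, 2 mm voxels."""
    geom = GridGeometry.centered((40, 40, 40), (2.0, 2.0, 2.0))
    xs = geom.axis_coords(0)[:, None, None]
    ys = geom.axis_coords(1)[None, :, None]
    zs = geom.axis_coords(2)[None, None, :]
    body = (xs**2 + ys**2) <= 35.0**2
    body = np.broadcast_to(body, geom.shape) & (np.abs(zs) <= 36.0)
    density = VoxelGrid(geom, body.astype(np.float32))
    external = ROIMask("External", geom, body)
    return density, external


@pytest.fixture(scope="session")
def phantom_default():
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def autoplan_result():
    """The full automated plan on the packaged phantom (seed 42, defaults).

    Session-scoped: the complete two-plan workflow runs once and every
    end-to-end assertion reads from it.
    """
    density, structs = generate_phantom(PhantomSpec())
    return run_autoplan(density, structs, default_goals(), AutoPlanConfig())
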