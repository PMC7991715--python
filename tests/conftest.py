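"""Shared fixtures: fixture machines, synthetic phantoms, contour stacks.

Session scope keeps the expensive artefacts (CT rasterization, contouring,
lofting, collision sweeps) computed once per run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

import rtclear as rc

warnings.filterwarnings("ignore", category=FutureWarning)

_hyp_settings.register_profile("repro", derandomize=True, deadline=None)
_hyp_settings.load_profile("repro")


@pytest.fixture(scope="session")
def machine_a():
    return rc.fixture_machine("machine_a")


@pytest.fixture(scope="session")
def machine_b():
    return rc.fixture_machine("machine_b")


@pytest.fixture(scope="session")
def phantom_params():
    return rc.PhantomParams(noise_seed=1)


@pytest.fixture(scope="session")
def phantom_vol(phantom_params):
    return rc.make_phantom_ct(phantom_params)


@pytest.fixture(scope="session")
def phantom_stack(phantom_vol):
    return rc.contour_pipeline(phantom_vol)


@pytest.fixture(scope="session")
def shell_stack():
    """Phantom wrapped in the low-density immobilization shell."""
    vol = rc.make_phantom_ct(rc.PhantomParams(bag_thickness_mm=12.0, noise_seed=1))
    return rc.contour_pipeline(vol, window_hu=(-800, 300), threshold_hu=-700)


@pytest.fixture(scope="session")
def body_mesh(phantom_stack):
    return rc.loft_collider(phantom_stack, "body", n_points=128)


@pytest.fixture(scope="session")
def placed_patient(phantom_stack, body_mesh):
    return rc.place_patient(
        body_mesh, phantom_stack.isocenter_mm, phantom_stack.plate_height_mm
    )


@pytest.fixture(scope="session")
def checker_a(machine_a):
    """Machine-only collision checker at production tessellation."""
    return rc.CollisionChecker(machine_a)


def random_convex_mesh(rng, n_points=30, scale=20.0, offset=None):
    """Small random convex mesh (trimesh hull of a Gaussian cloud)."""
    import trimesh

    pts = rng.normal(size=(n_points, 3)) * scale
    if offset is not None:
        pts = pts + offset
    hull = trimesh.convex.convex_hull(pts)
    return rc.TriMesh(np.asarray(hull.vertices), np.asarray(hull.faces))
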