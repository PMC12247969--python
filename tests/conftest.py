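"""Shared phantom fixtures.

All fixtures are generated programmatically and cached per session; every
stochastic fixture carries a fixed seed.
"""

import numpy as np
import pytest

import memthick as mt


@pytest.fixture(scope="session")
def plane_phantom():
    """Noiseless oblique plane, t = 3.6 nm."""
    return mt.rasterize_bilayer(mt.PhantomSpec(geometry="plane",
                                               phg_separation=3.6))


@pytest.fixture(scope="session")
def plane_graph(plane_phantom):
    return mt.build_face_graph(plane_phantom.mesh)


@pytest.fixture(scope="session")
def noisy_plane_phantom():
    """Plane at the standard SNR = 3 noisy condition."""
    return mt.rasterize_bilayer(
        mt.PhantomSpec(geometry="plane", phg_separation=3.6, seed=7).noisy())


@pytest.fixture(scope="session")
def sphere_phantom():
    """Noiseless sphere, r = 50 nm, t = 3.2 nm."""
    return mt.rasterize_bilayer(mt.PhantomSpec(geometry="sphere",
                                               phg_separation=3.2))


@pytest.fixture(scope="session")
def cristae_phantom():
    return mt.rasterize_bilayer(mt.PhantomSpec(geometry="cristae"))


@pytest.fixture(scope="session")
def strip_phantom():
    """30 nm-wide strip mesh for edge-exclusion tests."""
    return mt.rasterize_bilayer(mt.PhantomSpec(geometry="strip",
                                               strip_width=30.0))


def grid_plane_mesh(n=10, step=2.0, z=0.0):
    """Axis-aligned square grid mesh in the z-plane (helper, not a fixture)."""
    ax = step * np.arange(n)
    vv, uu = np.meshgrid(ax, ax, indexing="ij")
    verts = np.column_stack([uu.ravel(), vv.ravel(), np.full(n * n, z)])
    idx = np.arange(n * n).reshape(n, n)
    f1 = np.stack([idx[:-1, :-1], idx[1:, :-1], idx[1:, 1:]], -1).reshape(-1, 3)
    f2 = np.stack([idx[:-1, :-1], idx[1:, 1:], idx[:-1, 1:]], -1).reshape(-1, 3)
    return mt.SurfaceMesh(verts, np.concatenate([f1, f2]))
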