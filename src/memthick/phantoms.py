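"""Synthetic bilayer phantoms: known-truth volumes, meshes, and particles.

A phantom emulates what a membrane looks like in a binned tomogram: two
parallel Gaussian density shells (the phospholipid head-group layers) at a
known separation ``t`` around an analytic mid-surface, optionally with
embedded macromolecule blobs and additive Gaussian voxel noise:

    density(p) = background
                 + amplitude * [ G(s(p) - t/2) + G(s(p) + t/2) ]
                 + blobs + noise

where ``s(p)`` is the signed distance from point ``p`` to the mid-surface
and ``G`` a Gaussian of width ``shell_sigma``.  The signed distance is
computed analytically per geometry — never from the mesh — so the ground
truth is exact and independent of the code under test.

Geometries: an (obliquely oriented) plane, a sphere, a two-thickness slab,
a bounded strip (for edge-exclusion tests), and a "cristae" geometry (flat
outer membrane, inner boundary sheet 10 nm away, and a tubular crista
invagination) with construction-time IBM / crista-junction / crista-body
labels.

The default plane orientation is deliberately oblique to the voxel grid:
real membranes have no preferred orientation, and a grid-aligned plane is
an atypical special case for trilinear interpolation.  Default noise is
calibrated to amplitude/noise_sigma = 3, at which single-triangle fits
are unreliable but 12 nm-averaged fits converge — the regime that
motivates the local averaging strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh

from .mesh import SurfaceMesh
from .patches import ParticleSet
from .volume import DensityVolume

__all__ = [
    "PhantomSpec",
    "PhantomResult",
    "rasterize_bilayer",
    "add_blob",
    "make_particle_set",
    "DEFAULT_SNR",
]

DEFAULT_SNR = 3.0  # amplitude / noise_sigma in the standard noisy condition

#: default oblique plane normal, exactly unit length
_OBLIQUE = np.array([2.0, 1.0, 2.0]) / 3.0


@dataclass
class PhantomSpec:
    """Parameters of a synthetic bilayer phantom.

    ``phg_separation`` is the head-group peak separation (the ground-truth
    thickness, nm); ``shell_sigma`` the head-group shell width (nm).  For
    ``two_slab``, ``phg_separation_2`` is the thickness of the second
    half-plane.  ``volume_shape`` is ``(nz, ny, nx)``; ``None`` picks a
    geometry-appropriate default.
    """

    geometry: str = "plane"
    phg_separation: float = 3.6
    phg_separation_2: float = 3.8     # two_slab only
    shell_sigma: float = 0.8
    amplitude: float = 1.0
    background: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0
    voxel_size: float = 0.998          # nm; the study's binned pixel size
    volume_shape: tuple | None = None  # (nz, ny, nx)
    normal: tuple = tuple(_OBLIQUE)    # planar geometries
    mesh_step: float = 1.5             # nm vertex spacing of planar meshes
    mesh_halfwidth: float | None = None  # cap on the planar mesh half-width (nm)
    sphere_radius: float = 50.0
    subdivisions: int = 3              # icosphere refinement
    strip_width: float = 30.0          # nm (strip geometry)
    ibm_spacing: float = 10.0          # nm OMM->IBM distance (cristae)
    crista_depth: float = 50.0         # nm tube length (cristae)
    crista_radius: float = 8.0         # nm tube radius (cristae)
    blobs: list = field(default_factory=list)  # (face_index, offset_nm, radius_nm, amplitude)

    def __post_init__(self) -> None:
        if not 1.0 <= self.phg_separation <= 8.0:
            raise ValueError("phg_separation must be in [1, 8] nm")
        if not 0.3 <= self.shell_sigma <= 3.0:
            raise ValueError("shell_sigma must be in [0.3, 3] nm")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def noisy(self) -> "PhantomSpec":
        """Copy at the standard noisy condition (SNR = amplitude/sigma = 3)."""
        return replace(self, noise_sigma=self.amplitude / DEFAULT_SNR)


@dataclass
class PhantomResult:
    """Volume + ground-truth mesh + per-face truth table (+ extra meshes)."""

    volume: DensityVolume
    mesh: SurfaceMesh
    truth: pd.DataFrame
    extra_meshes: dict = field(default_factory=dict)


# -- helpers ----------------------------------------------------------------


def _default_shape(spec: PhantomSpec) -> tuple[int, int, int]:
    vs = spec.voxel_size
    if spec.geometry == "sphere":
        n = int(np.ceil((2 * spec.sphere_radius + 26) / vs))
        return (n, n, n)
    if spec.geometry == "cristae":
        nx = int(np.ceil((spec.ibm_spacing + spec.crista_depth + 26) / vs))
        n = int(np.ceil(64 / vs))
        return (n, n, nx)
    return (64, 64, 64)


def _axes(shape_zyx, vs, origin):
    nz, ny, nx = shape_zyx
    x = origin[0] + vs * np.arange(nx)
    y = origin[1] + vs * np.arange(ny)
    z = origin[2] + vs * np.arange(nz)
    # broadcastable to (nz, ny, nx)
    return x[None, None, :], y[None, :, None], z[:, None, None]


def _gauss(d, sigma):
    return np.exp(-0.5 * (d / sigma) ** 2)


def _bilayer_density(s, t, spec: PhantomSpec):
    return spec.amplitude * (_gauss(s - t / 2, spec.shell_sigma) +
                             _gauss(s + t / 2, spec.shell_sigma))


def _in_plane_basis(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e = np.zeros(3)
    e[np.argmin(np.abs(n))] = 1.0
    u = np.cross(n, e)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def _grid_mesh(center, u, v, a_vals, b_vals, keep=None) -> SurfaceMesh:
    """Planar quad grid split into triangles with normals along cross(u, v)."""
    aa, bb = np.meshgrid(a_vals, b_vals, indexing="ij")
    verts = (center[None, :] + aa.reshape(-1, 1) * u[None, :]
             + bb.reshape(-1, 1) * v[None, :])
    na, nb = len(a_vals), len(b_vals)
    idx = np.arange(na * nb).reshape(na, nb)
    f1 = np.stack([idx[:-1, :-1], idx[1:, :-1], idx[1:, 1:]], axis=-1).reshape(-1, 3)
    f2 = np.stack([idx[:-1, :-1], idx[1:, 1:], idx[:-1, 1:]], axis=-1).reshape(-1, 3)
    faces = np.concatenate([f1, f2])
    if keep is not None:
        centers = verts[faces].mean(axis=1)
        faces = faces[keep(centers)]
    return SurfaceMesh(verts, faces)


def _plane_extent(shape_zyx, vs, n, u, v) -> float:
    """Half-width of the square mesh keeping every ±10 nm scan (plus an
    interpolation guard) inside the volume, per axis."""
    halfbox = 0.5 * vs * (np.array([shape_zyx[2], shape_zyx[1], shape_zyx[0]]) - 1)
    margin = 11.0 * np.abs(n) + 1.5
    budget = halfbox - margin
    span = np.abs(u) + np.abs(v)
    active = span > 1e-9
    return float(max(np.min(budget[active] / span[active]), 2.0))


# -- geometry builders ------------------------------------------------------


def _build_plane(spec: PhantomSpec, shape, origin, two_slab: bool):
    vs = spec.voxel_size
    X, Y, Z = _axes(shape, vs, origin)
    c = origin + 0.5 * vs * (np.array([shape[2], shape[1], shape[0]]) - 1)
    n = np.asarray(spec.normal, dtype=np.float64)
    n = n / np.linalg.norm(n)
    u, v = _in_plane_basis(n)
    s = (X - c[0]) * n[0] + (Y - c[1]) * n[1] + (Z - c[2]) * n[2]
    if two_slab:
        ucoord = (X - c[0]) * u[0] + (Y - c[1]) * u[1] + (Z - c[2]) * u[2]
        t = np.where(ucoord < 0, spec.phg_separation, spec.phg_separation_2)
    else:
        t = spec.phg_separation
    density = _bilayer_density(s, t, spec)

    h = _plane_extent(shape, vs, n, u, v)
    if spec.mesh_halfwidth is not None:
        h = min(h, spec.mesh_halfwidth)
    a_vals = np.arange(-h, h + 1e-9, spec.mesh_step)
    if spec.geometry == "strip":
        half_w = spec.strip_width / 2.0
        a_mesh = np.arange(-half_w, half_w + 1e-9, spec.mesh_step)
    else:
        a_mesh = a_vals
    mesh = _grid_mesh(c, u, v, a_mesh, a_vals)
    if two_slab:
        uc = (mesh.face_centers - c) @ u
        true_t = np.where(uc < 0, spec.phg_separation, spec.phg_separation_2)
    else:
        true_t = np.full(mesh.n_faces, spec.phg_separation)
    truth = pd.DataFrame({
        "true_thickness_nm": true_t,
        "true_curvedness": np.zeros(mesh.n_faces),
        "label": [""] * mesh.n_faces,
    })
    return density, mesh, truth, {}


def _build_sphere(spec: PhantomSpec, shape, origin):
    vs = spec.voxel_size
    X, Y, Z = _axes(shape, vs, origin)
    c = origin + 0.5 * vs * (np.array([shape[2], shape[1], shape[0]]) - 1)
    r = spec.sphere_radius
    s = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2) - r
    density = _bilayer_density(s, spec.phg_separation, spec)
    ico = trimesh.creation.icosphere(subdivisions=spec.subdivisions, radius=r)
    mesh = SurfaceMesh(np.asarray(ico.vertices) + c, np.asarray(ico.faces))
    truth = pd.DataFrame({
        "true_thickness_nm": np.full(mesh.n_faces, spec.phg_separation),
        "true_curvedness": np.full(mesh.n_faces, 1.0 / r),
        "label": [""] * mesh.n_faces,
    })
    return density, mesh, truth, {}


def _tube_mesh(axis_yz, x_lo, x_hi, radius, step) -> tuple[np.ndarray, np.ndarray]:
    n_ang = max(int(np.ceil(2 * np.pi * radius / step)), 6)
    n_ax = max(int(np.ceil((x_hi - x_lo) / step)), 2)
    theta = np.linspace(0, 2 * np.pi, n_ang, endpoint=False)
    xs = np.linspace(x_lo, x_hi, n_ax + 1)
    verts = np.array([[x, axis_yz[0] + radius * np.cos(th),
                       axis_yz[1] + radius * np.sin(th)]
                      for x in xs for th in theta])
    faces = []
    for i in range(n_ax):
        for j in range(n_ang):
            a = i * n_ang + j
            b = i * n_ang + (j + 1) % n_ang
            c2 = (i + 1) * n_ang + j
            d = (i + 1) * n_ang + (j + 1) % n_ang
            faces.append([a, b, d])
            faces.append([a, d, c2])
    return verts, np.array(faces)


def _build_cristae(spec: PhantomSpec, shape, origin):
    vs = spec.voxel_size
    X, Y, Z = _axes(shape, vs, origin)
    extent = vs * (np.array([shape[2], shape[1], shape[0]]) - 1)
    x0 = origin[0] + 12.0                      # OMM plane
    x1 = x0 + spec.ibm_spacing                 # IBM sheet
    x2 = x1 + spec.crista_depth                # crista tip
    cy = origin[1] + extent[1] / 2
    cz = origin[2] + extent[2] / 2
    rc = spec.crista_radius

    rho = np.sqrt((Y - cy) ** 2 + (Z - cz) ** 2)
    d_omm = np.abs(X - x0)
    d_sheet = np.where(rho >= rc, np.abs(X - x1),
                       np.sqrt((X - x1) ** 2 + (rc - rho) ** 2))
    ax_over = np.maximum(np.maximum(x1 - X, X - x2), 0.0)
    d_tube = np.sqrt((rho - rc) ** 2 + ax_over ** 2)
    d_cap = np.sqrt(np.maximum(rho - rc, 0.0) ** 2 + (X - x2) ** 2)
    d_imm = np.minimum(np.minimum(d_sheet, d_tube), d_cap)
    density = (_bilayer_density(d_omm, spec.phg_separation, spec) +
               _bilayer_density(d_imm, spec.phg_separation, spec))

    half = min(extent[1], extent[2]) / 2 - 3.0
    grid = np.arange(-half, half + 1e-9, spec.mesh_step)
    ey, ez = np.array([0, 1.0, 0]), np.array([0, 0, 1.0])
    omm = _grid_mesh(np.array([x0, cy, cz]), ey, ez, grid, grid)
    sheet = _grid_mesh(np.array([x1, cy, cz]), ey, ez, grid, grid,
                       keep=lambda c: np.hypot(c[:, 1] - cy, c[:, 2] - cz) > rc)
    tv, tf = _tube_mesh((cy, cz), x1, x2, rc, spec.mesh_step)
    # cap: triangle fan over a disk at the tip
    n_ang = max(int(np.ceil(2 * np.pi * rc / spec.mesh_step)), 6)
    th = np.linspace(0, 2 * np.pi, n_ang, endpoint=False)
    cap_v = np.vstack([[x2, cy, cz],
                       np.column_stack([np.full(n_ang, x2),
                                        cy + rc * np.cos(th),
                                        cz + rc * np.sin(th)])])
    cap_f = np.array([[0, 1 + j, 1 + (j + 1) % n_ang] for j in range(n_ang)])

    verts = np.vstack([sheet.vertices, tv, cap_v])
    faces = np.vstack([sheet.faces,
                       tf + len(sheet.vertices),
                       cap_f + len(sheet.vertices) + len(tv)])
    imm = SurfaceMesh(verts, faces)

    dist = imm.face_centers[:, 0] - x0
    excess = dist - spec.ibm_spacing
    label = np.where(excess < 4.0, "IBM", np.where(excess <= 14.0, "CJ", "CB"))
    truth = pd.DataFrame({
        "true_thickness_nm": np.full(imm.n_faces, spec.phg_separation),
        "true_curvedness": np.where(
            np.abs(np.hypot(imm.face_centers[:, 1] - cy,
                            imm.face_centers[:, 2] - cz) - rc) < 1e-6,
            0.5 / rc, 0.0),
        "label": label,
        "true_distance_nm": dist,
    })
    return density, imm, truth, {"omm": omm}


# -- public API -------------------------------------------------------------


def rasterize_bilayer(spec: PhantomSpec) -> PhantomResult:
    """Render the phantom volume, mesh, and ground-truth table."""
    shape = tuple(spec.volume_shape or _default_shape(spec))
    vs = spec.voxel_size
    origin = np.zeros(3)
    extent = vs * (min(shape) - 1)
    if spec.phg_separation + 6 * spec.shell_sigma > extent:
        raise ValueError("membrane thicker than the volume extent")

    if spec.geometry in ("plane", "strip"):
        density, mesh, truth, extra = _build_plane(spec, shape, origin, False)
    elif spec.geometry == "two_slab":
        density, mesh, truth, extra = _build_plane(spec, shape, origin, True)
    elif spec.geometry == "sphere":
        density, mesh, truth, extra = _build_sphere(spec, shape, origin)
    elif spec.geometry == "cristae":
        density, mesh, truth, extra = _build_cristae(spec, shape, origin)
    else:
        raise ValueError(f"unknown phantom geometry {spec.geometry!r}")

    density = density + spec.background
    for face_idx, offset, radius, amp in spec.blobs:
        center = mesh.face_centers[face_idx] + offset * mesh.face_normals[face_idx]
        density = _blob_field(density, shape, vs, origin, center, radius, amp)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        density = density + rng.normal(0.0, spec.noise_sigma, size=shape)

    vol = DensityVolume(grid=density, voxel_size=vs, origin=origin)
    mesh.face_attributes["curvedness"] = truth["true_curvedness"].to_numpy().copy()
    return PhantomResult(volume=vol, mesh=mesh, truth=truth, extra_meshes=extra)


def _blob_field(density, shape, vs, origin, center, radius, amplitude):
    X, Y, Z = _axes(shape, vs, origin)
    r2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
    return density + amplitude * np.exp(-0.5 * r2 / radius ** 2)


def add_blob(vol: DensityVolume, center, radius: float,
             amplitude: float) -> DensityVolume:
    """Add a Gaussian blob (a macromolecule stand-in) to a copy of ``vol``."""
    center = np.asarray(center, dtype=np.float64)
    grid = _blob_field(vol.grid, vol.grid.shape, vol.voxel_size, vol.origin,
                       center, radius, amplitude)
    return DensityVolume(grid=grid, voxel_size=vol.voxel_size,
                         origin=vol.origin.copy(), polarity=vol.polarity)


def make_particle_set(mesh: SurfaceMesh, n: int, offset_nm: float,
                      seed: int = 0,
                      faces: np.ndarray | None = None,
                      ) -> tuple[ParticleSet, np.ndarray]:
    """Place ``n`` particles ``offset_nm`` along the normals of random faces.

    Returns the particle set and the ground-truth face indices, for
    assignment tests.  Pass ``faces`` to restrict the eligible faces.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    eligible = np.arange(mesh.n_faces) if faces is None else np.asarray(faces)
    chosen = rng.choice(eligible, size=n, replace=False)
    centers = (mesh.face_centers[chosen] +
               offset_nm * mesh.face_normals[chosen])
    return ParticleSet(centers=centers, source="phantom"), chosen
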