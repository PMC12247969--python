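"""Particle-centered membrane patches and extended density profiles.

A *patch* is the membrane "footprint" of a particle (e.g. an ATP synthase):
the set of faces within a 12 nm geodesic radius of the face nearest the
particle.  Particles farther than 24 nm (the height of an ATP synthase)
from every face are rejected to avoid cross-assignment between membranes.
Matched randomized patches — same count, centers > 12 nm apart — provide
the null comparison.

Patch profiles extend the ±10 nm bilayer scan to −10 → +30 nm along
particle-curated normals (flipped so +offset points toward the particle),
so membrane-associated complexes show up as extra density peaks beyond
the bilayer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .mesh import FaceGraph, SurfaceMesh, geodesic_neighborhood
from .profiling import LineScan, average_scans, neighborhood_weight, scan_normal
from .volume import DensityVolume

__all__ = [
    "ParticleSet",
    "Patch",
    "load_particles",
    "assign_particles",
    "extract_patch",
    "randomized_patches",
    "patch_mean",
    "curate_patch_normals",
    "patch_profile",
    "average_profiles",
]

DEFAULT_ASSIGN_CUTOFF = 24.0   # nm; ~height of an ATP synthase
DEFAULT_PATCH_RADIUS = 12.0    # nm geodesic patch radius
DEFAULT_MIN_CENTER_SEP = 12.0  # nm between randomized patch centers


@dataclass
class ParticleSet:
    """Particle coordinates (physical nm), optionally with orientations."""

    centers: np.ndarray
    orientations: np.ndarray | None = None
    labels: np.ndarray | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("particle centers must be finite")

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class Patch:
    """A geodesic disc of faces, optionally tied to a particle."""

    center_face: int
    member_faces: np.ndarray
    member_distances: np.ndarray
    particle: int | None = None   # index into the ParticleSet
    curated_sign: int = 1
    kind: str = "particle"        # or "random"


# -- particle input ---------------------------------------------------------


def _parse_star_loop(path: Path) -> pd.DataFrame:
    """Minimal STAR reader for a single data loop with _rln columns."""
    labels: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("loop_"):
            in_loop, labels, rows = True, [], []
            continue
        if in_loop and line.startswith("_"):
            labels.append(line.split()[0].lstrip("_"))
            continue
        if in_loop:
            if line.startswith("data_"):
                break
            fields = line.split()
            if len(fields) == len(labels):
                rows.append(fields)
    if not labels or not rows:
        raise ValueError(f"{path}: no STAR data loop found")
    return pd.DataFrame(rows, columns=labels)


def load_particles(path: str | Path,
                   particle_pixel_size_a: float | None = None) -> ParticleSet:
    """Read particle centers from a STAR or CSV file.

    STAR coordinates (``rlnCoordinateX/Y/Z``) are in voxels of the stated
    reference pixel size and require ``particle_pixel_size_a`` (Å) to
    convert to nm.  CSV input (columns ``x``, ``y``, ``z`` or
    ``x_nm, y_nm, z_nm``) is taken as nm directly.
    """
    path = Path(path)
    if path.suffix.lower() == ".star":
        if particle_pixel_size_a is None:
            raise ValueError("STAR input requires particle_pixel_size_a (Å/voxel)")
        df = _parse_star_loop(path)
        cols = ["rlnCoordinateX", "rlnCoordinateY", "rlnCoordinateZ"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing STAR columns {missing}")
        centers = df[cols].to_numpy(dtype=np.float64) * particle_pixel_size_a / 10.0
    else:
        df = pd.read_csv(path)
        for cols in (["x_nm", "y_nm", "z_nm"], ["x", "y", "z"]):
            if all(c in df.columns for c in cols):
                centers = df[cols].to_numpy(dtype=np.float64)
                break
        else:
            raise ValueError(f"{path}: need columns x,y,z (nm)")
    return ParticleSet(centers=centers, source=str(path))


# -- assignment and extraction ----------------------------------------------


def assign_particles(particles: ParticleSet, mesh: SurfaceMesh,
                     max_dist: float = DEFAULT_ASSIGN_CUTOFF,
                     ) -> tuple[list[tuple[int, int, float]], list[int]]:
    """Nearest-face assignment with a distance cutoff.

    Returns ``(accepted, rejected)`` where each accepted entry is
    ``(particle_index, face_index, distance_nm)``.  Equidistant ties break
    to the lowest face index for determinism.
    """
    if mesh.n_faces == 0:
        raise ValueError("cannot assign particles to an empty mesh")
    tree = cKDTree(mesh.face_centers)
    k = min(8, mesh.n_faces)
    dists, idxs = tree.query(particles.centers, k=k)
    dists = np.atleast_2d(dists)
    idxs = np.atleast_2d(idxs)
    accepted, rejected = [], []
    for p in range(len(particles)):
        d0 = dists[p, 0]
        if d0 > max_dist:
            rejected.append(p)
            continue
        tied = idxs[p][np.abs(dists[p] - d0) <= 1e-9 * max(d0, 1.0)]
        accepted.append((p, int(tied.min()), float(d0)))
    return accepted, rejected


def extract_patch(mesh: SurfaceMesh, graph: FaceGraph, center_face: int,
                  radius: float = DEFAULT_PATCH_RADIUS,
                  particle: int | None = None, kind: str = "particle") -> Patch:
    """Faces within ``radius`` nm geodesic distance of ``center_face``."""
    members, dist = geodesic_neighborhood(graph, center_face, radius)
    return Patch(center_face=int(center_face), member_faces=members,
                 member_distances=dist, particle=particle, kind=kind)


def randomized_patches(mesh: SurfaceMesh, graph: FaceGraph, n: int,
                       min_center_sep: float = DEFAULT_MIN_CENTER_SEP,
                       region_mask: np.ndarray | None = None,
                       seed: int = 0,
                       radius: float = DEFAULT_PATCH_RADIUS,
                       area_weighted: bool = False) -> list[Patch]:
    """``n`` random control patches with pairwise center separation > 12 nm.

    Centers are drawn uniformly over the eligible faces (by count; pass
    ``area_weighted=True`` to draw proportionally to face area) by
    rejection sampling; deterministic per ``seed``.  ``region_mask``
    restricts eligibility (True = eligible), e.g. to crista-body faces.
    """
    eligible = (np.arange(mesh.n_faces) if region_mask is None
                else np.flatnonzero(region_mask))
    if len(eligible) == 0:
        raise ValueError("no eligible faces for randomized patches")
    rng = np.random.default_rng(seed)
    prob = None
    if area_weighted:
        a = mesh.face_areas[eligible]
        prob = a / a.sum()
    centers: list[int] = []
    pts: list[np.ndarray] = []
    max_attempts = 10 * n * 100
    attempts = 0
    while len(centers) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"randomized patch placement failed: {len(centers)}/{n} placed "
                f"after {attempts} attempts"
            )
        attempts += 1
        f = int(rng.choice(eligible, p=prob))
        c = mesh.face_centers[f]
        if any(np.linalg.norm(c - q) <= min_center_sep for q in pts):
            continue
        centers.append(f)
        pts.append(c)
    return [extract_patch(mesh, graph, f, radius, kind="random") for f in centers]


# -- per-patch summaries ----------------------------------------------------


def patch_mean(patch: Patch, values: np.ndarray, areas: np.ndarray) -> float:
    """Area-weighted mean of a per-face quantity over the patch members.

    Faces with undefined (NaN) values are skipped; if none are defined
    the result is NaN (in-band, not an error).
    """
    v = np.asarray(values, dtype=np.float64)[patch.member_faces]
    a = np.asarray(areas, dtype=np.float64)[patch.member_faces]
    ok = np.isfinite(v)
    if not ok.any():
        return float("nan")
    return float(np.average(v[ok], weights=a[ok]))


def curate_patch_normals(patch: Patch, particle_center: np.ndarray,
                         mesh: SurfaceMesh) -> Patch:
    """Orient the patch toward its particle.

    ``curated_sign`` is +1 if the center face's normal points toward the
    particle, else −1; the sign is applied to every member scan so that
    positive offsets always run toward the particle.
    """
    to_particle = (np.asarray(particle_center, dtype=np.float64)
                   - mesh.face_centers[patch.center_face])
    norm = np.linalg.norm(to_particle)
    if norm == 0:
        raise ValueError("particle center coincides with the patch center face")
    dot = float(mesh.face_normals[patch.center_face] @ to_particle)
    return replace(patch, curated_sign=1 if dot > 0 else -1)


def patch_profile(vol: DensityVolume, mesh: SurfaceMesh, patch: Patch,
                  lo: float = -10.0, hi: float = 30.0,
                  step: float = 0.25) -> LineScan:
    """Distance-weighted average scan of a patch along curated normals.

    The asymmetric default range (−10 → +30 nm) reaches past the bilayer
    toward the particle, so membrane-associated complexes appear as extra
    peaks at positive offsets.
    """
    sign = patch.curated_sign
    scans = [scan_normal(vol, mesh.face_centers[f],
                         sign * mesh.face_normals[f], lo, hi, step)
             for f in patch.member_faces]
    return average_scans(scans, neighborhood_weight(patch.member_distances))


def average_profiles(profiles: list[LineScan]) -> LineScan:
    """Unweighted per-offset mean of patch profiles (grids must match)."""
    return average_scans(profiles, np.ones(len(profiles)))
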