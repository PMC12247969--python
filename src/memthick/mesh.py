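"""Attributed triangle surface meshes and their face-adjacency graph.

The mesh is the measurement scaffold: every thickness measurement is made
at a triangle (face) center along that face's normal, and every notion of
"nearby on the membrane" — the 12 nm averaging neighborhood, the 8 nm
edge-exclusion margin, particle patches — is a *geodesic* (graph) distance
through the face-adjacency graph, never a Euclidean ball.  Euclidean
neighborhoods would bleed across closely apposed membranes (opposing
crista leaflets sit ~20 nm apart); graph distance cannot leave the surface.

Faces are adjacent iff they share an edge; edge weights are the Euclidean
distances between face centers (nm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "SurfaceMesh",
    "FaceGraph",
    "build_face_graph",
    "geodesic_neighborhood",
    "boundary_faces",
    "edge_exclusion_mask",
    "load_mesh",
    "save_mesh",
    "save_face_table",
    "load_face_table",
]

_DEGENERATE_AREA = 1e-6  # nm^2; faces below this are dropped at load
_NORMAL_TOL = 1e-6


class SurfaceMesh:
    """Triangle mesh with per-face attributes, in physical nm coordinates.

    Vertices are ``(n, 3)`` physical ``(x, y, z)`` positions; faces are
    ``(m, 3)`` vertex-index triples.  Derived per-face geometry (center,
    unit normal, area) is computed on construction.  Degenerate faces
    (area < 1e-6 nm²) are dropped with a logged count; supplied per-face
    attribute arrays are filtered to match.

    Winding (and hence normal orientation) is made consistent within each
    connected component by breadth-first propagation; a mesh that cannot
    be consistently oriented raises ``ValueError``.  The global sign per
    component is arbitrary — line scans are symmetric in ±normal, so the
    sign never affects a thickness.
    """

    def __init__(self, vertices, faces, face_attributes=None,
                 fix_orientation: bool = True):
        vertices = np.asarray(vertices, dtype=np.float64)
        faces = np.asarray(faces, dtype=np.int64)
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) index array")
        if faces.size and (faces.min() < 0 or faces.max() >= len(vertices)):
            raise ValueError("face indices out of range")
        attrs = {k: np.asarray(v) for k, v in (face_attributes or {}).items()}
        for name, arr in attrs.items():
            if len(arr) != len(faces):
                raise ValueError(
                    f"attribute {name!r} has {len(arr)} rows but the mesh has "
                    f"{len(faces)} faces"
                )

        cross = np.cross(vertices[faces[:, 1]] - vertices[faces[:, 0]],
                         vertices[faces[:, 2]] - vertices[faces[:, 0]])
        areas = 0.5 * np.linalg.norm(cross, axis=1)
        keep = areas >= _DEGENERATE_AREA
        if not keep.all():
            logger.info("dropping %d degenerate faces (area < %g nm^2)",
                        (~keep).sum(), _DEGENERATE_AREA)
            faces = faces[keep]
            attrs = {k: v[keep] for k, v in attrs.items()}

        tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
        if fix_orientation and len(faces):
            trimesh.repair.fix_normals(tm, multibody=True)
            if not tm.is_winding_consistent:
                raise ValueError("mesh is non-orientable: no consistent winding exists")

        self.vertices: np.ndarray = np.asarray(tm.vertices, dtype=np.float64)
        self.faces: np.ndarray = np.asarray(tm.faces, dtype=np.int64)
        self.face_attributes: dict[str, np.ndarray] = attrs
        self._tm = tm
        self.face_centers: np.ndarray = self.vertices[self.faces].mean(axis=1)
        self.face_normals: np.ndarray = np.asarray(tm.face_normals, dtype=np.float64)
        self.face_areas: np.ndarray = np.asarray(tm.area_faces, dtype=np.float64)
        norms = np.linalg.norm(self.face_normals, axis=1)
        if len(self.faces) and np.any(np.abs(norms - 1.0) > _NORMAL_TOL):
            raise ValueError("face normals are not unit length")

    # ------------------------------------------------------------------

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def total_area(self) -> float:
        return float(self.face_areas.sum())

    def as_trimesh(self) -> trimesh.Trimesh:
        return self._tm

    def flipped(self) -> "SurfaceMesh":
        """Copy with all normals (winding) reversed."""
        return SurfaceMesh(self.vertices, self.faces[:, ::-1],
                           face_attributes=self.face_attributes,
                           fix_orientation=False)

    def face_adjacency_pairs(self) -> np.ndarray:
        """``(k, 2)`` pairs of faces sharing an edge."""
        return np.asarray(self._tm.face_adjacency, dtype=np.int64).reshape(-1, 2)


@dataclass
class FaceGraph:
    """Sparse symmetric face-adjacency graph with nm edge weights."""

    adjacency: csr_matrix
    n_faces: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_faces = self.adjacency.shape[0]


def build_face_graph(mesh: SurfaceMesh) -> FaceGraph:
    """Edge-sharing face adjacency weighted by center-to-center distance."""
    m = mesh.n_faces
    pairs = mesh.face_adjacency_pairs()
    if len(pairs) == 0:
        return FaceGraph(csr_matrix((m, m)))
    d = np.linalg.norm(mesh.face_centers[pairs[:, 0]] - mesh.face_centers[pairs[:, 1]],
                       axis=1)
    if np.any(d <= 0):
        # coincident face centers would create zero-weight edges; nudge them
        d = np.maximum(d, 1e-12)
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    w = np.concatenate([d, d])
    return FaceGraph(coo_matrix((w, (rows, cols)), shape=(m, m)).tocsr())


def geodesic_neighborhood(graph: FaceGraph, center_face: int,
                          radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Faces within graph distance ``radius`` nm of ``center_face``.

    Returns ``(face_indices, distances)`` sorted by distance; the center
    itself is included at distance 0.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if not 0 <= center_face < graph.n_faces:
        raise IndexError(f"face index {center_face} out of range")
    dist = dijkstra(graph.adjacency, directed=False, indices=center_face,
                    limit=radius * (1 + 1e-12) if radius > 0 else 0)
    idx = np.flatnonzero(dist <= radius)
    order = np.argsort(dist[idx], kind="stable")
    return idx[order], dist[idx][order]


def geodesic_distance_rows(graph: FaceGraph, sources: np.ndarray,
                           radius: float) -> np.ndarray:
    """Dijkstra distances from each source face, inf beyond ``radius``."""
    return dijkstra(graph.adjacency, directed=False,
                    indices=np.asarray(sources), limit=radius * (1 + 1e-12))


def boundary_faces(mesh: SurfaceMesh) -> np.ndarray:
    """Faces incident to an open (single-face) edge, as a sorted index array."""
    if mesh.n_faces == 0:
        return np.empty(0, dtype=np.int64)
    edges = np.sort(mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    _, inverse, counts = np.unique(edges, axis=0, return_inverse=True,
                                   return_counts=True)
    open_edge = counts[inverse] == 1          # per (face, edge-slot)
    on_boundary = open_edge.reshape(-1, 3).any(axis=1)
    return np.flatnonzero(on_boundary).astype(np.int64)


def edge_exclusion_mask(mesh: SurfaceMesh, graph: FaceGraph,
                        margin: float = 8.0,
                        metric: str = "geodesic") -> np.ndarray:
    """Boolean per face: True = within ``margin`` nm of the surface boundary.

    Thickness estimates near mesh edges are corrupted by missing-wedge
    artifacts, so faces whose distance to the nearest boundary face is
    <= ``margin`` are excluded (boundary faces themselves are at distance
    0).  Closed surfaces have no boundary and nothing is excluded.
    ``metric`` selects geodesic (default) or euclidean distance.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    excluded = np.zeros(mesh.n_faces, dtype=bool)
    bnd = boundary_faces(mesh)
    if len(bnd) == 0:
        return excluded
    if metric == "geodesic":
        dist = dijkstra(graph.adjacency, directed=False, indices=bnd,
                        limit=margin * (1 + 1e-12), min_only=True)
    elif metric == "euclidean":
        tree = cKDTree(mesh.face_centers[bnd])
        dist, _ = tree.query(mesh.face_centers)
    else:
        raise ValueError(f"unknown edge margin metric {metric!r}")
    excluded[dist <= margin] = True
    excluded[bnd] = True
    return excluded


# -- I/O --------------------------------------------------------------------

_GEOM_COLUMNS = ("x", "y", "z", "nx", "ny", "nz", "area_nm2")


def save_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write a PLY; numeric per-face attributes become per-face properties.

    String attributes (e.g. compartment labels) cannot be carried by PLY
    scalar properties; persist those with :func:`save_face_table`.
    """
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    for name, arr in mesh.face_attributes.items():
        if np.issubdtype(np.asarray(arr).dtype, np.number) or arr.dtype == bool:
            tm.face_attributes[name] = np.asarray(arr, dtype=np.float64)
    tm.export(str(path))


def load_mesh(path: str | Path, attribute_table: str | Path | None = None,
              fix_orientation: bool = True) -> SurfaceMesh:
    """Read a PLY (with optional per-face scalar properties).

    ``attribute_table`` optionally points at a companion per-face CSV (see
    :func:`save_face_table`); its columns are attached by face index and a
    row-count mismatch is an error.
    """
    tm = trimesh.load(str(path), process=False, force="mesh")
    attrs: dict[str, np.ndarray] = {}
    raw = tm.metadata.get("_ply_raw", {})
    if "face" in raw:
        data = raw["face"]["data"]
        if hasattr(data, "dtype") and data.dtype.names:
            for name in data.dtype.names:
                if name == "vertex_indices":
                    continue
                attrs[name] = np.asarray(data[name]).reshape(len(tm.faces))
    mesh = SurfaceMesh(tm.vertices, tm.faces, face_attributes=attrs,
                       fix_orientation=fix_orientation)
    if attribute_table is not None:
        df = load_face_table(attribute_table)
        if len(df) != mesh.n_faces:
            raise ValueError(
                f"attribute table has {len(df)} rows but the mesh has "
                f"{mesh.n_faces} faces"
            )
        for col in df.columns:
            if col in ("face_index",) + _GEOM_COLUMNS:
                continue
            mesh.face_attributes[col] = df[col].to_numpy()
    return mesh


def save_face_table(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write the per-face CSV interchange table.

    Columns: face_index, center (x, y, z), normal (nx, ny, nz), area_nm2,
    plus every per-face attribute (numeric or string).
    """
    df = pd.DataFrame({
        "face_index": np.arange(mesh.n_faces),
        "x": mesh.face_centers[:, 0],
        "y": mesh.face_centers[:, 1],
        "z": mesh.face_centers[:, 2],
        "nx": mesh.face_normals[:, 0],
        "ny": mesh.face_normals[:, 1],
        "nz": mesh.face_normals[:, 2],
        "area_nm2": mesh.face_areas,
    })
    for name, arr in mesh.face_attributes.items():
        df[name] = arr
    df.to_csv(path, index=False)


def load_face_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
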