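"""Density volumes: MRC I/O, trilinear sampling, and polarity handling.

A :class:`DensityVolume` is the in-memory surrogate for a (binned) tomogram:
a 3D scalar grid with a physical voxel size and origin.  The grid is stored
in ``(z, y, x)`` section order, matching the MRC convention, while every
physical coordinate exchanged with the rest of the package is an ``(x, y, z)``
vector in nanometres.  The conversion between the two conventions happens in
exactly one place (:meth:`DensityVolume.sample`).

Membrane head groups must appear as density *maxima* for peak fitting to
work; tomograms come in both sign conventions, so polarity is tracked
explicitly and normalised with :func:`normalize_polarity`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "DensityVolume",
    "load_volume",
    "save_volume",
    "normalize_polarity",
    "sample_density",
]

#: Values densities take where a sample point falls outside the grid.
OUT_OF_VOLUME = np.nan

PEAKS_BRIGHT = "peaks_bright"
PEAKS_DARK = "peaks_dark"


@dataclass
class DensityVolume:
    """A 3D density grid with physical metadata.

    Parameters
    ----------
    grid :
        Scalar densities, shape ``(nz, ny, nx)``, arbitrary units.
    voxel_size :
        Isotropic voxel edge length in nm (must be > 0).
    origin :
        Physical ``(x, y, z)`` coordinate (nm) of the *center* of voxel
        ``(0, 0, 0)``.
    polarity :
        ``"peaks_bright"`` if membrane density is high-valued,
        ``"peaks_dark"`` if it is low-valued.
    """

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    polarity: str = PEAKS_BRIGHT

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise ValueError(
                f"grid must be 3D with every dimension >= 2, got shape {self.grid.shape}"
            )
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.polarity not in (PEAKS_BRIGHT, PEAKS_DARK):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        self._interp: RegularGridInterpolator | None = None

    # -- geometry -----------------------------------------------------------

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def physical_extent(self) -> np.ndarray:
        """``(x, y, z)`` extent (nm) spanned by voxel centers."""
        nz, ny, nx = self.grid.shape
        return self.origin + self.voxel_size * (np.array([nx, ny, nz]) - 1)

    def center(self) -> np.ndarray:
        """Physical midpoint of the voxel-center bounding box."""
        return 0.5 * (self.origin + self.physical_extent)

    # -- sampling -----------------------------------------------------------

    def _interpolator(self) -> RegularGridInterpolator:
        if self._interp is None:
            nz, ny, nx = self.grid.shape
            axes = tuple(
                self.origin[2 - i] + self.voxel_size * np.arange(n)
                for i, n in enumerate((nz, ny, nx))
            )
            self._interp = RegularGridInterpolator(
                axes, self.grid, method="linear",
                bounds_error=False, fill_value=OUT_OF_VOLUME,
            )
        return self._interp

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinearly interpolate densities at physical ``(x, y, z)`` points.

        Points outside the voxel-center bounding box yield NaN (the
        out-of-volume sentinel) rather than raising, so that line scans can
        be truncated gracefully at volume edges.

        Parameters
        ----------
        points :
            Array of shape ``(..., 3)`` of physical coordinates in nm.
        """
        pts = np.asarray(points, dtype=np.float64)
        squeeze = pts.ndim == 1
        pts = np.atleast_2d(pts)
        # physical (x, y, z) -> grid (z, y, x)
        vals = self._interpolator()(pts[..., ::-1])
        return vals[0] if squeeze else vals

    def negated(self) -> "DensityVolume":
        """Sign-flipped copy with the opposite polarity tag."""
        flipped = PEAKS_DARK if self.polarity == PEAKS_BRIGHT else PEAKS_BRIGHT
        return replace(self, grid=-self.grid, polarity=flipped)


def sample_density(vol: DensityVolume, point: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`DensityVolume.sample`."""
    return vol.sample(point)


# -- polarity ---------------------------------------------------------------


def normalize_polarity(vol: DensityVolume, mesh=None, n_probe: int = 500,
                       seed: int = 0) -> DensityVolume:
    """Return a volume whose membrane head groups are density maxima.

    If ``vol.polarity`` is ``"peaks_bright"`` the volume is returned
    unchanged; if ``"peaks_dark"`` a negated copy is returned.  When a
    ``mesh`` is supplied the polarity is auto-detected first by probing
    densities at up to ``n_probe`` random triangle centers: membranes
    dominate the signal there, so a below-volume-mean probe average
    indicates dark membranes.
    """
    if mesh is not None:
        rng = np.random.default_rng(seed)
        n = len(mesh.face_centers)
        idx = rng.choice(n, size=min(n_probe, n), replace=False)
        probe = vol.sample(mesh.face_centers[idx])
        probe = probe[np.isfinite(probe)]
        if probe.size == 0:
            raise ValueError("polarity auto-detection: no mesh face centers inside the volume")
        detected = PEAKS_BRIGHT if probe.mean() >= vol.grid.mean() else PEAKS_DARK
        vol = replace(vol, polarity=detected)
    if vol.polarity == PEAKS_BRIGHT:
        return vol
    return vol.negated()


# -- MRC I/O ----------------------------------------------------------------

_ANGSTROM_PER_NM = 10.0
_ISOTROPY_RTOL = 1e-3  # header pixel sizes must agree to 0.1%


def load_volume(path: str | Path, voxel_size_nm: float | None = None,
                polarity: str = PEAKS_BRIGHT) -> DensityVolume:
    """Read an MRC2014 map into a :class:`DensityVolume`.

    The header pixel size (Å) is converted to nm; ``voxel_size_nm``
    overrides the header (required when the header carries a zero or
    missing pixel size).  Anisotropic headers are rejected.
    """
    m = gemmi.read_ccp4_map(str(path))
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    grid_xyz = np.array(m.grid, copy=True)  # (nx, ny, nz)
    grid = np.ascontiguousarray(grid_xyz.transpose(2, 1, 0))  # (nz, ny, nx)
    nx, ny, nz = grid_xyz.shape
    cell = m.grid.unit_cell
    spacings = np.array([cell.a / nx, cell.b / ny, cell.c / nz])
    if voxel_size_nm is None:
        if np.any(spacings <= 0) or not np.all(np.isfinite(spacings)):
            raise ValueError(
                f"{path}: MRC header has missing/zero pixel size; "
                "pass the voxel size explicitly (config key 'voxel_size_nm')"
            )
        if spacings.max() - spacings.min() > _ISOTROPY_RTOL * spacings.mean():
            raise ValueError(
                f"{path}: anisotropic voxels in header ({spacings} Å); only "
                "isotropic volumes are supported"
            )
        voxel_size_nm = float(spacings.mean()) / _ANGSTROM_PER_NM
    origin_a = np.array([m.header_float(w) for w in (50, 51, 52)])
    return DensityVolume(grid=grid, voxel_size=voxel_size_nm,
                         origin=origin_a / _ANGSTROM_PER_NM, polarity=polarity)


def save_volume(vol: DensityVolume, path: str | Path) -> None:
    """Write a :class:`DensityVolume` as an MRC2014 map (pixel size in Å)."""
    grid_xyz = np.ascontiguousarray(vol.grid.transpose(2, 1, 0), dtype=np.float32)
    g = gemmi.FloatGrid(grid_xyz)
    nx, ny, nz = grid_xyz.shape
    vs_a = vol.voxel_size * _ANGSTROM_PER_NM
    g.unit_cell = gemmi.UnitCell(nx * vs_a, ny * vs_a, nz * vs_a, 90.0, 90.0, 90.0)
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for w, v in zip((50, 51, 52), vol.origin * _ANGSTROM_PER_NM):
        m.set_header_float(w, float(v))
    m.write_ccp4_map(str(path))
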