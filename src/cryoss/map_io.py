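"""Reading, writing and resampling of volumetric density maps.

Maps are held in a :class:`DensityMap`, a plain 3D scalar grid in (x, y, z)
index order together with a world origin and voxel spacing in Angstrom.
The world coordinate of voxel index ``(i, j, k)`` is
``origin + (i, j, k) * spacing``; indices denote voxel *centers*.

On disk the MRC2014/CCP4 format is used (via gemmi).  Deposited maps come
with arbitrary axis permutations (MAPC/MAPR/MAPS); these are honoured on
read and normalised to the canonical 1,2,3 order, so the in-memory grid is
always x-fastest-index regardless of how the file was stored.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy import ndimage


class MapFormatError(ValueError):
    """Raised when an MRC/CCP4 file cannot be interpreted."""


@dataclass
class DensityMap:
    """A 3D scalar field on a regular grid.

    Parameters
    ----------
    grid : ndarray, shape (nx, ny, nz)
        Density values; axis order is (x, y, z).
    origin : ndarray, shape (3,)
        World coordinate (A) of the center of voxel (0, 0, 0).
    spacing : ndarray, shape (3,)
        Voxel edge lengths in A; all components > 0.
    """

    grid: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if self.grid.ndim != 3:
            raise ValueError(f"grid must be 3D, got ndim={self.grid.ndim}")
        if not np.all(self.spacing > 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def voxel_centers_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centers."""
        return tuple(
            self.origin[a] + np.arange(self.dims[a]) * self.spacing[a]
            for a in range(3)
        )

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world points (n, 3)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return (xyz - self.origin) / self.spacing

    def same_geometry(self, other: "DensityMap", tol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )


def _header_words(m: gemmi.Ccp4Map) -> dict:
    h = {
        "dims_file": (m.header_i32(1), m.header_i32(2), m.header_i32(3)),
        "mode": m.header_i32(4),
        "nstart": (m.header_i32(5), m.header_i32(6), m.header_i32(7)),
        "sampling": (m.header_i32(8), m.header_i32(9), m.header_i32(10)),
        "cell": tuple(m.header_float(i) for i in range(11, 17)),
        "mapcrs": (m.header_i32(17), m.header_i32(18), m.header_i32(19)),
        "origin": tuple(m.header_float(i) for i in range(50, 53)),
    }
    return h


def read_map(path: str | os.PathLike) -> DensityMap:
    """Read an MRC/CCP4 map (modes 0/1/2) into a :class:`DensityMap`.

    The MAPC/MAPR/MAPS axis assignment of the file is honoured: the returned
    grid is always indexed (x, y, z).  The world origin is taken from the
    ORIGIN header record; if that record is zero and the start indices are
    not, ``nstart * spacing`` is used instead (common CCP4 practice).
    """
    try:
        m = gemmi.read_ccp4_map(os.fspath(path))
    except Exception as exc:  # gemmi raises RuntimeError on bad headers
        raise MapFormatError(f"cannot read MRC/CCP4 map {path!r}: {exc}") from exc
    h = _header_words(m)
    if h["mode"] not in (0, 1, 2):
        raise MapFormatError(
            f"unsupported MODE={h['mode']} in {path!r} (expected 0, 1 or 2)"
        )
    mapcrs = h["mapcrs"]
    if sorted(mapcrs) != [1, 2, 3]:
        raise MapFormatError(f"invalid MAPC/MAPR/MAPS={mapcrs} in {path!r}")
    sampling = h["sampling"]
    if any(s <= 0 for s in sampling):
        raise MapFormatError(f"non-positive MX/MY/MZ={sampling} in {path!r}")
    cell = h["cell"]
    spacing = np.array([cell[a] / sampling[a] for a in range(3)], dtype=float)

    # Normalise axis order to X,Y,Z; gemmi permutes the data for us.
    m.setup(0.0, gemmi.MapSetup.ReorderOnly)
    grid = np.array(m.grid, copy=True).astype(np.float32)

    origin = np.array(h["origin"], dtype=float)
    if np.all(origin == 0.0) and any(s != 0 for s in h["nstart"]):
        # nstart words are in file (column, row, section) order; map to X,Y,Z
        nstart_xyz = [0, 0, 0]
        for file_axis, xyz_axis in enumerate(mapcrs):
            nstart_xyz[xyz_axis - 1] = h["nstart"][file_axis]
        origin = np.array(nstart_xyz, dtype=float) * spacing
    return DensityMap(grid=grid, origin=origin, spacing=spacing)


def write_map(dmap: DensityMap, path: str | os.PathLike) -> None:
    """Write a :class:`DensityMap` as MRC2014 mode 2 (float32).

    Axis order is written canonically (MAPC,MAPR,MAPS = 1,2,3), the cell is
    ``dims * spacing`` and DMIN/DMAX/DMEAN are filled from the data.
    """
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.grid, dtype=np.float32))
    nx, ny, nz = dmap.dims
    sx, sy, sz = dmap.spacing
    m.grid.unit_cell = gemmi.UnitCell(nx * sx, ny * sy, nz * sz, 90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    for w, v in zip((50, 51, 52), dmap.origin):
        m.set_header_float(w, float(v))
    try:
        m.write_ccp4_map(os.fspath(path))
    except Exception as exc:
        raise OSError(f"cannot write map to {path!r}: {exc}") from exc


def resample_to_unit_grid(dmap: DensityMap, target_spacing: float = 1.0) -> DensityMap:
    """Resample a map onto an isotropic grid by trilinear interpolation.

    The output grid starts at the input origin and covers the input's world
    extent at ``target_spacing`` A per voxel.  Values are trilinear
    interpolants of the input evaluated at output voxel centers; points
    outside the input support are 0 (background is treated as empty).
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    extent = (np.array(dmap.dims) - 1) * dmap.spacing
    out_dims = np.floor(extent / target_spacing + 1e-9).astype(int) + 1
    # fractional input indices of output voxel centers, separable per axis
    axes = [
        (np.arange(out_dims[a]) * target_spacing) / dmap.spacing[a]
        for a in range(3)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(
        dmap.grid.astype(np.float64),
        np.stack([c.ravel() for c in coords]),
        order=1,
        mode="constant",
        cval=0.0,
    ).reshape(tuple(out_dims))
    return DensityMap(
        grid=out.astype(dmap.grid.dtype),  # computed in float64, dtype preserved
        origin=dmap.origin.copy(),
        spacing=np.full(3, float(target_spacing)),
    )
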