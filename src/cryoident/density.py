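"""Cryo-EM density maps: MRC/CCP4 I/O, resampling and interpolation.

Maps are held as a canonical X,Y,Z-ordered float32 grid with per-axis voxel
spacing and an origin in Å. On read, permuted axis orders (MAPC/MAPR/MAPS)
are normalized, and the origin is taken from the ORIGIN header record when
nonzero, else from NXSTART/NYSTART/NZSTART times the voxel size — the two
conventions coexist in deposited maps, and ORIGIN takes precedence.

Resampling to a common voxel size (1 Å in the modelling pipeline) defaults
to real-space trilinear interpolation; Fourier cropping/padding is available
as an alternative for band-limited maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import gemmi
from scipy import ndimage

__all__ = ["DensityMap", "MapFormatError", "read_mrc", "write_mrc",
           "resample", "interpolate"]


class MapFormatError(ValueError):
    """Raised for malformed or unsupported MRC/CCP4 files."""


_SUPPORTED_MODES = {0, 1, 2, 6}


@dataclass
class DensityMap:
    """A 3-D density grid. ``grid[i, j, k]`` sits at world coordinate
    ``origin + (i, j, k) * voxel_size`` (Å)."""

    grid: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-D")
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size components must be positive")

    @property
    def shape(self) -> tuple:
        return self.grid.shape

    def world_coord(self, index) -> np.ndarray:
        """World coordinate (Å) of a (possibly fractional) grid index."""
        return self.origin + np.asarray(index, dtype=float) * self.voxel_size

    def index_coord(self, world) -> np.ndarray:
        """Fractional grid index of a world coordinate (Å)."""
        return (np.asarray(world, dtype=float) - self.origin) / self.voxel_size

    @property
    def extent(self) -> np.ndarray:
        """Physical span (Å) covered by the grid samples, per axis."""
        return (np.array(self.grid.shape) - 1) * self.voxel_size


def read_mrc(path) -> DensityMap:
    """Read an MRC/CCP4 volume, normalizing axis order to X,Y,Z."""
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"{path}: {exc}") from exc
    mode = m.header_i32(4)
    if mode not in _SUPPORTED_MODES:
        raise MapFormatError(
            f"{path}: unsupported MRC data MODE {mode} (header word 4); "
            f"supported modes: {sorted(_SUPPORTED_MODES)}"
        )
    # header words in file (column, row, section) order, before reordering
    mapc, mapr, maps = (m.header_i32(w) for w in (17, 18, 19))
    if sorted((mapc, mapr, maps)) != [1, 2, 3]:
        raise MapFormatError(
            f"{path}: invalid MAPC/MAPR/MAPS axis permutation "
            f"{(mapc, mapr, maps)} (header words 17-19)"
        )
    nstart_crs = [m.header_i32(w) for w in (5, 6, 7)]
    nstart = [0, 0, 0]
    for pos, axis in enumerate((mapc, mapr, maps)):
        nstart[axis - 1] = nstart_crs[pos]
    origin_rec = np.array([m.header_float(w) for w in (50, 51, 52)])
    sampling = np.array([m.header_i32(w) for w in (8, 9, 10)], dtype=float)
    cell = np.array([m.header_float(w) for w in (11, 12, 13)], dtype=float)

    m.setup(0.0, gemmi.MapSetup.ReorderOnly)
    grid = np.array(m.grid, copy=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        voxel = cell / sampling
    if np.any(~np.isfinite(voxel)) or np.any(voxel <= 0):
        raise MapFormatError(
            f"{path}: non-positive voxel size {tuple(voxel)} "
            "(cell words 11-13 / sampling words 8-10)"
        )
    if np.any(origin_rec != 0.0):
        origin = origin_rec
    else:
        origin = np.array(nstart, dtype=float) * voxel
    return DensityMap(grid, voxel, origin)


def write_mrc(dmap: DensityMap, path) -> None:
    """Write a map as MRC mode 2 (float32), canonical axis order."""
    g = gemmi.FloatGrid(*dmap.grid.shape)
    nx, ny, nz = dmap.grid.shape
    g.set_unit_cell(gemmi.UnitCell(
        nx * dmap.voxel_size[0], ny * dmap.voxel_size[1],
        nz * dmap.voxel_size[2], 90.0, 90.0, 90.0))
    np.array(g, copy=False)[...] = dmap.grid
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for w, v in zip((50, 51, 52), dmap.origin):
        m.set_header_float(w, float(v))
    m.write_ccp4_map(str(path))


def interpolate(dmap: DensityMap, points, fill_value: float = 0.0
                ) -> np.ndarray:
    """Trilinear interpolation of map values at world coordinates (Å).

    Points outside the grid return ``fill_value`` (default 0): shells
    sampled near the box edge degrade gracefully instead of raising.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    idx = (pts - dmap.origin) / dmap.voxel_size
    return ndimage.map_coordinates(
        dmap.grid.astype(float), idx.T, order=1,
        mode="constant", cval=fill_value)


def resample(dmap: DensityMap, target_voxel: float,
             method: str = "trilinear") -> DensityMap:
    """Resample a map to an isotropic target voxel size (Å).

    ``method='trilinear'`` (default) interpolates in real space;
    ``method='fourier'`` resamples by Fourier cropping/padding, which is
    exact for band-limited signals but may overshoot the input range.
    Physical extent and origin are preserved to within one voxel.
    """
    if target_voxel <= 0:
        raise ValueError("target_voxel must be positive")
    if target_voxel < 0.1:
        raise ValueError("target_voxel below 0.1 Å is not supported")
    if np.any(target_voxel > dmap.extent):
        raise ValueError(
            f"target_voxel {target_voxel} Å exceeds the map extent "
            f"{tuple(dmap.extent)} Å")
    if np.all(dmap.voxel_size == target_voxel):
        return DensityMap(dmap.grid.copy(), dmap.voxel_size.copy(),
                          dmap.origin.copy())

    new_shape = tuple(
        int(np.floor(dmap.extent[a] / target_voxel + 1e-9)) + 1
        for a in range(3))
    if method == "trilinear":
        axes = np.ix_(*[np.arange(n) * target_voxel / dmap.voxel_size[a]
                        for a, n in enumerate(new_shape)])
        coords = np.broadcast_arrays(*axes)
        grid = ndimage.map_coordinates(
            dmap.grid.astype(float), np.stack(coords), order=1,
            mode="nearest")
    elif method == "fourier":
        from scipy.signal import resample as fft_resample
        grid = dmap.grid.astype(float)
        for a, n in enumerate(new_shape):
            grid = fft_resample(grid, n, axis=a)
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    return DensityMap(grid.astype(np.float32),
                      np.full(3, float(target_voxel)),
                      dmap.origin.copy())
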