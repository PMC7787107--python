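"""Density-map data model, MRC-2014 I/O and grid algebra.

The :class:`DensityMap` is the universal currency of the toolkit: a 3D voxel
grid of intensities together with the geometry (origin, voxel spacing) that
places each voxel centre in world coordinates (ångström).  Conventions used
throughout the package:

* voxel indices are 0-based and the grid is stored in ``(x, y, z)`` axis
  order, i.e. ``grid[i, j, k]`` sits at ``origin + (i, j, k) * voxel_size``;
* world coordinates refer to voxel *centres*;
* all lengths are in Å.

MRC-2014 files (modes 0, 1, 2 and 6) are read natively, honouring the
machine stamp and the ``MAPC/MAPR/MAPS`` axis permutation; files are written
in mode 2 with little-endian word order.  gzip-compressed files are handled
transparently in both directions, detected by magic bytes rather than by
file extension.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DensityMap",
    "BinaryEnvelope",
    "MapFormatError",
    "read_mrc",
    "write_mrc",
    "resample_onto",
    "binarize",
    "surface_points",
    "gradient_normals",
    "radial_amplitudes",
]


class MapFormatError(ValueError):
    """Raised when a file is not a map format this package understands."""


GZIP_MAGIC = b"\x1f\x8b"

# MRC mode -> numpy dtype (without byte order)
_MRC_DTYPES = {0: "i1", 1: "i2", 2: "f4", 6: "u2"}


@dataclass
class DensityMap:
    """A 3D scalar density field on a regular grid.

    Parameters
    ----------
    grid:
        3D array of intensities, indexed ``[ix, iy, iz]``.
    voxel_size:
        spacing along (x, y, z) in Å/voxel; all components positive.
    origin:
        world position (Å) of the centre of voxel (0, 0, 0).
    axis_order:
        permutation recording the file's (MAPC, MAPR, MAPS) fields at read
        time; the in-memory grid is always (x, y, z).
    label:
        free-text label carried through I/O.
    """

    grid: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: tuple[int, int, int] = (1, 2, 3)
    label: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValueError("grid must be a 3D array with each dim >= 1")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size components must be > 0")
        self.origin = tuple(float(v) for v in self.origin)

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        vx, vy, vz = self.voxel_size
        return vx * vy * vz

    def same_grid_as(self, other: "DensityMap", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (Å) of voxel indices (..., 3)."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.voxel_size)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world points (..., 3)."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.voxel_size)

    def voxel_centres(self) -> np.ndarray:
        """All voxel-centre world coordinates, shape ``(*shape, 3)``."""
        nx, ny, nz = self.shape
        ix, iy, iz = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        return self.index_to_world(np.stack([ix, iy, iz], axis=-1))

    def centroid(self) -> np.ndarray:
        """Density-weighted centre of mass (negative density clamped to 0)."""
        w = np.clip(self.grid.astype(float), 0.0, None)
        total = w.sum()
        if total <= 0:
            raise ValueError("map has no positive density")
        nx, ny, nz = self.shape
        com = np.array(
            [
                (w.sum(axis=(1, 2)) * np.arange(nx)).sum(),
                (w.sum(axis=(0, 2)) * np.arange(ny)).sum(),
                (w.sum(axis=(0, 1)) * np.arange(nz)).sum(),
            ]
        ) / total
        return self.index_to_world(com)

    def copy(self) -> "DensityMap":
        return DensityMap(
            self.grid.copy(), self.voxel_size, self.origin, self.axis_order, self.label
        )

    def with_grid(self, grid: np.ndarray) -> "DensityMap":
        """New map sharing this map's geometry but holding ``grid``."""
        return DensityMap(grid, self.voxel_size, self.origin, self.axis_order, self.label)


@dataclass
class BinaryEnvelope:
    """Boolean support of a map above a contour threshold."""

    mask: np.ndarray
    threshold: float
    parent: DensityMap | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.parent is not None and self.mask.shape != self.parent.shape:
            raise ValueError("mask shape must equal parent grid shape")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# MRC-2014 I/O
# ---------------------------------------------------------------------------

def _open_maybe_gzip(path) -> io.BufferedReader:
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == GZIP_MAGIC:
        data = gzip.open(fh).read()
        fh.close()
        return io.BytesIO(data)  # type: ignore[return-value]
    return fh


def _parse_header(raw: bytes, order: str):
    ints = np.frombuffer(raw, dtype=order + "i4", count=56)
    floats = np.frombuffer(raw, dtype=order + "f4", count=56)
    return ints, floats


def read_mrc(path) -> DensityMap:
    """Read an MRC-2014 density map, optionally gzip-compressed.

    The machine stamp decides byte order; the MAPC/MAPR/MAPS permutation is
    applied so the returned grid is in (x, y, z) order.  The ORIGIN record
    wins; when it is all-zero and NSTART is not, the origin falls back to
    ``nstart * voxel_size``.
    """
    fh = _open_maybe_gzip(path)
    try:
        raw = fh.read(1024)
        if len(raw) < 1024:
            raise OSError(f"{path}: truncated MRC header ({len(raw)} bytes)")
        if raw[208:211] != b"MAP":
            raise MapFormatError(f"{path}: missing 'MAP ' magic; not MRC-2014")

        # byte 212 is the first machine-stamp byte: 0x44 little, 0x11 big
        order = ">" if raw[212] == 0x11 else "<"
        ints, floats = _parse_header(raw, order)
        mode = int(ints[3])
        if mode not in _MRC_DTYPES:
            # retry with the other byte order before giving up
            order = "<" if order == ">" else ">"
            ints, floats = _parse_header(raw, order)
            mode = int(ints[3])
        if mode not in _MRC_DTYPES:
            raise MapFormatError(f"{path}: unsupported MRC mode {mode}")

        ncol, nrow, nsec = (int(v) for v in ints[:3])
        nstart_file = tuple(int(v) for v in ints[4:7])
        mxyz = tuple(int(v) for v in ints[7:10])
        cella = tuple(float(v) for v in floats[10:13])
        mapc, mapr, maps_ = (int(v) for v in ints[16:19])
        if sorted((mapc, mapr, maps_)) != [1, 2, 3]:
            raise MapFormatError(f"{path}: invalid axis mapping {(mapc, mapr, maps_)}")
        nsymbt = int(ints[23])
        origin_rec = tuple(float(v) for v in floats[49:52])
        nlabl = int(ints[55])
        label = ""
        if 0 < nlabl <= 10:
            label = raw[224:224 + 80].decode("ascii", "replace").rstrip("\x00 ")

        dtype = np.dtype(order + _MRC_DTYPES[mode])
        n_vox = ncol * nrow * nsec
        fh.seek(1024 + nsymbt)
        data = fh.read(n_vox * dtype.itemsize)
        if len(data) < n_vox * dtype.itemsize:
            raise OSError(f"{path}: truncated MRC data block")
        arr = np.frombuffer(data, dtype=dtype).reshape(nsec, nrow, ncol)

        # file data axes are (sec, row, col) -> world axes (maps, mapr, mapc)
        world_of_data = (maps_ - 1, mapr - 1, mapc - 1)
        perm = [world_of_data.index(w) for w in (0, 1, 2)]
        grid = np.ascontiguousarray(np.transpose(arr, axes=perm))
        if order == ">":
            grid = grid.astype(grid.dtype.newbyteorder("<"))

        voxel = tuple(
            cella[w] / mxyz[w] if mxyz[w] else 1.0 for w in range(3)
        )
        # nstart is per file axis (col,row,sec); permute into world order
        nstart_world = [0, 0, 0]
        for file_axis, world_axis in enumerate((mapc - 1, mapr - 1, maps_ - 1)):
            nstart_world[world_axis] = nstart_file[file_axis]
        if any(origin_rec):
            origin = origin_rec
        else:
            origin = tuple(nstart_world[w] * voxel[w] for w in range(3))

        return DensityMap(
            grid,
            voxel_size=voxel,
            origin=origin,
            axis_order=(mapc, mapr, maps_),
            label=label,
        )
    finally:
        fh.close()


def write_mrc(density_map: DensityMap, path, compress: bool = False) -> None:
    """Write ``density_map`` as an MRC-2014 mode-2 (float32) file.

    With ``compress=True`` the output is gzip-wrapped so that
    :func:`read_mrc` can read it back transparently.
    """
    grid = np.asarray(density_map.grid, dtype="<f4")
    nx, ny, nz = grid.shape
    header_i = np.zeros(56, dtype="<i4")
    header_f = header_i.view("<f4")

    header_i[0:3] = (nx, ny, nz)  # written with mapc,mapr,maps = 1,2,3
    header_i[3] = 2
    header_i[7:10] = (nx, ny, nz)
    header_f[10:13] = np.asarray(density_map.voxel_size) * (nx, ny, nz)
    header_f[13:16] = (90.0, 90.0, 90.0)
    header_i[16:19] = (1, 2, 3)
    header_f[19] = float(grid.min())
    header_f[20] = float(grid.max())
    header_f[21] = float(grid.mean())
    header_i[22] = 1  # ISPG: 3D volume
    header_f[49:52] = density_map.origin
    header_f[54] = float(grid.std())
    header_i[55] = 1

    raw = bytearray(header_i.tobytes())
    raw[208:212] = b"MAP "
    raw[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    label = (density_map.label or "emfitkit")[:80].ljust(80).encode("ascii", "replace")
    raw += label + b" " * (800 - 80)

    # data stored (sec,row,col) = (z,y,x) under the identity axis mapping
    payload = bytes(raw) + np.ascontiguousarray(grid.transpose(2, 1, 0)).tobytes()
    opener = gzip.open if compress else open
    with opener(path, "wb") as fh:
        fh.write(payload)


# ---------------------------------------------------------------------------
# Grid algebra
# ---------------------------------------------------------------------------

def resample_onto(density_map: DensityMap, reference: DensityMap) -> DensityMap:
    """Trilinearly interpolate ``density_map`` onto ``reference``'s grid.

    Voxels of the reference grid falling outside the source map's support
    are set to zero.  Resampling a map onto its own grid returns the values
    unchanged.
    """
    if density_map.same_grid_as(reference):
        return reference.with_grid(np.array(density_map.grid, dtype=float))
    coords = density_map.world_to_index(reference.voxel_centres())
    out = ndimage.map_coordinates(
        density_map.grid.astype(float),
        [coords[..., 0], coords[..., 1], coords[..., 2]],
        order=1,
        mode="constant",
        cval=0.0,
    )
    return reference.with_grid(out)


def binarize(density_map: DensityMap, threshold: float) -> BinaryEnvelope:
    """Envelope of voxels strictly above ``threshold``."""
    return BinaryEnvelope(
        density_map.grid > threshold, float(threshold), parent=density_map
    )


_SIX_CONN = ndimage.generate_binary_structure(3, 1)


def surface_points(envelope: BinaryEnvelope) -> np.ndarray:
    """World coordinates (Å) of the envelope's surface voxels.

    A surface voxel is a true voxel with at least one six-connected
    neighbour outside the mask; voxels on the grid boundary count as
    surface.  Returns an ``(n, 3)`` array (empty for an empty mask).
    """
    mask = envelope.mask
    if not mask.any():
        return np.empty((0, 3))
    interior = ndimage.binary_erosion(mask, structure=_SIX_CONN, border_value=0)
    surf = mask & ~interior
    idx = np.argwhere(surf)
    if envelope.parent is None:
        return idx.astype(float)
    return envelope.parent.index_to_world(idx)


def _sobel_gradient(grid: np.ndarray, voxel_size) -> np.ndarray:
    """Per-voxel intensity gradient from 3D Sobel filters, shape (*grid, 3)."""
    g = grid.astype(float)
    comps = []
    for axis in range(3):
        # Sobel gain: central difference over 2 voxels x smoothing weight 16
        d = ndimage.sobel(g, axis=axis, mode="nearest") / (32.0 * voxel_size[axis])
        comps.append(d)
    return np.stack(comps, axis=-1)


def gradient_normals(
    density_map: DensityMap, voxel_indices: np.ndarray, eps: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Outward unit surface normals at the given voxel indices.

    The outward normal is ``-grad(rho)/|grad(rho)|`` (density decreases
    towards the outside).  Returns ``(normals, valid)`` where ``valid``
    flags points with non-vanishing gradient; invalid rows are zero and
    are meant to be excluded downstream.
    """
    idx = np.atleast_2d(np.asarray(voxel_indices, dtype=int))
    grad = _sobel_gradient(density_map.grid, density_map.voxel_size)
    vecs = -grad[idx[:, 0], idx[:, 1], idx[:, 2]]
    norms = np.linalg.norm(vecs, axis=1)
    valid = norms > eps
    out = np.zeros_like(vecs)
    out[valid] = vecs[valid] / norms[valid, None]
    return out, valid


def _frequency_radii(shape, voxel_size) -> np.ndarray:
    freqs = [np.fft.fftfreq(n, d=v) for n, v in zip(shape, voxel_size)]
    fx, fy, fz = np.meshgrid(*freqs, indexing="ij")
    return np.sqrt(fx**2 + fy**2 + fz**2)


def _shell_indices(shape, voxel_size, n_shells: int) -> tuple[np.ndarray, float]:
    """Assign each Fourier voxel to one of ``n_shells`` uniform shells.

    Shells are uniform in spatial frequency from 0 to the Nyquist frequency
    of the finest axis; corner frequencies beyond Nyquist fall into the last
    shell.  Returns ``(shell_index_grid, shell_width)``.
    """
    radii = _frequency_radii(shape, voxel_size)
    nyquist = 0.5 / min(voxel_size)
    width = nyquist / n_shells
    idx = np.minimum((radii / width).astype(int), n_shells - 1)
    return idx, width


def radial_amplitudes(density_map: DensityMap, n_shells: int) -> np.ndarray:
    """Mean Fourier amplitude in concentric spatial-frequency shells.

    Shell edges are uniform from zero frequency to Nyquist; the DC term
    lands in shell 0.  Linear in the input map.
    """
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    amps = np.abs(np.fft.fftn(density_map.grid.astype(float)))
    shells, _ = _shell_indices(density_map.shape, density_map.voxel_size, n_shells)
    sums = np.bincount(shells.ravel(), weights=amps.ravel(), minlength=n_shells)
    counts = np.bincount(shells.ravel(), minlength=n_shells)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return means
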