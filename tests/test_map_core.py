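"""Density-map I/O and grid algebra."""

import gzip
import struct

import numpy as np
import pytest

from emfitkit import (
    BinaryEnvelope,
    DensityMap,
    MapFormatError,
    binarize,
    gradient_normals,
    radial_amplitudes,
    read_mrc,
    resample_onto,
    surface_points,
    write_mrc,
)


def _independent_mrc(path, grid_xyz, voxel, origin):
    """Reference MRC-2014 writer built directly from the format definition.

    Deliberately independent of the package's writer: header assembled
    field by field with struct.pack, data written section-by-section.
    """
    nx, ny, nz = grid_xyz.shape
    words = [nx, ny, nz, 2, 0, 0, 0, nx, ny, nz]
    header = struct.pack("<10i", *words)
    header += struct.pack("<6f", nx * voxel[0], ny * voxel[1], nz * voxel[2],
                          90.0, 90.0, 90.0)
    header += struct.pack("<3i", 1, 2, 3)
    header += struct.pack("<3f", float(grid_xyz.min()), float(grid_xyz.max()),
                          float(grid_xyz.mean()))
    header += struct.pack("<2i", 1, 0)
    header += b"\x00" * (4 * 25)  # extra space, words 24..48
    header += struct.pack("<3f", *origin)
    header += b"MAP " + b"\x44\x44\x00\x00"
    header += struct.pack("<f", float(grid_xyz.std()))
    header += struct.pack("<i", 0)
    header += b"\x00" * 800
    assert len(header) == 1024
    data = np.ascontiguousarray(
        grid_xyz.astype("<f4").transpose(2, 1, 0)
    ).tobytes()
    with open(path, "wb") as fh:
        fh.write(header + data)


class TestMRCIO:
    def test_roundtrip_identity(self, tmp_path, rng):
        m = DensityMap(rng.random((6, 5, 4)).astype(np.float32),
                       voxel_size=(1.0, 1.2, 1.4), origin=(3.0, -2.0, 0.5))
        path = tmp_path / "m.mrc"
        write_mrc(m, path)
        r = read_mrc(path)
        assert np.array_equal(r.grid, m.grid)
        assert r.voxel_size == pytest.approx(m.voxel_size)
        assert r.origin == pytest.approx(m.origin)

    def test_gzip_transparency(self, tmp_path, rng):
        m = DensityMap(rng.random((4, 4, 4)).astype(np.float32))
        plain, packed = tmp_path / "m.mrc", tmp_path / "m.mrc.gz"
        write_mrc(m, plain)
        write_mrc(m, packed, compress=True)
        with open(packed, "rb") as fh:
            assert fh.read(2) == b"\x1f\x8b"
        a, b = read_mrc(plain), read_mrc(packed)
        assert np.array_equal(a.grid, b.grid)
        # gzip-wrapping an existing file is detected by magic, not name
        disguised = tmp_path / "sneaky.mrc"
        with open(plain, "rb") as fh:
            disguised.write_bytes(gzip.compress(fh.read()))
        assert np.array_equal(read_mrc(disguised).grid, m.grid)

    def test_reads_independent_writer_fields(self, tmp_path):
        grid = np.arange(4 * 3 * 2, dtype=np.float32).reshape(4, 3, 2)
        path = tmp_path / "crafted.mrc"
        _independent_mrc(path, grid, (1.5, 1.5, 1.5), (10.0, 0.0, -5.0))
        m = read_mrc(path)
        assert m.shape == (4, 3, 2)
        assert np.array_equal(m.grid, grid)
        assert m.voxel_size == pytest.approx((1.5, 1.5, 1.5))
        assert m.origin == pytest.approx((10.0, 0.0, -5.0))

    def test_gemmi_reads_our_output(self, tmp_path, rng):
        gemmi = pytest.importorskip("gemmi")
        m = DensityMap(rng.random((5, 4, 3)).astype(np.float32),
                       voxel_size=(2.0, 2.0, 2.0))
        path = tmp_path / "m.mrc"
        write_mrc(m, path)
        g = gemmi.read_ccp4_map(str(path))
        arr = np.array(g.grid, copy=False)
        assert arr.shape == (5, 4, 3)
        assert np.allclose(arr, m.grid, atol=1e-6)

    def test_nstart_origin_fallback(self, tmp_path):
        grid = np.ones((3, 3, 3), dtype=np.float32)
        path = tmp_path / "nstart.mrc"
        _independent_mrc(path, grid, (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))
        raw = bytearray(path.read_bytes())
        raw[16:28] = struct.pack("<3i", 5, -3, 1)  # nstart (cols, rows, secs)
        path.write_bytes(bytes(raw))
        m = read_mrc(path)
        assert m.origin == pytest.approx((10.0, -6.0, 2.0))

    def test_axis_permutation_applied(self, tmp_path):
        grid = np.arange(24, dtype=np.float32).reshape(4, 3, 2)
        path = tmp_path / "perm.mrc"
        _independent_mrc(path, grid, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        raw = bytearray(path.read_bytes())
        # declare file axes (col,row,sec) as (z,y,x) and store accordingly
        raw[64:76] = struct.pack("<3i", 3, 2, 1)
        raw[0:12] = struct.pack("<3i", 2, 3, 4)  # ncol,nrow,nsec
        data = np.ascontiguousarray(grid.transpose(0, 1, 2)).tobytes()
        path.write_bytes(bytes(raw[:1024]) + data)
        m = read_mrc(path)
        assert m.shape == (4, 3, 2)
        assert np.array_equal(m.grid, grid)

    @pytest.mark.parametrize("corruption", ["magic", "mode", "truncated"])
    def test_rejects_bad_files(self, tmp_path, rng, corruption):
        m = DensityMap(rng.random((4, 4, 4)).astype(np.float32))
        path = tmp_path / "bad.mrc"
        write_mrc(m, path)
        raw = bytearray(path.read_bytes())
        if corruption == "magic":
            raw[208:212] = b"XXXX"
            path.write_bytes(bytes(raw))
            with pytest.raises(MapFormatError):
                read_mrc(path)
        elif corruption == "mode":
            raw[12:16] = struct.pack("<i", 99)
            path.write_bytes(bytes(raw))
            with pytest.raises(MapFormatError):
                read_mrc(path)
        else:
            path.write_bytes(bytes(raw[: 1024 + 10]))
            with pytest.raises(OSError):
                read_mrc(path)


class TestGridAlgebra:
    def test_resample_identity_and_constant(self, blob_map):
        same = resample_onto(blob_map, blob_map)
        assert np.allclose(same.grid, blob_map.grid)
        const = blob_map.with_grid(np.full(blob_map.shape, 2.5))
        target = DensityMap(np.zeros((10, 10, 10)), voxel_size=(1.7, 1.7, 1.7),
                            origin=(3.0, 3.0, 3.0))
        out = resample_onto(const, target)
        # interior of the overlap keeps the constant to machine precision
        inside = out.grid[1:-1, 1:-1, 1:-1]
        assert np.allclose(inside[inside > 0], 2.5)

    def test_resample_one_voxel_shift(self):
        grid = np.zeros((7, 7, 7))
        grid[3, 3, 3] = 1.0
        m = DensityMap(grid)
        shifted = DensityMap(grid, origin=(1.0, 0.0, 0.0))  # same data, moved +x
        out = resample_onto(shifted, m)
        assert out.grid[4, 3, 3] == pytest.approx(1.0)
        assert out.grid[3, 3, 3] == pytest.approx(0.0)

    def test_binarize_counts(self):
        m = DensityMap(np.arange(8.0).reshape(2, 2, 2))
        assert binarize(m, -1.0).n_voxels == 8
        assert binarize(m, 7.0).n_voxels == 0  # strict >
        assert binarize(m, 3.5).n_voxels == 4

    def test_surface_points_enumeration(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:4, 1:4, 1:4] = True  # solid 3-cube: all but centre are surface
        m = DensityMap(np.zeros((5, 5, 5)))
        assert len(surface_points(BinaryEnvelope(mask, 0.5, parent=m))) == 26
        single = np.zeros((5, 5, 5), dtype=bool)
        single[2, 2, 2] = True
        assert len(surface_points(BinaryEnvelope(single, 0, parent=m))) == 1
        empty = np.zeros((5, 5, 5), dtype=bool)
        assert len(surface_points(BinaryEnvelope(empty, 0, parent=m))) == 0

    def test_surface_is_subset_of_mask(self, blob_map):
        env = binarize(blob_map, float(blob_map.grid.mean()))
        pts = surface_points(env)
        idx = np.round(blob_map.world_to_index(pts)).astype(int)
        assert env.mask[idx[:, 0], idx[:, 1], idx[:, 2]].all()

    def test_gradient_normals_ramp_and_flat(self):
        x = np.arange(8.0)
        grid = np.broadcast_to(x[:, None, None], (8, 8, 8)).copy()
        m = DensityMap(grid)
        idx = [[4, 4, 4], [2, 5, 3]]
        normals, valid = gradient_normals(m, idx)
        assert valid.all()
        assert np.allclose(normals, [[-1, 0, 0], [-1, 0, 0]], atol=1e-12)
        flat = DensityMap(np.ones((6, 6, 6)))
        _, valid = gradient_normals(flat, [[3, 3, 3]])
        assert not valid.any()

    def test_gradient_normals_radial_blob(self):
        n = 15
        ax = np.arange(n) - 7.0
        r2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
        m = DensityMap(np.exp(-r2 / 18.0))
        shell = [[11, 7, 7], [7, 11, 7], [7, 7, 11], [4, 7, 7], [9, 9, 7]]
        normals, valid = gradient_normals(m, shell)
        assert valid.all()
        for (i, j, k), nvec in zip(shell, normals):
            radial = np.array([i - 7.0, j - 7.0, k - 7.0])
            radial /= np.linalg.norm(radial)
            assert float(nvec @ radial) > 0.99

    def test_radial_amplitudes_constant_and_linear(self, blob_map):
        const = DensityMap(np.full((8, 8, 8), 3.0))
        shells = radial_amplitudes(const, 4)
        assert shells[0] > 0
        assert np.allclose(shells[1:], 0.0, atol=1e-9)
        a = radial_amplitudes(blob_map, 10)
        b = radial_amplitudes(blob_map.with_grid(2.5 * blob_map.grid), 10)
        assert np.allclose(b, 2.5 * a)

    def test_radial_amplitudes_white_noise_flat(self):
        rng = np.random.default_rng(7)
        reps = [
            radial_amplitudes(DensityMap(rng.normal(size=(16, 16, 16))), 6)[1:]
            for _ in range(8)
        ]
        mean = np.mean(reps, axis=0)
        # non-DC shells agree within a few standard errors of each other
        assert mean.max() / mean.min() < 1.3
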