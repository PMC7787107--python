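"""Synthetic test substrates: blob maps, toy helices, known-transform pairs.

Everything every test and example in the package consumes is generated
here, deterministically from an integer seed — no downloaded maps or
structures are ever required.  The fixtures are deliberately small
(tens of voxels per edge, tens of residues) but geometrically honest:
blob maps are sums of anisotropic-free 3D Gaussians, helices follow ideal
alpha-helical parameters (1.5 Å rise, 100 deg twist per residue), and
transform pairs carry their ground-truth rigid transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import _quaternion_rotation, transform_map_onto
from .map_core import DensityMap
from .model_core import Atom, AtomicModel, RigidTransform

__all__ = [
    "FixtureSpec",
    "make_blob_map",
    "make_helix_model",
    "make_two_chain_model",
    "make_transform_pair",
    "make_ligand_pair",
    "displace_residue",
]


@dataclass
class FixtureSpec:
    kind: str = "blob_map"
    size: tuple[int, int, int] = (24, 24, 24)
    voxel_size: float = 1.0
    seed: int = 0
    n_blobs: int | None = None
    n_residues: int = 20
    rotation_deg: float = 0.0
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.size) < 4:
            raise ValueError("size components must be >= 4")


def _blob_grid(shape, voxel_size: float, centres: np.ndarray, sigmas: np.ndarray):
    axes = [np.arange(shape[d]) * voxel_size for d in range(3)]
    grid = np.zeros(tuple(shape), dtype=float)
    for c, s in zip(np.atleast_2d(centres), np.atleast_1d(sigmas)):
        dx2 = (axes[0] - c[0])[:, None, None] ** 2
        dy2 = (axes[1] - c[1])[None, :, None] ** 2
        dz2 = (axes[2] - c[2])[None, None, :] ** 2
        grid += np.exp(-(dx2 + dy2 + dz2) / (2 * s**2))
    return grid


def make_blob_map(
    spec: FixtureSpec, band: tuple[float, float] = (0.25, 0.75)
) -> tuple[DensityMap, np.ndarray]:
    """Sum of 1–5 seeded Gaussian blobs on the requested grid.

    Blob centres fall inside the fractional ``band`` of the grid extent
    and stay well separated relative to their widths, so the declared
    centres are local maxima of the output.  Returns the map and the
    ``(n_blobs, 4)`` table of blob centres (Å) and sigmas.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_blobs if spec.n_blobs is not None else int(rng.integers(1, 6))
    shape = np.asarray(spec.size)
    extent = (shape - 1) * spec.voxel_size
    lo, hi = band[0] * extent, band[1] * extent

    centres: list[np.ndarray] = []
    min_sep = 0.22 * float(extent.min())
    for _ in range(200):
        if len(centres) == n:
            break
        cand = lo + rng.random(3) * (hi - lo)
        if all(np.linalg.norm(cand - c) >= min_sep for c in centres):
            centres.append(cand)
    sigmas = rng.uniform(1.5, 2.5, size=len(centres)) * spec.voxel_size

    grid = _blob_grid(shape, spec.voxel_size, np.array(centres), sigmas)
    blob_table = np.column_stack([np.array(centres), sigmas])
    density = DensityMap(
        grid.astype(np.float32),
        voxel_size=(spec.voxel_size,) * 3,
        origin=(0.0, 0.0, 0.0),
        label=f"blob fixture seed={spec.seed}",
    )
    return density, blob_table


# cylindrical coordinates (radius Å, phase deg, rise Å) of ideal
# alpha-helix backbone atoms relative to the Calpha of the same residue
_HELIX_ATOMS = {
    "N": (1.56, -28.3, -0.85),
    "CA": (2.27, 0.0, 0.0),
    "C": (1.99, 26.2, 0.75),
    "O": (2.00, 23.0, 1.95),
    "CB": (3.26, -6.0, -0.65),
}
_HELIX_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
_RISE = 1.5  # Å per residue
_TWIST = 100.0  # degrees per residue


def make_helix_model(
    spec: FixtureSpec, chain: str = "A", start_res: int = 1
) -> AtomicModel:
    """Ideal poly-alanine alpha-helix along z (N, CA, C, O, CB per residue)."""
    atoms: list[Atom] = []
    for i in range(spec.n_residues):
        phi0 = np.radians(_TWIST * i)
        z0 = _RISE * i
        for name, (radius, dphi, dz) in _HELIX_ATOMS.items():
            phi = phi0 + np.radians(dphi)
            atoms.append(
                Atom(
                    element=_HELIX_ELEMENTS[name],
                    name=name,
                    coords=(
                        radius * np.cos(phi),
                        radius * np.sin(phi),
                        z0 + dz,
                    ),
                    b_factor=20.0,
                    chain=chain,
                    res_seq=start_res + i,
                    res_name="ALA",
                )
            )
    return AtomicModel(atoms, id=f"helix-{spec.n_residues}")


def make_two_chain_model(spec: FixtureSpec, separation: float = 12.0) -> AtomicModel:
    """Two parallel helices (chains A and B) ``separation`` Å apart in x."""
    a = make_helix_model(spec, chain="A")
    b = make_helix_model(spec, chain="B")
    shifted = b.with_coords(b.coords + np.array([separation, 0.0, 0.0]))
    return AtomicModel(a.atoms + shifted.atoms, id="two-chain")


def _seeded_transform(spec: FixtureSpec, centre: np.ndarray) -> RigidTransform:
    rng = np.random.default_rng(spec.seed)
    if spec.rotation_deg == 0.0:
        rot = np.eye(3)
    else:
        axis_u = rng.random(2)
        # uniform axis from two unit-interval coordinates
        z = 2 * axis_u[0] - 1
        phi = 2 * np.pi * axis_u[1]
        r = np.sqrt(max(0.0, 1 - z * z))
        axis = np.array([r * np.cos(phi), r * np.sin(phi), z])
        angle = np.radians(spec.rotation_deg)
        k = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    return RigidTransform(rot, np.asarray(spec.translation, float), centre)


def make_transform_pair(
    spec: FixtureSpec,
) -> tuple[DensityMap, DensityMap, RigidTransform]:
    """A blob map, the same map under a known rigid transform, and the truth.

    Because the blobs are isotropic Gaussians, the transformed map is
    built *analytically* by moving the blob centres, on the same grid —
    no interpolation loss — so a perfect re-fit can reach CCC ~ 1.  Blob
    centres sit in the central band of the grid, leaving room for the
    transform to keep the density on-grid.
    """
    base, blobs = make_blob_map(spec, band=(0.35, 0.65))
    truth = _seeded_transform(spec, base.centroid())
    centres_moved = truth.apply(blobs[:, :3])
    grid2 = _blob_grid(
        np.asarray(spec.size), spec.voxel_size, centres_moved, blobs[:, 3]
    )
    moved = base.with_grid(grid2.astype(np.float32))
    return base, moved, truth


def make_ligand_pair(
    spec: FixtureSpec, blob_sigma: float = 1.5, blob_height: float = 1.0
) -> tuple[DensityMap, DensityMap, np.ndarray, float]:
    """A map and the same map with one extra compact "ligand" blob.

    The blob is ``height * exp(-(r / sigma)^2)`` — ``blob_sigma`` is its
    1/e half-width, the compact-feature convention, so virtually all of
    the blob's mass lies within 2 sigma of its centre.  Returns
    (apo, holo, blob_centre, blob_sigma); the blob sits in a low-density
    corner region of the grid, away from the existing blobs.
    """
    base, blobs = make_blob_map(spec)
    shape = np.asarray(spec.size)
    extent = (shape - 1) * spec.voxel_size
    candidate = 0.18 * extent  # corner region, outside the blob band
    axes = [np.arange(shape[d]) * spec.voxel_size for d in range(3)]
    dx2 = (axes[0] - candidate[0])[:, None, None] ** 2
    dy2 = (axes[1] - candidate[1])[None, :, None] ** 2
    dz2 = (axes[2] - candidate[2])[None, None, :] ** 2
    blob = blob_height * np.exp(-(dx2 + dy2 + dz2) / blob_sigma**2)
    holo = base.with_grid(base.grid.astype(float) + blob)
    return base, holo, candidate, blob_sigma


def displace_residue(
    model: AtomicModel, chain: str, res_seq: int, shift: tuple[float, float, float]
) -> AtomicModel:
    """Rigidly displace one residue's atoms (a local model error fixture)."""
    coords = model.coords
    for i, atom in enumerate(model.atoms):
        if atom.chain == chain and atom.res_seq == res_seq:
            coords[i] += np.asarray(shift)
    return model.with_coords(coords)
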