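"""Amplitude-matched difference maps between two aligned density maps.

Two reconstructions of related specimens (with/without a ligand, two
conformations) rarely share the same resolution-dependent amplitude
falloff, so a naive subtraction leaves global artefacts.  Here the probe
map's rotationally averaged Fourier amplitudes are rescaled shell-by-shell
to match the reference before subtracting; phases are untouched.  Both
difference directions are always produced, plus an optional "dust" filter
that drops small positive connected components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .map_core import (
    DensityMap,
    _shell_indices,
    resample_onto,
)

__all__ = [
    "DiffMapResult",
    "amplitude_scale",
    "difference_map",
    "significant_positive",
]

DEFAULT_N_SHELLS = 30


@dataclass
class DiffMapResult:
    diff_ab: DensityMap  # A - B_scaled, on A's grid
    diff_ba: DensityMap  # B - A_scaled, on A's grid
    shell_scale_factors: np.ndarray  # factors applied when scaling B -> A


def _shell_means(amplitudes: np.ndarray, shells: np.ndarray, n_shells: int):
    sums = np.bincount(shells.ravel(), weights=amplitudes.ravel(), minlength=n_shells)
    counts = np.bincount(shells.ravel(), minlength=n_shells)
    return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)


#: shells whose probe amplitude falls below this fraction of the probe's
#: strongest shell are left unscaled — matching amplitudes is meaningless
#: where the probe carries no signal, and dividing by a near-zero mean
#: would amplify numerical noise into real-space artefacts
AMPLITUDE_FLOOR = 1e-4


def _scale_grid(
    probe: np.ndarray, reference: np.ndarray, voxel_size, n_shells: int
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale probe's Fourier shell amplitudes to the reference's."""
    shells, _ = _shell_indices(probe.shape, voxel_size, n_shells)
    f_probe = np.fft.fftn(probe)
    f_ref = np.fft.fftn(reference)
    m_probe = _shell_means(np.abs(f_probe), shells, n_shells)
    m_ref = _shell_means(np.abs(f_ref), shells, n_shells)
    factors = np.ones(n_shells)
    # attenuation is always safe; amplification only where the probe
    # carries real signal, else near-zero shell means blow up into noise
    usable = (m_probe > 0) & (
        (m_ref <= m_probe) | (m_probe > AMPLITUDE_FLOOR * m_probe.max())
    )
    factors[usable] = m_ref[usable] / m_probe[usable]
    scaled = np.fft.ifftn(f_probe * factors[shells]).real
    return scaled, factors


def amplitude_scale(
    probe: DensityMap, reference: DensityMap, n_shells: int = DEFAULT_N_SHELLS
) -> DensityMap:
    """Scale ``probe`` so its radial amplitude profile matches ``reference``.

    Each spatial-frequency shell of the probe's Fourier transform is
    multiplied by (reference shell mean amplitude)/(probe shell mean
    amplitude); shells where the probe has zero amplitude are left alone.
    Idempotent, and an identity when the maps already agree.
    """
    if not probe.same_grid_as(reference):
        probe = resample_onto(probe, reference)
    scaled, _ = _scale_grid(
        probe.grid.astype(float),
        reference.grid.astype(float),
        reference.voxel_size,
        n_shells,
    )
    return reference.with_grid(scaled)


def significant_positive(diff: DensityMap, n_sigma: float = 3.0) -> np.ndarray:
    """Positive difference density above the ``n_sigma`` significance contour.

    The cutoff is ``n_sigma`` times the RMS of the positive difference
    values — the same convention as contouring a crystallographic Fo−Fc
    map at 3 sigma.  Voxels below the contour are zeroed.
    """
    d = np.clip(diff.grid.astype(float), 0.0, None)
    pos = d[d > 0]
    if pos.size == 0:
        return np.zeros_like(d)
    cutoff = n_sigma * float(np.sqrt((pos**2).mean()))
    return np.where(d > cutoff, d, 0.0)


def _dust_filter(diff: np.ndarray, min_voxels: int) -> np.ndarray:
    """Zero positive connected components smaller than ``min_voxels``.

    Components are six-connected regions above the positive RMS of the
    difference map.
    """
    pos = diff[diff > 0]
    if pos.size == 0 or min_voxels <= 1:
        return diff
    rms = float(np.sqrt((pos**2).mean()))
    blob_mask = diff > rms
    labels, n = ndimage.label(blob_mask, structure=ndimage.generate_binary_structure(3, 1))
    if n == 0:
        return diff
    sizes = np.bincount(labels.ravel())
    small = np.isin(labels, np.nonzero(sizes < min_voxels)[0]) & blob_mask
    out = diff.copy()
    out[small] = 0.0
    return out


def difference_map(
    a: DensityMap,
    b: DensityMap,
    n_shells: int = DEFAULT_N_SHELLS,
    dust_min_voxels: int = 0,
) -> DiffMapResult:
    """Amplitude-matched difference maps in both directions.

    The caller is responsible for aligning the maps first (this is
    normally run after map-to-map fitting).  ``diff_ab`` is A minus the
    B-scaled-to-A map and ``diff_ba`` the converse; both live on A's grid.
    With ``dust_min_voxels > 0`` small positive speckle components are
    removed from both difference maps.
    """
    if not b.same_grid_as(a):
        b = resample_onto(b, a)
    ga = a.grid.astype(float)
    gb = b.grid.astype(float)
    b_scaled, factors = _scale_grid(gb, ga, a.voxel_size, n_shells)
    a_scaled, _ = _scale_grid(ga, gb, a.voxel_size, n_shells)
    diff_ab = ga - b_scaled
    diff_ba = gb - a_scaled
    if dust_min_voxels > 0:
        diff_ab = _dust_filter(diff_ab, dust_min_voxels)
        diff_ba = _dust_filter(diff_ba, dust_min_voxels)
    return DiffMapResult(
        diff_ab=a.with_grid(diff_ab),
        diff_ba=a.with_grid(diff_ba),
        shell_scale_factors=factors,
    )
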