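"""Whole-map fit scores: CCC, MI, LSF, NV, CD and ENV.

Every score works map-vs-map; :func:`score_model` additionally accepts an
atomic model, which is first blurred onto the experimental grid (see
:mod:`emfitkit.simulate`).  When the two maps live on different grids the
second map is silently resampled onto the first map's grid.

Conventions: CCC is Pearson correlation (higher better, in [-1, 1]); MI is
in bits (higher better); LSF is a raw sum of squared differences (lower
better); NV is the mean angle in radians between paired surface normals
(lower better); CD is the mean surface-to-surface nearest-neighbour
distance in Å (lower better); ENV is a penalised envelope-overlap fraction
with maximum 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .map_core import (
    BinaryEnvelope,
    DensityMap,
    binarize,
    gradient_normals,
    resample_onto,
    surface_points,
)
from .model_core import AtomicModel
from .simulate import SimulationParams, simulate_map

__all__ = [
    "GlobalScoreConfig",
    "UndefinedScoreError",
    "ccc",
    "mutual_information",
    "lsf",
    "normal_vector_score",
    "chamfer_distance",
    "envelope_score",
    "score_model",
    "GLOBAL_SCORES",
]


class UndefinedScoreError(ValueError):
    """A score is mathematically undefined for the given inputs."""


@dataclass
class GlobalScoreConfig:
    """Shared knobs for the envelope- and histogram-based scores.

    ``threshold_a``/``threshold_b`` default to mean + 1 SD of the relevant
    map when left as ``None`` — a parameter-free contour choice.
    """

    threshold_a: float | None = None
    threshold_b: float | None = None
    mi_bins: int = 20
    cd_mode: str = "one_sided"  # or "symmetric"
    env_penalty: float = 2.0

    def __post_init__(self) -> None:
        if self.mi_bins < 2:
            raise ValueError("mi_bins must be >= 2")
        if self.env_penalty < 0:
            raise ValueError("env_penalty must be >= 0")
        if self.cd_mode not in ("one_sided", "symmetric"):
            raise ValueError("cd_mode must be 'one_sided' or 'symmetric'")


def _default_threshold(density_map: DensityMap) -> float:
    g = density_map.grid.astype(float)
    return float(g.mean() + g.std())


def _common_grid(a: DensityMap, b: DensityMap) -> tuple[np.ndarray, np.ndarray]:
    if not a.same_grid_as(b):
        b = resample_onto(b, a)
    return a.grid.astype(float), b.grid.astype(float)


def ccc(
    a: DensityMap, b: DensityMap, mask: BinaryEnvelope | None = None
) -> float:
    """Cross-correlation coefficient (Pearson r of voxel intensities)."""
    ga, gb = _common_grid(a, b)
    if mask is not None:
        ga, gb = ga[mask.mask], gb[mask.mask]
    ga, gb = ga.ravel(), gb.ravel()
    da, db = ga - ga.mean(), gb - gb.mean()
    denom = np.sqrt((da**2).sum() * (db**2).sum())
    if denom == 0:
        raise UndefinedScoreError("zero intensity variance; CCC undefined")
    return float((da * db).sum() / denom)


def mutual_information(
    a: DensityMap, b: DensityMap, cfg: GlobalScoreConfig | None = None
) -> float:
    """Mutual information of the joint intensity histogram, in bits.

    Equal-width bins span each map's own [min, max]; a constant map yields
    zero information.
    """
    cfg = cfg or GlobalScoreConfig()
    ga, gb = _common_grid(a, b)
    joint, _, _ = np.histogram2d(
        ga.ravel(), gb.ravel(), bins=cfg.mi_bins
    )
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def entropy_bits(a: DensityMap, bins: int = 20) -> float:
    """Shannon entropy of the voxel-intensity histogram, in bits."""
    hist, _ = np.histogram(a.grid.ravel(), bins=bins)
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def lsf(a: DensityMap, b: DensityMap) -> float:
    """Least-squares fit: sum of squared voxel differences (lower better)."""
    ga, gb = _common_grid(a, b)
    return float(((ga - gb) ** 2).sum())


def normal_vector_score(
    a: DensityMap, b: DensityMap, cfg: GlobalScoreConfig | None = None
) -> float:
    """Mean angle (radians) between surface normals of the two maps.

    The evaluation set is the surface of map ``a``'s envelope at
    ``threshold_a``, restricted to intensities not exceeding
    ``threshold_b`` (unbounded by default).  Normals come from Sobel
    gradients in each map at the same voxels; pairs with a vanishing
    gradient in either map are skipped.
    """
    cfg = cfg or GlobalScoreConfig()
    ta = cfg.threshold_a if cfg.threshold_a is not None else _default_threshold(a)
    ga, gb = _common_grid(a, b)
    b_on_a = a.with_grid(gb)

    env = binarize(a, ta)
    surf = surface_points(env)
    if surf.size == 0:
        raise UndefinedScoreError("empty envelope surface; NV undefined")
    idx = np.asarray(np.round(a.world_to_index(surf)), dtype=int)
    if cfg.threshold_b is not None:
        keep = ga[idx[:, 0], idx[:, 1], idx[:, 2]] <= cfg.threshold_b
        idx = idx[keep]
    if idx.size == 0:
        raise UndefinedScoreError("no usable surface voxels; NV undefined")

    na, va = gradient_normals(a, idx)
    nb, vb = gradient_normals(b_on_a, idx)
    valid = va & vb
    if not valid.any():
        raise UndefinedScoreError("all surface gradients vanish; NV undefined")
    dots = np.clip((na[valid] * nb[valid]).sum(axis=1), -1.0, 1.0)
    return float(np.arccos(dots).mean())


def chamfer_distance(
    a: DensityMap, b: DensityMap, cfg: GlobalScoreConfig | None = None
) -> float:
    """Mean nearest-neighbour distance (Å) between envelope surfaces.

    One-sided by default (surface of ``a`` onto surface of ``b``);
    ``cfg.cd_mode='symmetric'`` averages both directions.
    """
    cfg = cfg or GlobalScoreConfig()
    ta = cfg.threshold_a if cfg.threshold_a is not None else _default_threshold(a)
    tb = cfg.threshold_b if cfg.threshold_b is not None else _default_threshold(b)
    pa = surface_points(binarize(a, ta))
    pb = surface_points(binarize(b, tb))
    if len(pa) == 0 or len(pb) == 0:
        raise UndefinedScoreError("empty envelope surface; CD undefined")
    d_ab = cKDTree(pb).query(pa)[0].mean()
    if cfg.cd_mode == "one_sided":
        return float(d_ab)
    d_ba = cKDTree(pa).query(pb)[0].mean()
    return float((d_ab + d_ba) / 2.0)


def envelope_score(
    a: DensityMap, b: DensityMap, cfg: GlobalScoreConfig | None = None
) -> float:
    """Penalised envelope overlap; 1 when the probe exactly covers the target.

    ``(N_overlap - penalty * N_probe_only) / N_target`` with the target
    envelope from ``a`` at ``threshold_a`` and the probe envelope from
    ``b`` at ``threshold_b``.
    """
    cfg = cfg or GlobalScoreConfig()
    ta = cfg.threshold_a if cfg.threshold_a is not None else _default_threshold(a)
    tb = cfg.threshold_b if cfg.threshold_b is not None else _default_threshold(b)
    ga, gb = _common_grid(a, b)
    target = ga > ta
    probe = gb > tb
    n_target = int(target.sum())
    if n_target == 0:
        raise UndefinedScoreError("empty target envelope; ENV undefined")
    n_overlap = int((target & probe).sum())
    n_probe_only = int((probe & ~target).sum())
    return float((n_overlap - cfg.env_penalty * n_probe_only) / n_target)


GLOBAL_SCORES = {
    "ccc": ccc,
    "mi": mutual_information,
    "lsf": lsf,
    "nv": normal_vector_score,
    "cd": chamfer_distance,
    "env": envelope_score,
}

#: scores where larger values mean better fits
HIGHER_IS_BETTER = {"ccc": True, "mi": True, "lsf": False, "nv": False,
                    "cd": False, "env": True}


def score_model(
    model: AtomicModel,
    density_map: DensityMap,
    score: str,
    params: SimulationParams,
    cfg: GlobalScoreConfig | None = None,
) -> float:
    """Score a model against a map via its simulated density.

    The model is blurred onto the experimental grid, then the named
    map-vs-map score is applied (experimental map first).
    """
    if score not in GLOBAL_SCORES:
        raise ValueError(
            f"unknown score {score!r}; choose from {sorted(GLOBAL_SCORES)}"
        )
    sim = simulate_map(model, params, grid=density_map)
    fn = GLOBAL_SCORES[score]
    if score in ("ccc", "lsf"):
        return fn(density_map, sim)
    return fn(density_map, sim, cfg)
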