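"""Rigid-body fitting of a probe map (or model) into a reference map.

Three optimizers are provided, mirroring the usual global-then-local
workflow:

* :func:`mc_local` — Metropolis Monte Carlo with small Gaussian steps,
  by default maximising CCC (temperature 0 degenerates to greedy ascent);
* :func:`em_local` — deterministic expectation–maximization refinement:
  reference voxels are weighted by the product of reference and (moved)
  probe density, and the transform is re-estimated from the weighted
  point match (weighted centroids for the translation, the proper
  orthogonal polar factor of the weighted cross-covariance for the
  rotation);
* :func:`qmc_global` — a quasi-Monte Carlo scan of the 6D pose space
  using a scrambled low-discrepancy sequence (translations mapped into a
  box, orientations through the uniform-quaternion parameterization), so
  samples cover the space evenly without repeats.

:func:`fit_pipeline` chains the global scan into the local Monte Carlo
search; :func:`fit_model` does the same for an atomic model via its
simulated map.  All stochastic routines take an explicit integer seed and
are bitwise reproducible from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import qmc

from .map_core import DensityMap
from .model_core import AtomicModel, RigidTransform, apply_transform, compose
from .score_global import GLOBAL_SCORES, HIGHER_IS_BETTER, UndefinedScoreError
from .simulate import SimulationParams, simulate_map

__all__ = [
    "MCConfig",
    "QMCConfig",
    "FitTrace",
    "transform_map_onto",
    "mc_local",
    "em_local",
    "qmc_global",
    "fit_pipeline",
    "fit_model",
]

DEFAULT_SEED = 42


@dataclass
class MCConfig:
    n_steps: int = 200
    trans_step: float = 1.0  # Å, Gaussian sigma per axis
    rot_step: float = 2.0  # degrees, Gaussian sigma of the rotation angle
    temperature: float = 0.01  # in objective-score units; 0 = greedy
    seed: int = DEFAULT_SEED
    objective: str = "ccc"

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.trans_step <= 0 or self.rot_step <= 0:
            raise ValueError("step sizes must be > 0")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.objective not in GLOBAL_SCORES:
            raise ValueError(f"unknown objective {self.objective!r}")


@dataclass
class QMCConfig:
    n_samples: int = 256
    trans_bounds: float | np.ndarray = 10.0  # half-width Å or (3, 2) box
    max_rot_deg: float | None = None  # None: search all orientations
    keep_top: int = 10
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_samples < self.keep_top or self.keep_top < 1:
            raise ValueError("need n_samples >= keep_top >= 1")
        if self.max_rot_deg is not None and not 0 < self.max_rot_deg <= 180:
            raise ValueError("max_rot_deg must lie in (0, 180]")

    def bounds_array(self) -> np.ndarray:
        b = self.trans_bounds
        if np.isscalar(b):
            return np.array([[-b, b]] * 3, dtype=float)
        arr = np.asarray(b, dtype=float).reshape(3, 2)
        if np.any(arr[:, 1] < arr[:, 0]):
            raise ValueError("trans_bounds upper < lower")
        return arr


@dataclass
class TraceStep:
    index: int
    trial_score: float
    best_score: float
    transform: RigidTransform


@dataclass
class FitTrace:
    """Per-iteration record of an optimization run."""

    steps: list[TraceStep] = field(default_factory=list)
    final: RigidTransform = field(default_factory=RigidTransform.identity)

    @property
    def best_score(self) -> float:
        return self.steps[-1].best_score if self.steps else float("nan")

    def record(self, trial: float, transform: RigidTransform) -> float:
        best = max(trial, self.steps[-1].best_score) if self.steps else trial
        self.steps.append(TraceStep(len(self.steps), trial, best, transform))
        return best

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="ascii") as fh:
            fh.write("step\ttrial_score\tbest_score\n")
            for s in self.steps:
                fh.write(f"{s.index}\t{s.trial_score:.6f}\t{s.best_score:.6f}\n")


# ---------------------------------------------------------------------------
# Transform evaluation
# ---------------------------------------------------------------------------

def transform_map_onto(
    probe: DensityMap, transform: RigidTransform, reference: DensityMap
) -> DensityMap:
    """Evaluate the rigidly moved probe on the reference grid.

    The moved density is ``rho'(x) = rho(T^-1 x)``, sampled trilinearly;
    zero outside the probe's support.
    """
    inv = transform.inverse()
    pts = inv.apply(reference.voxel_centres().reshape(-1, 3))
    coords = probe.world_to_index(pts).T
    values = ndimage.map_coordinates(
        probe.grid.astype(float), coords, order=1, mode="constant", cval=0.0
    )
    return reference.with_grid(values.reshape(reference.shape))


def _signed_objective(name: str):
    fn = GLOBAL_SCORES[name]
    sign = 1.0 if HIGHER_IS_BETTER[name] else -1.0

    def objective(reference: DensityMap, moved: DensityMap) -> float:
        if name in ("ccc", "lsf"):
            return sign * fn(reference, moved)
        return sign * fn(reference, moved, None)

    return objective


def _score_pose(probe, reference, transform, objective) -> float:
    return objective(reference, transform_map_onto(probe, transform, reference))


def _score_pose_or_neg_inf(probe, reference, transform, objective) -> float:
    """Score a trial pose; poses with no overlap rank below everything.

    Search routines must visit poses that push the probe entirely off the
    reference support; those get -inf (never silently zero, which would
    look like a mediocre-but-valid fit).
    """
    try:
        return _score_pose(probe, reference, transform, objective)
    except UndefinedScoreError:
        return float("-inf")


def _random_rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def _quaternion_rotation(u1: float, u2: float, u3: float) -> np.ndarray:
    """Uniform rotation matrix from three unit-interval coordinates."""
    a, b = np.sqrt(1.0 - u1), np.sqrt(u1)
    t2, t3 = 2.0 * np.pi * u2, 2.0 * np.pi * u3
    w, x, y, z = a * np.sin(t2), a * np.cos(t2), b * np.sin(t3), b * np.cos(t3)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

def mc_local(
    probe: DensityMap,
    reference: DensityMap,
    cfg: MCConfig | None = None,
    initial: RigidTransform | None = None,
) -> FitTrace:
    """Metropolis Monte Carlo local search.

    Each step proposes a small rigid perturbation about the probe's current
    centroid: a rotation about a uniformly random axis with Gaussian-
    distributed angle (sigma ``rot_step`` degrees) and a Gaussian
    translation (sigma ``trans_step`` Å per axis).  Improvements are always
    accepted; deteriorations with probability ``exp(delta/temperature)``.
    The best transform ever visited is returned as ``trace.final``.
    """
    cfg = cfg or MCConfig()
    rng = np.random.default_rng(cfg.seed)
    objective = _signed_objective(cfg.objective)
    centroid = probe.centroid()

    current = initial if initial is not None else RigidTransform.identity()
    current_score = _score_pose(probe, reference, current, objective)
    best, best_score = current, current_score

    trace = FitTrace()
    trace.record(current_score, current)
    for _ in range(cfg.n_steps):
        axis = rng.normal(size=3)
        while np.linalg.norm(axis) < 1e-12:
            axis = rng.normal(size=3)
        angle = np.radians(rng.normal(0.0, cfg.rot_step))
        shift = rng.normal(0.0, cfg.trans_step, size=3)
        pivot = current.apply(centroid)
        perturb = RigidTransform(
            _random_rotation_matrix(axis, angle), shift, centre=pivot
        )
        candidate = compose(perturb, current)
        trial = _score_pose_or_neg_inf(probe, reference, candidate, objective)

        delta = trial - current_score
        if delta >= 0:
            accept = True
        elif cfg.temperature == 0:
            accept = False
        else:
            accept = rng.random() < np.exp(delta / cfg.temperature)
        if accept:
            current, current_score = candidate, trial
            if trial > best_score:
                best, best_score = candidate, trial
        trace.record(trial, candidate)
    trace.final = best
    return trace


def em_local(
    probe: DensityMap,
    reference: DensityMap,
    max_iter: int = 50,
    tol: float = 1e-6,
    translation_only: bool = False,
    initial: RigidTransform | None = None,
) -> FitTrace:
    """Expectation–maximization local refinement (deterministic).

    E-step: weight every reference voxel by the product of its (clamped
    nonnegative) reference density and the moved probe density there, i.e.
    by the local overlap.  M-step: re-estimate the most likely position of
    the probe's centre — the weighted reference centroid replaces the
    probe's own density centroid, and the rotation comes from the proper
    orthogonal (Kabsch) factor of the weighted cross-covariance between
    probe-frame preimages about the probe centroid and reference
    positions about the weighted centroid.  An update is kept only while
    the CCC objective improves, so the reported trace is nondecreasing by
    construction.
    """
    objective = _signed_objective("ccc")
    ref_vals = np.clip(reference.grid.astype(float).ravel(), 0.0, None)
    if ref_vals.sum() <= 0:
        raise UndefinedScoreError("reference map has no positive mass")
    ref_pts = reference.voxel_centres().reshape(-1, 3)
    probe_nn = probe.with_grid(np.clip(probe.grid.astype(float), 0.0, None))
    mu_probe = probe_nn.centroid()  # fixed, in the probe's own frame

    current = initial if initial is not None else RigidTransform.identity()
    score = _score_pose(probe, reference, current, objective)
    trace = FitTrace()
    trace.record(score, current)

    for _ in range(max_iter):
        moved = transform_map_onto(probe_nn, current, reference)
        weights = ref_vals * moved.grid.ravel()
        w_sum = weights.sum()
        if w_sum <= 0:
            raise UndefinedScoreError("degenerate overlap: zero total weight")
        mu_ref = weights @ ref_pts / w_sum
        if translation_only:
            rot = np.eye(3)
        else:
            pre = current.inverse().apply(ref_pts)
            yc = pre - mu_probe
            xc = ref_pts - mu_ref
            h = (yc * weights[:, None]).T @ xc  # probe-frame -> reference
            u, _, vt = np.linalg.svd(h)
            d = np.sign(np.linalg.det(vt.T @ u.T))
            rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
        candidate = RigidTransform(rot, mu_ref - rot @ mu_probe, np.zeros(3))
        trial = _score_pose(probe, reference, candidate, objective)
        if trial <= score + tol:
            if trial > score:
                trace.record(trial, candidate)
                current, score = candidate, trial
            break
        current, score = candidate, trial
        trace.record(trial, candidate)
    trace.final = current
    return trace


def _bounded_rotation(u4: float, u5: float, u6: float, max_rad: float) -> np.ndarray:
    """Uniform rotation with angle <= max_rad from three unit coordinates.

    Axis uniform on the sphere; the angle follows the Haar density
    proportional to sin^2(theta/2), inverted numerically from its CDF
    ``(theta - sin theta) / (max - sin max)``.
    """
    z = 2.0 * u4 - 1.0
    phi = 2.0 * np.pi * u5
    r = np.sqrt(max(0.0, 1.0 - z * z))
    axis = np.array([r * np.cos(phi), r * np.sin(phi), z])
    grid = np.linspace(0.0, max_rad, 256)
    cdf = (grid - np.sin(grid)) / (max_rad - np.sin(max_rad))
    angle = float(np.interp(u6, cdf, grid))
    return _random_rotation_matrix(axis, angle) if angle > 0 else np.eye(3)


def qmc_global(
    probe: DensityMap,
    reference: DensityMap,
    cfg: QMCConfig | None = None,
) -> list[tuple[RigidTransform, float]]:
    """Quasi-Monte Carlo scan of the 6D rigid-pose space.

    Draws ``n_samples`` points from a scrambled Halton sequence: three
    coordinates become a translation inside ``trans_bounds`` and three
    parameterize a uniform random rotation (applied about the probe
    centroid) — over all of SO(3) by default, or restricted to angles up
    to ``max_rot_deg`` when the caller knows the misalignment is bounded.
    Returns the ``keep_top`` best poses by CCC, best first.
    """
    cfg = cfg or QMCConfig()
    bounds = cfg.bounds_array()
    objective = _signed_objective("ccc")
    centroid = probe.centroid()

    sampler = qmc.Halton(d=6, scramble=True, seed=cfg.seed)
    u = sampler.random(cfg.n_samples)
    scored: list[tuple[RigidTransform, float]] = []
    for row in u:
        shift = bounds[:, 0] + row[:3] * (bounds[:, 1] - bounds[:, 0])
        if cfg.max_rot_deg is None:
            rot = _quaternion_rotation(*row[3:6])
        else:
            rot = _bounded_rotation(*row[3:6], np.radians(cfg.max_rot_deg))
        t = RigidTransform(rot, shift, centre=centroid)
        scored.append((t, _score_pose_or_neg_inf(probe, reference, t, objective)))
    scored.sort(key=lambda pair: pair[1], reverse=True)
    return scored[: cfg.keep_top]


def fit_pipeline(
    probe: DensityMap,
    reference: DensityMap,
    qcfg: QMCConfig | None = None,
    mcfg: MCConfig | None = None,
) -> FitTrace:
    """Default global-then-local protocol.

    A quasi-Monte Carlo scan seeds the Metropolis local search with its
    best pose; the returned trace starts with that pose so its best score
    never falls below the global stage's.
    """
    ranked = qmc_global(probe, reference, qcfg)
    best_t, _ = ranked[0]
    return mc_local(probe, reference, mcfg, initial=best_t)


def fit_model(
    model: AtomicModel,
    reference: DensityMap,
    params: SimulationParams,
    qcfg: QMCConfig | None = None,
    mcfg: MCConfig | None = None,
) -> tuple[AtomicModel, FitTrace]:
    """Fit an atomic model into a map via its simulated density.

    The model is blurred on its own padded grid, that map is fitted with
    :func:`fit_pipeline`, and the winning transform is applied to the
    model's coordinates.
    """
    probe = simulate_map(model, params)
    trace = fit_pipeline(probe, reference, qcfg, mcfg)
    return apply_transform(model, trace.final), trace
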