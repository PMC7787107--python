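"""Per-segment and per-residue local quality-of-fit scores.

SCCC restricts the cross-correlation to the density footprint of a model
segment (a domain, subdomain or secondary-structure element).  SMOC walks
the sequence and computes Mander's overlap coefficient (MOC) between the
experimental map and the model's simulated map over a local voxel mask:

* SMOC_f — the mask is the union of residue footprints in a sequence
  window centred on the residue of interest (truncated at chain ends);
* SMOC_d — the mask covers voxels within a fixed distance of the
  residue's own atoms, with no sequence smearing.

MOC presumes nonnegative signal, so negative experimental intensities are
clamped to zero inside the masks.  Scores are emitted as a
sequence-indexed :class:`ScoreProfile` and can be written to / read from a
tab-separated profile file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .map_core import BinaryEnvelope, DensityMap
from .model_core import AtomicModel, select
from .score_global import UndefinedScoreError, ccc
from .simulate import SimulationParams, footprint_mask, simulate_map

__all__ = [
    "SMOCParams",
    "ScoreProfile",
    "moc",
    "sccc",
    "smoc_f",
    "smoc_d",
    "write_profile",
    "read_profile",
]

#: atom-distance radius (Å) used to turn residues into voxel footprints
DEFAULT_FOOTPRINT_RADIUS = 3.0
#: SCCC segment mask keeps voxels above this fraction of the segment's peak
SCCC_FOOTPRINT_FRACTION = 0.1


@dataclass
class SMOCParams:
    """Window/radius settings for the two SMOC variants.

    With ``auto_by_resolution`` the window (SMOC_f) becomes the nearest odd
    integer to ``1.5 * resolution`` and the radius (SMOC_d) becomes
    ``max(3.0, 0.5 * resolution)`` Å — both are explicit, overridable rules.
    """

    window: int = 11
    radius: float = DEFAULT_FOOTPRINT_RADIUS
    auto_by_resolution: bool = False
    resolution: float | None = None

    def __post_init__(self) -> None:
        if self.auto_by_resolution:
            if self.resolution is None or self.resolution <= 0:
                raise ValueError("auto_by_resolution requires a positive resolution")
            w = max(1, round(1.5 * self.resolution))
            self.window = w if w % 2 == 1 else w + 1
            self.radius = max(3.0, 0.5 * self.resolution)
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be an odd count >= 1")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


@dataclass
class ScoreProfile:
    """Ordered per-residue scores; ``None`` marks an undefined entry."""

    entries: list[tuple[str, int, float | None]] = field(default_factory=list)
    method: str = "smoc_f"

    def __post_init__(self) -> None:
        for chain, res, score in self.entries:
            if score is not None and not (-1e-9 <= score <= 1 + 1e-9):
                raise ValueError(
                    f"score {score} for {chain}{res} outside [0, 1]"
                )

    def scores(self) -> list[float | None]:
        return [s for _, _, s in self.entries]

    def argmin(self) -> tuple[str, int]:
        """(chain, res_seq) of the lowest defined score."""
        defined = [(s, c, r) for c, r, s in self.entries if s is not None]
        if not defined:
            raise ValueError("profile has no defined scores")
        _, chain, res = min(defined, key=lambda t: t[0])
        return chain, res


def moc(a: DensityMap, b: DensityMap, mask: BinaryEnvelope) -> float:
    """Mander's overlap coefficient over the masked voxels.

    ``sum(x*y) / sqrt(sum(x^2) * sum(y^2))`` with intensities clamped to be
    nonnegative; NaN signals an undefined score (all-zero signal in the
    mask) rather than raising.
    """
    if not mask.mask.any():
        raise UndefinedScoreError("empty MOC mask")
    x = np.clip(a.grid[mask.mask].astype(float), 0.0, None)
    y = np.clip(b.grid[mask.mask].astype(float), 0.0, None)
    denom = math.sqrt(float((x**2).sum()) * float((y**2).sum()))
    if denom == 0.0:
        return float("nan")
    return float((x * y).sum() / denom)


def sccc(
    model: AtomicModel,
    segment: AtomicModel,
    density_map: DensityMap,
    params: SimulationParams,
    footprint_fraction: float = SCCC_FOOTPRINT_FRACTION,
) -> float:
    """Segment-based cross-correlation.

    The whole model is blurred onto the experimental grid; the mask keeps
    voxels where the *segment's* simulated density exceeds
    ``footprint_fraction`` of its own maximum, and the CCC is evaluated
    there.
    """
    if not segment.atoms:
        raise ValueError("segment selection is empty")
    sim_full = simulate_map(model, params, grid=density_map)
    sim_seg = simulate_map(segment, params, grid=density_map)
    peak = sim_seg.grid.max()
    mask = sim_seg.grid > footprint_fraction * peak
    if peak <= 0 or not mask.any():
        raise UndefinedScoreError("segment footprint mask is empty")
    return ccc(density_map, sim_full, BinaryEnvelope(mask, footprint_fraction * peak))


def _residue_masks(
    model: AtomicModel,
    chain: str,
    grid: DensityMap,
    radius: float,
) -> tuple[list[tuple[str, int]], list[np.ndarray | None]]:
    """Per-residue boolean footprint masks (heavy atoms only)."""
    chain_model = select(model, chain=chain)
    if not chain_model.atoms:
        raise ValueError(f"chain {chain!r} not present in model")
    keys = chain_model.residues()
    masks: list[np.ndarray | None] = []
    for ch, res in keys:
        res_model = select(chain_model, chain=ch, res_range=(res, res))
        heavy = AtomicModel(res_model.heavy_atoms(), res_model.id)
        if not heavy.atoms:
            masks.append(None)
            continue
        masks.append(footprint_mask(heavy, grid, radius).mask)
    return keys, masks


def _moc_profile(
    keys, masks, experimental: DensityMap, simulated: DensityMap, method: str
) -> ScoreProfile:
    entries: list[tuple[str, int, float | None]] = []
    for (chain, res), mask in zip(keys, masks):
        if mask is None or not mask.any():
            entries.append((chain, res, None))
            continue
        value = moc(experimental, simulated, BinaryEnvelope(mask, 0.0))
        entries.append((chain, res, None if math.isnan(value) else value))
    return ScoreProfile(entries, method=method)


def smoc_f(
    model: AtomicModel,
    chain: str,
    density_map: DensityMap,
    params: SimulationParams,
    sp: SMOCParams | None = None,
) -> ScoreProfile:
    """Sliding-window SMOC along a chain.

    The mask for residue *r* is the union of the footprints of the
    ``sp.window`` residues centred at *r*; the window truncates at chain
    ends and never wraps.
    """
    sp = sp or SMOCParams()
    simulated = simulate_map(model, params, grid=density_map)
    keys, masks = _residue_masks(model, chain, density_map, sp.radius)
    half = sp.window // 2
    window_masks: list[np.ndarray | None] = []
    for i in range(len(keys)):
        lo, hi = max(0, i - half), min(len(keys), i + half + 1)
        stack = [m for m in masks[lo:hi] if m is not None]
        window_masks.append(np.logical_or.reduce(stack) if stack else None)
    return _moc_profile(keys, window_masks, density_map, simulated, "smoc_f")


def smoc_d(
    model: AtomicModel,
    chain: str,
    density_map: DensityMap,
    params: SimulationParams,
    sp: SMOCParams | None = None,
) -> ScoreProfile:
    """Distance-based SMOC: one footprint mask per residue, no smearing."""
    sp = sp or SMOCParams()
    simulated = simulate_map(model, params, grid=density_map)
    keys, masks = _residue_masks(model, chain, density_map, sp.radius)
    return _moc_profile(keys, masks, density_map, simulated, "smoc_d")


def write_profile(profile: ScoreProfile, path) -> None:
    """Write a profile as TSV: chain, residue number, score ('NA' if undefined)."""
    with open(path, "w", encoding="ascii") as fh:
        fh.write(f"# method: {profile.method}\n")
        fh.write("chain\tres_seq\tscore\n")
        for chain, res, score in profile.entries:
            text = "NA" if score is None else f"{score:.6f}"
            fh.write(f"{chain}\t{res}\t{text}\n")


def read_profile(path) -> ScoreProfile:
    """Inverse of :func:`write_profile`."""
    entries: list[tuple[str, int, float | None]] = []
    method = "smoc_f"
    with open(path, encoding="ascii") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# method:"):
                method = line.split(":", 1)[1].strip()
                continue
            if not line or line.startswith(("#", "chain")):
                continue
            chain, res, score = line.split("\t")
            entries.append(
                (chain, int(res), None if score == "NA" else float(score))
            )
    return ScoreProfile(entries, method=method)
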