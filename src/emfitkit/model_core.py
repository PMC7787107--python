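"""Atomic models, PDB/mmCIF I/O, selections and rigid transforms.

Parsing is delegated to :mod:`gemmi`; on top of it this module applies a
deterministic reading policy: first model only, waters excluded, and for
alternate conformations the highest-occupancy altloc is kept (ties go to the
first listed).  Writers emit legacy fixed-column PDB (coordinates to three
decimals) or an mmCIF ``_atom_site`` loop (full-precision coordinates), with
transparent gzip on both ends.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .map_core import GZIP_MAGIC

__all__ = [
    "Atom",
    "AtomicModel",
    "RigidTransform",
    "read_structure",
    "write_structure",
    "select",
    "apply_transform",
    "compose",
    "rmsd_ca",
]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(frozen=True)
class Atom:
    element: str
    name: str
    coords: tuple[float, float, float]
    b_factor: float = 0.0
    occupancy: float = 1.0
    chain: str = "A"
    res_seq: int = 1
    res_name: str = "ALA"
    hetero: bool = False

    @property
    def atomic_number(self) -> int:
        z = gemmi.Element(self.element).atomic_number
        if z < 1:
            warnings.warn(
                f"unknown element {self.element!r}; treating as carbon", stacklevel=2
            )
            return 6
        return z

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class AtomicModel:
    """Ordered collection of atoms with chain/residue bookkeeping."""

    atoms: list[Atom] = field(default_factory=list)
    id: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def residues(self) -> list[tuple[str, int]]:
        """(chain, res_seq) keys in atom order, deduplicated."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain, a.res_seq), None)
        return list(seen)

    def ca_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.name.strip() == "CA"]

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def with_coords(self, coords: np.ndarray) -> "AtomicModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            replace(a, coords=tuple(float(v) for v in xyz))
            for a, xyz in zip(self.atoms, coords)
        ]
        return AtomicModel(atoms, self.id)

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass
class RigidTransform:
    """Rotation about ``centre`` followed by a translation.

    Acts on points as ``R @ (x - centre) + centre + translation``.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    centre: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.centre = np.asarray(self.centre, dtype=float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        if not np.allclose(
            self.rotation.T @ self.rotation, np.eye(3), atol=1e-9
        ):
            raise ValueError("rotation must be orthogonal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (pts - self.centre) @ self.rotation.T + self.centre + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(
            self.rotation.T, -self.rotation.T @ self.translation, self.centre
        )

    def rotation_angle_deg(self) -> float:
        tr = np.clip((np.trace(self.rotation) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(tr)))


def compose(outer: RigidTransform, inner: RigidTransform) -> RigidTransform:
    """Single transform equivalent to applying ``inner`` then ``outer``."""
    rot = outer.rotation @ inner.rotation
    # expand both actions about a common (zero) pivot
    t = (
        outer.rotation @ (inner.centre + inner.translation - outer.centre)
        - rot @ inner.centre
        + outer.centre
        + outer.translation
    )
    return RigidTransform(rot, t, np.zeros(3))


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _read_text(path) -> str:
    with open(path, "rb") as fh:
        payload = fh.read()
    if payload[:2] == GZIP_MAGIC:
        payload = gzip.decompress(payload)
    return payload.decode("utf-8", "replace")


def _looks_like_cif(text: str) -> bool:
    head = text[:4000]
    return head.lstrip().startswith("data_") or "_atom_site." in head


def read_structure(path, include_waters: bool = False) -> AtomicModel:
    """Read a PDB or mmCIF file (format auto-detected, gzip transparent).

    Only the first model is kept.  Hetero atoms are included; waters are
    excluded unless ``include_waters``.  For altloc groups the
    highest-occupancy conformer wins, ties going to the first listed.
    """
    text = _read_text(path)
    try:
        if _looks_like_cif(text):
            block = gemmi.cif.read_string(text).sole_block()
            structure = gemmi.make_structure_from_block(block)
        else:
            structure = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: cannot parse as PDB or mmCIF: {exc}") from exc

    if len(structure) == 0:
        raise ValueError(f"{path}: file contains no model")
    model = structure[0]

    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            if not include_waters and residue.name.strip() in _WATER_NAMES:
                continue
            # altloc policy: per atom name keep highest occupancy, first wins ties
            chosen: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = chosen.get(atom.name)
                if prev is None or atom.occ > prev.occ + 1e-9:
                    chosen[atom.name] = atom
            for atom in chosen.values():
                atoms.append(
                    Atom(
                        element=atom.element.name,
                        name=atom.name,
                        coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                        b_factor=atom.b_iso,
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        chain=chain.name,
                        res_seq=residue.seqid.num,
                        res_name=residue.name,
                        hetero=residue.het_flag == "H",
                    )
                )
    if not atoms:
        raise ValueError(f"{path}: no atoms after filtering")
    return AtomicModel(atoms, id=str(path))


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _pdb_atom_name(atom: Atom) -> str:
    name = atom.name.strip()
    if len(name) < 4 and len(atom.element.strip()) < 2:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _write_bytes(path, payload: bytes, compress: bool) -> None:
    opener = gzip.open if compress else open
    with opener(path, "wb") as fh:
        fh.write(payload)


def write_structure(
    model: AtomicModel, path, format: str = "pdb", compress: bool = False
) -> None:
    """Serialize ``model`` as legacy PDB or mmCIF.

    PDB uses the fixed-column record layout (coordinates to 3 decimals);
    models exceeding its column capacity (≥100 000 atoms, residue numbers
    over 9999, multi-character chain ids) raise a ``ValueError`` advising
    mmCIF, which has no such limits.
    """
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}")
    if not model.atoms:
        raise ValueError("cannot write an empty model")

    if format == "pdb":
        if len(model.atoms) > 99999:
            raise ValueError(
                "model exceeds PDB fixed-column capacity (>99999 atoms); use mmCIF"
            )
        lines = []
        prev_chain = None
        serial = 0
        for atom in model.atoms:
            if len(atom.chain) > 1:
                raise ValueError(
                    f"chain id {atom.chain!r} too wide for PDB; use mmCIF"
                )
            if not -999 <= atom.res_seq <= 9999:
                raise ValueError(
                    f"residue number {atom.res_seq} exceeds PDB columns; use mmCIF"
                )
            if prev_chain is not None and atom.chain != prev_chain:
                lines.append("TER")
            prev_chain = atom.chain
            serial += 1
            record = "HETATM" if atom.hetero else "ATOM  "
            x, y, z = atom.coords
            lines.append(
                f"{record}{serial:5d} {_pdb_atom_name(atom)} {atom.res_name:>3s} "
                f"{atom.chain:1s}{atom.res_seq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
                f"          {atom.element.upper():>2s}"
            )
        lines += ["TER", "END", ""]
        _write_bytes(path, "\n".join(lines).encode("ascii"), compress)
        return

    # mmCIF: a minimal _atom_site loop with full-precision coordinates
    lines = [
        f"data_{model.id or 'model'}",
        "loop_",
        "_atom_site.group_PDB",
        "_atom_site.id",
        "_atom_site.type_symbol",
        "_atom_site.label_atom_id",
        "_atom_site.label_alt_id",
        "_atom_site.label_comp_id",
        "_atom_site.label_asym_id",
        "_atom_site.label_seq_id",
        "_atom_site.Cartn_x",
        "_atom_site.Cartn_y",
        "_atom_site.Cartn_z",
        "_atom_site.occupancy",
        "_atom_site.B_iso_or_equiv",
        "_atom_site.auth_seq_id",
        "_atom_site.auth_asym_id",
        "_atom_site.pdbx_PDB_model_num",
    ]
    for i, atom in enumerate(model.atoms, start=1):
        record = "HETATM" if atom.hetero else "ATOM"
        x, y, z = (float(v) for v in atom.coords)
        lines.append(
            f"{record} {i} {atom.element.upper()} {atom.name} . {atom.res_name} "
            f"{atom.chain} {atom.res_seq} {x!r} {y!r} {z!r} "
            f"{atom.occupancy:.2f} {atom.b_factor:.2f} {atom.res_seq} {atom.chain} 1"
        )
    lines.append("")
    _write_bytes(path, "\n".join(lines).encode("ascii"), compress)


# ---------------------------------------------------------------------------
# Selections and geometry
# ---------------------------------------------------------------------------

def select(
    model: AtomicModel,
    chain: str | None = None,
    res_range: tuple[int, int] | None = None,
) -> AtomicModel:
    """Sub-model by chain and/or inclusive residue-number range.

    ``None`` means "any"; atom order is preserved and an empty selection is
    allowed.
    """
    atoms = [
        a
        for a in model.atoms
        if (chain is None or a.chain == chain)
        and (res_range is None or res_range[0] <= a.res_seq <= res_range[1])
    ]
    return AtomicModel(atoms, model.id)


def apply_transform(model: AtomicModel, transform: RigidTransform) -> AtomicModel:
    """Rigidly move all atoms; every non-coordinate field is unchanged."""
    return model.with_coords(transform.apply(model.coords))


def rmsd_ca(a: AtomicModel, b: AtomicModel) -> float:
    """Cα root-mean-square deviation without superposition.

    Requires the same Cα residues (chain, number) in matching order.
    """
    ca_a, ca_b = a.ca_atoms(), b.ca_atoms()
    if len(ca_a) != len(ca_b) or not ca_a:
        raise ValueError("models have mismatched (or empty) Calpha sets")
    for p, q in zip(ca_a, ca_b):
        if (p.chain, p.res_seq) != (q.chain, q.res_seq):
            raise ValueError(
                f"residue mismatch: {(p.chain, p.res_seq)} vs {(q.chain, q.res_seq)}"
            )
    pa = np.array([p.coords for p in ca_a])
    pb = np.array([q.coords for q in ca_b])
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))
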