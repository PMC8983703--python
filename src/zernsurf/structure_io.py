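"""Reading protein structures and per-residue confidence profiles.

Structures come from PDB or mmCIF files (parsed with gemmi). Only ATOM
records of the first model are kept: HETATM groups, waters and hydrogens
are excluded, and alternate locations are resolved to the highest-occupancy
conformer. Predicted models (AlphaFold-style) store the per-residue pLDDT
confidence in the B-factor column; :func:`confidence_profile` extracts it
on the canonical 0-100 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "ConfidenceProfile",
    "StructureParseError",
    "EmptyStructureError",
    "parse_structure",
    "select_atoms",
    "confidence_profile",
    "write_pdb",
]

MAIN_CHAIN_NAMES = ("N", "CA", "C")


class StructureParseError(ValueError):
    """File could not be parsed under the named standard."""


class EmptyStructureError(ValueError):
    """No atoms remained after filtering."""


@dataclass(frozen=True)
class Atom:
    """A single heavy atom.

    ``bfactor`` carries the crystallographic B-factor for experimental
    structures and the pLDDT confidence for predicted models.
    """

    element: str
    name: str
    coord: tuple[float, float, float]
    residue_index: int
    chain_id: str
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coord):
            raise ValueError(f"non-finite coordinate for atom {self.name}")
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")


@dataclass
class Structure:
    """An ordered collection of atoms grouped contiguously by residue."""

    id: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys())

    def residue_keys(self) -> list[tuple[str, int]]:
        """Distinct (chain, residue_index) pairs in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.residue_index), None)
        return list(seen)

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclass
class ConfidenceProfile:
    """Per-residue confidence values on the 0-100 pLDDT scale."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile must be one-dimensional")
        if len(self.values) and (self.values.min() < 0 or self.values.max() > 100):
            raise ValueError("pLDDT values must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.values)


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".cif", ".mmcif"}:
        return "mmcif"
    if suffix in {".pdb", ".ent"}:
        return "pdb"
    # sniff: mmCIF files start with "data_"
    head = path.read_text(errors="replace")[:64]
    return "mmcif" if head.lstrip().startswith("data_") else "pdb"


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties to the first."""
    best: dict[str, gemmi.Atom] = {}
    for at in residue:
        prev = best.get(at.name)
        if prev is None or at.occ > prev.occ + 1e-9:
            best[at.name] = at
    # preserve file order of the winners
    winners = set(id(a) for a in best.values())
    return [a for a in residue if id(a) in winners]


def parse_structure(
    path: str | Path,
    format: Literal["pdb", "mmcif", "auto"] = "auto",
) -> Structure:
    """Read a structure file into a :class:`Structure`.

    Keeps ATOM records of the first model only; drops HETATM, waters and
    hydrogens; resolves alternate locations to the highest-occupancy copy.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = _detect_format(path) if format == "auto" else format
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise StructureParseError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:  # gemmi raises RuntimeError
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: file contains no model")
    st.setup_entities()
    model = st[0]

    atoms: list[Atom] = []
    for chain in model:
        for res_pos, residue in enumerate(chain, start=1):
            if residue.het_flag == "H" or residue.is_water():
                continue
            seqid = residue.seqid.num if residue.seqid.num is not None else res_pos
            for at in _resolve_altlocs(residue):
                if at.element.is_hydrogen:
                    continue
                el = at.element.name
                atoms.append(
                    Atom(
                        element=el,
                        name=at.name,
                        coord=(at.pos.x, at.pos.y, at.pos.z),
                        residue_index=max(int(seqid), 1),
                        chain_id=chain.name,
                        bfactor=float(at.b_iso),
                    )
                )
    if not atoms:
        raise EmptyStructureError(f"{path}: no polymer ATOM records after filtering")
    return Structure(id=path.stem, atoms=atoms)


def select_atoms(
    s: Structure, mode: Literal["full_atom", "main_chain"] = "full_atom"
) -> list[Atom]:
    """Atom subset used to build the molecular surface.

    ``full_atom`` keeps every heavy atom; ``main_chain`` keeps exactly the
    backbone N, CA and C atoms (the representation that gave the better
    fold-classification accuracy in the source benchmarks).
    """
    if not s.atoms:
        raise EmptyStructureError("structure has no atoms")
    if mode == "full_atom":
        return [a for a in s.atoms if a.element != "H"]
    if mode == "main_chain":
        subset = [a for a in s.atoms if a.name in MAIN_CHAIN_NAMES]
        if not subset:
            raise EmptyStructureError(
                "no main-chain N/CA/C atoms found; input does not look like a protein"
            )
        return subset
    raise ValueError(f"unknown mode {mode!r}")


def confidence_profile(s: Structure) -> ConfidenceProfile:
    """Per-residue confidence from the B-factor column.

    One value per residue, taken from the CA atom (first atom of the
    residue as fallback). Profiles on a [0, 1] scale are rescaled by 100
    so that downstream thresholds always operate on 0-100 pLDDT.
    """
    per_res: dict[tuple[str, int], float] = {}
    fallback: dict[tuple[str, int], float] = {}
    for a in s.atoms:
        key = (a.chain_id, a.residue_index)
        fallback.setdefault(key, a.bfactor)
        if a.name == "CA":
            per_res.setdefault(key, a.bfactor)
    values = np.array(
        [per_res.get(k, fallback[k]) for k in s.residue_keys()], dtype=float
    )
    if len(values) == 0:
        raise EmptyStructureError("structure has no residues")
    if values.max() <= 1.0:
        values = values * 100.0
    return ConfidenceProfile(values=values)


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write fixed-column PDB ATOM records (fixture/export helper)."""
    lines = []
    for i, a in enumerate(s.atoms, start=1):
        x, y, z = a.coord
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {i:>5d} {name}{'':1s}ALA {a.chain_id[:1] or 'A'}"
            f"{a.residue_index:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.00:6.2f}{a.bfactor:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
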