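"""Sphere-set representation of molecules read from PDB coordinate files.

A molecule is modelled as a rigid set of van der Waals balls: each atom
contributes a sphere centred at its coordinates with an element-dependent
radius.  Two chain selections of one PDB entry define the two binding
partners of a complex.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SphereAtom",
    "Molecule",
    "RadiiTable",
    "BONDI_RADII",
    "parse_complex",
    "write_fixture_pdb",
]

#: Bondi van der Waals radii (Å) for the elements common in protein structures.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}

_WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(frozen=True)
class SphereAtom:
    """One atom as a ball: centre and van der Waals radius in Å."""

    center: tuple[float, float, float]
    radius: float
    element: str = ""
    chain_id: str = ""
    residue_seq: int = 0
    atom_name: str = ""
    residue_name: str = ""

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"atom radius must be positive, got {self.radius}")
        if not all(math.isfinite(c) for c in self.center):
            raise ValueError(f"non-finite atom center {self.center}")


class Molecule:
    """A named, ordered set of :class:`SphereAtom` forming one rigid body.

    Parameters
    ----------
    label:
        Free-form name, typically the chain selection (e.g. ``"A"``).
    atoms:
        The spheres; at least one is required.
    """

    def __init__(self, label: str, atoms: Sequence[SphereAtom]):
        atoms = list(atoms)
        if not atoms:
            raise ValueError(f"molecule {label!r} has no atoms")
        self.label = label
        self.atoms = atoms
        self._centers: np.ndarray | None = None
        self._radii: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def __repr__(self) -> str:
        return f"Molecule({self.label!r}, {len(self.atoms)} atoms)"

    @property
    def centers(self) -> np.ndarray:
        """(n, 3) array of atom centres in Å."""
        if self._centers is None:
            self._centers = np.array([a.center for a in self.atoms], dtype=float)
        return self._centers

    @property
    def radii(self) -> np.ndarray:
        """(n,) array of van der Waals radii in Å."""
        if self._radii is None:
            self._radii = np.array([a.radius for a in self.atoms], dtype=float)
        return self._radii

    def centroid(self) -> np.ndarray:
        return self.centers.mean(axis=0)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Molecule":
        """Return a rigidly moved copy: ``x -> rotation @ x + translation``."""
        pts = self.centers
        if rotation is not None:
            pts = pts @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            pts = pts + np.asarray(translation, dtype=float)
        atoms = [
            SphereAtom(tuple(p), a.radius, a.element, a.chain_id,
                       a.residue_seq, a.atom_name, a.residue_name)
            for p, a in zip(pts, self.atoms)
        ]
        return Molecule(self.label, atoms)

    def subset(self, indices: Iterable[int], label: str | None = None) -> "Molecule":
        atoms = [self.atoms[i] for i in indices]
        return Molecule(label if label is not None else self.label, atoms)


@dataclass
class RadiiTable:
    """Element symbol → van der Waals radius (Å) with a fallback default.

    All radii must lie in the physically sensible open interval (0.5, 3.0) Å.
    Unknown elements get ``default`` and a logged warning, so radius
    assignment is total.
    """

    radii: Mapping[str, float] = field(default_factory=lambda: dict(BONDI_RADII))
    default: float = 1.70

    def __post_init__(self) -> None:
        for elem, r in {**self.radii, "<default>": self.default}.items():
            if not (0.5 < r < 3.0):
                raise ValueError(
                    f"radius {r} Å for {elem!r} outside the plausible (0.5, 3.0) Å range")

    def lookup(self, element: str) -> float:
        elem = element.strip().capitalize()
        if elem in self.radii:
            return self.radii[elem]
        logger.warning("unknown element %r: using default radius %.2f Å",
                       element, self.default)
        return self.default


def _infer_element(atom: gemmi.Atom) -> str:
    name = atom.element.name
    if name and name.upper() not in ("X", ""):
        return name
    # fall back to the atom-name heuristic: first alphabetic character
    for ch in atom.name:
        if ch.isalpha():
            return ch
    return ""


def _read_structure(pdb_source) -> gemmi.Structure:
    if isinstance(pdb_source, gemmi.Structure):
        return pdb_source
    if hasattr(pdb_source, "read"):
        text = pdb_source.read()
        if isinstance(text, bytes):
            text = text.decode()
        return gemmi.read_pdb_string(text)
    path = Path(pdb_source)
    if path.exists():
        return gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    # treat as raw PDB text
    return gemmi.read_pdb_string(str(pdb_source))


def _chains_to_molecule(model: gemmi.Model, chain_ids: Sequence[str],
                        radii: RadiiTable, include_hydrogens: bool) -> Molecule:
    atoms: list[SphereAtom] = []
    seen: set[tuple[str, int, str, str]] = set()
    for chain_id in chain_ids:
        chain = model.find_chain(chain_id)
        if chain is None:
            raise ValueError(f"chain {chain_id!r} not found in structure")
        for residue in chain:
            if residue.name.strip().upper() in _WATER_RESNAMES:
                continue
            for atom in residue:
                element = _infer_element(atom)
                if not include_hydrogens and element.upper() in ("H", "D"):
                    continue
                # collapse alternate locations: first occurrence wins
                key = (chain_id, residue.seqid.num, residue.name, atom.name)
                if key in seen:
                    continue
                seen.add(key)
                atoms.append(SphereAtom(
                    center=(atom.pos.x, atom.pos.y, atom.pos.z),
                    radius=radii.lookup(element),
                    element=element,
                    chain_id=chain_id,
                    residue_seq=residue.seqid.num,
                    atom_name=atom.name,
                    residue_name=residue.name,
                ))
    label = "".join(chain_ids)
    if not atoms:
        raise ValueError(
            f"selection {label!r} is empty after filtering waters"
            + ("" if include_hydrogens else " and hydrogens"))
    return Molecule(label, atoms)


def parse_complex(pdb_source,
                  chains_a: Sequence[str] | str,
                  chains_b: Sequence[str] | str,
                  radii: RadiiTable | None = None,
                  include_hydrogens: bool = True) -> tuple[Molecule, Molecule]:
    """Read a PDB entry into two sphere-set molecules.

    Parameters
    ----------
    pdb_source:
        Path to a PDB file, an open text stream, raw PDB text, or a
        ``gemmi.Structure``.  Model 1 is used when several models exist.
    chains_a, chains_b:
        Chain identifiers defining the two binding partners.  Either a
        string of chain letters (``"AB"``) or a sequence of ids.  The
        selections must be non-empty and disjoint.
    radii:
        Van der Waals radii table; Bondi values by default.
    include_hydrogens:
        Keep hydrogen/deuterium atoms when present (most X-ray entries
        deposit none).

    Returns
    -------
    (Molecule, Molecule)
        One molecule per selection; waters excluded, alternate locations
        collapsed to the first occurrence, every atom carrying a radius.
    """
    sel_a = list(chains_a)
    sel_b = list(chains_b)
    if not sel_a or not sel_b:
        raise ValueError("both chain selections must be non-empty")
    if set(sel_a) & set(sel_b):
        raise ValueError(
            f"chain selections overlap: {sorted(set(sel_a) & set(sel_b))}")
    if radii is None:
        radii = RadiiTable()
    try:
        structure = _read_structure(pdb_source)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse PDB input: {exc}") from exc
    if len(structure) == 0:
        raise ValueError("PDB input contains no model")
    model = structure[0]
    mol_a = _chains_to_molecule(model, sel_a, radii, include_hydrogens)
    mol_b = _chains_to_molecule(model, sel_b, radii, include_hydrogens)
    return mol_a, mol_b


_PDB_COORD_MIN, _PDB_COORD_MAX = -999.999, 9999.999


def write_fixture_pdb(molecules: Molecule | Sequence[Molecule], path) -> None:
    """Write molecules as minimal fixed-column ATOM records.

    The output round-trips through :func:`parse_complex`: centres survive to
    the 3-decimal precision of the 8.3 coordinate columns, and each
    molecule's ``chain_id`` metadata (or a generated chain letter) is kept.
    Coordinates outside the representable column range raise ``ValueError``.
    """
    if isinstance(molecules, Molecule):
        molecules = [molecules]
    lines: list[str] = []
    serial = 1
    default_chains = iter("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    for mol in molecules:
        chain_default = next(default_chains)
        for atom in mol.atoms:
            x, y, z = atom.center
            for c in (x, y, z):
                if not (_PDB_COORD_MIN <= c <= _PDB_COORD_MAX):
                    raise ValueError(
                        f"coordinate {c} Å does not fit the PDB 8.3 column format")
            chain = (atom.chain_id or chain_default)[:1]
            name = atom.atom_name or (atom.element or "X")
            # columns: serial 7-11, name 13-16, resName 18-20, chain 22,
            # resSeq 23-26, xyz 31-54, occupancy, b-factor, element 77-78
            lines.append(
                "ATOM  {serial:>5d} {name:<4.4s} {res:<3.3s} {chain}{seq:>4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2.2s}".format(
                    serial=serial, name=name[:4], res=(atom.residue_name or "UNK"),
                    chain=chain, seq=atom.residue_seq or serial,
                    x=x, y=y, z=z, occ=1.00, b=0.00,
                    elem=atom.element[:2].upper() or "X"))
            serial += 1
        lines.append("TER")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text)
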