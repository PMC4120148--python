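"""Molecular structure model: PDB I/O and covalent bond perception.

A :class:`Molecule` is the flat, index-based container the rigidity pipeline
operates on: an ordered list of atoms with Cartesian coordinates in Å plus a
set of covalent bonds (unordered index pairs). PDB parsing is delegated to
gemmi; writing emits standard fixed-width ATOM records so that per-sample
conformations can be inspected in any viewer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Molecule",
    "read_pdb",
    "write_pdb",
    "infer_covalent_bonds",
    "COVALENT_RADII",
    "BOND_TOLERANCE",
]

# Single-bond covalent radii in Å (Cordero et al. consensus values for the
# elements that occur in protein structures); unknown elements fall back to
# DEFAULT_COVALENT_RADIUS with a logged warning.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "S": 1.05,
    "P": 1.07,
    "SE": 1.20,
    "F": 0.57,
    "CL": 1.02,
    "BR": 1.20,
    "I": 1.39,
    "FE": 1.32,
    "ZN": 1.22,
    "MG": 1.41,
    "CA": 1.76,
    "NA": 1.66,
    "K": 2.03,
    "MN": 1.39,
}
DEFAULT_COVALENT_RADIUS = 0.77
#: Distance slack added to the sum of covalent radii when perceiving bonds.
BOND_TOLERANCE = 0.45

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class Atom:
    """One atom of the input structure; coordinates in Å."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    position: tuple[float, float, float]
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if len(self.position) != 3 or not all(math.isfinite(c) for c in self.position):
            raise ValueError(f"atom serial {self.serial}: position must have 3 finite components")


@dataclass
class Molecule:
    """Ordered atoms plus a symmetric set of covalent bonds (index pairs)."""

    atoms: list[Atom]
    covalent_bonds: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serial numbers are not unique")
        n = len(self.atoms)
        norm = set()
        for i, j in self.covalent_bonds:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"invalid covalent bond ({i}, {j})")
            norm.add((min(i, j), max(i, j)))
        self.covalent_bonds = norm

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(n, 3) array of atom positions in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def bond_neighbors(self) -> list[set[int]]:
        """Adjacency sets of the covalent bond graph."""
        adj: list[set[int]] = [set() for _ in self.atoms]
        for i, j in self.covalent_bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def has_hydrogens(self) -> bool:
        return any(a.element == "H" for a in self.atoms)


def _read_conect_serial_pairs(path: Path) -> set[tuple[int, int]]:
    """Collect CONECT record serial pairs from the raw PDB text."""
    pairs: set[tuple[int, int]] = set()
    with open(path) as fh:
        for line in fh:
            if not line.startswith("CONECT"):
                continue
            fields = []
            for start in range(6, 31, 5):
                tok = line[start : start + 5].strip()
                if tok:
                    try:
                        fields.append(int(tok))
                    except ValueError:
                        continue
            if len(fields) >= 2:
                a = fields[0]
                for b in fields[1:]:
                    pairs.add((min(a, b), max(a, b)))
    return pairs


def read_pdb(
    path: str | Path,
    model_index: int = 0,
    chain_filter: str | None = None,
    include_hetero: bool = False,
) -> Molecule:
    """Read a PDB file into a :class:`Molecule`.

    Parameters
    ----------
    path:
        PDB file with at least one ATOM/HETATM record in the selection.
    model_index:
        Which model of a multi-model (e.g. NMR) entry to read; default first.
    chain_filter:
        If given, keep only atoms of this chain.
    include_hetero:
        Keep non-water HETATM records (ligands, ions). Waters are always
        dropped; default drops all heteroatoms.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by first appearance). CONECT records, when present, are
    recorded as covalent bonds between the referenced atoms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PDB file not found: {path}")
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse PDB file {path}: {exc}") from exc
    if model_index >= len(structure):
        raise ValueError(
            f"model index {model_index} out of range: file has {len(structure)} model(s)"
        )
    model = structure[model_index]

    atoms: list[Atom] = []
    serial_to_index: dict[int, int] = {}
    for chain in model:
        if chain_filter is not None and chain.name != chain_filter:
            continue
        for residue in chain:
            is_het = residue.het_flag == "H"
            if residue.name in _WATER_NAMES:
                continue
            if is_het and not include_hetero:
                continue
            # resolve altlocs: group by atom name, keep highest occupancy
            by_name: dict[str, gemmi.Atom] = {}
            for at in residue:
                prev = by_name.get(at.name)
                if prev is None or at.occ > prev.occ:
                    by_name[at.name] = at
            for at in residue:  # preserve file order among the winners
                if by_name.get(at.name) is not at:
                    continue
                pos = (at.pos.x, at.pos.y, at.pos.z)
                if not all(math.isfinite(c) for c in pos):
                    raise ValueError(
                        f"malformed coordinates for atom serial {at.serial} in {path}"
                    )
                idx = len(atoms)
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name.upper(),
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        chain=chain.name,
                        position=pos,
                        is_hetero=is_het,
                    )
                )
                if at.serial not in serial_to_index:
                    serial_to_index[at.serial] = idx

    if not atoms:
        raise ValueError(
            f"empty selection: no atoms in {path} "
            f"(model {model_index}, chain {chain_filter!r})"
        )

    bonds: set[tuple[int, int]] = set()
    for sa, sb in _read_conect_serial_pairs(path):
        ia, ib = serial_to_index.get(sa), serial_to_index.get(sb)
        if ia is not None and ib is not None and ia != ib:
            bonds.add((min(ia, ib), max(ia, ib)))
    return Molecule(atoms=atoms, covalent_bonds=bonds)


def write_pdb(
    molecule: Molecule,
    coordinates: Sequence[Sequence[float]] | np.ndarray | None,
    path: str | Path,
) -> None:
    """Write the molecule as standard ATOM/HETATM records.

    ``coordinates`` replaces the atom positions (same order, same count);
    pass ``None`` to write the molecule's own coordinates. Coordinates are
    formatted with 3 decimals as the PDB format prescribes.
    """
    coords = molecule.coordinates if coordinates is None else np.asarray(coordinates, float)
    if coords.shape != (len(molecule), 3):
        raise ValueError(
            f"coordinate count {coords.shape} does not match atom count {len(molecule)}"
        )
    lines = []
    for atom, xyz in zip(molecule.atoms, coords):
        record = "HETATM" if atom.is_hetero else "ATOM  "
        name = atom.name
        # standard PDB name justification: 1-char elements start in column 14
        if len(name) < 4 and len(atom.element) == 1:
            name = " " + name
        lines.append(
            f"{record}{atom.serial % 100000:5d} {name:<4s}"
            f"{atom.residue_name:>4s} {atom.chain[:1]:1s}"
            f"{atom.residue_number % 10000:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def infer_covalent_bonds(
    molecule: Molecule,
    tolerance: float = BOND_TOLERANCE,
) -> set[tuple[int, int]]:
    """Perceive covalent bonds by the covalent-radii distance criterion.

    Two atoms are bonded when their distance is below the sum of their
    element covalent radii plus ``tolerance``. Bonds carried by CONECT
    records on the molecule are unioned into the result. Pairs involving
    unknown elements use a default radius (with a warning).
    """
    if len(molecule) == 0:
        raise ValueError("molecule is empty")
    coords = molecule.coordinates
    radii = np.empty(len(molecule))
    for i, atom in enumerate(molecule.atoms):
        r = COVALENT_RADII.get(atom.element.upper())
        if r is None:
            logger.warning(
                "unknown element %r (atom serial %d): using default covalent radius",
                atom.element,
                atom.serial,
            )
            r = DEFAULT_COVALENT_RADIUS
        radii[i] = r

    from scipy.spatial import cKDTree

    max_cut = 2 * radii.max() + tolerance
    tree = cKDTree(coords)
    bonds: set[tuple[int, int]] = set(molecule.covalent_bonds)
    for i, j in tree.query_pairs(max_cut):
        d = np.linalg.norm(coords[i] - coords[j])
        if d < radii[i] + radii[j] + tolerance and d > 1e-6:
            bonds.add((min(i, j), max(i, j)))
    return bonds


def with_bonds(molecule: Molecule, tolerance: float = BOND_TOLERANCE) -> Molecule:
    """Return a copy of the molecule with inferred covalent bonds attached."""
    return Molecule(atoms=list(molecule.atoms), covalent_bonds=infer_covalent_bonds(molecule, tolerance))
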