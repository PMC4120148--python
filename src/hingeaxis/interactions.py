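"""Noncovalent interaction detection.

Hydrogen bonds become hinges in the body-bar-hinge model, with a geometric
energy (kcal/mol, more negative = stronger) that drives the energy-cutoff
search of the cluster decomposition; hydrophobic contacts (off by default)
become bars. The H-bond energy is a Mayo-style well: a 12-10 distance term
with equilibrium donor–acceptor distance 2.8 Å and well depth 8 kcal/mol,
multiplied by an angular factor when an explicit donor hydrogen is present.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_model import Molecule

__all__ = [
    "Interaction",
    "detect_hbonds",
    "detect_hydrophobics",
    "filter_by_cutoff",
    "hbond_energy",
    "write_interactions_tsv",
]

HB_EQUILIBRIUM = 2.8  # Å, donor–acceptor
HB_WELL_DEPTH = 8.0  # kcal/mol
HB_DISTANCE_CUTOFF = 3.6  # Å, donor–acceptor screen
HB_MIN_DHA_ANGLE = 100.0  # degrees, screen when H present
HYDROPHOBIC_CUTOFF = 4.25  # Å, C/S–C/S contact distance

_DONOR_ACCEPTOR_ELEMENTS = {"N", "O"}
_HYDROPHOBIC_ELEMENTS = {"C", "S"}


@dataclass(frozen=True)
class Interaction:
    """A detected noncovalent interaction between two atoms.

    For hydrogen bonds ``donor_index``/``acceptor_index`` are the heavy
    donor and acceptor atoms and ``energy`` is in kcal/mol (≤ 0). For
    hydrophobic contacts the two indices are the contacting carbon/sulfur
    atoms and the energy is 0.
    """

    kind: str  # "hbond" | "hydrophobic"
    donor_index: int
    acceptor_index: int
    energy: float = 0.0
    distance: float = float("nan")
    angle: float = float("nan")  # D-H...A angle, degrees; nan if no H

    def __post_init__(self) -> None:
        if self.kind not in ("hbond", "hydrophobic"):
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if self.donor_index == self.acceptor_index:
            raise ValueError("interaction endpoints must be distinct atoms")
        if not math.isfinite(self.energy):
            raise ValueError("interaction energy must be finite")


def hbond_energy(distance: float, dha_angle_deg: float | None = None) -> float:
    """Mayo-style hydrogen bond energy in kcal/mol.

    ``E = D0 * (5 (R0/R)^12 - 6 (R0/R)^10) * cos^2(theta)`` with
    R0 = 2.8 Å and D0 = 8 kcal/mol; the angular factor is 1 when no
    explicit hydrogen is available (``dha_angle_deg`` is None). At the
    equilibrium geometry the energy is -8 kcal/mol.
    """
    ratio = HB_EQUILIBRIUM / distance
    radial = HB_WELL_DEPTH * (5.0 * ratio**12 - 6.0 * ratio**10)
    if dha_angle_deg is None:
        angular = 1.0
    else:
        angular = math.cos(math.radians(dha_angle_deg)) ** 2
    return radial * angular


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, v = a - b, c - b
    cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _bond_distance_leq(adj: list[set[int]], i: int, j: int, k: int) -> bool:
    """True if atoms i, j are within k covalent bonds of each other."""
    frontier = {i}
    seen = {i}
    for _ in range(k):
        nxt = set()
        for u in frontier:
            nxt |= adj[u]
        if j in nxt:
            return True
        nxt -= seen
        seen |= nxt
        frontier = nxt
    return False


def detect_hbonds(molecule: Molecule) -> list[Interaction]:
    """Detect hydrogen bonds between N/O donors and N/O acceptors.

    Requires covalent bonds on the molecule (to find attached hydrogens and
    to exclude 1-2/1-3 pairs). A donor is an N/O with an attached hydrogen;
    when the structure carries no hydrogens at all, every N/O is treated as
    a potential donor and the angular term is dropped. Candidates pass a
    donor–acceptor distance screen (≤ 3.6 Å) and, when an H is present, a
    D-H···A angle screen (≥ 100°); each survivor is scored with
    :func:`hbond_energy` and kept only if the energy is negative.
    """
    if not molecule.covalent_bonds:
        raise ValueError("covalent bonds must be inferred before hydrogen bond detection")
    adj = molecule.bond_neighbors()
    coords = molecule.coordinates
    elements = [a.element.upper() for a in molecule.atoms]
    has_h = molecule.has_hydrogens()

    donors: list[tuple[int, list[int]]] = []  # (heavy atom, attached H indices)
    acceptors: list[int] = []
    for i, el in enumerate(elements):
        if el not in _DONOR_ACCEPTOR_ELEMENTS:
            continue
        acceptors.append(i)
        hs = [j for j in adj[i] if elements[j] == "H"]
        if hs or not has_h:
            donors.append((i, hs))

    if not donors or not acceptors:
        return []

    tree = cKDTree(coords)
    acceptor_set = set(acceptors)
    out: list[Interaction] = []
    for d_idx, hs in donors:
        for a_idx in sorted(tree.query_ball_point(coords[d_idx], HB_DISTANCE_CUTOFF)):
            if a_idx == d_idx or a_idx not in acceptor_set:
                continue
            if a_idx in adj[d_idx] or _bond_distance_leq(adj, d_idx, a_idx, 2):
                continue
            da = float(np.linalg.norm(coords[d_idx] - coords[a_idx]))
            if da > HB_DISTANCE_CUTOFF or da < 1e-6:
                continue
            angle = None
            if hs:
                # best (most linear) D-H...A geometry over attached hydrogens
                angle = max(_angle_deg(coords[d_idx], coords[h], coords[a_idx]) for h in hs)
                if angle < HB_MIN_DHA_ANGLE:
                    continue
            energy = hbond_energy(da, angle)
            if energy >= 0.0:
                continue
            out.append(
                Interaction(
                    kind="hbond",
                    donor_index=d_idx,
                    acceptor_index=a_idx,
                    energy=energy,
                    distance=da,
                    angle=float("nan") if angle is None else angle,
                )
            )
    # symmetric duplicates (i donates to j and j to i) are distinct bonds in
    # principle, but with heavy-atom-only donors they are one geometric pair:
    # keep the lower-energy orientation.
    best: dict[tuple[int, int], Interaction] = {}
    for ia in out:
        key = (min(ia.donor_index, ia.acceptor_index), max(ia.donor_index, ia.acceptor_index))
        prev = best.get(key)
        if prev is None or ia.energy < prev.energy:
            best[key] = ia
    return sorted(best.values(), key=lambda x: (x.donor_index, x.acceptor_index))


def detect_hydrophobics(molecule: Molecule, enabled: bool = False,
                        cutoff: float = HYDROPHOBIC_CUTOFF) -> list[Interaction]:
    """Detect carbon/sulfur contacts between different residues.

    Disabled by default (returns an empty list), matching the default
    constraint model in which only covalent bonds and hydrogen bonds
    constrain the structure.
    """
    if not enabled:
        return []
    coords = molecule.coordinates
    elements = [a.element.upper() for a in molecule.atoms]
    residue_key = [(a.chain, a.residue_number) for a in molecule.atoms]
    tree = cKDTree(coords)
    out = []
    for i, j in sorted(tree.query_pairs(cutoff)):
        if elements[i] not in _HYDROPHOBIC_ELEMENTS or elements[j] not in _HYDROPHOBIC_ELEMENTS:
            continue
        if residue_key[i] == residue_key[j]:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        out.append(Interaction(kind="hydrophobic", donor_index=i, acceptor_index=j,
                               energy=0.0, distance=d))
    return out


def filter_by_cutoff(
    interactions: Iterable[Interaction],
    cutoff: float | str = "default",
) -> list[Interaction]:
    """Keep hydrogen bonds with energy ≤ cutoff; pass other kinds through.

    ``cutoff="default"`` keeps every hydrogen bond, including the weakest;
    a numeric cutoff (kcal/mol, typically negative) removes the weak tail.
    """
    items = list(interactions)
    if cutoff == "default":
        return items
    c = float(cutoff)
    if math.isnan(c):
        raise ValueError("cutoff must be a finite number or 'default'")
    return [ia for ia in items if ia.kind != "hbond" or ia.energy <= c]


def write_interactions_tsv(interactions: Sequence[Interaction], path: str | Path) -> None:
    """Export detected interactions as TSV (kind, donor, acceptor, distance, energy)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["kind", "donor", "acceptor", "distance", "energy"])
        for ia in interactions:
            w.writerow([ia.kind, ia.donor_index, ia.acceptor_index,
                        f"{ia.distance:.4f}", f"{ia.energy:.4f}"])
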