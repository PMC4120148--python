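"""Constraint frameworks: bar-joint and body-bar-hinge (BBH).

A bar-joint framework is the classical rigidity-theory object (universal
joints, fixed-length bars); it is used here for 2D sanity checks of the
rigidity machinery. The BBH framework is the production model: rigid bodies
connected by bars (one scalar constraint) and hinges (five constraints,
leaving one relative rotation about the hinge line). The *fine* model has
one body per atom with every covalent bond and retained hydrogen bond as a
hinge along the bond axis; *coarsening* over a rigid cluster decomposition
replaces each cluster by a single body, keeping only inter-cluster
constraints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .interactions import Interaction, filter_by_cutoff
from .structure_model import Molecule

if TYPE_CHECKING:  # pragma: no cover
    from .decomposition import ClusterDecomposition

__all__ = [
    "BarJointFramework",
    "Bar",
    "Hinge",
    "BBHFramework",
    "build_fine_framework",
    "coarsen",
    "framework_to_json",
    "framework_from_json",
]


@dataclass
class BarJointFramework:
    """Universal joints constrained by fixed-length bars, in 2D or 3D."""

    dimension: int
    joints: np.ndarray  # (n_joints, dimension)
    bars: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.dimension not in (2, 3):
            raise ValueError("dimension must be 2 or 3")
        self.joints = np.asarray(self.joints, dtype=float)
        if self.joints.ndim != 2 or self.joints.shape[1] != self.dimension:
            raise ValueError("joints must be an (n, dimension) array")
        n = len(self.joints)
        seen = set()
        norm = []
        for i, j in self.bars:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"invalid bar ({i}, {j})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bar {key}")
            seen.add(key)
            norm.append(key)
        self.bars = norm

    @property
    def n_joints(self) -> int:
        return len(self.joints)


@dataclass(frozen=True)
class Bar:
    """Distance constraint between a point on body_a and a point on body_b."""

    body_a: int
    body_b: int
    point_a: tuple[float, float, float]
    point_b: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.body_a == self.body_b:
            raise ValueError("bar must connect two distinct bodies")


@dataclass(frozen=True)
class Hinge:
    """Shared rotation axis between two bodies: 5 constraints, 1 relative DOF."""

    body_a: int
    body_b: int
    axis_point: tuple[float, float, float]
    axis_direction: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.body_a == self.body_b:
            raise ValueError("hinge must connect two distinct bodies")
        norm = float(np.linalg.norm(self.axis_direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("hinge axis_direction must be a unit vector")


def make_hinge(body_a: int, body_b: int, p: Sequence[float], q: Sequence[float]) -> Hinge:
    """Hinge along the line through points p and q (e.g. a bond axis)."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    d = q - p
    norm = float(np.linalg.norm(d))
    if norm < 1e-9:
        raise ValueError("degenerate hinge: coincident axis points")
    d = d / norm
    return Hinge(body_a, body_b, tuple(p), tuple(float(x) for x in d))


@dataclass
class BBHFramework:
    """A body-bar-hinge framework over ``n`` rigid bodies.

    ``body_members`` maps each body to the atom indices it contains (a
    singleton per atom in the fine model); it may be empty lists for
    abstract frameworks that carry no atoms.
    """

    n: int
    bars: list[Bar] = field(default_factory=list)
    hinges: list[Hinge] = field(default_factory=list)
    body_members: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("framework needs at least one body")
        if not self.body_members:
            self.body_members = [[] for _ in range(self.n)]
        if len(self.body_members) != self.n:
            raise ValueError("body_members length must equal n")
        for c in list(self.bars) + list(self.hinges):
            if not (0 <= c.body_a < self.n and 0 <= c.body_b < self.n):
                raise ValueError("constraint references an invalid body id")

    @property
    def n_constraints(self) -> int:
        return len(self.bars) + len(self.hinges)

    def constraint_pairs(self) -> list[tuple[int, int]]:
        """Body-id pairs (normalized) of every bar and hinge."""
        return [
            (min(c.body_a, c.body_b), max(c.body_a, c.body_b))
            for c in list(self.bars) + list(self.hinges)
        ]


def build_fine_framework(
    molecule: Molecule,
    interactions: Iterable[Interaction] = (),
    cutoff: float | str = "default",
    merge_terminal_atoms: bool = False,
) -> BBHFramework:
    """Build the atom-level BBH framework of a molecule.

    One body per atom. Every covalent bond and every hydrogen bond retained
    at ``cutoff`` becomes a hinge whose axis runs through the two bonded
    atoms (for H-bonds: donor and acceptor); hydrophobic contacts become
    bars between the contacting atoms. With ``merge_terminal_atoms`` each
    atom with a single covalent neighbor is absorbed into that neighbor's
    body (it carries no extra rigidity information of its own).
    """
    if not molecule.covalent_bonds:
        raise ValueError("structure has no constraints: no covalent bonds on molecule")
    coords = molecule.coordinates
    n_atoms = len(molecule)

    atom_body = list(range(n_atoms))
    if merge_terminal_atoms:
        adj = molecule.bond_neighbors()
        for i in range(n_atoms):
            if len(adj[i]) == 1:
                atom_body[i] = next(iter(adj[i]))
        # compress chains (terminal merged into another terminal's neighbor)
        for i in range(n_atoms):
            while atom_body[atom_body[i]] != atom_body[i]:
                atom_body[i] = atom_body[atom_body[i]]
        remap = {b: k for k, b in enumerate(sorted(set(atom_body)))}
        atom_body = [remap[b] for b in atom_body]
    n_bodies = max(atom_body) + 1

    members: list[list[int]] = [[] for _ in range(n_bodies)]
    for a, b in enumerate(atom_body):
        members[b].append(a)

    hinges: list[Hinge] = []
    bars: list[Bar] = []
    for i, j in sorted(molecule.covalent_bonds):
        bi, bj = atom_body[i], atom_body[j]
        if bi == bj:
            continue
        hinges.append(make_hinge(bi, bj, coords[i], coords[j]))
    for ia in filter_by_cutoff(interactions, cutoff):
        bi, bj = atom_body[ia.donor_index], atom_body[ia.acceptor_index]
        if bi == bj:
            continue
        if ia.kind == "hbond":
            hinges.append(make_hinge(bi, bj, coords[ia.donor_index], coords[ia.acceptor_index]))
        else:
            bars.append(
                Bar(bi, bj, tuple(coords[ia.donor_index]), tuple(coords[ia.acceptor_index]))
            )
    return BBHFramework(n=n_bodies, bars=bars, hinges=hinges, body_members=members)


def _same_hinge_axis(a: Hinge, b: Hinge, tol: float = 1e-9) -> bool:
    da = np.asarray(a.axis_direction)
    db = np.asarray(b.axis_direction)
    if np.linalg.norm(np.cross(da, db)) > tol:
        return False
    offset = np.asarray(b.axis_point) - np.asarray(a.axis_point)
    return bool(np.linalg.norm(np.cross(offset, da)) <= tol * max(1.0, np.linalg.norm(offset)))


def coarsen(framework: BBHFramework, decomposition: "ClusterDecomposition") -> BBHFramework:
    """Collapse each rigid cluster to a single body.

    Constraints internal to a cluster are dropped; constraints spanning two
    clusters keep their geometry. Duplicate hinges on the same axis between
    the same cluster pair (e.g. consecutive collinear bonds) are
    deduplicated. Body ``k`` of the coarse framework is cluster ``k``, so
    cluster labels remain valid body ids.
    """
    body_cluster = decomposition.body_labels
    if len(body_cluster) != framework.n:
        raise ValueError("decomposition does not cover the framework's bodies")
    k = decomposition.n_clusters

    members: list[list[int]] = [[] for _ in range(k)]
    for body, cl in enumerate(body_cluster):
        members[cl].extend(framework.body_members[body])
    for m in members:
        m.sort()

    hinges: list[Hinge] = []
    bars: list[Bar] = []
    for h in framework.hinges:
        ca, cb = body_cluster[h.body_a], body_cluster[h.body_b]
        if ca == cb:
            continue
        nh = Hinge(min(ca, cb), max(ca, cb), h.axis_point, h.axis_direction)
        if any(
            nh.body_a == e.body_a and nh.body_b == e.body_b and _same_hinge_axis(nh, e, 1e-7)
            for e in hinges
        ):
            continue
        hinges.append(nh)
    for b in framework.bars:
        ca, cb = body_cluster[b.body_a], body_cluster[b.body_b]
        if ca == cb:
            continue
        bars.append(Bar(min(ca, cb), max(ca, cb), b.point_a, b.point_b))
    return BBHFramework(n=k, bars=bars, hinges=hinges, body_members=members)


def framework_to_json(framework: BBHFramework, path: str | Path | None = None) -> str:
    """Serialize a BBH framework (bodies, bars, hinges with coordinates)."""
    doc = {
        "n_bodies": framework.n,
        "body_members": framework.body_members,
        "bars": [
            {"body_a": b.body_a, "body_b": b.body_b,
             "point_a": list(b.point_a), "point_b": list(b.point_b)}
            for b in framework.bars
        ],
        "hinges": [
            {"body_a": h.body_a, "body_b": h.body_b,
             "axis_point": list(h.axis_point), "axis_direction": list(h.axis_direction)}
            for h in framework.hinges
        ],
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def framework_from_json(source: str | Path) -> BBHFramework:
    """Load a BBH framework from :func:`framework_to_json` output (text or path)."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).exists()):
        source = Path(source).read_text()
    doc = json.loads(source)
    return BBHFramework(
        n=int(doc["n_bodies"]),
        body_members=[list(map(int, m)) for m in doc["body_members"]],
        bars=[
            Bar(int(b["body_a"]), int(b["body_b"]),
                tuple(b["point_a"]), tuple(b["point_b"]))
            for b in doc["bars"]
        ],
        hinges=[
            Hinge(int(h["body_a"]), int(h["body_b"]),
                  tuple(h["axis_point"]), tuple(h["axis_direction"]))
            for h in doc["hinges"]
        ],
    )
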