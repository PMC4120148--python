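"""Deterministic synthetic fixtures with known ground truth.

Everything the test-suite and the examples need is generated here at run
time: generic planar bar-joint mechanisms, random body-bar-hinge frameworks
for cross-checking the pebble game against the algebraic rank, a two-block
hinge fixture whose axis of motion is known by construction, idealized
peptide and hydrogen-bond geometries, and a desk-scale "toy protein" — two
covalently rigid atom blocks joined by a sparse linker and a few weak,
deliberately bent hydrogen bonds so that the energy-cutoff search has a
known separating value. The toy structures use idealized bond lengths, not
physically realistic chemistry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .decomposition import ClusterDecomposition
from .frameworks import Bar, BarJointFramework, BBHFramework, Hinge, make_hinge
from .structure_model import Atom, Molecule

__all__ = [
    "HingeFixture",
    "ToyProtein",
    "make_four_bar",
    "make_hinge_fixture",
    "make_random_framework",
    "make_toy_protein",
    "make_toy_peptide",
    "make_hbond_ladder",
]


def make_four_bar(
    dimension: int = 2, seed: int = 0, with_diagonal: bool = False
) -> BarJointFramework:
    """Generic planar 4-joint cycle: the classic 1-DOF four-bar mechanism.

    Joints sit at perturbed square corners (perturbation seeded, so the
    framework is generic); bars form the 4-cycle, plus one diagonal when
    ``with_diagonal`` — which stabilizes the mechanism to 0 DOF.
    """
    if dimension != 2:
        raise ValueError("the four-bar fixture is planar")
    rng = np.random.default_rng(seed)
    corners = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    joints = corners + rng.uniform(-0.2, 0.2, size=(4, 2))
    bars = [(0, 1), (1, 2), (2, 3), (3, 0)]
    if with_diagonal:
        bars.append((0, 2))
    return BarJointFramework(dimension=2, joints=joints, bars=bars)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, float)
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("degenerate direction vector")
    return v / n


def _perpendicular(d: np.ndarray) -> np.ndarray:
    probe = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(d, probe))


def _spread_points(center: np.ndarray, count: int, rng: np.random.Generator,
                   spacing: float = 4.0) -> np.ndarray:
    """Generic, well-separated points around a center (rejection sampling)."""
    pts: list[np.ndarray] = []
    radius = spacing * max(1.5, count ** (1 / 3))
    while len(pts) < count:
        cand = center + rng.uniform(-radius, radius, size=3)
        if all(np.linalg.norm(cand - p) >= spacing * 0.9 for p in pts):
            pts.append(cand)
    return np.array(pts)


@dataclass
class HingeFixture:
    """Two rigid blocks joined by a single hinge with a known axis."""

    framework: BBHFramework
    molecule: Molecule
    decomposition: ClusterDecomposition
    pdb_text: str
    axis_point: np.ndarray
    axis_direction: np.ndarray
    clash_pair: tuple[int, int] | None = None


def make_hinge_fixture(
    block_size: int = 6,
    axis_point=(0.0, 0.0, 0.0),
    axis_direction=(0.0, 0.0, 1.0),
    seed: int = 0,
    with_clash: bool = False,
    with_cross_bar: bool = False,
) -> HingeFixture:
    """Two multi-atom rigid bodies joined by one hinge on a requested line.

    Pinning block 0 leaves exactly one degree of freedom: rotation of block
    1 about the line through ``axis_point`` with direction
    ``axis_direction`` — the pipeline's ground truth. ``with_clash`` adds an
    atom pair that touches at rest so rotation in the positive sense drives
    a steric clash; ``with_cross_bar`` adds one generic bar between the
    blocks, which removes the last degree of freedom.
    """
    if block_size < 4:
        raise ValueError("block_size must be at least 4")
    rng = np.random.default_rng(seed)
    a = np.asarray(axis_point, float)
    d = _unit(axis_direction)
    e1 = _perpendicular(d)
    e2 = np.cross(d, e1)

    offset = 5.0 + 2.0 * block_size ** (1 / 3)
    centers = [a - offset * e1 + 2.0 * d, a + offset * e1 - 2.0 * d]
    blocks = [_spread_points(c, block_size, rng) for c in centers]

    clash_pair = None
    if with_clash:
        # x1 on block 1 whose velocity under + rotation points at x0 on block 0
        x1 = a + 6.0 * e1 + 6.0 * e2
        vel = np.cross(d, x1 - a)
        x0 = x1 + 3.55 * _unit(vel)
        blocks[0] = np.vstack([blocks[0], x0])
        blocks[1] = np.vstack([blocks[1], x1])
        clash_pair = (len(blocks[0]) - 1, len(blocks[0]) + len(blocks[1]) - 1)

    atoms: list[Atom] = []
    bonds: set[tuple[int, int]] = set()
    members: list[list[int]] = [[], []]
    for body, pts in enumerate(blocks):
        start = len(atoms)
        for k, p in enumerate(pts):
            atoms.append(
                Atom(
                    serial=len(atoms) + 1,
                    name=f"C{k + 1}",
                    element="C",
                    residue_name="BLK",
                    residue_number=body + 1,
                    chain="A",
                    position=tuple(float(x) for x in p),
                )
            )
            members[body].append(start + k)
        for k in range(len(pts) - 1):
            bonds.add((start + k, start + k + 1))
    molecule = Molecule(atoms=atoms, covalent_bonds=bonds)

    hinge = Hinge(0, 1, tuple(a), tuple(d))
    bars: list[Bar] = []
    if with_cross_bar:
        bars.append(Bar(0, 1, tuple(blocks[0][0]), tuple(blocks[1][0])))
    framework = BBHFramework(n=2, bars=bars, hinges=[hinge], body_members=members)

    decomposition = ClusterDecomposition(
        body_labels=[0, 1],
        assignment={i: (0 if i in members[0] else 1) for i in range(len(atoms))},
        sizes=[len(members[0]), len(members[1])],
    )
    from .structure_model import write_pdb
    import os
    import tempfile

    # render PDB text via the standard writer
    fd, tmp = tempfile.mkstemp(suffix=".pdb")
    os.close(fd)
    try:
        write_pdb(molecule, None, tmp)
        pdb_text = open(tmp).read()
    finally:
        os.unlink(tmp)

    return HingeFixture(
        framework=framework,
        molecule=molecule,
        decomposition=decomposition,
        pdb_text=pdb_text,
        axis_point=a,
        axis_direction=d,
        clash_pair=clash_pair,
    )


def make_random_framework(
    n_bodies: int, n_bars: int, n_hinges: int, seed: int = 0
) -> BBHFramework:
    """Random generic BBH framework (reproducible), for oracle cross-checks."""
    if n_bodies < 1 or n_bars < 0 or n_hinges < 0:
        raise ValueError("counts must be non-negative (and at least one body)")
    rng = np.random.default_rng(seed)
    bars = []
    hinges = []
    if n_bodies >= 2:
        for _ in range(n_bars):
            u, v = rng.choice(n_bodies, size=2, replace=False)
            p = rng.normal(0, 3, size=3)
            q = rng.normal(0, 3, size=3)
            bars.append(Bar(int(u), int(v), tuple(p), tuple(q)))
        for _ in range(n_hinges):
            u, v = rng.choice(n_bodies, size=2, replace=False)
            a = rng.normal(0, 3, size=3)
            d = _unit(rng.normal(0, 1, size=3))
            hinges.append(Hinge(int(u), int(v), tuple(a), tuple(d)))
    return BBHFramework(n=n_bodies, bars=bars, hinges=hinges)


def make_toy_peptide() -> tuple[Molecule, set[tuple[int, int]]]:
    """Idealized 2-residue alanine-like fragment with known bond topology.

    Returns the molecule (without bonds attached) and the ground-truth
    covalent bond set for bond-perception tests.
    """
    # idealized backbone with standard bond lengths, zigzag in the xy plane
    def place(prev: np.ndarray, length: float, angle_deg: float) -> np.ndarray:
        ang = math.radians(angle_deg)
        return prev + length * np.array([math.cos(ang), math.sin(ang), 0.0])

    coords: list[np.ndarray] = []
    names: list[tuple[str, str, int]] = []  # (name, element, residue)

    n1 = np.array([0.0, 0.0, 0.0])
    ca1 = place(n1, 1.46, 20)
    c1 = place(ca1, 1.52, -35)
    o1 = c1 + 1.23 * np.array([0.2, -0.9, 0.37])
    o1 = c1 + 1.23 * (o1 - c1) / np.linalg.norm(o1 - c1)
    cb1 = ca1 + 1.53 * np.array([0.1, 0.6, 0.79])
    cb1 = ca1 + 1.53 * (cb1 - ca1) / np.linalg.norm(cb1 - ca1)
    n2 = place(c1, 1.33, 30)
    ca2 = place(n2, 1.46, -25)
    c2 = place(ca2, 1.52, 40)
    o2 = c2 + 1.23 * np.array([-0.1, 0.9, -0.42])
    o2 = c2 + 1.23 * (o2 - c2) / np.linalg.norm(o2 - c2)
    cb2 = ca2 + 1.53 * np.array([0.0, -0.5, 0.87])
    cb2 = ca2 + 1.53 * (cb2 - ca2) / np.linalg.norm(cb2 - ca2)

    for pos, (name, el, res) in [
        (n1, ("N", "N", 1)), (ca1, ("CA", "C", 1)), (c1, ("C", "C", 1)),
        (o1, ("O", "O", 1)), (cb1, ("CB", "C", 1)),
        (n2, ("N", "N", 2)), (ca2, ("CA", "C", 2)), (c2, ("C", "C", 2)),
        (o2, ("O", "O", 2)), (cb2, ("CB", "C", 2)),
    ]:
        coords.append(pos)
        names.append((name, el, res))

    atoms = [
        Atom(serial=i + 1, name=nm, element=el, residue_name="ALA",
             residue_number=res, chain="A", position=tuple(float(x) for x in coords[i]))
        for i, (nm, el, res) in enumerate(names)
    ]
    truth = {(0, 1), (1, 2), (2, 3), (1, 4), (2, 5), (5, 6), (6, 7), (7, 8), (6, 9)}
    return Molecule(atoms=atoms), truth


def make_hbond_ladder(n_rungs: int = 4, rung_spacing: float = 10.0) -> Molecule:
    """A molecule with exactly ``n_rungs`` ideal N-H···O hydrogen-bond
    geometries (donor-acceptor 2.9 Å, linear), arranged like the i→i+4
    ladder of an alpha helix but spread far enough apart that no other
    candidate pair passes the screens. Covalent bonds are attached.
    """
    atoms: list[Atom] = []
    bonds: set[tuple[int, int]] = set()
    for r in range(n_rungs):
        base = np.array([0.0, 0.0, r * rung_spacing])
        # donor fragment: C - N - H, acceptor fragment: O - C
        c_d = base + np.array([-1.4, 0.6, 0.0])
        n = base
        h = base + np.array([1.0, 0.0, 0.0])
        o = base + np.array([2.9, 0.0, 0.0])
        c_a = o + np.array([1.2, 0.6, 0.0])
        start = len(atoms)
        for k, (pos, name, el, res) in enumerate([
            (c_d, "CD", "C", 2 * r + 1), (n, "N", "N", 2 * r + 1),
            (h, "H", "H", 2 * r + 1), (o, "O", "O", 2 * r + 2),
            (c_a, "CA", "C", 2 * r + 2),
        ]):
            atoms.append(Atom(serial=start + k + 1, name=name, element=el,
                              residue_name="GLY", residue_number=res, chain="A",
                              position=tuple(float(x) for x in pos)))
        bonds |= {(start, start + 1), (start + 1, start + 2), (start + 3, start + 4)}
    return Molecule(atoms=atoms, covalent_bonds=bonds)


@dataclass
class ToyProtein:
    """Desk-scale hinge structure with constructed cluster ground truth."""

    pdb_text: str
    domain_a_residues: list[int]
    domain_b_residues: list[int]
    hinge_residue: int
    linker_center: np.ndarray
    bridge_energy_range: tuple[float, float]  # designed weak H-bond energies


def _lattice(dims: tuple[int, int, int], spacing: float, origin: np.ndarray,
             rng: np.random.Generator, jitter: float) -> np.ndarray:
    pts = []
    for ix in range(dims[0]):
        for iy in range(dims[1]):
            for iz in range(dims[2]):
                pts.append(origin + spacing * np.array([ix, iy, iz], float))
    pts = np.array(pts)
    return pts + rng.uniform(-jitter, jitter, size=pts.shape)


def make_toy_protein(n_residues: int = 6, hinge_position: int = 3, seed: int = 0) -> ToyProtein:
    """Two covalently rigid atom blocks joined by a one-atom linker.

    Each block is a jittered 2×2×L lattice of carbons at 1.8 Å spacing
    (dense enough that distance-based bond perception makes it a single
    rigid cluster); the gap between facing block surfaces is 3.4 Å,
    crossed by one linker carbon (two collinear-ish bonds, the hinge) and
    by three deliberately bent N-H···O bridges whose energies sit near
    -0.8 kcal/mol — so the default decomposition merges the domains and
    the cutoff search separates them once the bridges fall away.
    """
    if n_residues < 6:
        raise ValueError("need at least 6 residues")
    if not (1 < hinge_position < n_residues):
        raise ValueError("hinge_position must be interior")
    rng = np.random.default_rng(seed)
    spacing, jitter, gap = 1.8, 0.02, 3.4
    n_a = hinge_position - 1
    n_b = n_residues - hinge_position
    dims_a = (2, 2, max(2, n_a))
    dims_b = (2, 2, max(2, n_b))

    block_a = _lattice(dims_a, spacing, np.zeros(3), rng, jitter)
    bx = spacing * (dims_a[0] - 1) + gap
    block_b = _lattice(dims_b, spacing, np.array([bx, 0.0, 0.0]), rng, jitter)

    def lat_index(dims: tuple[int, int, int], ix: int, iy: int, iz: int) -> int:
        return ix * dims[1] * dims[2] + iy * dims[2] + iz

    # linker carbon midway between the two (iy=0, iz=0) corner surface atoms
    a_anchor = lat_index(dims_a, dims_a[0] - 1, 0, 0)
    linker = 0.5 * (block_a[a_anchor] + block_b[0])

    # bridge sites: facing surface pairs (same iy, iz) away from the linker corner
    bridge_pairs: list[tuple[int, int]] = []
    for iy in range(2):
        for iz in range(min(dims_a[2], dims_b[2])):
            if (iy, iz) == (0, 0):
                continue
            bridge_pairs.append(
                (lat_index(dims_a, dims_a[0] - 1, iy, iz), lat_index(dims_b, 0, iy, iz))
            )
    bridge_pairs = bridge_pairs[:3]
    bridge_a = {p[0] for p in bridge_pairs}
    bridge_b = {p[1] for p in bridge_pairs}

    atoms: list[Atom] = []

    def add(pos: np.ndarray, name: str, el: str, res: int) -> int:
        atoms.append(Atom(serial=len(atoms) + 1, name=name, element=el,
                          residue_name="TOY", residue_number=res, chain="A",
                          position=tuple(float(x) for x in pos)))
        return len(atoms) - 1

    def residue_of(k: int, n_block: int, first: int, count: int) -> int:
        return first + min(count - 1, k * count // n_block)

    for k, p in enumerate(block_a):
        res = residue_of(k, len(block_a), 1, n_a)
        if k in bridge_a:
            # H 45° off the N→O line (bent, hence weak, bridge), tilted toward
            # the open side of the lattice so it bonds to its N only
            iy = (k // dims_a[2]) % dims_a[1]
            h_dir = _unit(np.array([1.0, 1.0 if iy == dims_a[1] - 1 else -1.0, 0.0]))
            add(p, f"N{k + 1}", "N", res)
            add(p + 1.0 * h_dir, f"H{k + 1}", "H", res)
        else:
            add(p, f"C{k + 1}", "C", res)
    add(linker, "CL", "C", hinge_position)
    for k, p in enumerate(block_b):
        res = residue_of(k, len(block_b), hinge_position + 1, n_b)
        add(p, ("O" if k in bridge_b else "C") + f"{k + 1}",
            "O" if k in bridge_b else "C", res)

    molecule = Molecule(atoms=atoms)
    from .structure_model import write_pdb
    import os, tempfile

    fd, tmp = tempfile.mkstemp(suffix=".pdb")
    os.close(fd)
    try:
        write_pdb(molecule, None, tmp)
        pdb_text = open(tmp).read()
    finally:
        os.unlink(tmp)

    return ToyProtein(
        pdb_text=pdb_text,
        domain_a_residues=list(range(1, hinge_position)),
        domain_b_residues=list(range(hinge_position + 1, n_residues + 1)),
        hinge_residue=hinge_position,
        linker_center=linker,
        bridge_energy_range=(-1.5, -0.3),
    )
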