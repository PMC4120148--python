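"""Rigid cluster decomposition via the (6,6) pebble game.

Generic rigidity of 3D body-bar-hinge frameworks has a purely combinatorial
characterization (Tay): on the body multigraph where a bar contributes one
edge and a hinge five parallel edges, independent constraints are exactly
the edges of a (6,6)-sparse subgraph. The pebble game computes this matroid
rank incrementally: every body starts with six pebbles, inserting an edge
requires gathering seven pebbles on its endpoints, and a successful
insertion consumes one. Remaining free pebbles minus six give the internal
degrees of freedom; a pair of bodies is rigidly connected exactly when a
seventh pebble can no longer be gathered on it, and since zero relative
motion is transitive these pairs union into the rigid clusters.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .frameworks import BBHFramework, build_fine_framework
from .interactions import Interaction
from .structure_model import Molecule

__all__ = [
    "ClusterDecomposition",
    "PebbleGame",
    "dof_pebble",
    "rigid_clusters",
    "find_cutoff",
    "CutoffSearchError",
    "majority_cluster",
    "write_decomposition_tsv",
    "read_decomposition_tsv",
]

K_PEBBLES = 6  # pebbles per body: 3D rigid body DOF
L_SPARSITY = 6  # (6,6)-sparsity: subtracted trivial motions


@dataclass
class ClusterDecomposition:
    """Partition of bodies (and their atoms) into rigid clusters.

    Labels run 0..k-1 with cluster sizes non-increasing (cluster 0 is the
    largest); ``assignment`` maps atom index -> label when the framework
    carries atoms, and ``body_labels`` maps body id -> label always.
    """

    body_labels: list[int]
    assignment: dict[int, int] = field(default_factory=dict)
    sizes: list[int] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return max(self.body_labels) + 1 if self.body_labels else 0

    def atoms_of(self, label: int) -> list[int]:
        return sorted(a for a, c in self.assignment.items() if c == label)


class PebbleGame:
    """The (6,6) pebble game on a body multigraph."""

    def __init__(self, n: int):
        if n < 1:
            raise ValueError("need at least one body")
        self.n = n
        self.pebbles = [K_PEBBLES] * n
        self.out: list[dict[int, int]] = [dict() for _ in range(n)]
        self.rank = 0

    def _find_pebble(self, root: int, avoid: int) -> bool:
        """Move one free pebble to ``root`` by a path reversal (DFS), never
        taking one from ``avoid``."""
        seen = [False] * self.n
        seen[root] = True
        seen[avoid] = True
        parent = {root: -1}
        stack = [root]
        found = -1
        while stack:
            u = stack.pop()
            for w, mult in self.out[u].items():
                if mult <= 0 or seen[w]:
                    continue
                seen[w] = True
                parent[w] = u
                if self.pebbles[w] > 0:
                    found = w
                    stack.clear()
                    break
                stack.append(w)
        if found < 0:
            return False
        # reverse the tree path root -> found, carrying the pebble back
        w = found
        while parent[w] != -1:
            u = parent[w]
            self.out[u][w] -= 1
            if self.out[u][w] == 0:
                del self.out[u][w]
            self.out[w][u] = self.out[w].get(u, 0) + 1
            w = u
        self.pebbles[found] -= 1
        self.pebbles[root] += 1
        return True

    def gather(self, u: int, v: int, target: int) -> bool:
        """Try to accumulate ``target`` pebbles on {u, v}."""
        while self.pebbles[u] + self.pebbles[v] < target:
            if self.pebbles[u] < K_PEBBLES and self._find_pebble(u, v):
                continue
            if self.pebbles[v] < K_PEBBLES and self._find_pebble(v, u):
                continue
            return False
        return True

    def insert_edge(self, u: int, v: int) -> bool:
        """Insert one multigraph edge; True iff it is independent."""
        if u == v:
            raise ValueError("self-loops are not part of the model")
        if not self.gather(u, v, L_SPARSITY + 1):
            return False
        self.pebbles[u] -= 1
        self.out[u][v] = self.out[u].get(v, 0) + 1
        self.rank += 1
        return True

    def pair_rigid(self, u: int, v: int) -> bool:
        """True when no further independent constraint fits between u and v,
        i.e. the pair has zero relative motion."""
        return not self.gather(u, v, L_SPARSITY + 1)

    @property
    def free_pebbles(self) -> int:
        return sum(self.pebbles)


def _play(framework: BBHFramework) -> PebbleGame:
    game = PebbleGame(framework.n)
    for bar in framework.bars:
        game.insert_edge(bar.body_a, bar.body_b)
    for hinge in framework.hinges:
        for _ in range(5):
            game.insert_edge(hinge.body_a, hinge.body_b)
    return game


def dof_pebble(framework: BBHFramework) -> int:
    """Internal degrees of freedom (excluding the 6 trivial motions)."""
    return _play(framework).free_pebbles - L_SPARSITY


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def rigid_clusters(framework: BBHFramework) -> ClusterDecomposition:
    """Partition the framework's bodies into maximal rigid clusters.

    Bodies sharing a constraint are tested for mutual rigidity in the final
    pebble-game state and unioned when rigid; transitivity and the
    connectivity of tight subgraphs make edge-restricted testing complete.
    Clusters are labeled by decreasing size (atom count when atoms are
    present, else body count), ties broken by smallest member atom/body.
    """
    game = _play(framework)
    uf = _UnionFind(framework.n)
    for u, v in sorted(set(framework.constraint_pairs())):
        if uf.find(u) != uf.find(v) and game.pair_rigid(u, v):
            uf.union(u, v)

    groups: dict[int, list[int]] = {}
    for body in range(framework.n):
        groups.setdefault(uf.find(body), []).append(body)

    def group_key(bodies: list[int]) -> tuple[int, int]:
        atoms = [a for b in bodies for a in framework.body_members[b]]
        size = len(atoms) if atoms else len(bodies)
        smallest = min(atoms) if atoms else min(bodies)
        return (-size, smallest)

    ordered = sorted(groups.values(), key=group_key)
    body_labels = [0] * framework.n
    assignment: dict[int, int] = {}
    sizes: list[int] = []
    for label, bodies in enumerate(ordered):
        atoms = sorted(a for b in bodies for a in framework.body_members[b])
        for b in bodies:
            body_labels[b] = label
        for a in atoms:
            assignment[a] = label
        sizes.append(len(atoms) if atoms else len(bodies))
    return ClusterDecomposition(body_labels=body_labels, assignment=assignment, sizes=sizes)


def majority_cluster(decomposition: ClusterDecomposition, atom_indices: Iterable[int]) -> int:
    """The cluster containing the majority (plurality) of the given atoms."""
    counts: dict[int, int] = {}
    for a in atom_indices:
        label = decomposition.assignment.get(a)
        if label is not None:
            counts[label] = counts.get(label, 0) + 1
    if not counts:
        raise ValueError("none of the given atoms is covered by the decomposition")
    return min(counts, key=lambda c: (-counts[c], c))


class CutoffSearchError(RuntimeError):
    """No energy cutoff separates the two domains; carries the last decomposition."""

    def __init__(self, message: str, decomposition: ClusterDecomposition):
        super().__init__(message)
        self.decomposition = decomposition


def find_cutoff(
    molecule: Molecule,
    interactions: Sequence[Interaction],
    domain_a: Iterable[int],
    domain_b: Iterable[int],
    step: float = 0.25,
    floor: float = -10.0,
) -> tuple[float | str, ClusterDecomposition]:
    """Find the first H-bond energy cutoff putting two domains in distinct clusters.

    ``domain_a``/``domain_b`` are disjoint sets of atom indices (use
    :func:`hingeaxis.pipeline.residues_to_atoms` to build them from residue
    ranges). The scan starts at ``"default"`` (all hydrogen bonds modeled)
    and tightens by ``step`` kcal/mol until the majority clusters of the two
    domains differ, mirroring the iterative weakest-bond removal used to
    prepare hinge proteins for motion analysis.
    """
    atoms_a = sorted(set(domain_a))
    atoms_b = sorted(set(domain_b))
    if not atoms_a or not atoms_b:
        raise ValueError("domains must be non-empty")
    if set(atoms_a) & set(atoms_b):
        raise ValueError("domains must be disjoint")

    cutoffs: list[float | str] = ["default"]
    c = -step
    while c >= floor - 1e-9:
        cutoffs.append(round(c, 10))
        c -= step

    decomposition = None
    for cutoff in cutoffs:
        framework = build_fine_framework(molecule, interactions, cutoff)
        decomposition = rigid_clusters(framework)
        if majority_cluster(decomposition, atoms_a) != majority_cluster(decomposition, atoms_b):
            return cutoff, decomposition
    assert decomposition is not None
    raise CutoffSearchError(
        f"no hydrogen-bond cutoff down to {floor} kcal/mol separates the two domains",
        decomposition,
    )


def write_decomposition_tsv(
    molecule: Molecule, decomposition: ClusterDecomposition, path: str | Path
) -> None:
    """Export the atom-level decomposition as TSV (atom_serial, cluster_label)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["atom_serial", "cluster_label"])
        for idx, atom in enumerate(molecule.atoms):
            label = decomposition.assignment.get(idx)
            if label is not None:
                w.writerow([atom.serial, label])


def read_decomposition_tsv(molecule: Molecule, path: str | Path) -> ClusterDecomposition:
    """Import a decomposition (e.g. from an external rigidity tool).

    The file maps atom serials to cluster labels; labels are re-ranked by
    decreasing cluster size to satisfy the labeling convention. Body labels
    are per-atom (fine model: one body per atom).
    """
    serial_to_index = {a.serial: i for i, a in enumerate(molecule.atoms)}
    raw: dict[int, int] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0] == "atom_serial":
                continue
            serial, label = int(row[0]), int(row[1])
            idx = serial_to_index.get(serial)
            if idx is None:
                raise ValueError(f"decomposition references unknown atom serial {serial}")
            raw[idx] = label
    missing = set(range(len(molecule))) - set(raw)
    if missing:
        raise ValueError(f"decomposition does not cover {len(missing)} atoms")
    groups: dict[int, list[int]] = {}
    for idx, label in raw.items():
        groups.setdefault(label, []).append(idx)
    ordered = sorted(groups.values(), key=lambda atoms: (-len(atoms), min(atoms)))
    assignment: dict[int, int] = {}
    sizes = []
    for new_label, atoms in enumerate(ordered):
        for a in atoms:
            assignment[a] = new_label
        sizes.append(len(atoms))
    body_labels = [assignment[i] for i in range(len(molecule))]
    return ClusterDecomposition(body_labels=body_labels, assignment=assignment, sizes=sizes)
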