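"""Motion sampling and steric screening.

Each sample draws uniform weights c₁..c_d in [0, 1], forms the motion
vector s = Σ cᵢ·bᵢ from the motion-space basis, slices s into per-body
twists, displaces every atom along its first-order velocity p' = ω×p + v
(scaled so the largest atom displacement equals ``step`` Å), and scores the
displaced coordinates with a repulsion-only soft-sphere clash score — the
dominant varying term of a physics score on such samples is the van der
Waals repulsion, so clashes alone rank steric feasibility. The lowest 5%
by score are retained for twist aggregation.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .decomposition import ClusterDecomposition
from .rigidity_core import MotionSpace
from .structure_model import Molecule, write_pdb
from .twist_analysis import Twist

__all__ = [
    "Sample",
    "draw_weights",
    "combine",
    "displace",
    "steric_score",
    "run_sampling",
    "select_low_energy",
    "write_scores_tsv",
    "VDW_RADII",
]

#: Van der Waals radii in Å (Bondi-style values for protein elements).
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.70

DEFAULT_STEP = 0.5  # Å, largest per-atom displacement of a sample
DEFAULT_N_SAMPLES = 1000
DEFAULT_KEEP_FRACTION = 0.05


@dataclass
class Sample:
    """One sampled motion with its displaced conformation and clash score."""

    index: int
    weights: np.ndarray  # (d,)
    motion_vector: np.ndarray  # (6n,)
    per_body_twists: list[Twist]  # length n
    displaced_coordinates: np.ndarray  # (n_atoms, 3)
    steric_score: float


def draw_weights(d: int, rng: np.random.Generator | int, low: float = 0.0,
                 high: float = 1.0) -> np.ndarray:
    """Draw d independent uniform weight coefficients.

    Default range [0, 1]; pass ``low=-1`` to explore both orientations of
    each basis direction. ``rng`` may be a Generator or an integer seed.
    """
    if d < 1:
        raise ValueError("framework is rigid; no motion to sample")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.uniform(low, high, size=d)


def combine(basis: MotionSpace, weights: Sequence[float]) -> tuple[np.ndarray, list[Twist]]:
    """Linear combination s = Σ cᵢ·bᵢ and its per-body twist slices."""
    weights = np.asarray(weights, float)
    if weights.shape != (basis.d,):
        raise ValueError(f"expected {basis.d} weights, got {weights.shape}")
    s = weights @ basis.basis if basis.d else np.zeros(basis.n_bodies * 6)
    twists = [Twist.from_vector(s[6 * i : 6 * i + 6]) for i in range(basis.n_bodies)]
    return s, twists


def displace(
    molecule: Molecule,
    decomposition: ClusterDecomposition,
    per_body_twists: Sequence[Twist],
    step: float = DEFAULT_STEP,
) -> np.ndarray:
    """Move every atom along its first-order velocity under its cluster's twist.

    Velocities are normalized by the largest atom speed so the maximum
    displacement is exactly ``step`` Å, keeping all samples in the
    infinitesimal regime at a comparable scale. All-zero velocities leave
    the coordinates unchanged.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    coords = molecule.coordinates
    velocities = np.zeros_like(coords)
    for j in range(len(molecule)):
        label = decomposition.assignment.get(j)
        if label is None:
            continue
        t = per_body_twists[label]
        velocities[j] = np.cross(t.omega, coords[j]) + np.asarray(t.v)
    vmax = float(np.linalg.norm(velocities, axis=1).max()) if len(coords) else 0.0
    if vmax <= 1e-15:
        return coords.copy()
    return coords + step * velocities / vmax


def steric_score(
    coordinates: np.ndarray,
    molecule: Molecule,
    _cache: dict | None = None,
) -> float:
    """Repulsion-only soft-sphere clash score (unitless, ≥ 0).

    Sum over atom pairs at least three covalent bonds apart of
    ``max(0, (r_i + r_j) - r)²`` with van der Waals radii r_i; bonded
    (1-2) and angle (1-3) pairs are excluded since their distances are set
    by covalent geometry, not packing.
    """
    coordinates = np.asarray(coordinates, float)
    if coordinates.shape != (len(molecule), 3):
        raise ValueError("coordinate count does not match atom count")
    if _cache is not None and "radii" in _cache:
        radii = _cache["radii"]
        excluded = _cache["excluded"]
    else:
        radii = np.array(
            [VDW_RADII.get(a.element.upper(), DEFAULT_VDW_RADIUS) for a in molecule.atoms]
        )
        excluded = _near_bonded_pairs(molecule)
        if _cache is not None:
            _cache["radii"] = radii
            _cache["excluded"] = excluded
    cutoff = 2 * radii.max()
    tree = cKDTree(coordinates)
    score = 0.0
    for i, j in tree.query_pairs(cutoff):
        key = (min(i, j), max(i, j))
        if key in excluded:
            continue
        overlap = radii[i] + radii[j] - float(
            np.linalg.norm(coordinates[i] - coordinates[j])
        )
        if overlap > 0:
            score += overlap * overlap
    return score


def _near_bonded_pairs(molecule: Molecule) -> set[tuple[int, int]]:
    """Atom pairs within two covalent bonds (1-2 and 1-3 neighbors)."""
    adj = molecule.bond_neighbors()
    pairs: set[tuple[int, int]] = set()
    for i in range(len(molecule)):
        for j in adj[i]:
            pairs.add((min(i, j), max(i, j)))
            for k in adj[j]:
                if k != i:
                    pairs.add((min(i, k), max(i, k)))
    return pairs


def run_sampling(
    molecule: Molecule,
    decomposition: ClusterDecomposition,
    basis: MotionSpace,
    n_samples: int = DEFAULT_N_SAMPLES,
    step: float = DEFAULT_STEP,
    seed: int = 0,
    weight_low: float = 0.0,
    pdb_dir: str | Path | None = None,
) -> list[Sample]:
    """Generate and score ``n_samples`` motion samples (reproducible from seed).

    With ``pdb_dir`` set, each displaced conformation is also written as
    ``sample_{i:04d}.pdb``.
    """
    if basis.d < 1:
        raise ValueError("framework is rigid; no motion to sample")
    if n_samples < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    cache: dict = {}
    out: list[Sample] = []
    if pdb_dir is not None:
        pdb_dir = Path(pdb_dir)
        pdb_dir.mkdir(parents=True, exist_ok=True)
    for i in range(n_samples):
        weights = draw_weights(basis.d, rng, low=weight_low)
        s, twists = combine(basis, weights)
        coords = displace(molecule, decomposition, twists, step=step)
        score = steric_score(coords, molecule, _cache=cache)
        out.append(
            Sample(
                index=i,
                weights=weights,
                motion_vector=s,
                per_body_twists=twists,
                displaced_coordinates=coords,
                steric_score=score,
            )
        )
        if pdb_dir is not None:
            write_pdb(molecule, coords, pdb_dir / f"sample_{i:04d}.pdb")
    return out


def select_low_energy(
    samples: Sequence[Sample], fraction: float = DEFAULT_KEEP_FRACTION
) -> list[Sample]:
    """The ⌈fraction·n⌉ samples of smallest steric score (ties by index)."""
    if not samples:
        raise ValueError("empty sample set")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    keep = math.ceil(fraction * len(samples))
    ranked = sorted(samples, key=lambda s: (s.steric_score, s.index))
    return ranked[:keep]


def write_scores_tsv(
    samples: Sequence[Sample], retained: Sequence[Sample], path: str | Path
) -> None:
    """Scores table: sample_index, weights..., score, retained flag."""
    retained_idx = {s.index for s in retained}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        d = len(samples[0].weights) if samples else 0
        w.writerow(["sample_index", *[f"c{i+1}" for i in range(d)], "steric_score", "retained"])
        for s in samples:
            w.writerow(
                [s.index, *[f"{c:.8f}" for c in s.weights],
                 f"{s.steric_score:.8f}", int(s.index in retained_idx)]
            )
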