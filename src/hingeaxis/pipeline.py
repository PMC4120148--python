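"""End-to-end hinge-axis prediction pipeline.

Wires the stages together: read structure → perceive covalent bonds →
detect hydrogen bonds → rigid cluster decomposition (at a fixed H-bond
energy cutoff, or searching for the first cutoff separating the two chosen
domains) → coarsen to a body-bar-hinge framework of clusters → pin one
cluster → motion-space basis → sample, score and select motions → aggregate
the moving cluster's twists into a mean twist, purity and axis of motion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from . import __version__
from .decomposition import (
    ClusterDecomposition,
    find_cutoff,
    majority_cluster,
    read_decomposition_tsv,
    rigid_clusters,
    write_decomposition_tsv,
)
from .frameworks import build_fine_framework, coarsen
from .interactions import detect_hbonds, detect_hydrophobics
from .rigidity_core import bbh_matrix, null_space, pin
from .sampling import (
    DEFAULT_KEEP_FRACTION,
    DEFAULT_N_SAMPLES,
    DEFAULT_STEP,
    run_sampling,
    select_low_energy,
    write_scores_tsv,
)
from .structure_model import Molecule, infer_covalent_bonds, read_pdb
from .twist_analysis import AxisPrediction, predict_axis
from .viz import write_axis_scripts

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "residues_to_atoms"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run (all randomness derives from ``seed``)."""

    input_path: str | Path
    model_index: int = 0
    chain: str | None = None
    include_hetero: bool = False
    # cluster choice: literal labels, or residue ranges to locate them
    pinned_cluster: int | None = None
    moving_cluster: int | None = None
    pinned_residues: str | None = None  # e.g. "1-88" or "5,6,7"
    moving_residues: str | None = None
    hbond_cutoff: float | str = "default"  # kcal/mol, "default", or "auto"
    hydrophobics: bool = False
    decomposition_file: str | Path | None = None
    n_samples: int = DEFAULT_N_SAMPLES
    keep_fraction: float = DEFAULT_KEEP_FRACTION
    step: float = DEFAULT_STEP
    weight_low: float = 0.0
    seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if not (0 < self.keep_fraction <= 1):
            raise ValueError("keep_fraction must be in (0, 1]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be at least 1")
        has_labels = self.pinned_cluster is not None and self.moving_cluster is not None
        has_ranges = self.pinned_residues is not None and self.moving_residues is not None
        if not (has_labels or has_ranges):
            raise ValueError(
                "choose clusters by labels (pinned_cluster/moving_cluster) "
                "or residue ranges (pinned_residues/moving_residues)"
            )
        if has_labels and self.pinned_cluster == self.moving_cluster:
            raise ValueError("pinned and moving cluster must differ")
        if self.hbond_cutoff == "auto" and not has_ranges:
            raise ValueError("'auto' cutoff search requires residue ranges for both domains")


@dataclass
class PipelineResult:
    prediction: AxisPrediction
    report: dict
    molecule: Molecule
    decomposition: ClusterDecomposition
    files: dict = field(default_factory=dict)


def _parse_residue_spec(spec: str) -> list[int]:
    out: list[int] = []
    for part in str(spec).split(","):
        part = part.strip()
        if "-" in part[1:]:  # allow negative-free simple ranges
            lo, hi = part.split("-", 1)
            out.extend(range(int(lo), int(hi) + 1))
        elif part:
            out.append(int(part))
    if not out:
        raise ValueError(f"empty residue specification {spec!r}")
    return out


def residues_to_atoms(molecule: Molecule, residues: Iterable[int] | str,
                      chain: str | None = None) -> list[int]:
    """Atom indices of the given residue numbers (optionally one chain)."""
    nums = set(_parse_residue_spec(residues)) if isinstance(residues, str) else set(residues)
    return [
        i
        for i, a in enumerate(molecule.atoms)
        if a.residue_number in nums and (chain is None or a.chain == chain)
    ]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full prediction; optionally write report files to ``out_dir``.

    Output files: ``report.json`` (parameters, seed and prediction),
    ``scores.tsv`` (per-sample weights, steric score, retained flag),
    ``clusters.tsv`` (atom → cluster), and Jmol/PyMOL axis scripts.
    """
    molecule = read_pdb(
        config.input_path,
        model_index=config.model_index,
        chain_filter=config.chain,
        include_hetero=config.include_hetero,
    )
    molecule.covalent_bonds = infer_covalent_bonds(molecule)
    hbonds = detect_hbonds(molecule)
    interactions = hbonds + detect_hydrophobics(molecule, enabled=config.hydrophobics)

    atoms_a = atoms_b = None
    if config.pinned_residues is not None:
        atoms_a = residues_to_atoms(molecule, config.pinned_residues, config.chain)
        atoms_b = residues_to_atoms(molecule, config.moving_residues, config.chain)
        if not atoms_a or not atoms_b:
            raise ValueError("a residue range selects no atoms")

    cutoff_used: float | str = config.hbond_cutoff
    if config.decomposition_file is not None:
        decomposition = read_decomposition_tsv(molecule, config.decomposition_file)
        cutoff_used = "imported"
        fine = build_fine_framework(molecule, interactions, "default")
    elif config.hbond_cutoff == "auto":
        cutoff_used, decomposition = find_cutoff(molecule, interactions, atoms_a, atoms_b)
        fine = build_fine_framework(molecule, interactions, cutoff_used)
    else:
        fine = build_fine_framework(molecule, interactions, config.hbond_cutoff)
        decomposition = rigid_clusters(fine)

    if config.pinned_cluster is not None:
        pinned, moving = config.pinned_cluster, config.moving_cluster
    else:
        pinned = majority_cluster(decomposition, atoms_a)
        moving = majority_cluster(decomposition, atoms_b)
        if pinned == moving:
            raise ValueError(
                "the two residue ranges fall in the same rigid cluster; "
                "tighten the hydrogen-bond cutoff (or use 'auto')"
            )
    if not (0 <= pinned < decomposition.n_clusters and 0 <= moving < decomposition.n_clusters):
        raise ValueError("cluster label out of range")

    coarse = coarsen(fine, decomposition)
    matrix = pin(bbh_matrix(coarse), pinned)
    motion = null_space(matrix)
    if motion.d == 0:
        raise RuntimeError(
            "no relative motion between chosen clusters: the pinned framework is rigid; "
            "remove weak hydrogen bonds with a more negative cutoff"
        )
    logger.info("motion space dimension d=%d over %d clusters", motion.d, coarse.n)

    samples = run_sampling(
        molecule,
        decomposition,
        motion,
        n_samples=config.n_samples,
        step=config.step,
        seed=config.seed,
        weight_low=config.weight_low,
    )
    retained = select_low_energy(samples, config.keep_fraction)
    prediction = predict_axis(retained, moving_cluster=moving, pinned_cluster=pinned)

    report = {
        "tool": {"name": "hingeaxis", "version": __version__},
        "parameters": {
            "input": str(config.input_path),
            "model_index": config.model_index,
            "chain": config.chain,
            "hbond_cutoff": config.hbond_cutoff,
            "cutoff_used": cutoff_used,
            "hydrophobics": config.hydrophobics,
            "n_samples": config.n_samples,
            "keep_fraction": config.keep_fraction,
            "step_angstrom": config.step,
            "weight_low": config.weight_low,
            "seed": config.seed,
        },
        "structure": {
            "n_atoms": len(molecule),
            "n_covalent_bonds": len(molecule.covalent_bonds),
            "n_hbonds": len(hbonds),
        },
        "decomposition": {
            "n_clusters": decomposition.n_clusters,
            "cluster_sizes": decomposition.sizes,
            "pinned_cluster": pinned,
            "moving_cluster": moving,
        },
        "motion_space": {"d": motion.d, "n_bodies": coarse.n},
        "sampling": {
            "n_samples": len(samples),
            "n_retained": len(retained),
            "score_min": float(min(s.steric_score for s in samples)),
            "score_max": float(max(s.steric_score for s in samples)),
        },
        "prediction": prediction.as_dict(),
    }

    files: dict[str, Path] = {}
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files["report"] = out / "report.json"
        files["report"].write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
        files["scores"] = out / "scores.tsv"
        write_scores_tsv(samples, retained, files["scores"])
        files["clusters"] = out / "clusters.tsv"
        write_decomposition_tsv(molecule, decomposition, files["clusters"])
        script_files = write_axis_scripts(prediction, molecule, decomposition, out)
        files.update(script_files)

    return PipelineResult(
        prediction=prediction,
        report=report,
        molecule=molecule,
        decomposition=decomposition,
        files=files,
    )
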