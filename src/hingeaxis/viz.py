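"""Jmol and PyMOL script emitters for the predicted axis of motion.

The scripts color the pinned cluster red, the moving cluster green and draw
the axis in blue (the usual presentation of hinge predictions), with the
axis segment extended to span the structure's bounding box.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .decomposition import ClusterDecomposition
from .structure_model import Molecule
from .twist_analysis import AxisPrediction

__all__ = ["write_axis_scripts", "axis_segment"]


def axis_segment(
    prediction: AxisPrediction, molecule: Molecule, margin: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Two points on the predicted axis spanning the structure's extent.

    The axis line through ``axis_point`` with direction ω is clipped to the
    parameter range covering the projections of all atoms, plus a margin.
    """
    p = np.asarray(prediction.axis_point, float)
    omega = np.asarray(prediction.mean_twist.omega, float)
    d = omega / np.linalg.norm(omega)
    t = (molecule.coordinates - p) @ d
    return p + (t.min() - margin) * d, p + (t.max() + margin) * d


def _serial_ranges(serials: Sequence[int]) -> list[tuple[int, int]]:
    """Compress sorted serials into inclusive ranges."""
    ranges: list[tuple[int, int]] = []
    for s in sorted(serials):
        if ranges and s == ranges[-1][1] + 1:
            ranges[-1] = (ranges[-1][0], s)
        else:
            ranges.append((s, s))
    return ranges


def _cluster_serials(molecule: Molecule, decomposition: ClusterDecomposition,
                     label: int) -> list[int]:
    return [molecule.atoms[i].serial for i in decomposition.atoms_of(label)]


def write_axis_scripts(
    prediction: AxisPrediction,
    molecule: Molecule,
    decomposition: ClusterDecomposition,
    out_dir: str | Path,
    pdb_name: str = "structure.pdb",
) -> dict:
    """Write ``axis.jmol`` and ``axis.pml`` plus the structure they load."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .structure_model import write_pdb

    pdb_path = out / pdb_name
    write_pdb(molecule, None, pdb_path)
    e1, e2 = axis_segment(prediction, molecule)

    pinned = _serial_ranges(_cluster_serials(molecule, decomposition, prediction.pinned_cluster))
    moving = _serial_ranges(_cluster_serials(molecule, decomposition, prediction.moving_cluster))

    def jmol_sel(ranges: list[tuple[int, int]]) -> str:
        return " or ".join(
            f"atomno={a}" if a == b else f"(atomno>={a} and atomno<={b})" for a, b in ranges
        )

    jmol = [
        f'load "{pdb_name}"',
        "select all; color gray; spacefill 23%",
        f"select {jmol_sel(pinned)}; color red",
        f"select {jmol_sel(moving)}; color green",
        (
            f"draw axis line {{{e1[0]:.3f} {e1[1]:.3f} {e1[2]:.3f}}} "
            f"{{{e2[0]:.3f} {e2[1]:.3f} {e2[2]:.3f}}} diameter 0.4 color blue"
        ),
    ]
    jmol_path = out / "axis.jmol"
    jmol_path.write_text("\n".join(jmol) + "\n")

    def pml_sel(ranges: list[tuple[int, int]]) -> str:
        return "+".join(f"{a}" if a == b else f"{a}-{b}" for a, b in ranges)

    pml = [
        f"load {pdb_name}, struct",
        "color gray80, struct",
        f"select pinned, struct and id {pml_sel(pinned)}",
        "color red, pinned",
        f"select moving, struct and id {pml_sel(moving)}",
        "color green, moving",
        f"pseudoatom axis_a, pos=[{e1[0]:.3f}, {e1[1]:.3f}, {e1[2]:.3f}]",
        f"pseudoatom axis_b, pos=[{e2[0]:.3f}, {e2[1]:.3f}, {e2[2]:.3f}]",
        "distance axis, axis_a, axis_b",
        "hide labels, axis",
        "color blue, axis",
        "set dash_gap, 0",
    ]
    pml_path = out / "axis.pml"
    pml_path.write_text("\n".join(pml) + "\n")
    return {"jmol": jmol_path, "pymol": pml_path, "structure": pdb_path}
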