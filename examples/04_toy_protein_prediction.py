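"""Full prediction on a toy hinge structure, from PDB file to axis report.

The toy protein is two covalently rigid atom blocks bridged by weak, bent
hydrogen bonds and one covalent linker. At the default cutoff every hydrogen
bond is a hinge and the two domains fuse into one rigid cluster; the 'auto'
cutoff search tightens the hydrogen-bond energy threshold until the domains
separate, after which the pipeline samples the inter-domain motion and
reports the axis.
"""

import tempfile
from pathlib import Path

import numpy as np

from hingeaxis.fixtures import make_toy_protein
from hingeaxis.pipeline import RunConfig, run_pipeline

toy = make_toy_protein(n_residues=6, hinge_position=3, seed=0)
workdir = Path(tempfile.mkdtemp(prefix="hingeaxis_example_"))
pdb = workdir / "toy.pdb"
pdb.write_text(toy.pdb_text)

result = run_pipeline(RunConfig(
    input_path=pdb,
    pinned_residues="1-2",   # first block
    moving_residues="4-6",   # second block
    hbond_cutoff="auto",
    n_samples=1000,
    keep_fraction=0.05,
    seed=3,
    out_dir=workdir / "out",
))

pred = result.prediction
rep = result.report
print(f"cutoff found by the search: {rep['parameters']['cutoff_used']} kcal/mol")
print(f"rigid clusters: {rep['decomposition']['n_clusters']} "
      f"(sizes {rep['decomposition']['cluster_sizes']})")
print(f"motion space dimension: d = {rep['motion_space']['d']}")
print(f"retained samples: {pred.n_samples_used}")
print(f"mean twist purity: {pred.mean_purity:.2f} deg")

omega = np.array(pred.mean_twist.omega)
u = omega / np.linalg.norm(omega)
dist = np.linalg.norm(np.cross(toy.linker_center - np.array(pred.axis_point), u))
print(f"axis distance to the constructed linker: {dist:.3f} Angstrom")
print(f"report and Jmol/PyMOL scripts in {workdir / 'out'}")
print()
print("The predicted axis runs through the linker region — the hinge the")
print("generator built in — and purity ~90 deg marks a nearly pure rotation.")
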