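"""Recovering a known hinge axis with the sampling pipeline.

Two rigid blocks joined by a single hinge on a known line: pinning one block
leaves one degree of freedom. Sampling the motion space, keeping the
sterically best 5% and averaging the moving block's twists must give back
the constructed axis — the ground-truth check behind the whole method.
"""

import numpy as np

from hingeaxis.fixtures import make_hinge_fixture
from hingeaxis.rigidity_core import bbh_matrix, null_space, pin
from hingeaxis.sampling import run_sampling, select_low_energy
from hingeaxis.twist_analysis import predict_axis

fx = make_hinge_fixture(
    block_size=6, axis_point=(1.0, 2.0, 3.0), axis_direction=(0.3, 0.4, 0.5), seed=2
)
motion = null_space(pin(bbh_matrix(fx.framework), 0))
print(f"motion space dimension after pinning block 0: d = {motion.d}")

samples = run_sampling(fx.molecule, fx.decomposition, motion, n_samples=1000, seed=17)
retained = select_low_energy(samples, 0.05)
pred = predict_axis(retained, moving_cluster=1, pinned_cluster=0)

omega = np.array(pred.mean_twist.omega)
u = omega / np.linalg.norm(omega)
angle = np.degrees(np.arccos(np.clip(abs(u @ fx.axis_direction), 0, 1)))
line_dist = np.linalg.norm(np.cross(fx.axis_point - np.array(pred.axis_point), u))

print(f"retained samples: {pred.n_samples_used} of {len(samples)}")
print(f"mean twist purity: {pred.mean_purity:.4f} deg (90 = pure rotation)")
print(f"axis direction error: {angle:.2e} deg")
print(f"axis line distance:   {line_dist:.2e} Angstrom")
print()
print("Both errors are at numerical precision: the aggregated mean twist is")
print("exactly the hinge twist, since every sample is a positive multiple of it.")
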