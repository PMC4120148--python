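"""Degrees of freedom of the classic planar four-bar mechanism.

Four joints connected in a cycle by four fixed-length bars form a mechanism:
after grounding one bar (removing the trivial planar motions), exactly one
internal motion remains. A fifth, diagonal bar braces it rigid.
"""

from hingeaxis.fixtures import make_four_bar
from hingeaxis.rigidity_core import bar_joint_matrix, null_space

cycle = make_four_bar(seed=0)
d_cycle = null_space(bar_joint_matrix(cycle, pin_bar=0)).d

braced = make_four_bar(seed=0, with_diagonal=True)
d_braced = null_space(bar_joint_matrix(braced, pin_bar=0)).d

print(f"4-joint cycle, one bar grounded: {d_cycle} internal degree(s) of freedom")
print(f"with the diagonal brace:         {d_braced} internal degree(s) of freedom")
print()
print("1 DOF means the framework is a mechanism (it can flex); 0 means rigid —")
print("the null-space dimension of the pinned rigidity matrix counts exactly")
print("how many independent bars are still missing.")
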