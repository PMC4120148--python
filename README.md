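# hingeaxis

Predicting the **axis of motion of a hinge protein from a single
conformation**, using infinitesimal rigidity theory.

Many proteins work by rotating one domain relative to another about a hinge
(calmodulin, periplasmic binding proteins, kinases, ...). Methods that
locate hinge residues from one structure exist, and methods that compute an
axis from *two* conformations exist; `hingeaxis` computes the axis itself
from **one** structure. It is aimed at structural biologists and method
developers who want a quantitative, reproducible description of a domain
motion when only a single conformational state is available.

## The method

1. **Model** — atoms become rigid bodies of a *body-bar-hinge framework*:
   every covalent bond and every detected hydrogen bond is a hinge (5
   constraints, one free dihedral rotation about the bond line); optional
   hydrophobic contacts are bars (1 constraint). Hydrogen bonds carry a
   Mayo-style geometric energy in kcal/mol (more negative = stronger).
2. **Rigid cluster decomposition** — a (6,6) pebble game (Tay's counting
   condition for generic body-bar-hinge rigidity) partitions the atoms into
   maximal rigid clusters, labeled 0, 1, ... by decreasing size. If the two
   domains of interest fuse into one cluster, the hydrogen-bond energy
   cutoff is tightened (dropping the weakest bonds) until they separate.
3. **Motion space** — each cluster is a rigid body with a twist
   t = (ω, v) ∈ ℝ⁶ (point velocity p′ = ω×p + v). The rigidity matrix R
   collects the first-order constraints; after appending six rows that pin
   the chosen *pinned cluster*, the null space of R — computed by SVD — is
   the d-dimensional space of internal motions, with orthonormal basis
   b₁..b_d.
4. **Sampling & steric screening** — each of n (default 1000) samples draws
   weights cᵢ ~ U[0,1], forms s = Σ cᵢ bᵢ, moves every atom along its
   first-order velocity (largest displacement = 0.5 Å), and scores the
   result with a repulsion-only soft-sphere clash score
   Σ max(0, r_vdw,i + r_vdw,j − r)². The lowest-scoring 5% are retained.
5. **Twist aggregation** — the retained twists of the *moving cluster* are
   averaged; the mean twist (rescaled so v₃ = 1) yields the **twist purity**
   α = ∠(ω, v) ∈ [0°, 180°] (90° ⇔ Plücker relation 〈ω, v〉 = 0 ⇔ pure
   rotation) and the **average axis of motion**, reported as a pair of
   points on the screw axis.

## Worked example

No downloads needed — the `hingeaxis.fixtures` module generates structures
with known ground truth:

```bash
python examples/04_toy_protein_prediction.py
```

```
cutoff found by the search: -1.0 kcal/mol
rigid clusters: 6 (sizes [12, 8, 1, 1, 1, 1])
motion space dimension: d = 5
retained samples: 50
mean twist purity: 90.00 deg
axis distance to the constructed linker: 0.001 Angstrom
```

The toy structure is two covalently rigid blocks joined by one linker atom
and three weak hydrogen-bond bridges. At the default cutoff the bridges fuse
both domains into a 21-atom cluster; the automatic search finds that a
−1.0 kcal/mol cutoff separates them (sizes 12 and 8, plus the linker and
three spinning donor hydrogens as singletons). The sampled motion is a
nearly pure rotation (purity 90°) about an axis passing 0.001 Å from the
constructed linker — the generator's ground-truth hinge.

On a real structure:

```bash
hingeaxis predict protein.pdb --chain A \
    --pinned-residues 1-88 --moving-residues 120-180 \
    --cutoff auto --n-samples 1000 --seed 1 --out run/
```

writes `report.json` (all parameters, the seed, the mean twist, purity and
axis points), `scores.tsv`, `clusters.tsv` and Jmol/PyMOL scripts that color
the pinned cluster red, the moving cluster green and draw the axis in blue.
Published aggregated twists can be checked directly:

```bash
hingeaxis twist-tools -- 6.5286 -5.7547 3.9852 -1.6767 -2.3933 1
# purity: 76.6793 deg
# axis point (closest to origin): (-0.0413, 0.1442, 0.2759)
# second axis point (+ω):         (6.4873, -5.6105, 4.2611)
```

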