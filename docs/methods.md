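# Methods

## Model

A protein conformation is modeled as a **body-bar-hinge (BBH) framework**.
In the fine model every atom is a rigid body; a covalent bond or hydrogen
bond between atoms i and j is a **hinge** on the line through the two atoms
(five scalar constraints, leaving the dihedral rotation about the bond
axis), and an optional hydrophobic contact is a **bar** (one distance
constraint between the two contact points). The theory is first-order:
a motion assigns each body a twist t = (ω, v), ω the angular velocity and
v the translational part, with point velocity p′ = ω×p + v. All twists are
expressed in the global coordinate frame of the input file (Å), so reported
axis points are directly comparable with the structure.

The rigidity matrix has six columns per body, ordered
(ω_x, ω_y, ω_z, v_x, v_y, v_z). A bar between point p on body a and q on
body b contributes the row (p×u, u | −q×u, −u) with u = p − q. A hinge with
axis point a and unit direction d constrains the *relative* twist
t_b − t_a to the line spanned by the hinge twist (d, a×d); its five rows
are an orthonormal basis of that line's orthogonal complement in ℝ⁶,
obtained from the SVD of the 1×6 twist. This construction is basis-free and
keeps the rows orthonormal, which is numerically gentler than picking five
arbitrary complement vectors. Pinning a body appends six identity rows on
its columns — the minimal faithful way to remove its motion.

Degrees of freedom d = dimension of the pinned null space. The null space
is computed by full SVD with a **relative singular-value threshold of
1e-8**: far above double-precision noise for these well-scaled matrices and
far below the 1e-6-scale genericity perturbations used in tests. The basis
is made deterministic by fixing the SVD ordering and flipping each vector's
sign so its largest-magnitude entry is positive.

Singular (non-generic) geometries can make the algebraic rank differ from
the generic count; the decomposition is combinatorial (see below) and
unaffected, while matrix-based DOF values reflect the actual geometry.

## Interactions

Hydrogen bonds are detected geometrically: N/O donors (with an attached
hydrogen when the structure has any hydrogens; otherwise every N/O is a
candidate donor and the angular term is dropped), N/O acceptors,
donor–acceptor distance ≤ 3.6 Å, D-H···A angle ≥ 100° when an H is present,
and pairs closer than three covalent bonds excluded. Each survivor gets a
Mayo-style energy

    E = 8 kcal/mol · (5 (2.8/R)¹² − 6 (2.8/R)¹⁰) · cos²θ,

R the donor–acceptor distance and θ the D-H···A angle (angular factor 1
without hydrogens); only E < 0 is kept. The well depth (8 kcal/mol) and
equilibrium distance (2.8 Å) follow the energy function family used by
established flexibility servers, but no attempt is made to match any other
tool's energies numerically — cutoffs are meaningful only on this
implementation's own scale. The cutoff semantics are "keep hydrogen bonds
with energy ≤ cutoff"; the string `"default"` keeps all of them. Hydrophobic
contacts (C/S pairs of different residues within 4.25 Å) are off by default
because hydrogen bonds dominate the constraint network the method rests on.

Covalent bonds are perceived by distance: bonded if closer than the sum of
single-bond covalent radii plus 0.45 Å; CONECT records are unioned in.
Alternate locations resolve to the highest-occupancy conformer (ties: first
seen); waters are always dropped and other heteroatoms only kept on request.
Peptide-bond partial double bonds are not distinguished — every covalent
bond is a hinge.

## Rigid cluster decomposition

Generic rigidity of BBH frameworks is characterized combinatorially (Tay):
on the multigraph with one edge per bar and five parallel edges per hinge,
independent constraints are the edges of a (6,6)-sparse subgraph. The
**(6,6) pebble game** computes this rank: six pebbles per body, an edge
insertion requires gathering seven pebbles on its endpoints and consumes
one. Internal DOF = free pebbles − 6.

Clusters are the equivalence classes of "zero relative motion": two bodies
are rigidly connected exactly when no seventh pebble can be gathered on the
pair in the final game state. Zero relative twist is transitive, so
union-find over the pairs that share a constraint suffices (a rigid cluster
induces a connected tight subgraph). Atoms inherit their body's cluster;
labels are assigned by decreasing atom count, ties broken by the smallest
member atom index.

The cutoff search mirrors manual practice: starting from `"default"`, the
hydrogen-bond cutoff is lowered in 0.25 kcal/mol steps (floor −10) until the
majority clusters of the two chosen domains differ. "Majority" (plurality of
the domain's atoms) is used because domain boundaries rarely coincide
exactly with cluster boundaries. A decomposition can also be imported from
TSV, e.g. from an external rigidity server, bypassing the internal game.

## Sampling and steric screening

Weights are uniform on [0,1] per basis vector, as in the original recipe;
note this explores a single orthant of the motion space (a documented
faithful-but-questionable choice — pass `weight_low=-1` to sample both
orientations). Displacements are first-order velocities normalized so the
**largest atom displacement is exactly `step` = 0.5 Å**: the motion must
stay in the infinitesimal regime for the constraints to hold, and a fixed
maximum displacement makes clash scores comparable across samples.

The steric score replaces a full physics energy with its only term that
varies between such samples: van der Waals repulsion. It is a soft-sphere
penalty Σ max(0, (r_i + r_j) − r)² over pairs at least three covalent bonds
apart, with Bondi-style radii. Structures are never relaxed. The lowest 5%
of samples by score (⌈0.05·n⌉, ties broken by sample index) are retained.
All randomness flows from one seed through a single named generator; rerun
outputs are byte-identical.

## Twist aggregation and the axis conventions

The moving cluster's twists over retained samples are averaged
component-wise, then rescaled so the sixth component equals 1 (the
convention in which aggregated twists are published); per-sample
normalization before averaging is available behind a flag but is not the
default. The mean twist purity is the arithmetic mean of per-sample
purities α = arccos(〈ω,v〉/‖ω‖‖v‖); samples with ω = 0 or v = 0 (pure
translations/origin rotations, where α is undefined) are excluded and
counted. Purity of the mean twist is *not* the mean purity — both are
reported.

Two sign conventions for the axis point coexist. Published aggregated-twist
tables report (v×ω)/‖ω‖², which `axis_from_twist` uses by default
(`convention="table"`); but for a twist obeying p′ = ω×p + v the rotation
axis actually passes through the reflected point (ω×v)/‖ω‖²
(`convention="kinematic"`). The two coincide only for axes through the
origin. `predict_axis` uses the kinematic point for the geometric axis (so
the drawn axis is the true rotation line — verified by exact recovery of a
constructed hinge) and carries the table-convention pair alongside for
comparison with published values. For published tables the discrepancy is
visually negligible because those ω are large relative to v, placing both
candidate points within ~0.5 Å of the origin.

## Synthetic data

The fixtures module generates every structure the tests need:

* `make_four_bar` — the generic planar 4-joint cycle (1 DOF; 0 with the
  diagonal), seeded corner perturbations for genericity;
* `make_random_framework` — generic random BBH frameworks for the
  pebble-vs-rank cross-oracle;
* `make_hinge_fixture` — two internally rigid multi-atom blocks joined by
  one hinge on a requested line; optional touching atom pair (so rotating
  one way clashes) and optional cross-bar (removing the last DOF);
* `make_toy_protein` — two jittered carbon lattices (1.8 Å spacing, dense
  enough that distance-perceived bonds make each block one rigid cluster)
  joined by a one-atom covalent linker and three deliberately bent N-H···O
  bridges near −0.8 kcal/mol, so the default decomposition fuses the
  domains and the cutoff search separates them at a constructed value.

These fixtures use idealized bond lengths and lattice packings, not real
protein chemistry: no side-chain variety, no realistic secondary structure,
no solvent, and clash baselines far below protein packing density. Passing
tests therefore certify the rigidity analysis, sampling and aggregation
machinery — not hydrogen-bond detection accuracy on real proteins, nor
agreement with any particular external rigidity server's clusters, whose
energy scales differ.

## Problem sizes and defaults

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 1000 | motion samples per run |
| `keep_fraction` | 0.05 | sterically retained fraction |
| `step` | 0.5 Å | largest per-atom displacement |
| `hbond_cutoff` | `"default"` | keep all hydrogen bonds |
| cutoff search step / floor | 0.25 / −10 kcal/mol | tightening schedule |
| SVD tolerance | 1e-8 (relative) | rank / null-space threshold |

The test suite runs on fixtures of ≤ 30 atoms and frameworks of ≤ 8 bodies —
sizes at which the rank oracle (dense SVD) is exact and instant; the
pipeline itself is routinely used on structures of a few thousand atoms,
where the dense SVD of the coarse (cluster-level) matrix remains small
because the number of clusters, not atoms, sets its size.

## Known limitations

* First-order theory only: no finite-motion or second-order flexibility
  analysis; large motions extrapolated from a twist are approximations.
* The [0,1] weight range biases sampling to one orthant (kept for fidelity
  to the original recipe; `weight_low=-1` available).
* Hydrogen-bond energies are not calibrated against other tools, so a
  cutoff value from another server's scale does not transfer.
* Averaging feasible twists can produce an infeasible axis when the
  retained set is multimodal.
* Validation against a second known conformation is out of scope; the
  package certifies itself on constructed ground truth instead.
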