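import numpy as np
import pytest

from hingeaxis.fixtures import make_hinge_fixture
from hingeaxis.rigidity_core import bbh_matrix, hinge_twist, null_space, pin
from hingeaxis.sampling import (
    combine,
    displace,
    draw_weights,
    run_sampling,
    select_low_energy,
    steric_score,
)
from hingeaxis.structure_model import Atom, Molecule
from hingeaxis.twist_analysis import Twist


@pytest.fixture
def hinge_motion(hinge_fixture):
    ms = null_space(pin(bbh_matrix(hinge_fixture.framework), 0))
    return hinge_fixture, ms


class TestDrawWeights:
    def test_deterministic_under_seed(self):
        assert np.array_equal(draw_weights(5, 42), draw_weights(5, 42))

    def test_all_in_unit_interval(self):
        w = draw_weights(1000, 7)
        assert w.min() >= 0.0 and w.max() <= 1.0

    def test_empirical_mean_of_uniform(self):
        w = np.array([draw_weights(1, rng)[0] for rng in [np.random.default_rng(3)] * 10_000])
        assert 0.48 <= w.mean() <= 0.52

    def test_rigid_framework_rejected(self):
        with pytest.raises(ValueError, match="rigid"):
            draw_weights(0, 1)


class TestCombine:
    def test_scaling_single_basis_vector(self, hinge_motion):
        _, ms = hinge_motion
        s, twists = combine(ms, [0.5])
        np.testing.assert_allclose(s, 0.5 * ms.basis[0])
        np.testing.assert_allclose(twists[1].vector, 0.5 * ms.basis[0][6:12])

    def test_zero_weights_zero_motion(self, hinge_motion):
        _, ms = hinge_motion
        s, twists = combine(ms, [0.0])
        assert not s.any()
        assert all(not t.vector.any() for t in twists)

    def test_pinned_body_twist_is_zero(self, hinge_motion):
        _, ms = hinge_motion
        _, twists = combine(ms, [0.9])
        assert np.linalg.norm(twists[0].vector) < 1e-10

    def test_weight_count_mismatch(self, hinge_motion):
        _, ms = hinge_motion
        with pytest.raises(ValueError):
            combine(ms, [0.1, 0.2])


class TestDisplace:
    def test_unit_rotation_velocity(self, hinge_fixture):
        """omega=(0,0,1), v=0 moves the atom at (1,0,0) along (0,1,0)."""
        mol = Molecule(atoms=[
            Atom(serial=1, name="C1", element="C", residue_name="UNK",
                 residue_number=1, chain="A", position=(1.0, 0.0, 0.0))
        ])
        from hingeaxis.decomposition import ClusterDecomposition
        dec = ClusterDecomposition(body_labels=[0], assignment={0: 0}, sizes=[1])
        twist = Twist(omega=(0, 0, 1), v=(0, 0, 0))
        out = displace(mol, dec, [twist], step=0.5)
        np.testing.assert_allclose(out[0], (1.0, 0.5, 0.0), atol=1e-12)

    def test_zero_twists_leave_coordinates(self, hinge_fixture):
        zero = [Twist(omega=(0, 0, 0), v=(0, 0, 0))] * 2
        out = displace(hinge_fixture.molecule, hinge_fixture.decomposition, zero)
        np.testing.assert_array_equal(out, hinge_fixture.molecule.coordinates)

    def test_max_displacement_equals_step(self, hinge_motion):
        fx, ms = hinge_motion
        _, twists = combine(ms, [0.7])
        out = displace(fx.molecule, fx.decomposition, twists, step=0.5)
        moved = np.linalg.norm(out - fx.molecule.coordinates, axis=1)
        assert moved.max() == pytest.approx(0.5, abs=1e-12)


class TestStericScore:
    def _pair(self, distance):
        return Molecule(atoms=[
            Atom(serial=1, name="C1", element="C", residue_name="UNK",
                 residue_number=1, chain="A", position=(0.0, 0.0, 0.0)),
            Atom(serial=2, name="C2", element="C", residue_name="UNK",
                 residue_number=2, chain="A", position=(float(distance), 0.0, 0.0)),
        ])

    def test_separated_carbons_score_zero(self):
        mol = self._pair(5.0)
        assert steric_score(mol.coordinates, mol) == 0.0

    def test_overlapping_carbons_score_positive(self):
        mol = self._pair(1.0)
        assert steric_score(mol.coordinates, mol) > 0.0

    def test_score_decreases_monotonically_with_separation(self):
        scores = []
        for r in np.linspace(1.0, 3.5, 15):
            mol = self._pair(r)
            scores.append(steric_score(mol.coordinates, mol))
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert scores[-1] == 0.0

    def test_bonded_and_angle_pairs_excluded(self):
        # three collinear atoms at bonding distance: all pairs are 1-2 or 1-3
        atoms = [
            Atom(serial=i + 1, name=f"C{i+1}", element="C", residue_name="UNK",
                 residue_number=1, chain="A", position=(i * 1.5, 0.0, 0.0))
            for i in range(3)
        ]
        mol = Molecule(atoms=atoms, covalent_bonds={(0, 1), (1, 2)})
        assert steric_score(mol.coordinates, mol) == 0.0


class TestRunSampling:
    def test_sample_count_and_determinism(self, hinge_motion):
        fx, ms = hinge_motion
        s1 = run_sampling(fx.molecule, fx.decomposition, ms, n_samples=50, seed=5)
        s2 = run_sampling(fx.molecule, fx.decomposition, ms, n_samples=50, seed=5)
        assert len(s1) == 50
        assert [a.steric_score for a in s1] == [b.steric_score for b in s2]
        assert all(np.array_equal(a.weights, b.weights) for a, b in zip(s1, s2))

    def test_motion_vector_reconstructs_per_body_twists(self, hinge_motion):
        fx, ms = hinge_motion
        for s in run_sampling(fx.molecule, fx.decomposition, ms, n_samples=5, seed=1):
            for i, t in enumerate(s.per_body_twists):
                np.testing.assert_array_equal(t.vector, s.motion_vector[6 * i : 6 * i + 6])

    def test_first_order_constraint_preservation(self, hinge_motion):
        """The hinge's relative twist stays on its allowed line for every sample."""
        fx, ms = hinge_motion
        h = fx.framework.hinges[0]
        line = hinge_twist(h.axis_point, h.axis_direction)
        line = line / np.linalg.norm(line)
        for s in run_sampling(fx.molecule, fx.decomposition, ms, n_samples=20, seed=3):
            rel = s.per_body_twists[1].vector - s.per_body_twists[0].vector
            residual = rel - (rel @ line) * line
            assert np.linalg.norm(residual) <= 1e-8 * max(1.0, np.linalg.norm(rel))

    def test_clash_side_scores_higher(self):
        """Samples rotating into the built-in clash score strictly above
        samples rotating away from it."""
        fx = make_hinge_fixture(seed=2, with_clash=True)
        ms = null_space(pin(bbh_matrix(fx.framework), 0))
        samples = run_sampling(fx.molecule, fx.decomposition, ms, n_samples=200,
                               seed=11, weight_low=-1.0)
        # orient: positive rotation about the fixture axis drives the clash
        h = fx.framework.hinges[0]
        t = hinge_twist(h.axis_point, h.axis_direction)
        into = [s for s in samples if s.per_body_twists[1].vector @ t > 0.2]
        away = [s for s in samples if s.per_body_twists[1].vector @ t < -0.2]
        assert into and away
        assert min(s.steric_score for s in into) > max(s.steric_score for s in away)

    def test_per_sample_pdbs_written_and_parseable(self, hinge_motion, tmp_path):
        from hingeaxis.structure_model import read_pdb

        fx, ms = hinge_motion
        run_sampling(fx.molecule, fx.decomposition, ms, n_samples=4, seed=2,
                     pdb_dir=tmp_path)
        files = sorted(tmp_path.glob("sample_*.pdb"))
        assert len(files) == 4
        for f in files:
            assert len(read_pdb(f)) == len(fx.molecule)


class TestSelectLowEnergy:
    def _samples(self, hinge_motion, n):
        fx, ms = hinge_motion
        return run_sampling(fx.molecule, fx.decomposition, ms, n_samples=n, seed=13)

    def test_five_percent_of_1000_is_50(self, hinge_motion):
        samples = self._samples(hinge_motion, 1000)
        assert len(select_low_energy(samples, 0.05)) == 50

    def test_fraction_one_keeps_all(self, hinge_motion):
        samples = self._samples(hinge_motion, 40)
        assert len(select_low_energy(samples, 1.0)) == 40

    def test_retained_scores_below_discarded(self, hinge_motion):
        samples = self._samples(hinge_motion, 200)
        kept = select_low_energy(samples, 0.05)
        kept_idx = {s.index for s in kept}
        discarded = [s for s in samples if s.index not in kept_idx]
        assert max(s.steric_score for s in kept) <= min(s.steric_score for s in discarded)
        mean_kept = np.mean([s.steric_score for s in kept])
        mean_all = np.mean([s.steric_score for s in samples])
        assert mean_kept <= mean_all

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_low_energy([], 0.05)
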