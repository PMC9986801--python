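import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from itermodel.metrics import (ComparisonError, RigidTransform,
                               assess_prediction, compare_models, kabsch,
                               symmetry_expand_best)
from itermodel.model_io import SymmetryOperator
from itermodel.synthetic import FixtureSpec, make_true_model

from oracles import oracle_rmsd_minimum


@pytest.fixture(scope="module")
def helix40():
    return make_true_model(FixtureSpec(fold="helix", n_res=40, seed=0))


def random_rigid(seed):
    rng = np.random.default_rng(seed)
    rotation = Rotation.from_euler("xyz", rng.uniform(0, 360, 3),
                                   degrees=True).as_matrix()
    return RigidTransform(rotation, rng.uniform(-20, 20, 3))


class TestKabsch:
    def test_identity(self, rng):
        coords = rng.normal(size=(10, 3))
        transform, rmsd = kabsch(coords, coords)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-9)

    def test_recovers_rigid_transform(self, rng):
        coords = rng.normal(size=(15, 3)) * 10
        moved = random_rigid(5).apply(coords)
        _, rmsd = kabsch(coords, moved)
        assert rmsd < 1e-9

    def test_proper_rotation_always(self, rng):
        for _ in range(5):
            a = rng.normal(size=(6, 3))
            b = rng.normal(size=(6, 3))
            transform, _ = kabsch(a, b)
            assert np.linalg.det(transform.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_minimum(self):
        # unit right triangle vs same with one vertex moved
        a = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1.0, 0]])
        b = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 2.0, 0]])
        _, rmsd = kabsch(a, b)
        assert rmsd == pytest.approx(oracle_rmsd_minimum(a, b), abs=1e-5)

    def test_too_few_points(self):
        with pytest.raises(ComparisonError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ComparisonError):
            kabsch(line, line)

    def test_rmsd_invariant_under_joint_rotation(self, rng):
        a = rng.normal(size=(12, 3)) * 8
        b = a + rng.normal(size=(12, 3))
        _, rmsd1 = kabsch(a, b)
        pre = random_rigid(9)
        _, rmsd2 = kabsch(pre.apply(a), pre.apply(b))
        assert rmsd1 == pytest.approx(rmsd2, abs=1e-9)


class TestCompareModels:
    def test_self_comparison(self, helix40):
        result = compare_models(helix40, helix40)
        assert result.rmsd == pytest.approx(0.0, abs=1e-12)
        assert result.completeness == 100.0
        assert result.coverage == 100.0

    def test_completeness_threshold_is_2A(self, helix40):
        # displace everything by just under / just over the threshold
        for shift, expected in ((1.9, 100.0), (2.1, 0.0)):
            moved = helix40.copy()
            offset = np.array([0.0, 0.0, shift])
            moved.set_coordinates(moved.coordinates() + offset)
            # axial shift: nearest CA is the shifted copy of the same residue
            result = compare_models(helix40, moved)
            assert result.completeness == expected

    def test_half_displaced_is_50_percent(self, helix40):
        moved = helix40.copy()
        displaced = moved.chains[0].residues[20:]
        # axial displacement: 3 A along the helix axis keeps every displaced
        # CA more than 2 A from all original CAs (the 100 degree twist means
        # the residue two steps up sits at a 4.5 A chord)
        for residue in displaced:
            for atom in residue.atoms:
                atom.position = atom.position + np.array([0.0, 0.0, 3.0])
        # guard: displaced CAs must not sit within 2 A of any original CA
        orig = np.array([r.ca.position for r in helix40.iter_residues()])
        disp = np.array([r.ca.position for r in displaced])
        dists = np.linalg.norm(orig[None, :, :] - disp[:, None, :], axis=2)
        assert dists.min() > 2.0
        result = compare_models(helix40, moved)
        assert result.completeness == pytest.approx(50.0)

    def test_superpose_flag(self, helix40):
        moved = helix40.copy()
        moved.set_coordinates(random_rigid(3).apply(moved.coordinates()))
        raw = compare_models(helix40, moved)
        fitted = compare_models(helix40, moved, superpose=True)
        assert fitted.rmsd < 1e-9 < raw.rmsd
        assert fitted.completeness == 100.0

    def test_disjoint_numbering_raises(self, helix40):
        shifted = helix40.copy()
        for residue in shifted.chains[0].residues:
            residue.number += 1000
        far = shifted.copy()
        far.set_coordinates(far.coordinates() + 500.0)
        with pytest.raises(ComparisonError):
            compare_models(helix40, far)


class TestSymmetryExpandBest:
    @staticmethod
    def p21_like_operators():
        identity = SymmetryOperator(np.eye(3), np.zeros(3), fractional=True,
                                    allowed_origin_shift=np.array([0.5, 0.0, 0.5]))
        # 2-fold screw along b and its inverse image translation
        screw = SymmetryOperator(np.diag([-1.0, 1.0, -1.0]),
                                 np.array([0.0, 0.5, 0.0]), fractional=True,
                                 allowed_origin_shift=np.array([0.5, 0.0, 0.5]))
        return [identity, screw]

    @staticmethod
    def apply_op(model, op, cell, shift=(0.0, 0.0, 0.0)):
        out = model.copy()
        cell_arr = np.asarray(cell, float)
        frac = out.coordinates() / cell_arr
        frac = frac @ op.rotation.T + op.translation + np.asarray(shift)
        out.set_coordinates(frac * cell_arr)
        return out

    def test_identity_operator_equals_compare(self, helix40):
        result = symmetry_expand_best(
            helix40, helix40, [SymmetryOperator.identity()], cell=(80, 80, 90))
        plain = compare_models(helix40, helix40, pairing="nearest")
        assert result.completeness == plain.completeness
        assert result.rmsd == pytest.approx(plain.rmsd, abs=1e-12)

    def test_recovers_generating_operator(self, helix40):
        cell = (60.0, 50.0, 80.0)
        ops = self.p21_like_operators()
        # mobile = screw image of the reference; mapping back needs the
        # inverse screw, supplied as an operator in the search list
        inverse_screw = SymmetryOperator(np.diag([-1.0, 1.0, -1.0]),
                                         np.array([0.0, -0.5, 0.0]),
                                         fractional=True)
        mobile = self.apply_op(helix40, ops[1], cell)
        result = symmetry_expand_best(
            helix40, mobile, [ops[0], inverse_screw], cell=cell)
        assert result.operator_index == 1
        assert result.completeness == 100.0
        assert result.rmsd < 1e-6

    def test_origin_shift_recovered(self, helix40):
        cell = (60.0, 50.0, 80.0)
        identity_with_shifts = SymmetryOperator(
            np.eye(3), np.zeros(3), fractional=True,
            allowed_origin_shift=np.array([0.5, 0.0, 0.5]))
        mobile = self.apply_op(helix40, identity_with_shifts, cell,
                               shift=(0.5, 0.0, 0.5))
        # invert: mapping back needs shift (-0.5, 0, -0.5) == (0.5, 0, 0.5)
        # only on a half-step grid modulo 1; supply the matching image
        inverse = SymmetryOperator(np.eye(3), np.array([-1.0, 0.0, -1.0]),
                                   fractional=True,
                                   allowed_origin_shift=np.array([0.5, 0.0, 0.5]))
        result = symmetry_expand_best(helix40, mobile,
                                      [identity_with_shifts, inverse], cell=cell)
        assert result.completeness == 100.0
        assert result.rmsd < 1e-6

    def test_tie_breaking_prefers_lower_rmsd(self, helix40):
        wrong = SymmetryOperator(np.eye(3), np.array([5.0, 5.0, 5.0]),
                                 fractional=False)
        right = SymmetryOperator.identity()
        right.fractional = False
        result = symmetry_expand_best(helix40, helix40, [wrong, right])
        assert result.operator_index == 1

    def test_no_operators_warns_and_uses_identity(self, helix40):
        with pytest.warns(UserWarning):
            result = symmetry_expand_best(helix40, helix40, [])
        assert result.completeness == 100.0

    def test_never_below_plain_compare(self, helix40):
        moved = helix40.copy()
        moved.set_coordinates(moved.coordinates() + np.array([1.0, 0.0, 0.0]))
        plain = compare_models(helix40, moved, pairing="nearest")
        best = symmetry_expand_best(
            helix40, moved,
            [SymmetryOperator.identity(),
             SymmetryOperator(np.eye(3), np.array([-1 / 60, 0, 0]),
                              fractional=True)],
            cell=(60.0, 50.0, 80.0))
        assert best.completeness >= plain.completeness


class TestAssessPrediction:
    def test_perfect_prediction(self, helix40):
        predicted = helix40.copy()
        predicted.provenance = "predicted"
        for residue in predicted.iter_residues():
            for atom in residue.atoms:
                atom.b_iso = 95.0
        rmsd, coverage = assess_prediction(predicted, helix40)
        assert coverage == 100.0
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_bad_region_excluded_by_smoothed_cap(self):
        model = make_true_model(FixtureSpec(fold="helix", n_res=60, seed=0))
        predicted = model.copy()
        predicted.provenance = "predicted"
        for residue in predicted.iter_residues():
            for atom in residue.atoms:
                atom.b_iso = 95.0
        # 15-residue region displaced 5 A
        for residue in predicted.chains[0].residues[20:35]:
            for atom in residue.atoms:
                atom.position = atom.position + np.array([5.0, 0.0, 0.0])
        rmsd, coverage = assess_prediction(predicted, model)
        assert coverage < 100.0
        assert coverage <= 100.0 * (60 - 15) / 60 + 10  # roughly the region's share
        assert rmsd < 1.5

    def test_low_confidence_removed(self, helix40):
        predicted = helix40.copy()
        predicted.provenance = "predicted"
        for i, residue in enumerate(predicted.iter_residues()):
            value = 50.0 if i < 10 else 95.0
            for atom in residue.atoms:
                atom.b_iso = value
        _, coverage = assess_prediction(predicted, helix40)
        assert coverage == pytest.approx(100.0 * 30 / 40)

    def test_single_spike_survives_smoothing(self):
        model = make_true_model(FixtureSpec(fold="helix", n_res=40, seed=0))
        predicted = model.copy()
        predicted.provenance = "predicted"
        for residue in predicted.iter_residues():
            for atom in residue.atoms:
                atom.b_iso = 95.0
        # one residue 4 A off inside accurate surroundings: smoothed mean
        # stays below the 3 A cap, so the spike survives the filter
        spike = predicted.chains[0].residues[20]
        for atom in spike.atoms:
            atom.position = atom.position + np.array([4.0, 0.0, 0.0])
        rmsd, coverage = assess_prediction(predicted, model)
        assert coverage == 100.0
        assert rmsd > 0.1
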