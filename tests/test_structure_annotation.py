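"""Helix assignment, hairpin pairing and Kabsch superposition."""

import numpy as np
import pytest
from conftest import horn_rmsd, random_rigid_transform

from pprscan.structure_annotation import (HelixGeometryParams, StructureModel,
                                          annotate_structure, assign_helices,
                                          detect_ppr_hairpins, superpose)
from pprscan.synthetic_data import _arc_points, _helix_points, generate_ideal_solenoid


def _model(coords, names=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return StructureModel(np.arange(1, n + 1), names or "A" * n, coords)


class TestAssignHelices:
    def test_ideal_helix_detected_in_full(self):
        pts = _helix_points(12, np.zeros(3), +1.0)
        (seg,) = assign_helices(_model(pts))
        assert (seg.start_residue, seg.end_residue) == (1, 12)
        # the principal axis of a finite helix tilts slightly off ideal
        assert seg.axis[2] > 0.99

    def test_extended_chain_yields_nothing(self):
        pts = np.zeros((12, 3))
        pts[:, 2] = 3.8 * np.arange(12)   # collinear, 3.8 A spacing
        assert assign_helices(_model(pts)) == []

    def test_two_helices_with_loop_in_order(self):
        a = _helix_points(12, np.zeros(3), +1.0)
        b = _helix_points(11, np.array([10.0, 0.0, 16.5]), -1.0)
        loop = _arc_points(a[-1], b[0], 4, np.array([0.0, 0.0, 1.0]))
        segs = assign_helices(_model(np.vstack([a, loop, b])))
        assert [(s.start_residue, s.end_residue) for s in segs] == [(1, 12), (17, 27)]

    def test_too_few_residues(self):
        pts = _helix_points(3, np.zeros(3), +1.0)
        assert assign_helices(_model(pts)) == []

    def test_numbering_gap_breaks_a_helix(self):
        pts = _helix_points(12, np.zeros(3), +1.0)
        nums = np.array([1, 2, 3, 4, 5, 6, 20, 21, 22, 23, 24, 25])
        segs = assign_helices(StructureModel(nums, "A" * 12, pts))
        assert all(s.length < 12 for s in segs)


class TestDetectHairpins:
    def test_two_hairpin_bundle(self):
        st, truth = generate_ideal_solenoid(2, jitter_sd=0.0)
        ann = annotate_structure(st)
        assert [m.index for m in ann.motifs] == [1, 2]
        assert [m.span for m in ann.motifs] == [m.span for m in truth.motifs]

    def test_parallel_helices_rejected(self):
        a = _helix_points(12, np.zeros(3), +1.0)
        b = _helix_points(11, np.array([10.0, 0.0, 0.0]), +1.0)
        loop = _arc_points(a[-1], b[0], 4, np.array([0.0, 0.0, 1.0]))
        st = _model(np.vstack([a, loop, b]))
        ann = detect_ppr_hairpins(assign_helices(st), st)
        assert len(ann) == 0

    def test_31_hairpin_solenoid(self):
        st, truth = generate_ideal_solenoid(31, seed=5)
        ann = annotate_structure(st)
        assert len(ann) == 31
        assert [m.span for m in ann.motifs] == [m.span for m in truth.motifs]

    def test_motifs_non_overlapping_consecutive(self):
        st, _ = generate_ideal_solenoid(8, seed=2)
        ann = annotate_structure(st)
        assert [m.index for m in ann.motifs] == list(range(1, 9))
        for a, b in zip(ann.motifs, ann.motifs[1:]):
            assert b.start_residue > a.end_residue

    def test_rigid_transform_invariance(self):
        st, _ = generate_ideal_solenoid(5, seed=3)
        ref = [m.span for m in annotate_structure(st).motifs]
        rng = np.random.default_rng(42)
        for _ in range(10):
            rot, trans = random_rigid_transform(rng)
            moved = annotate_structure(st.transformed(rot, trans))
            assert [m.span for m in moved.motifs] == ref


class TestSuperpose:
    def test_identity(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        rot, trans, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-9)
        assert np.allclose(trans, 0.0, atol=1e-9)

    def test_recovers_inverse_of_rigid_motion(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(12, 3))
        theta = np.pi / 2
        rz = np.array([[np.cos(theta), -np.sin(theta), 0],
                       [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        b = a @ rz.T + np.array([1.0, -2.0, 3.0])
        rot, trans, rmsd = superpose(a, b)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(rot, rz.T, atol=1e-9)   # inverts the motion
        assert np.allclose(b @ rot.T + trans, a, atol=1e-9)

    def test_displaced_square_matches_quaternion_oracle(self):
        a = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        b = a.copy()
        b[2, 2] = 0.4
        _, _, rmsd = superpose(a, b)
        assert rmsd == pytest.approx(horn_rmsd(a, b), abs=1e-9)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=(9, 3)), rng.normal(size=(9, 3))
        assert superpose(a, b)[2] == pytest.approx(superpose(b, a)[2], abs=1e-9)

    def test_argument_errors(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            superpose(a, a[:4])
        with pytest.raises(ValueError):
            superpose(a[:2], a[:2])

    def test_reflection_not_allowed(self):
        # a mirrored cloud must still produce a proper rotation, rmsd > 0
        rng = np.random.default_rng(9)
        a = rng.normal(size=(10, 3))
        b = a * np.array([1.0, 1.0, -1.0])
        rot, _, rmsd = superpose(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1
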