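"""Superposition, inter-domain rotation and pairwise sequence identity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from ispkit import compare as cmp
from ispkit.struct_io import AtomRecord, ResidueUnit, StructureModel


def ca_model(coord_blocks, chain="A", start=1, resnames=None):
    residues = []
    serial = 1
    num = start
    for block_i, block in enumerate(coord_blocks):
        name = (resnames or ["ALA"] * len(coord_blocks))[block_i]
        for c in block:
            r = ResidueUnit(chain, num, "", name, "protein")
            r.atoms.append(AtomRecord(serial, "CA", "C", "", 1.0,
                                      np.asarray(c, float)))
            residues.append(r)
            serial += 1
            num += 1
    return StructureModel("fix", {chain: residues})


class TestKabsch:
    def test_self_superposition_is_identity(self, rng):
        X = rng.normal(size=(25, 3)) * 4
        s = cmp.kabsch(X, X)
        assert s.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(s.rotation, np.eye(3), atol=1e-9)
        assert abs(np.linalg.det(s.rotation) - 1.0) < 1e-6

    def test_planted_transform_recovered(self, rng):
        X = rng.normal(size=(40, 3)) * 6
        R = Rotation.random(random_state=2).as_matrix()
        t = np.array([3.0, -1.0, 8.0])
        s = cmp.kabsch(X, X @ R.T + t)
        assert s.rmsd < 1e-6
        assert np.allclose(s.rotation, R, atol=1e-8)
        assert np.allclose(s.translation, t, atol=1e-8)

    def test_agrees_with_scipy_alignment(self, rng):
        # independent route: scipy's align_vectors on centred coordinates
        X = rng.normal(size=(30, 3)) * 5
        Y = rng.normal(size=(30, 3)) * 5
        s = cmp.kabsch(X, Y)
        rot, rssd = Rotation.align_vectors(Y - Y.mean(0), X - X.mean(0))
        assert np.allclose(s.rotation, rot.as_matrix(), atol=1e-8)
        assert s.rmsd == pytest.approx(rssd / np.sqrt(len(X)), abs=1e-8)

    def test_rmsd_symmetric_under_swap(self, rng):
        X = rng.normal(size=(20, 3)) * 5
        Y = X + rng.normal(size=(20, 3)) * 0.5
        assert cmp.kabsch(X, Y).rmsd == pytest.approx(cmp.kabsch(Y, X).rmsd,
                                                      abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(cmp.ComparisonError):
            cmp.kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(10.0), [1.0, 0.0, 0.0])
        with pytest.raises(cmp.ComparisonError, match="collinear"):
            cmp.kabsch(line, line)


class TestInterdomainRotation:
    @staticmethod
    def two_domain_pair(theta, seed=5):
        rng = np.random.default_rng(seed)
        domA = rng.normal(size=(40, 3)) * 6
        domB = rng.normal(size=(40, 3)) * 6 + np.array([30.0, 0.0, 0.0])
        m1 = ca_model([domA, domB])
        axis = np.array([0.3, -0.5, 0.81])
        axis /= np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.deg2rad(theta) * axis).as_matrix()
        hinge = np.array([20.0, 0.0, 0.0])
        m2 = ca_model([domA, (domB - hinge) @ R.T + hinge])
        return m1, m2

    def test_identical_models_zero(self):
        m1, _ = self.two_domain_pair(0.001)
        assert cmp.interdomain_rotation(
            m1, m1, "1-40", "1-40", "41-80", "41-80") == pytest.approx(0.0, abs=1e-4)

    @pytest.mark.parametrize("theta", [15.0, 47.0, 92.0])
    def test_planted_hinge_rotation_recovered(self, theta):
        m1, m2 = self.two_domain_pair(theta)
        ang = cmp.interdomain_rotation(m1, m2, "1-40", "1-40", "41-80", "41-80")
        assert ang == pytest.approx(theta, abs=0.5)

    def test_invariant_to_pre_applied_rigid_transform(self):
        m1, m2 = self.two_domain_pair(47.0)
        R = Rotation.random(random_state=8).as_matrix()
        m2moved = m2.transformed(R, np.array([12.0, 5.0, -9.0]))
        a = cmp.interdomain_rotation(m1, m2, "1-40", "1-40", "41-80", "41-80")
        b = cmp.interdomain_rotation(m1, m2moved, "1-40", "1-40",
                                     "41-80", "41-80")
        assert a == pytest.approx(b, abs=1e-6)

    def test_empty_selection_rejected(self):
        m1, m2 = self.two_domain_pair(30.0)
        with pytest.raises(cmp.ComparisonError):
            cmp.interdomain_rotation(m1, m2, "900-950", "900-950",
                                     "41-80", "41-80")


def gotoh_score(a, b, matrix, open_pen=10.0, ext_pen=0.5):
    """Free-end-gap affine alignment score by explicit dynamic programming."""
    n, m = len(a), len(b)
    neg = -1e9
    M = np.full((n + 1, m + 1), neg)
    Ix = np.full((n + 1, m + 1), neg)   # gap in b (insertion in a)
    Iy = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = 0.0   # free end gaps
    for j in range(1, m + 1):
        Iy[0, j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1],
                          Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] - open_pen, Ix[i - 1, j] - ext_pen)
            Iy[i, j] = max(M[i, j - 1] - open_pen, Iy[i, j - 1] - ext_pen)
            if j == m:
                Ix[i, j] = max(Ix[i, j], max(M[i - 1, j], Ix[i - 1, j]))
            if i == n:
                Iy[i, j] = max(Iy[i, j], max(M[i, j - 1], Iy[i, j - 1]))
    return max(M[n, m], Ix[n, m], Iy[n, m])


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert cmp.pairwise_identity("MKVLAW", "MKVLAW") == pytest.approx(100.0)

    def test_single_substitution(self):
        assert cmp.pairwise_identity("ACDEFG", "ACDEFA") == pytest.approx(83.33, abs=0.01)

    def test_symmetry(self):
        a, b = "MKVLAWGHILK", "MKVIAWGHLK"
        assert cmp.pairwise_identity(a, b) == pytest.approx(
            cmp.pairwise_identity(b, a), abs=1e-9)

    def test_end_gaps_excluded_from_denominator(self):
        # terminal truncation does not dilute identity
        assert cmp.pairwise_identity("MKVLAW", "KVLAW") == pytest.approx(100.0)

    def test_alphabet_error(self):
        with pytest.raises(cmp.ComparisonError):
            cmp.pairwise_identity("MKVL1", "MKVL")

    @pytest.mark.parametrize("seed", range(10))
    def test_alignment_score_matches_dp_oracle(self, seed):
        from Bio.Align import substitution_matrices
        rng = np.random.default_rng(seed)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(aa, 10))
        b = "".join(rng.choice(aa, 10))
        mat = substitution_matrices.load("BLOSUM62")
        aligner = cmp._make_aligner()
        assert aligner.score(a, b) == pytest.approx(gotoh_score(a, b, mat))

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=12),
           st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=12))
    @settings(max_examples=25, deadline=None)
    def test_identity_bounds_and_symmetry(self, a, b):
        pid = cmp.pairwise_identity(a, b)
        assert 0.0 <= pid <= 100.0
        assert pid == pytest.approx(cmp.pairwise_identity(b, a), abs=1e-9)


class TestSelections:
    def test_parse_chain_and_ranges(self):
        chain, ranges = cmp.parse_selection("chain A and 1200-1440,1500-1578")
        assert chain == "A"
        assert ranges == [(1200, 1440), (1500, 1578)]

    def test_alignment_pairing_across_numbering_offset(self, rng):
        # same fold, author numbering shifted by 8: alignment pairing fixes it
        coords = rng.normal(size=(30, 3)) * 5
        seq_names = ["ALA", "GLY", "SER", "LEU", "LYS"] * 6
        m1 = ca_model([coords], start=1)
        m2 = ca_model([coords], start=9)
        for mdl in (m1, m2):
            for i, r in enumerate(mdl.chain("A")):
                r.name = seq_names[i]
        sup = cmp.superpose(m1, m2, "1-30", "9-38", pairing="alignment")
        assert sup.rmsd < 1e-9
        assert sup.n_atoms == 30
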