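"""Pedigree renumbering, inbreeding, A and sparse A^-1."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matvar.pedigree import (PedigreeError, a_inverse, a_matrix,
                             compute_inbreeding, load_and_renumber, renumber)

from conftest import random_pedigree


class TestRenumber:
    def test_founders_identity_map(self):
        ped = renumber([("a", 0, 0), ("b", 0, 0), ("c", 0, 0)])
        assert ped.q == 3
        assert np.all(ped.f() == 0)
        assert ped.labels == ["a", "b", "c"]

    def test_undeclared_parents_inserted_as_founders(self):
        ped = renumber([("C", "A", "B")])
        assert ped.q == 3
        # A and B must precede C after renumbering
        c = ped.label_map()["C"]
        assert c == 3 and ped.sire[2] in (1, 2) and ped.dam[2] in (1, 2)

    def test_parents_precede_offspring(self):
        ped = renumber([("x", "y", "z"), ("y", "w", 0), ("z", 0, 0), ("w", 0, 0)])
        for i in range(ped.q):
            assert ped.sire[i] < i + 1 and ped.dam[i] < i + 1

    def test_self_parent_rejected(self):
        with pytest.raises(PedigreeError, match="own parent"):
            renumber([("A", "A", 0)])

    def test_cycle_rejected(self):
        with pytest.raises(PedigreeError, match="cycle"):
            renumber([("A", "B", 0), ("B", "A", 0)])

    def test_conflicting_duplicates_rejected(self):
        with pytest.raises(PedigreeError, match="conflicting"):
            renumber([("C", "A", "B"), ("C", "A", "D")])

    def test_renumbering_idempotent(self):
        rng = np.random.default_rng(5)
        ped = random_pedigree(60, rng)
        triples = [(i + 1, ped.sire[i], ped.dam[i]) for i in range(ped.q)]
        again = renumber(triples)
        assert again.labels == list(range(1, 61))
        assert np.array_equal(again.sire, ped.sire)
        assert np.array_equal(again.dam, ped.dam)

    def test_load_detects_header_and_csv(self, tmp_path):
        p = tmp_path / "ped.csv"
        p.write_text("animal,sire,dam\nA,0,0\nB,0,0\nC,A,B\n")
        ped = load_and_renumber(p)
        assert ped.q == 3 and ped.sire[2] == 1


class TestPedigreeProperties:
    """Structural invariants on arbitrary valid pedigrees."""

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), q=st.integers(20, 120))
    def test_relationship_matrix_invariants(self, seed, q):
        ped = random_pedigree(q, np.random.default_rng(seed))
        A = a_matrix(ped)
        # diagonal carries inbreeding; A is PSD; Henderson inverse inverts it
        np.testing.assert_allclose(np.diag(A), 1.0 + ped.f(), atol=1e-12)
        assert np.linalg.eigvalsh(A).min() >= -1e-10
        assert np.abs(a_inverse(ped) @ A - np.eye(q)).max() < 1e-8


class TestInbreeding:
    def test_outbred_offspring(self):
        ped = renumber([("s", 0, 0), ("d", 0, 0), ("o", "s", "d")])
        assert compute_inbreeding(ped)[2] == 0.0

    def test_full_sib_mating_gives_quarter(self):
        ped = renumber([("A", 0, 0), ("B", 0, 0), ("C", "A", "B"),
                        ("D", "A", "B"), ("X", "C", "D")])
        f = compute_inbreeding(ped)
        # brute-force tabular oracle: a(C, D) = 0.5 for full sibs
        A = a_matrix(ped)
        assert A[2, 3] == pytest.approx(0.5)
        assert f[4] == pytest.approx(0.25)

    def test_parent_offspring_mating_gives_quarter(self):
        ped = renumber([("A", 0, 0), ("B", "A", 0), ("X", "A", "B")])
        assert compute_inbreeding(ped)[2] == pytest.approx(0.25)

    def test_matches_tabular_diagonal_on_random_pedigrees(self):
        rng = np.random.default_rng(17)
        for _ in range(3):
            ped = random_pedigree(120, rng)
            f = compute_inbreeding(ped)
            A = a_matrix(ped)
            np.testing.assert_allclose(np.diag(A), 1.0 + f, atol=1e-12)


class TestAMatrix:
    def test_unrelated_founders_identity(self):
        ped = renumber([(i, 0, 0) for i in range(1, 9)])
        np.testing.assert_array_equal(a_matrix(ped), np.eye(8))

    def test_classic_relationships(self):
        ped = renumber([("s", 0, 0), ("d", 0, 0), ("d2", 0, 0),
                        ("o1", "s", "d"), ("o2", "s", "d"), ("o3", "s", "d2")])
        A = a_matrix(ped)
        m = ped.label_map()
        assert A[m["s"] - 1, m["o1"] - 1] == pytest.approx(0.5)   # parent-offspring
        assert A[m["o1"] - 1, m["o2"] - 1] == pytest.approx(0.5)  # full sibs
        assert A[m["o1"] - 1, m["o3"] - 1] == pytest.approx(0.25)  # half sibs

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(23)
        ped = random_pedigree(150, rng)
        assert np.linalg.eigvalsh(a_matrix(ped)).min() >= -1e-10

    def test_dense_cap_guard(self):
        rng = np.random.default_rng(3)
        ped = random_pedigree(50, rng)
        with pytest.raises(PedigreeError, match="cap"):
            a_matrix(ped, cap=10)


class TestAInverse:
    def test_unrelated_founders_identity(self):
        ped = renumber([(i, 0, 0) for i in range(1, 6)])
        np.testing.assert_array_equal(a_inverse(ped).toarray(), np.eye(5))

    def test_trio_henderson_pattern(self):
        ped = renumber([("s", 0, 0), ("d", 0, 0), ("o", "s", "d")])
        expected = np.array([[1.5, 0.5, -1.0],
                             [0.5, 1.5, -1.0],
                             [-1.0, -1.0, 2.0]])
        np.testing.assert_allclose(a_inverse(ped).toarray(), expected)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_inverse_matches_dense_inversion(self, seed):
        rng = np.random.default_rng(seed)
        ped = random_pedigree(50, rng)
        A = a_matrix(ped)
        prod = a_inverse(ped) @ A
        np.testing.assert_allclose(prod, np.eye(ped.q), atol=1e-8)

    def test_no_inbreeding_mode_differs_for_inbred_lines(self):
        # X is inbred (F = 0.25); its offspring Y has a Mendelian sampling
        # variance shrunk by F_X, so the two modes must disagree
        ped = renumber([("A", 0, 0), ("B", 0, 0), ("C", "A", "B"),
                        ("D", "A", "B"), ("X", "C", "D"), ("Y", "X", "B")])
        with_f = a_inverse(ped, use_inbreeding=True).toarray()
        without = a_inverse(ped, use_inbreeding=False).toarray()
        assert not np.allclose(with_f, without)
        # only the inbreeding-aware form inverts A for an inbred pedigree
        np.testing.assert_allclose(with_f @ a_matrix(ped), np.eye(6), atol=1e-8)
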