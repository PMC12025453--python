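"""Dempster-Shafer engine and the DS fusion score."""

import random

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_dempster, random_bpa
from dsrank.centrality import CentralityVector, all_centralities
from dsrank.evidence import (
    Bpa,
    TotalConflictError,
    build_evaluation_matrix,
    columns_to_bpas,
    dempster_combine,
    ds_score,
    normalize_columns,
    rank_nodes,
    vacuous_bpa,
)
from dsrank.netcore import generate_named


def fs(*elems):
    return frozenset(elems)


class TestBpaValidation:
    def test_rejects_unnormalized_mass(self):
        with pytest.raises(ValueError, match="sum"):
            Bpa(("a", "b"), {fs("a"): 0.5, fs("b"): 0.4})

    def test_rejects_mass_on_empty_set(self):
        with pytest.raises(ValueError, match="empty"):
            Bpa(("a",), {frozenset(): 0.3, fs("a"): 0.7})

    def test_rejects_foreign_focal_element(self):
        with pytest.raises(ValueError, match="subset"):
            Bpa(("a", "b"), {fs("z"): 1.0})

    def test_rejects_empty_frame(self):
        with pytest.raises(ValueError):
            Bpa((), {})


class TestDempsterCombine:
    def test_vacuous_is_neutral(self):
        m1 = Bpa(("a", "b", "c"), {fs("a"): 0.3, fs("a", "b"): 0.7})
        fused = dempster_combine(m1, vacuous_bpa(("a", "b", "c")))
        assert fused.mass == m1.mass

    def test_singleton_hand_example(self):
        """Two singleton bodies: k = 0.6*0.3 + 0.4*0.7 = 0.46."""
        m1 = Bpa(("A", "B"), {fs("A"): 0.6, fs("B"): 0.4})
        m2 = Bpa(("A", "B"), {fs("A"): 0.7, fs("B"): 0.3})
        fused = dempster_combine(m1, m2)
        assert fused.mass[fs("A")] == pytest.approx(0.42 / 0.54)
        assert fused.mass[fs("B")] == pytest.approx(0.12 / 0.54)

    def test_general_subset_hand_example(self):
        """Mixed singleton/pair focal elements, k = 0.5*0.4 = 0.2."""
        m1 = Bpa(("A", "B"), {fs("A"): 0.5, fs("A", "B"): 0.5})
        m2 = Bpa(("A", "B"), {fs("B"): 0.4, fs("A", "B"): 0.6})
        fused = dempster_combine(m1, m2)
        assert fused.mass[fs("A")] == pytest.approx(0.375)
        assert fused.mass[fs("B")] == pytest.approx(0.25)
        assert fused.mass[fs("A", "B")] == pytest.approx(0.375)

    def test_total_conflict_raises(self):
        m1 = Bpa(("A", "B"), {fs("A"): 1.0})
        m2 = Bpa(("A", "B"), {fs("B"): 1.0})
        with pytest.raises(TotalConflictError):
            dempster_combine(m1, m2)

    def test_frame_mismatch(self):
        with pytest.raises(ValueError, match="frame"):
            dempster_combine(vacuous_bpa(("a",)), vacuous_bpa(("b",)))

    def test_matches_exhaustive_enumeration(self):
        """Agreement with the all-subset-pairs oracle on frames up to size 6."""
        rng = random.Random(99)
        for trial in range(60):
            frame = tuple(range(rng.randint(2, 6)))
            m1, m2 = random_bpa(frame, rng), random_bpa(frame, rng)
            expected = brute_force_dempster(m1, m2)
            try:
                fused = dempster_combine(m1, m2)
            except TotalConflictError:
                assert expected == {}
                continue
            assert set(fused.mass) == set(expected)
            for s, w in expected.items():
                assert fused.mass[s] == pytest.approx(w, abs=1e-9)

    def test_commutative_and_associative(self):
        """Fusion order never matters; totally conflicting evidence conflicts
        totally under every grouping."""

        def fold(*ms):
            try:
                acc = ms[0]
                for m in ms[1:]:
                    acc = dempster_combine(acc, m)
                return acc
            except TotalConflictError:
                return None

        rng = random.Random(4)
        frame = tuple("abcde")
        for _ in range(40):
            m1, m2, m3 = (random_bpa(frame, rng) for _ in range(3))
            ab, ba = fold(m1, m2), fold(m2, m1)
            left, right = fold(m1, m2, m3), fold(m3, m2, m1)
            for x, y in ((ab, ba), (left, right)):
                if x is None or y is None:
                    assert x is None and y is None
                    continue
                for s in set(x.mass) | set(y.mass):
                    assert x.mass.get(s, 0) == pytest.approx(y.mass.get(s, 0), abs=1e-9)


class TestEvaluationMatrix:
    def test_single_vector(self):
        B = build_evaluation_matrix([CentralityVector("dc", {0: 1.0, 1: 2.0, 2: 1.0})])
        assert B.shape == (3, 1)
        assert list(B["dc"]) == [1.0, 2.0, 1.0]

    def test_karate_six_columns(self, karate):
        B = build_evaluation_matrix(all_centralities(karate))
        assert B.shape == (34, 6)

    def test_column_order_permutes_columns_only(self, karate):
        vecs = all_centralities(karate)
        B1 = build_evaluation_matrix(vecs)
        B2 = build_evaluation_matrix(vecs[::-1])
        assert list(B2.columns) == list(B1.columns)[::-1]
        pd.testing.assert_frame_equal(B2[B1.columns], B1)

    def test_mismatched_node_sets(self):
        v1 = CentralityVector("dc", {0: 1.0})
        v2 = CentralityVector("cc", {1: 1.0})
        with pytest.raises(ValueError, match="node set"):
            build_evaluation_matrix([v1, v2])


class TestNormalizeColumns:
    def test_simple_column(self):
        B = pd.DataFrame({"m": [2.0, 3.0, 5.0]})
        V = normalize_columns(B)
        assert list(V["m"]) == pytest.approx([0.2, 0.3, 0.5])

    def test_zero_column_becomes_uniform(self):
        V = normalize_columns(pd.DataFrame({"m": [0.0] * 4}))
        assert list(V["m"]) == pytest.approx([0.25] * 4)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        B = pd.DataFrame(rng.random((6, 4)))
        V = normalize_columns(B)
        pd.testing.assert_frame_equal(normalize_columns(V), V)

    def test_rejects_negative_entries(self):
        with pytest.raises(ValueError):
            normalize_columns(pd.DataFrame({"m": [1.0, -0.1]}))


class TestColumnsToBpas:
    def test_singleton_masses(self):
        V = pd.DataFrame({"m": [0.2, 0.8]}, index=["a", "b"])
        (bpa,) = columns_to_bpas(V)
        assert bpa.mass == {fs("a"): 0.2, fs("b"): 0.8}

    def test_zero_entry_excluded_from_focal_set(self):
        V = pd.DataFrame({"m": [0.0, 1.0]}, index=["a", "b"])
        (bpa,) = columns_to_bpas(V)
        assert fs("a") not in bpa.mass
        assert sum(bpa.mass.values()) == pytest.approx(1.0)


class TestDsScore:
    def test_single_column_is_identity(self):
        V = pd.DataFrame({"m": [0.2, 0.3, 0.5]}, index=list("abc"))
        assert list(ds_score(V)) == pytest.approx([0.2, 0.3, 0.5])

    def test_two_column_hand_value(self):
        V = pd.DataFrame({"m1": [0.6, 0.4], "m2": [0.7, 0.3]}, index=["a", "b"])
        s = ds_score(V)
        assert s["a"] == pytest.approx(0.42 / 0.54)
        assert s["b"] == pytest.approx(0.12 / 0.54)

    def test_zero_entry_zeroes_the_node(self):
        V = normalize_columns(pd.DataFrame({"m1": [1.0, 1.0], "m2": [1.0, 0.0]}))
        s = ds_score(V)
        assert s[1] == 0.0
        assert s[0] == pytest.approx(1.0)

    def test_total_conflict_when_every_row_has_a_zero(self):
        V = normalize_columns(pd.DataFrame({"m1": [1.0, 0.0], "m2": [0.0, 1.0]}))
        with pytest.raises(TotalConflictError, match="no node"):
            ds_score(V)

    def test_row_product_oracle(self):
        """For strictly positive V the Dempster fold collapses to normalized
        row products; checked elementwise on random matrices."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            raw = rng.random((rng.integers(2, 12), rng.integers(1, 7))) + 1e-6
            V = normalize_columns(pd.DataFrame(raw))
            expected = V.to_numpy().prod(axis=1)
            expected /= expected.sum()
            assert np.allclose(ds_score(V).to_numpy(), expected, atol=1e-9)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(7)
        raw = rng.random((8, 5)) + 0.01
        V = normalize_columns(pd.DataFrame(raw, columns=list("vwxyz")))
        s1 = ds_score(V)
        s2 = ds_score(V[list("zyxwv")])
        assert np.allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-9)

    def test_scale_invariance_of_raw_columns(self, karate):
        """Positive rescaling of any raw column is absorbed by normalization."""
        B = build_evaluation_matrix(all_centralities(karate))
        s1 = ds_score(normalize_columns(B))
        B2 = B.copy()
        B2["bc"] *= 1000.0
        B2["dc"] *= 0.003
        s2 = ds_score(normalize_columns(B2))
        assert np.allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-12)

    def test_monotonicity_in_single_entry(self):
        """Boosting a node's evidence in one metric never lowers its rank."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = 6
            raw = rng.random((n, 3)) + 0.05
            V = normalize_columns(pd.DataFrame(raw))
            i = int(rng.integers(n))
            before = rank_nodes(ds_score(V)).index(i)
            raw2 = raw.copy()
            raw2[i, 1] *= 1.0 + rng.random()
            after = rank_nodes(ds_score(normalize_columns(pd.DataFrame(raw2)))).index(i)
            assert after <= before


class TestRankNodes:
    def test_descending_order(self):
        assert rank_nodes({"a": 0.1, "b": 0.9}) == ["b", "a"]

    def test_tie_break_ascending_label(self):
        assert rank_nodes({"c": 0.5, "a": 0.5, "b": 0.5}) == ["a", "b", "c"]

    def test_star_top_node_is_center(self, star5):
        V = normalize_columns(build_evaluation_matrix(all_centralities(star5)))
        assert rank_nodes(ds_score(V))[0] == 0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            rank_nodes({})
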