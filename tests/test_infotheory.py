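"""Mutual information plug-in estimates and greedy JMI selection.

Oracles here are independent nested-loop summations of the defining
formulas over the empirical joint distribution, kept free of the bincount
machinery they check.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mciprog import jmi_score, jmi_select, mutual_information
from mciprog.infotheory import (
    DiscretizedFeature,
    discretize,
    entropy,
    joint_variable,
)


def mi_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    """Direct summation of sum_{q,r} p(q,r) log2 p(q,r)/(p(q) p(r))."""
    n = len(a)
    total = 0.0
    for q in np.unique(a):
        for r in np.unique(b):
            pqr = np.mean((a == q) & (b == r))
            if pqr == 0:
                continue
            total += pqr * np.log2(pqr / (np.mean(a == q) * np.mean(b == r)))
    return total


def jmi_score_bruteforce(cand, selected, y) -> float:
    """Pairwise JMI criterion with each joint MI by direct summation over
    the product alphabet (candidate, selected_j) x label."""
    if not selected:
        return mi_bruteforce(cand, y)
    total = 0.0
    for s in selected:
        pair = np.array([f"{c}|{v}" for c, v in zip(cand, s)])
        total += mi_bruteforce(pair, y)
    return total


def greedy_bruteforce(columns, y, n):
    """Independent greedy JMI selector over discrete columns."""
    remaining = list(range(len(columns)))
    selected = []
    while len(selected) < n:
        scores = [
            jmi_score_bruteforce(columns[j], [columns[s] for s in selected], y)
            for j in remaining
        ]
        best = remaining[int(np.argmax(scores))]
        selected.append(best)
        remaining.remove(best)
    return selected


def counts_to_codes(table):
    """Expand a contingency table of counts into paired code vectors."""
    a, b = [], []
    for i, row in enumerate(table):
        for j, c in enumerate(row):
            a += [i] * c
            b += [j] * c
    return np.array(a), np.array(b)


class TestMutualInformation:
    def test_identity_of_fair_coin_is_one_bit(self):
        x = np.array([0, 1] * 25)
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_independent_counts_give_zero(self):
        a, b = counts_to_codes([[25, 25], [25, 25]])
        assert mutual_information(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_dependent_2x2_table_frozen_value(self):
        # direct Eq summation over 4 cells: 0.75*log2(1.5) - 0.25
        a, b = counts_to_codes([[30, 10], [10, 30]])
        assert mutual_information(a, b) == pytest.approx(0.18872187554086717, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.array([0, 1]), np.array([0, 1, 0]))

    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)), min_size=2, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_symmetry_bounds_and_oracle(self, pairs):
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        mi_ab = mutual_information(a, b)
        assert mi_ab == pytest.approx(mutual_information(b, a), abs=1e-12)
        assert -1e-12 <= mi_ab <= min(entropy(a), entropy(b)) + 1e-12
        assert mi_ab == pytest.approx(mi_bruteforce(a, b), abs=1e-10)

    def test_merging_bins_never_increases_mi(self, rng):
        # coarsening one variable is data processing: MI cannot grow
        for _ in range(20):
            a = rng.integers(0, 4, size=80)
            b = rng.integers(0, 3, size=80)
            merged = np.where(a >= 2, 1, 0)  # merge levels {0,1} and {2,3}
            assert mutual_information(merged, b) <= mutual_information(a, b) + 1e-12


class TestDiscretize:
    def test_equal_frequency_bins(self, rng):
        v = rng.normal(size=500)
        d = discretize(v, bins=5)
        counts = np.bincount(d.codes, minlength=5)
        assert counts.min() >= 80  # roughly 100 each
        assert np.all(np.diff(d.edges) >= 0)

    def test_binary_passthrough(self):
        v = np.array([0.0, 1.0, 1.0, 0.0])
        d = discretize(v, bins=5)
        assert d.n_levels == 2
        np.testing.assert_array_equal(d.codes, [0, 1, 1, 0])

    def test_edges_learned_on_fit_rows_only(self, rng):
        v = rng.normal(size=100)
        d1 = discretize(v, bins=4, fit_values=v[:50])
        d2 = discretize(np.r_[v[:50], v[50:] + 100], bins=4, fit_values=v[:50])
        np.testing.assert_array_equal(d1.edges, d2.edges)


def informative_duplicate_toy():
    """F1 informative, F2 = copy of F1, F3 independent informative."""
    rows = []
    # P(F1 = y) = 0.8, P(F3 = y) = 0.8 independently given y
    for y in (0, 1):
        for f1 in (0, 1):
            for f3 in (0, 1):
                n = 50
                n = int(n * (0.8 if f1 == y else 0.2) * (0.8 if f3 == y else 0.2))
                rows += [(f1, f1, f3, y)] * n
    arr = np.array(rows)
    return arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]


class TestJmiScore:
    def test_empty_set_reduces_to_relevance(self):
        f1, _, _, y = informative_duplicate_toy()
        assert jmi_score(f1, [], y) == pytest.approx(mutual_information(f1, y), abs=1e-12)

    def test_independent_informative_beats_duplicate(self):
        f1, f2, f3, y = informative_duplicate_toy()
        s_dup = jmi_score(f2, [f1], y)
        s_new = jmi_score(f3, [f1], y)
        assert s_new > s_dup
        # both match the independent direct-summation oracle
        assert s_dup == pytest.approx(jmi_score_bruteforce(f2, [f1], y), abs=1e-10)
        assert s_new == pytest.approx(jmi_score_bruteforce(f3, [f1], y), abs=1e-10)

    def test_product_alphabet_joint_variable(self):
        a = DiscretizedFeature(codes=np.array([0, 1, 0]), n_levels=2, edges=np.empty(0))
        b = DiscretizedFeature(codes=np.array([0, 0, 2]), n_levels=3, edges=np.empty(0))
        j = joint_variable(a, b)
        np.testing.assert_array_equal(j.codes, [0, 3, 2])
        assert j.n_levels == 6


class TestJmiSelect:
    def test_single_feature_is_max_relevance(self):
        f1, f2, f3, y = informative_duplicate_toy()
        X = np.column_stack([f2, f1, f3]).astype(float)
        res = jmi_select(X, y, n=1)
        rel = [mutual_information(X[:, j].astype(int), y) for j in range(3)]
        assert res.selected == [int(np.argmax(rel))]

    def test_duplicate_never_selected_second(self):
        f1, f2, f3, y = informative_duplicate_toy()
        X = np.column_stack([f1, f2, f3]).astype(float)
        res = jmi_select(X, y, n=2)
        assert set(res.selected) == {0, 2} or set(res.selected) == {1, 2}

    def test_clamps_with_warning(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.integers(0, 2, size=50)
        with pytest.warns(UserWarning, match="clamped"):
            res = jmi_select(X, y, n=10)
        assert len(res.selected) == 3

    def test_greedy_trace_matches_bruteforce_on_discrete_toys(self, rng):
        # fully discrete random tables, <= 5 features, <= 3 levels
        for trial in range(10):
            P = int(rng.integers(3, 6))
            X = rng.integers(0, 3, size=(60, P)).astype(float)
            y = rng.integers(0, 2, size=60)
            res = jmi_select(X, y, n=P)
            cols = [X[:, j].astype(int) for j in range(P)]
            assert res.selected == greedy_bruteforce(cols, y, P)
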