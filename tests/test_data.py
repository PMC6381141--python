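"""Feature tables, standardization and stratified partitioning contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mciprog import (
    FeatureTable,
    Standardizer,
    read_feature_table,
    standardize,
    stratified_kfold,
    stratified_split,
    write_feature_table,
)
from mciprog.data import StratificationError


def make_table(X, y):
    names = [f"f{i}" for i in range(X.shape[1])]
    return FeatureTable(X=X, y=y, feature_names=names, modality_map={n: "m" for n in names})


class TestStandardize:
    def test_all_rows_reference_gives_unit_columns(self, rng):
        t = make_table(rng.normal(5, 3, size=(40, 6)), np.r_[np.ones(20, int), -np.ones(20, int)])
        out, _ = standardize(t)
        assert np.all(np.abs(out.X.mean(axis=0)) < 1e-10)
        assert np.allclose(out.X.std(axis=0), 1.0)

    def test_idempotent_on_standardized_table(self, rng):
        t = make_table(rng.normal(size=(30, 4)), np.r_[np.ones(15, int), -np.ones(15, int)])
        once, _ = standardize(t)
        twice, _ = standardize(once)
        np.testing.assert_allclose(twice.X, once.X, atol=1e-10)

    def test_hand_arithmetic_population_and_sample_sd(self):
        # reference values {1, 3}: mean 2, population sd 1, sample sd sqrt(2)
        X = np.array([[1.0], [3.0], [5.0]])
        pop = Standardizer.fit(X, rows=[0, 1], ddof=0)
        assert pop.transform(np.array([[5.0]]))[0, 0] == pytest.approx(3.0)
        samp = Standardizer.fit(X, rows=[0, 1], ddof=1)
        assert samp.transform(np.array([[5.0]]))[0, 0] == pytest.approx(3 / np.sqrt(2))

    def test_constant_feature_warns_and_uses_unit_sd(self):
        X = np.array([[1.0, 2.0], [1.0, 4.0], [1.0, 6.0]])
        with pytest.warns(UserWarning, match="constant"):
            s = Standardizer.fit(X)
        assert s.sd_[0] == 1.0

    def test_reference_rows_shield_from_test_perturbation(self, rng):
        # fitting on training rows only: changing a held-out row changes nothing
        X = rng.normal(size=(20, 3))
        ref = np.arange(15)
        s1 = Standardizer.fit(X, rows=ref)
        X2 = X.copy()
        X2[19] += 100.0
        s2 = Standardizer.fit(X2, rows=ref)
        np.testing.assert_array_equal(s1.mean_, s2.mean_)
        np.testing.assert_array_equal(s1.sd_, s2.sd_)


class TestStratifiedSplit:
    def test_study_counts(self):
        y = np.r_[np.ones(39, int), -np.ones(96, int)]
        tr, te = stratified_split(y, 0.2, seed=0)
        assert len(te) == 26  # floor(39*0.2) + floor(96*0.2) = 7 + 19
        assert int((y[te] == 1).sum()) == 7
        assert int((y[te] == -1).sum()) == 19
        assert len(np.intersect1d(tr, te)) == 0
        assert len(np.union1d(tr, te)) == len(y)

    def test_determinism_and_seed_sensitivity(self):
        y = np.r_[np.ones(39, int), -np.ones(96, int)]
        a = stratified_split(y, 0.2, seed=5)
        b = stratified_split(y, 0.2, seed=5)
        c = stratified_split(y, 0.2, seed=6)
        np.testing.assert_array_equal(a[1], b[1])
        assert not np.array_equal(a[1], c[1])
        assert int((y[c[1]] == 1).sum()) == 7  # counts invariant across seeds

    @pytest.mark.parametrize("frac", [0.0, 1.0, 0.01])
    def test_degenerate_fractions_rejected(self, frac):
        y = np.r_[np.ones(10, int), -np.ones(10, int)]
        with pytest.raises(StratificationError):
            stratified_split(y, frac, seed=0)

    def test_tiny_class_rejected(self):
        y = np.r_[np.ones(1, int), -np.ones(20, int)]
        with pytest.raises(StratificationError):
            stratified_split(y, 0.5, seed=0)

    @given(n_pos=st.integers(2, 5), n_neg=st.integers(2, 6), seed=st.integers(0, 10))
    @settings(max_examples=40, deadline=None)
    def test_floor_rule_on_tiny_vectors(self, n_pos, n_neg, seed):
        y = np.r_[np.ones(n_pos, int), -np.ones(n_neg, int)]
        frac = 0.5
        try:
            tr, te = stratified_split(y, frac, seed=seed)
        except StratificationError:
            assert min(n_pos, n_neg) * frac < 1
            return
        assert int((y[te] == 1).sum()) == int(np.floor(n_pos * frac))
        assert int((y[te] == -1).sum()) == int(np.floor(n_neg * frac))


class TestStratifiedKFold:
    def test_study_fold_counts(self):
        y = np.r_[np.ones(39, int), -np.ones(96, int)]
        plan = stratified_kfold(y, k=5, seed=0)
        for tr, te in plan.folds:
            assert int((y[te] == 1).sum()) in (7, 8)
            assert int((y[te] == -1).sum()) in (19, 20)

    def test_partition_property(self):
        y = np.r_[np.ones(39, int), -np.ones(96, int)]
        plan = stratified_kfold(y, k=5, seed=3)
        all_test = np.concatenate([te for _, te in plan.folds])
        assert len(all_test) == len(y)
        assert len(np.unique(all_test)) == len(y)
        for tr, te in plan.folds:
            assert len(np.intersect1d(tr, te)) == 0

    def test_leave_one_out_on_balanced_labels(self):
        y = np.r_[np.ones(4, int), -np.ones(4, int)]
        plan = stratified_kfold(y, k=4, seed=0)
        # with k = class size each fold holds one member of each class
        for _, te in plan.folds:
            assert len(te) == 2

    def test_small_class_rejected(self):
        y = np.r_[np.ones(3, int), -np.ones(20, int)]
        with pytest.raises(StratificationError):
            stratified_kfold(y, k=5, seed=0)


class TestIO:
    def test_csv_round_trip(self, tmp_path, rng):
        t = make_table(rng.normal(size=(12, 3)), np.r_[np.ones(5, int), -np.ones(7, int)])
        f, l, mj = tmp_path / "x.csv", tmp_path / "y.csv", tmp_path / "m.json"
        write_feature_table(t, f, l, mj)
        back = read_feature_table(f, l, mj)
        np.testing.assert_allclose(back.X, t.X)
        np.testing.assert_array_equal(back.y, t.y)
        assert back.feature_names == t.feature_names
        assert back.modality_map == t.modality_map

    def test_validation_catches_bad_tables(self):
        with pytest.raises(ValueError, match="NaN"):
            make_table(np.array([[np.nan, 1.0]]), np.array([1])).validate()
        with pytest.raises(ValueError, match="classes"):
            make_table(np.ones((3, 2)), np.ones(3, int)).validate()
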