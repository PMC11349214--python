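"""Preprocessing: filtering, Cramér's V, category merging, Gower/KNN
imputation, SMOTE-NC and the spirometry variable sets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from copdgraph.preprocess import (
    cramers_v,
    filter_variables,
    gower_distance,
    gower_matrix,
    knn_impute,
    make_variable_sets,
    merge_sparse_categories,
    smote_nc,
)
from copdgraph.simulate import CohortSpec, inject_missing, make_copd_like
from conftest import make_dataset


class TestCramersV:
    def test_identical_binary_columns_give_one(self):
        x = pd.Series(["a", "b"] * 20)
        assert cramers_v(x, x) == pytest.approx(1.0)

    def test_diagonal_table_gives_one(self):
        x = ["a"] * 10 + ["b"] * 10
        y = ["u"] * 10 + ["v"] * 10
        assert cramers_v(pd.Series(x), pd.Series(y)) == pytest.approx(1.0)

    def test_independent_uniform_binaries_near_zero(self, rng):
        n = 10000
        x = pd.Series(np.where(rng.random(n) < 0.5, "a", "b"))
        y = pd.Series(np.where(rng.random(n) < 0.5, "u", "v"))
        assert cramers_v(x, y) < 0.05

    def test_symmetry(self, rng):
        x = pd.Series(rng.choice(list("abc"), 200))
        y = pd.Series(rng.choice(list("uv"), 200))
        assert cramers_v(x, y) == pytest.approx(cramers_v(y, x))

    def test_single_level_is_an_error(self):
        with pytest.raises(ValueError, match="<2 observed levels"):
            cramers_v(pd.Series(["a"] * 10), pd.Series(["u", "v"] * 5))


class TestGower:
    def test_hand_computed_mixed_example(self):
        a = pd.Series({"x": 2.0, "c": "red"})
        b = pd.Series({"x": 7.0, "c": "blue"})
        d = gower_distance(a, b, {"x": 10.0}, {"x": "continuous", "c": "categorical"})
        assert d == pytest.approx((0.5 + 1.0) / 2)

    def test_missing_variables_are_excluded(self):
        a = pd.Series({"x": 2.0, "c": "red"})
        b = pd.Series({"x": 7.0, "c": None})
        d = gower_distance(a, b, {"x": 10.0}, {"x": "continuous", "c": "categorical"})
        assert d == pytest.approx(0.5)

    def test_no_common_variable_is_an_error(self):
        a = pd.Series({"x": 1.0, "c": None})
        b = pd.Series({"x": np.nan, "c": "red"})
        with pytest.raises(ValueError, match="commonly observed"):
            gower_distance(a, b, {"x": 1.0}, {"x": "continuous", "c": "categorical"})

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 10, allow_nan=False),
                st.sampled_from(["a", "b", "c"]),
            ),
            min_size=2, max_size=6,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_symmetric_bounded_and_zero_iff_equal(self, rows):
        frame = pd.DataFrame(rows, columns=["x", "c"])
        kinds = {"x": "continuous", "c": "categorical"}
        D = gower_matrix(frame, frame, {"x": 10.0}, kinds)
        assert np.allclose(D, D.T)
        assert (D >= -1e-12).all() and (D <= 1 + 1e-12).all()
        for i in range(len(rows)):
            for j in range(len(rows)):
                if rows[i] == rows[j]:
                    assert D[i, j] == pytest.approx(0.0)


class TestMergeSparseCategories:
    def make(self, counts, levels):
        col = sum(([lv] * c for lv, c in zip(levels, counts)), [])
        return make_dataset({"v": col}, {"v": "categorical"}, {"v": tuple(levels)})

    def test_rarest_levels_merged_up_to_the_category_cap(self):
        # e merges into d, then d|e into c; the <=3-level cap then holds
        ds = self.make([500, 400, 300, 5, 3], list("abcde"))
        out = merge_sparse_categories(ds, min_count=10)
        assert out.levels("v") == ("a", "b", "c|d|e")
        counts = out.values["v"].value_counts()
        assert counts.min() >= 10

    def test_level_cap_of_three_binds_on_balanced_levels(self):
        ds = self.make([50, 50, 50, 50], list("abcd"))
        out = merge_sparse_categories(ds, min_count=10)
        assert len(out.levels("v")) == 3

    def test_binary_untouched(self):
        ds = self.make([3, 997], list("ab"))
        out = merge_sparse_categories(ds, min_count=10)
        assert out.levels("v") == ("a", "b")

    def test_collapse_to_single_level_flagged(self):
        ds = self.make([4, 3, 2], list("abc"))
        out = merge_sparse_categories(ds, min_count=100)
        assert bool(out.meta.loc["v", "collapsed"])


class TestFilterVariables:
    def test_constant_and_duplicate_dropped_with_reasons(self, rng):
        x = rng.normal(size=50)
        ds = make_dataset(
            {"x": x, "x2": x.copy(), "const": np.ones(50)},
            {"x": "continuous", "x2": "continuous", "const": "continuous"},
        )
        out, rep = filter_variables(ds)
        reasons = dict(rep.dropped)
        assert reasons["const"] == "duplicate/constant"
        assert reasons["x2"] == "duplicate/constant"
        assert out.variables == ["x"]

    def test_correlated_pair_reported_with_statistic(self, rng):
        n = 400
        base = rng.normal(size=n)
        cols = {f"v{i}": rng.normal(size=n) for i in range(8)}
        cols["a"] = base
        cols["b"] = base + 0.22 * rng.normal(size=n)  # R^2 ~ 0.95
        ds = make_dataset(cols, {k: "continuous" for k in cols})
        out, rep = filter_variables(ds, corr_max=0.9)
        assert len(out.variables) == 9
        (va, vb, stat, kind) = rep.correlation_pairs[0]
        assert {va, vb} == {"a", "b"} and kind == "r2"
        assert stat == pytest.approx(0.95, abs=0.03)

    def test_idempotent(self, copd_cohort):
        data, _, _ = copd_cohort
        once, _ = filter_variables(data)
        twice, rep2 = filter_variables(once)
        assert twice.variables == once.variables
        assert rep2.dropped == []

    def test_outcome_never_dropped(self):
        y = ["no", "yes"] * 25
        ds = make_dataset(
            {"y": y, "ycopy": list(y)},
            {"y": "categorical", "ycopy": "categorical"},
            levels={"y": ("no", "yes"), "ycopy": ("no", "yes")},
            outcome="y",
        )
        out, rep = filter_variables(ds)
        assert "y" in out.variables and "ycopy" not in out.variables


class TestKnnImpute:
    def test_identical_donors_recover_exact_value(self):
        rows = {"x": [3.0] * 6, "c": ["a"] * 6}
        ds = make_dataset(rows, {"x": "continuous", "c": "categorical"},
                          {"c": ("a", "b")})
        ds.values.loc[0, "x"] = np.nan
        ds.values.loc[1, "c"] = np.nan
        # give x some spread so its range is positive
        ds.values.loc[5, "x"] = 4.0
        out = knn_impute(ds, k=5)
        assert out.values.loc[0, "x"] == pytest.approx(np.mean([3, 3, 3, 3, 4]))
        assert out.values.loc[1, "c"] == "a"
        assert out.is_complete()

    def test_observed_cells_unchanged_and_complete_is_identity(self, copd_cohort):
        data, _, _ = copd_cohort
        assert knn_impute(data, k=5).values.equals(data.values)
        masked = inject_missing(data, 0.03, seed=2)
        filled = knn_impute(masked, k=5)
        obs = ~masked.mask
        for v in data.variables:
            assert (
                filled.values[v][obs[v]].tolist()
                == masked.values[v][obs[v]].tolist()
            )

    def test_beats_column_mean_imputation_on_continuous(self):
        data, _, _ = make_copd_like(CohortSpec(seed=8, n_subjects=1000))
        masked = inject_missing(data, 0.05, seed=3)
        filled = knn_impute(masked, k=5)
        err_knn, err_mean = [], []
        for v in data.continuous_vars:
            m = masked.mask[v]
            if not m.any():
                continue
            truth = data.values[v][m].to_numpy(dtype=float)
            got = filled.values[v][m].to_numpy(dtype=float)
            colmean = masked.values[v].mean()
            err_knn.append(((got - truth) ** 2).sum())
            err_mean.append(((colmean - truth) ** 2).sum())
        assert np.sqrt(sum(err_knn)) < np.sqrt(sum(err_mean))


class TestSmoteNC:
    def test_balances_exactly_and_keeps_prefix(self, copd_cohort):
        data, _, _ = copd_cohort
        out = smote_nc(data, k=5, seed=1)
        y = out.outcome_values()
        assert y.sum() == (1 - y).sum()
        n = data.n_subjects
        assert out.values.iloc[:n].equals(data.values)
        assert not out.synthetic[:n].any() and out.synthetic[n:].all()

    def test_interpolation_stays_in_seed_neighbor_range(self, copd_cohort):
        data, _, _ = copd_cohort
        out = smote_nc(data, k=5, seed=2)
        synth = out.values[out.synthetic]
        real_min = data.values[data.continuous_vars].min()
        real_max = data.values[data.continuous_vars].max()
        for v in data.continuous_vars:
            assert (synth[v] >= real_min[v] - 1e-9).all()
            assert (synth[v] <= real_max[v] + 1e-9).all()

    def test_balanced_input_is_identity(self):
        ds = make_dataset(
            {"x": np.arange(40.0), "y": ["no", "yes"] * 20},
            {"x": "continuous", "y": "categorical"},
            {"y": ("no", "yes")}, outcome="y",
        )
        out = smote_nc(ds, k=3, seed=0)
        assert out.values.equals(ds.values)

    def test_minority_smaller_than_k_fails_with_guidance(self):
        ds = make_dataset(
            {"x": np.arange(20.0), "y": ["no"] * 17 + ["yes"] * 3},
            {"x": "continuous", "y": "categorical"},
            {"y": ("no", "yes")}, outcome="y",
        )
        with pytest.raises(ValueError, match="lower k"):
            smote_nc(ds, k=5, seed=0)


class TestVariableSets:
    def test_spirometry_roles_partition_columns(self, copd_cohort):
        data, _, _ = copd_cohort
        limited, nospiro = make_variable_sets(data)
        derived = [v for v in data.variables if data.role(v) == "spirometry-derived"]
        spiro = [v for v in data.variables if data.role(v) == "spirometry"]
        assert set(limited.variables) == set(data.variables) - set(derived)
        assert set(nospiro.variables) == set(limited.variables) - set(spiro)
        assert "fef2575" in limited.variables and "fef2575" not in nospiro.variables
        assert limited.outcome_name == nospiro.outcome_name == "dgold0"
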