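"""Markov-blanket extraction, AUROC, model fits, Shapley attributions,
stability counts and validation refits."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from copdgraph.fci import learn_pag_oracle
from copdgraph.mb import extract_mb, stability_table, MarkovBlanket
from copdgraph.pag import PAG
from copdgraph.predict import (
    FeatureEncoder,
    alpha_grid,
    auroc,
    fit_elastic_net,
    fit_logistic,
    fit_random_forest,
    fit_subgroup_models,
    nested_cv,
    refit_without,
    roc_curve,
    shapley_importance,
)
from copdgraph.simulate import CohortSpec, GroundTruthDAG, make_copd_like, simulate_mixed
from conftest import make_dataset


def make_dag(edges):
    g = nx.DiGraph()
    for v in {v for e in edges for v in e}:
        g.add_node(v, kind="continuous")
    g.add_edges_from(edges)
    return GroundTruthDAG(g, {})


class TestExtractMB:
    def test_isolated_target_gives_empty_blanket(self):
        pag = PAG(["T", "A"])
        assert extract_mb(pag, "T").members == []

    def test_textbook_blanket_includes_spouse(self):
        # A -> T <- B, T -> C, D -> C: MB(T) = {A, B, C, D}
        pag = learn_pag_oracle(
            make_dag([("A", "T"), ("B", "T"), ("T", "C"), ("D", "C")])
        )
        mb = extract_mb(pag, "T")
        assert set(mb.members) >= {"A", "B", "C", "D"}
        assert "T" not in mb.members

    def test_unknown_target_rejected(self):
        with pytest.raises(KeyError):
            extract_mb(PAG(["A"]), "missing")


class TestAuroc:
    def test_textbook_values(self):
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)
        assert auroc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert auroc([4, 3, 2, 1], [0, 0, 1, 1]) == 0.0

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="both classes"):
            auroc([0.1, 0.2], [1, 1])

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_invariant_under_monotone_transform_and_equals_trapezoid(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        scores = np.round(rng.normal(size=n), 1)  # ties likely
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        a = auroc(scores, labels)
        assert auroc(np.exp(scores), labels) == pytest.approx(a, abs=1e-12)
        assert roc_curve(scores, labels).area == pytest.approx(a, abs=1e-10)


class TestFitLogistic:
    def test_recovers_generative_coefficient(self, rng):
        n = 5000
        est = []
        for _ in range(10):
            x = rng.normal(size=n)
            p = 1 / (1 + np.exp(1.2 * x))  # slope -1.2
            y = np.where(rng.random(n) < p, "yes", "no")
            ds = make_dataset(
                {"x": x, "y": y}, {"x": "continuous", "y": "categorical"},
                {"y": ("no", "yes")}, outcome="y",
            )
            fit = fit_logistic(ds, ["x"])
            est.append(float(fit.coefficients.set_index("term")
                             .loc["x", "estimate"]))
        assert np.mean(est) == pytest.approx(-1.2, abs=0.15)

    def test_intercept_near_zero_on_balanced_outcome(self, rng):
        n = 10000
        y = np.r_[["no"] * (n // 2), ["yes"] * (n // 2)]
        ds = make_dataset({"y": y}, {"y": "categorical"}, {"y": ("no", "yes")},
                          outcome="y")
        fit = fit_logistic(ds, [])
        assert abs(fit.coefficients["estimate"].iloc[0]) < 0.05

    def test_perfect_separation_flagged_not_crashed(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = np.r_[["no"] * 20, ["yes"] * 20]
        ds = make_dataset({"x": x, "y": y},
                          {"x": "continuous", "y": "categorical"},
                          {"y": ("no", "yes")}, outcome="y")
        fit = fit_logistic(ds, ["x"])
        assert "perfect-separation-ridge" in fit.flags
        assert np.isfinite(fit.coefficients["SE"]).all()

    def test_coefficient_table_has_reporting_layout(self, copd_cohort):
        data, dag, _ = copd_cohort
        fit = fit_logistic(data, sorted(dag.markov_blanket("dgold0")))
        assert list(fit.coefficients.columns) == [
            "term", "estimate", "SE", "p-value"
        ]
        assert fit.coefficients["term"].iloc[0] == "(Intercept)"
        assert "sex[female]" in set(fit.coefficients["term"])


class TestComparisonModels:
    def test_forest_separates_deterministic_outcome(self, rng):
        n = 800
        a, b = rng.normal(size=n), rng.normal(size=n)
        y = np.where(a + b > 0, "yes", "no")
        ds = make_dataset(
            {"a": a, "b": b, "y": y},
            {"a": "continuous", "b": "continuous", "y": "categorical"},
            {"y": ("no", "yes")}, outcome="y",
        )
        fit = fit_random_forest(ds, n_folds=4, seed=0)
        assert fit.auroc["train_mean"] > 0.95

    def test_forest_near_chance_on_permuted_outcome(self, rng):
        n = 600
        cols = {f"v{i}": rng.normal(size=n) for i in range(6)}
        cols["y"] = rng.permutation(np.r_[["yes"] * 120, ["no"] * 480])
        ds = make_dataset(
            cols, {k: "continuous" for k in cols} | {"y": "categorical"},
            {"y": ("no", "yes")}, outcome="y",
        )
        fit = fit_random_forest(ds, n_folds=4, seed=1)
        assert 0.4 < fit.auroc["train_mean"] < 0.6

    def test_elastic_net_heavy_penalty_zeroes_slopes(self, rng):
        n = 500
        x = rng.normal(size=n)
        y = np.where(rng.random(n) < 1 / (1 + np.exp(-x)), "yes", "no")
        ds = make_dataset({"x": x, "y": y},
                          {"x": "continuous", "y": "categorical"},
                          {"y": ("no", "yes")}, outcome="y")
        from sklearn.linear_model import LogisticRegression

        enc = FeatureEncoder(ds, ["x"])
        m = LogisticRegression(solver="saga", l1_ratio=1.0, C=1e-6,
                               max_iter=2000)
        m.fit(enc.transform(ds), ds.outcome_values())
        assert np.allclose(m.coef_, 0.0)

    def test_lasso_keeps_at_most_one_of_duplicated_feature(self, rng):
        n = 800
        x = rng.normal(size=n)
        y = np.where(rng.random(n) < 1 / (1 + np.exp(-1.5 * x)), "yes", "no")
        ds = make_dataset(
            {"x1": x, "x2": x.copy(), "y": y},
            {"x1": "continuous", "x2": "continuous", "y": "categorical"},
            {"y": ("no", "yes")}, outcome="y",
        )
        from sklearn.linear_model import LogisticRegression

        enc = FeatureEncoder(ds, ["x1", "x2"])
        # with exact duplicates the l1 solution is non-unique, but at some
        # moderate penalty a coordinate-descent solver retains exactly one of
        # the pair while it is still predictive
        found = False
        for C in (0.2, 0.1, 0.05, 0.02, 0.01):
            m = LogisticRegression(penalty="l1", solver="liblinear", C=C,
                                   max_iter=4000, random_state=0)
            m.fit(enc.transform(ds), ds.outcome_values())
            nonzero = np.abs(m.coef_[0]) > 1e-8
            if nonzero.sum() == 1:
                found = True
                break
        assert found


class TestSubgroupModels:
    def test_too_few_events_rejected(self, copd_cohort):
        data, dag, axes = copd_cohort
        subtype = np.where(axes.copd_type, "copd", "")
        # no prism events at all
        with pytest.raises(ValueError, match="prism"):
            fit_subgroup_models(data, ["age"], subtype)

    def test_identical_wiring_gives_agreeing_coefficients(self, rng):
        # when both axes share every mechanism the two subgroup fits see
        # exchangeable event sets
        from copdgraph.predict import fit_subgroup_models
        import copdgraph.simulate as S

        saved = {k: dict(v) for k, v in S._AXIS_WEIGHTS.items()}
        try:
            for k in S._AXIS_WEIGHTS:
                w = S._AXIS_WEIGHTS[k]
                m = (abs(w["f"]) + abs(w["r"])) / 2 * np.sign(w["f"] + w["r"])
                w["f"] = w["r"] = m
            data, dag, axes = S.make_copd_like(S.CohortSpec(seed=23))
            subtype = np.where(axes.copd_type, "copd",
                               np.where(axes.prism_type, "prism", ""))
            feats = sorted(dag.markov_blanket("dgold0"))
            copd_fit, prism_fit = fit_subgroup_models(data, feats, subtype)
            a = copd_fit.coefficients.set_index("term")
            b = prism_fit.coefficients.set_index("term")
            for term in a.index:
                diff = abs(a.loc[term, "estimate"] - b.loc[term, "estimate"])
                joint_se = np.hypot(a.loc[term, "SE"], b.loc[term, "SE"])
                assert diff < 3.5 * joint_se
        finally:
            S._AXIS_WEIGHTS.clear()
            S._AXIS_WEIGHTS.update(saved)


class TestShapley:
    def test_additive_model_ratio_and_efficiency(self, rng):
        n = 400
        a, b = rng.normal(size=n), rng.normal(size=n)
        p = 1 / (1 + np.exp(-(2 * a + 1 * b)))
        y = np.where(rng.random(n) < p, "yes", "no")
        ds = make_dataset(
            {"a": a, "b": b, "y": y},
            {"a": "continuous", "b": "continuous", "y": "categorical"},
            {"y": ("no", "yes")}, outcome="y",
        )
        fit = fit_logistic(ds, ["a", "b"])
        sub = ds.subset_rows(np.arange(60))
        vals = shapley_importance(fit, sub, n_mc=200, seed=0, background=ds)
        ratio = vals["a"].abs().mean() / vals["b"].abs().mean()
        assert ratio == pytest.approx(2.0, rel=0.2)
        # efficiency: per-subject attributions sum to prediction - base rate
        pred = fit.predict_risk(sub)
        base = fit.predict_risk(ds).mean()
        gap = vals.sum(axis=1).to_numpy() - (pred - base)
        assert np.abs(gap).mean() < 0.03

    def test_ignored_feature_gets_no_credit(self, rng):
        n = 300
        a = rng.normal(size=n)
        dummy = rng.normal(size=n)
        y = np.where(rng.random(n) < 1 / (1 + np.exp(-2 * a)), "yes", "no")
        ds = make_dataset(
            {"a": a, "dummy": dummy, "y": y},
            {"a": "continuous", "dummy": "continuous", "y": "categorical"},
            {"y": ("no", "yes")}, outcome="y",
        )
        fit = fit_logistic(ds, ["a"])
        fit.features = ["a", "dummy"]  # model never looks at dummy
        enc_fit = fit_logistic(ds, ["a"])
        vals = shapley_importance(enc_fit, ds.subset_rows(np.arange(50)),
                                  n_mc=50, seed=1, background=ds)
        assert "dummy" not in vals.columns or vals["dummy"].abs().mean() < 0.01

    def test_too_few_samples_refused(self, copd_cohort):
        data, dag, _ = copd_cohort
        fit = fit_logistic(data, ["age"])
        with pytest.raises(ValueError, match="n_mc"):
            shapley_importance(fit, data, n_mc=5, seed=0)


class TestRefitWithout:
    def test_drop_changes_feature_list_and_scores_eval(self, copd_cohort):
        data, dag, _ = copd_cohort
        mb = sorted(dag.markov_blanket("dgold0"))
        fit = fit_logistic(data, mb)
        fresh = simulate_mixed(dag, 4000, seed=77)
        out = refit_without(fit, "pi10", data, fresh)
        assert "pi10" not in out.features
        assert 0.5 < out.auroc["test"] < 1.0

    def test_dropping_strongest_feature_hurts_more_than_weakest(self, copd_cohort):
        data, dag, _ = copd_cohort
        mb = sorted(dag.markov_blanket("dgold0"))
        fit = fit_logistic(data, mb)
        fresh = simulate_mixed(dag, 8000, seed=78)
        full_auc = auroc(fit.predict_risk(fresh), fresh.outcome_values())
        drop_fef = refit_without(fit, "fef2575", data, fresh).auroc["test"]
        assert drop_fef < full_auc

    def test_empty_remainder_rejected(self, copd_cohort):
        data, _, _ = copd_cohort
        fit = fit_logistic(data, ["age"])
        with pytest.raises(ValueError, match="no features left"):
            refit_without(fit, "age", data, data)


class TestStabilityAndGrid:
    def test_grid_shape_and_bounds(self):
        g = alpha_grid()
        assert len(g) == 10
        assert g[0] == pytest.approx(1e-5) and g[-1] == pytest.approx(1e-1)
        assert np.all(np.diff(np.log10(g)) > 0)
        ratios = np.diff(np.log10(g))
        assert np.allclose(ratios, ratios[0])

    def test_stability_counts_folds_per_alpha(self):
        mbs = {}
        for fold in range(3):
            mbs[(fold, 0.01)] = MarkovBlanket("y", ["a"], [])
            mbs[(fold, 0.1)] = MarkovBlanket("y", ["a", "b"] if fold < 2
                                             else ["a"], [])
        table = stability_table(mbs, n_folds=3, alphas=[0.01, 0.1])
        frame = table.to_frame()
        assert frame.loc["a", 0.01] == 3 and frame.loc["a", 0.1] == 3
        assert frame.loc["b", 0.1] == 2 and frame.loc["b", 0.01] == 0
        assert "c" not in frame.index
        assert frame.index[0] == "a"  # ordered by total count


class TestNestedCVLight:
    def test_no_leakage_of_validation_rows_into_training(self, monkeypatch):
        # every record entering SMOTE/graph/model fitting for a fold must
        # come from outside that fold's validation subjects
        import copdgraph.predict as P

        data, dag, _ = make_copd_like(CohortSpec(seed=31, n_subjects=400,
                                                 n_observed=16, n_latent=1,
                                                 mb_size=4))
        data.values["row_id"] = np.arange(len(data.values))  # tracer
        tracer = data.values.pop("row_id")
        seen = []
        orig = P.smote_nc

        def spy(ds, **kw):
            seen.append(set(ds.values["age"].round(9)))
            return orig(ds, **kw)

        monkeypatch.setattr(P, "smote_nc", spy)
        from sklearn.model_selection import StratifiedKFold

        res = nested_cv(data, alpha_grid(3), n_folds=3, seed=5)
        y = data.outcome_values()
        folds = list(
            StratifiedKFold(3, shuffle=True, random_state=5).split(y * 0, y)
        )
        for (tr, va), train_ages in zip(folds, seen[:3]):
            val_ages = set(data.values["age"].iloc[va].round(9))
            assert not (train_ages & val_ages)

    def test_reproducible_end_to_end(self):
        data, _, _ = make_copd_like(CohortSpec(seed=13, n_subjects=400,
                                               n_observed=16, n_latent=1,
                                               mb_size=4))
        r1 = nested_cv(data, alpha_grid(3), n_folds=3, seed=2)
        r2 = nested_cv(data, alpha_grid(3), n_folds=3, seed=2)
        assert r1.selected_alpha == r2.selected_alpha
        assert r1.final_mb.members == r2.final_mb.members
        assert r1.cv_auroc.equals(r2.cv_auroc)
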