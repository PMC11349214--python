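"""Markov-blanket-restricted prediction of the spirometric outcome.

The outcome's blanket is re-extracted inside every cross-validation fold
at every sparsity level (CI-test alpha); the alpha maximizing mean
validation AUROC is selected, and the final blanket-restricted logistic
model is refit on the full training data at that alpha.  Comparison models
(an all-variable random forest and a logistic elastic net) reuse the same
folds.  Class rebalancing (SMOTE-NC) is applied strictly inside fold
training portions; validation subjects never enter oversampling, graph
learning or model fitting for their fold.

AUROC is computed in Mann-Whitney (concordance) form with ties counted
one half, which equals the trapezoidal area under the empirical ROC curve.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .citest import CITester
from .dataset import CATEGORICAL, CONTINUOUS, MixedDataset
from .fci import learn_pag
from .mb import MarkovBlanket, StabilityTable, extract_mb, stability_table
from .mgm import fit_mgm
from .preprocess import smote_nc

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# AUROC


def auroc(scores, labels) -> float:
    """Concordance-probability AUROC (Mann-Whitney form, ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclasses.dataclass
class RocCurve:
    """Empirical ROC curve; ``area`` is the trapezoidal integral."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray

    @property
    def area(self) -> float:
        return float(np.trapezoid(self.sensitivity, self.one_minus_specificity))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "one_minus_specificity": self.one_minus_specificity,
            }
        ).to_csv(path, index=False)


def roc_curve(scores, labels) -> RocCurve:
    """Empirical ROC computed by direct threshold sweep."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    n1, n0 = int(y.sum()), int(len(y) - y.sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC undefined: both classes must be present")
    # collapse tied thresholds
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    sens = np.r_[0.0, tp / n1]
    fpr = np.r_[0.0, fp / n0]
    thr = np.r_[np.inf, s[distinct]]
    return RocCurve(thr, sens, fpr)


# ---------------------------------------------------------------------------
# feature encoding


class FeatureEncoder:
    """Standardized continuous + reference-coded categorical design.

    Fitted on training data; the held-out transform reuses the training
    means, SDs and level lists.
    """

    def __init__(self, data: MixedDataset, features):
        self.features = list(features)
        self.terms: list[str] = []
        self._spec: list[tuple] = []
        for var in self.features:
            if data.kind(var) == CONTINUOUS:
                col = data.values[var].to_numpy(dtype=float)
                sd = float(col.std())
                self._spec.append((var, "cont", float(col.mean()), sd if sd else 1.0))
                self.terms.append(var)
            else:
                levels = list(data.levels(var))
                self._spec.append((var, "cat", levels))
                self.terms.extend(f"{var}[{lv}]" for lv in levels[1:])

    def transform(self, data: MixedDataset) -> np.ndarray:
        cols = []
        for spec in self._spec:
            var = spec[0]
            if spec[1] == "cont":
                _, _, mean, sd = spec
                cols.append((data.values[var].to_numpy(dtype=float) - mean) / sd)
            else:
                col = data.values[var].to_numpy()
                for lv in spec[2][1:]:
                    cols.append((col == lv).astype(float))
        if not cols:
            return np.zeros((data.n_subjects, 0))
        return np.column_stack(cols)


# ---------------------------------------------------------------------------
# fit results


@dataclasses.dataclass
class FitResult:
    """A fitted classifier with its evaluation record.

    ``coefficients`` (term, estimate, SE, p-value) is present for linear
    model kinds only; ``auroc`` holds train_mean / train_sd / test /
    validation entries as they become available.
    """

    model_kind: str
    features: list
    auroc: dict
    coefficients: pd.DataFrame | None = None
    selected_alpha: float | None = None
    flags: tuple = ()
    _predict: object | None = dataclasses.field(default=None, repr=False)

    def predict_risk(self, data: MixedDataset) -> np.ndarray:
        if self._predict is None:
            raise ValueError("fit carries no predictor")
        return self._predict(data)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model_kind": self.model_kind,
            "features": list(self.features),
            "selected_alpha": self.selected_alpha,
            "auroc": {k: (None if v is None else float(v))
                      for k, v in self.auroc.items()},
            "flags": list(self.flags),
        }
        if self.coefficients is not None:
            payload["coefficients"] = self.coefficients.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def coefficients_csv(self, path: str | Path) -> None:
        if self.coefficients is None:
            raise ValueError(f"{self.model_kind} fit has no coefficient table")
        self.coefficients.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# logistic regression


def fit_logistic(data: MixedDataset, features) -> FitResult:
    """Maximum-likelihood logistic regression on blanket features.

    Continuous predictors are standardized and categorical predictors
    reference-coded; the coefficient table reports Wald standard errors and
    p-values.  Under perfect separation the fit falls back to a
    ridge-stabilized Newton solve (penalty 1e-4) and the result is flagged.
    """
    features = [f for f in features if f != data.outcome_name]
    enc = FeatureEncoder(data, features)
    X = sm.add_constant(enc.transform(data), has_constant="add")
    y = data.outcome_values()
    terms = ["(Intercept)"] + enc.terms
    flags: tuple = ()
    try:
        import warnings as _warnings

        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.filterwarnings(
                "error", category=sm.tools.sm_exceptions.PerfectSeparationWarning
            )
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params, bse = res.params, res.bse
        if not np.all(np.isfinite(bse)) or np.abs(params).max() > 1e3:
            raise np.linalg.LinAlgError
    except Exception:
        params, bse = _ridge_logistic(X, y, penalty=1e-4)
        flags = ("perfect-separation-ridge",)
        logger.warning("logistic fit unstable; ridge-stabilized estimates reported")
    z = params / bse
    from scipy.stats import norm as _norm

    pvals = 2 * _norm.sf(np.abs(z))
    table = pd.DataFrame(
        {"term": terms, "estimate": params, "SE": bse, "p-value": pvals}
    )

    def predict(ds: MixedDataset, _enc=enc, _b=np.asarray(params)) -> np.ndarray:
        Xn = sm.add_constant(_enc.transform(ds), has_constant="add")
        return 1.0 / (1.0 + np.exp(-Xn @ _b))

    scores = predict(data)
    return FitResult(
        "logistic",
        features,
        {"train_mean": auroc(scores, y) if 0 < y.sum() < len(y) else None},
        coefficients=table,
        flags=flags,
        _predict=predict,
    )


def _ridge_logistic(X, y, penalty=1e-4, max_iter=100):
    n, d = X.shape
    b = np.zeros(d)
    for _ in range(max_iter):
        eta = X @ b
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        H = X.T @ (X * W[:, None]) + penalty * np.eye(d)
        g = X.T @ (y - p) - penalty * b
        step = np.linalg.solve(H, g)
        b = b + step
        if np.abs(step).max() < 1e-10:
            break
    eta = X @ b
    p = 1.0 / (1.0 + np.exp(-eta))
    H = X.T @ (X * (p * (1 - p))[:, None]) + penalty * np.eye(X.shape[1])
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return b, se


# ---------------------------------------------------------------------------
# alpha grid and nested cross-validation


def alpha_grid(n: int = 10, lo: float = 1e-5, hi: float = 1e-1) -> np.ndarray:
    """Log-spaced CI-test significance levels (ascending)."""
    if not (0 < lo < hi <= 1):
        raise ValueError("need 0 < lo < hi <= 1")
    return np.logspace(np.log10(lo), np.log10(hi), n)


@dataclasses.dataclass
class NestedCVResult:
    selected_alpha: float
    fold_mbs: dict  # (fold, alpha) -> MarkovBlanket
    stability: StabilityTable
    fit: FitResult
    cv_auroc: pd.DataFrame  # folds x alphas validation AUROC
    final_mb: MarkovBlanket


def nested_cv(
    data: MixedDataset,
    grid=None,
    n_folds: int = 10,
    seed: int = 0,
    lam: float | None = None,
    max_cond: int | None = 3,
    smote_k: int = 5,
    rebalance_graphs: bool = False,
) -> NestedCVResult:
    """Select the sparsity level by fold-held-out AUROC of blanket models.

    Per (fold, alpha): SMOTE-NC on the fold-training portion, MGM + FCI-max
    graph, blanket extraction, logistic fit, AUROC on the untouched fold
    validation portion.  The MGM skeleton and the CI-test cache are shared
    across the alpha grid within a fold (both are alpha-independent).
    Alpha ties break toward the sparser (smaller) value; the final model is
    refit on all data at the selected alpha.

    By default the oversampled records feed only the classifier: the graph
    stages run on the raw fold-training data.  Mode-voting on categorical
    features during SMOTE-NC shifts the synthetic minority's level
    frequencies, which manufactures outcome associations for variables that
    have none, while the CI tests are valid under class imbalance anyway
    (see the methods note).  Set ``rebalance_graphs=True`` to run graph
    learning on the oversampled records as well.
    """
    if grid is None:
        grid = alpha_grid()
    grid = np.asarray(sorted(grid), dtype=float)
    y = data.outcome_values()
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_mbs: dict = {}
    scores = np.full((n_folds, len(grid)), np.nan)
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(y)), y)):
        train = data.subset_rows(tr)
        val = data.subset_rows(va)
        balanced = smote_nc(train, k=smote_k, seed=seed * 1009 + fold)
        graph_data = balanced if rebalance_graphs else train
        _, skeleton = fit_mgm(graph_data, lam=lam)
        tester = CITester(graph_data)
        for j, alpha in enumerate(grid):
            pag = learn_pag(
                graph_data, alpha, max_cond=max_cond,
                skeleton=skeleton, tester=tester,
            )
            mb = extract_mb(pag, data.outcome_name)
            fold_mbs[(fold, float(alpha))] = mb
            if not mb.members:
                scores[fold, j] = 0.5
                logger.info("fold %d alpha %.2g: empty blanket", fold, alpha)
                continue
            fit = fit_logistic(balanced, mb.members)
            scores[fold, j] = auroc(fit.predict_risk(val), y[va])
    # parsimony rule: the sparsest alpha whose mean validation AUROC is
    # within one standard error of the best (fold-to-fold noise dwarfs the
    # differences among near-optimal alphas, and ties break sparse)
    mean_by_alpha = np.nanmean(scores, axis=0)
    argmax = int(np.flatnonzero(mean_by_alpha == mean_by_alpha.max())[0])
    se = float(np.nanstd(scores[:, argmax]) / np.sqrt(n_folds))
    best = int(np.flatnonzero(mean_by_alpha >= mean_by_alpha.max() - se)[0])
    selected = float(grid[best])

    balanced = smote_nc(data, k=smote_k, seed=seed * 1009 + n_folds)
    graph_data = balanced if rebalance_graphs else data
    pag = learn_pag(graph_data, selected, lam=lam, max_cond=max_cond)
    final_mb = extract_mb(pag, data.outcome_name)
    if final_mb.members:
        fit = fit_logistic(balanced, final_mb.members)
    else:
        fit = fit_logistic(balanced, [])
        logger.warning("final blanket is empty; intercept-only model")
    fit.selected_alpha = selected
    fit.auroc["train_mean"] = float(np.nanmean(scores[:, best]))
    fit.auroc["train_sd"] = float(np.nanstd(scores[:, best]))
    table = stability_table(fold_mbs, n_folds, [float(a) for a in grid])
    cv = pd.DataFrame(scores, columns=[float(a) for a in grid])
    return NestedCVResult(selected, fold_mbs, table, fit, cv, final_mb)


# ---------------------------------------------------------------------------
# comparison models


def _cv_auroc_sklearn(model_factory, X, y, folds):
    out = []
    for tr, va in folds:
        m = model_factory()
        m.fit(X[tr], y[tr])
        out.append(auroc(m.predict_proba(X[va])[:, 1], y[va]))
    return float(np.mean(out)), float(np.std(out))


def fit_random_forest(
    data: MixedDataset, n_folds: int = 10, seed: int = 0
) -> FitResult:
    """All-variable random forest tuned by out-of-fold AUROC.

    Tree count and per-split feature count are tuned on the same stratified
    folds used by the blanket models; the reported train AUROC is
    out-of-fold for the best configuration.
    """
    features = [v for v in data.variables if v != data.outcome_name]
    enc = FeatureEncoder(data, features)
    X = enc.transform(data)
    y = data.outcome_values()
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best = None
    for n_est in (100, 300):
        for mf in ("sqrt", 0.5):
            mean, sd = _cv_auroc_sklearn(
                lambda: RandomForestClassifier(
                    n_estimators=n_est, max_features=mf, random_state=seed,
                    n_jobs=1,
                ),
                X, y, folds,
            )
            if best is None or mean > best[0]:
                best = (mean, sd, n_est, mf)
    mean, sd, n_est, mf = best
    model = RandomForestClassifier(
        n_estimators=n_est, max_features=mf, random_state=seed, n_jobs=1
    )
    model.fit(X, y)

    def predict(ds: MixedDataset, _enc=enc, _m=model) -> np.ndarray:
        return _m.predict_proba(_enc.transform(ds))[:, 1]

    return FitResult(
        "random_forest", features,
        {"train_mean": mean, "train_sd": sd}, _predict=predict,
    )


def fit_elastic_net(
    data: MixedDataset, n_folds: int = 10, seed: int = 0
) -> FitResult:
    """All-variable logistic elastic net, mixing and penalty tuned by
    out-of-fold AUROC on the shared folds."""
    features = [v for v in data.variables if v != data.outcome_name]
    enc = FeatureEncoder(data, features)
    X = enc.transform(data)
    y = data.outcome_values()
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best = None
    for l1 in (0.2, 0.5, 0.8):
        for C in (0.05, 0.2, 1.0):
            mean, sd = _cv_auroc_sklearn(
                lambda: LogisticRegression(
                    solver="saga", l1_ratio=l1, C=C, max_iter=4000,
                    random_state=seed,
                ),
                X, y, folds,
            )
            if best is None or mean > best[0]:
                best = (mean, sd, l1, C)
    mean, sd, l1, C = best
    model = LogisticRegression(solver="saga", l1_ratio=l1, C=C, max_iter=4000,
                               random_state=seed)
    model.fit(X, y)
    table = pd.DataFrame(
        {
            "term": ["(Intercept)"] + enc.terms,
            "estimate": np.r_[model.intercept_, model.coef_[0]],
            "SE": np.nan,
            "p-value": np.nan,
        }
    )

    def predict(ds: MixedDataset, _enc=enc, _m=model) -> np.ndarray:
        return _m.predict_proba(_enc.transform(ds))[:, 1]

    return FitResult(
        "elastic_net", features,
        {"train_mean": mean, "train_sd": sd},
        coefficients=table, _predict=predict,
    )


# ---------------------------------------------------------------------------
# subtype-specific models


def fit_subgroup_models(data: MixedDataset, features, subtype):
    """Trajectory-specific logistic fits.

    ``subtype`` labels each subject ``"copd"`` (ratio-driven leaver),
    ``"prism"`` (FEV1%%predicted-driven leaver with preserved ratio) or
    ``""``/None.  Each model keeps all non-leavers as controls and
    restricts events to one trajectory.  Requires >= 10 events per group.
    """
    subtype = np.asarray(subtype, dtype=object)
    y = data.outcome_values()
    fits = []
    for label in ("copd", "prism"):
        keep = (y == 0) | (subtype == label)
        n_events = int(((y == 1) & (subtype == label)).sum())
        if n_events < 10:
            raise ValueError(
                f"subgroup {label!r} has {n_events} events (<10); "
                "cannot fit a trajectory-specific model"
            )
        sub = data.subset_rows(np.flatnonzero(keep))
        fits.append(fit_logistic(sub, features))
    return tuple(fits)


# ---------------------------------------------------------------------------
# Shapley importances


def shapley_importance(
    fit: FitResult,
    data: MixedDataset,
    n_mc: int = 100,
    seed: int = 0,
    background: MixedDataset | None = None,
) -> pd.DataFrame:
    """Monte-Carlo permutation-sampling Shapley values on the risk scale.

    For each draw a random feature order and a random background record are
    sampled; each feature's marginal contribution is the change in
    predicted risk when its value switches from the background's to the
    subject's, given the features already switched.  Returns a
    subject-by-feature table; ranking features by mean absolute value gives
    the importance ordering.
    """
    if n_mc < 10:
        raise ValueError("n_mc < 10 gives unusably noisy estimates")
    rng = np.random.default_rng(seed)
    bg = background if background is not None else data
    feats = [f for f in fit.features if f != data.outcome_name]
    p = len(feats)
    n = data.n_subjects
    values = np.zeros((n, p))
    work = data.values.copy()
    for _ in range(n_mc):
        order = rng.permutation(p)
        bg_rows = bg.values.iloc[rng.integers(0, bg.n_subjects, size=n)].reset_index(
            drop=True
        )
        for f in feats:
            work[f] = bg_rows[f].to_numpy()
        hybrid = MixedDataset(work, data.meta, data.outcome_name)
        prev = fit.predict_risk(hybrid)
        for j in order:
            f = feats[j]
            work[f] = data.values[f].to_numpy()
            hybrid = MixedDataset(work, data.meta, data.outcome_name)
            cur = fit.predict_risk(hybrid)
            values[:, j] += cur - prev
            prev = cur
    values /= n_mc
    return pd.DataFrame(values, columns=feats)


# ---------------------------------------------------------------------------
# validation refits


def refit_without(
    fit: FitResult, drop: str, train: MixedDataset, eval_data: MixedDataset
) -> FitResult:
    """Refit the same model kind without one predictor and evaluate.

    Mirrors external validation against a cohort missing a variable: the
    reduced model is retrained on the training cohort and scored on the
    evaluation cohort.
    """
    if drop not in fit.features:
        raise ValueError(f"{drop!r} is not a feature of the fit")
    remaining = [f for f in fit.features if f != drop]
    if not remaining:
        raise ValueError("no features left after dropping")
    if fit.model_kind == "logistic":
        new = fit_logistic(train, remaining)
    elif fit.model_kind == "random_forest":
        new = fit_random_forest(train.select(remaining + [train.outcome_name]))
    elif fit.model_kind == "elastic_net":
        new = fit_elastic_net(train.select(remaining + [train.outcome_name]))
    else:
        raise ValueError(f"unknown model kind {fit.model_kind!r}")
    new.selected_alpha = fit.selected_alpha
    new.auroc["test"] = auroc(
        new.predict_risk(eval_data), eval_data.outcome_values()
    )
    return new
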