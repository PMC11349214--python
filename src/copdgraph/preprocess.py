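"""Data-quality pipeline for mixed-type cohort tables.

Implements the preprocessing stages applied before graph learning:
variable filtering (future information, duplicates/constants, excess
missingness, sparse categories, high correlation), merging of sparse
categorical levels down to 2-3 categories, k-nearest-neighbour imputation
under the Gower distance, SMOTE-NC minority oversampling, and construction
of the "limited spirometry" / "no spirometry" variable sets.

Correlation screening uses the coefficient of determination (R^2) for
continuous pairs and Cramér's V for categorical pairs.  Mixed
continuous-categorical screening is deliberately not performed; see the
methods note.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .dataset import CATEGORICAL, CONTINUOUS, MixedDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# association statistics


def cramers_v(x, y) -> float:
    """Cramér's V between two categorical columns.

    ``V = sqrt(chi2 / (n * min(r - 1, c - 1)))`` from the contingency table
    of the pairwise-observed subset.  Raises if either variable shows a
    single observed level (the statistic is undefined).
    """
    x = pd.Series(x)
    y = pd.Series(np.asarray(y), index=x.index)
    keep = x.notna() & y.notna()
    x, y = x[keep], y[keep]
    table = pd.crosstab(x, y)
    r, c = table.shape
    if r < 2 or c < 2:
        raise ValueError("Cramér's V undefined: a variable has <2 observed levels")
    chi2 = chi2_contingency(table.to_numpy(), correction=False)[0]
    n = table.to_numpy().sum()
    return float(np.sqrt(chi2 / (n * min(r - 1, c - 1))))


# ---------------------------------------------------------------------------
# variable filtering


@dataclasses.dataclass
class FilterReport:
    """Audit trail of the variable-filtering stage."""

    dropped: list  # (variable, reason)
    retained_count: int
    correlation_pairs: list  # (varA, varB, statistic, kind)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


REASON_FUTURE = "future-info"
REASON_CONSTANT = "duplicate/constant"
REASON_MISSING = "too-missing"
REASON_SPARSE = "sparse-category"
REASON_CORR = "too-correlated"


def filter_variables(
    data: MixedDataset,
    missing_max: float = 0.2,
    min_category_count: int = 10,
    corr_max: float = 0.9,
):
    """Drop uninformative or redundant variables; returns the reduced
    dataset and a :class:`FilterReport`.

    Order of checks: future-information roles, constants and exact
    duplicates, excess missingness, sparse categories, then pairwise
    correlation (R^2 for continuous pairs, Cramér's V for categorical
    pairs) where the member with more missingness is dropped (ties break
    toward the later column).  The outcome column is never dropped.
    """
    if not 0 < missing_max <= 1 or not 0 < corr_max <= 1:
        raise ValueError("thresholds must lie in (0, 1]")
    outcome = data.outcome_name
    if outcome is not None and data.values[outcome].isna().any():
        raise ValueError("outcome column must be complete")

    dropped: list[tuple[str, str]] = []
    retained = list(data.variables)

    def drop(var: str, reason: str) -> None:
        if var == outcome:
            return
        retained.remove(var)
        dropped.append((var, reason))

    for var in list(retained):
        if data.role(var) == "future-info":
            drop(var, REASON_FUTURE)

    # constants (over observed cells) and exact duplicates
    for var in list(retained):
        col = data.values[var]
        if col.dropna().nunique() <= 1:
            drop(var, REASON_CONSTANT)
    seen: dict = {}
    for var in list(retained):
        key = tuple(data.values[var].fillna("\0NA"))
        if key in seen:
            drop(var, REASON_CONSTANT)
        else:
            seen[key] = var

    for var in list(retained):
        if data.values[var].isna().mean() > missing_max:
            drop(var, REASON_MISSING)

    for var in list(retained):
        if data.kind(var) == CATEGORICAL and var != outcome:
            counts = data.values[var].value_counts()
            if len(counts) > 0 and counts.min() < min_category_count:
                drop(var, REASON_SPARSE)

    # pairwise correlation screening within retained variables
    cont = [v for v in retained if data.kind(v) == CONTINUOUS]
    cat = [v for v in retained if data.kind(v) == CATEGORICAL and v != outcome]
    pairs: list[tuple[str, str, float, str]] = []
    for group, kind in ((cont, "r2"), (cat, "cramers_v")):
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                stat = _pair_statistic(data, a, b, kind)
                if stat is not None and stat > corr_max:
                    pairs.append((a, b, stat, kind))
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    order = {v: i for i, v in enumerate(data.variables)}
    for a, b, stat, kind in pairs:
        if a not in retained or b not in retained:
            continue
        miss_a = data.values[a].isna().mean()
        miss_b = data.values[b].isna().mean()
        if a == outcome:
            victim = b
        elif b == outcome:
            victim = a
        elif miss_a > miss_b:
            victim = a
        elif miss_b > miss_a:
            victim = b
        else:
            victim = a if order[a] > order[b] else b
        drop(victim, REASON_CORR)

    report = FilterReport(dropped, len(retained), pairs)
    return data.select(retained), report


def _pair_statistic(data: MixedDataset, a: str, b: str, kind: str) -> float | None:
    xa, xb = data.values[a], data.values[b]
    keep = xa.notna() & xb.notna()
    if keep.sum() < 3:
        return None
    if kind == "r2":
        va = xa[keep].to_numpy(dtype=float)
        vb = xb[keep].to_numpy(dtype=float)
        if va.std() == 0 or vb.std() == 0:
            return None
        return float(np.corrcoef(va, vb)[0, 1] ** 2)
    try:
        return cramers_v(xa[keep], xb[keep])
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# sparse-category merging


def merge_sparse_categories(data: MixedDataset, min_count: int = 10) -> MixedDataset:
    """Merge rare categorical levels until every level has ``min_count``
    members and no variable exceeds 3 levels.

    The rarest level is merged into the next-rarest at each step (names
    concatenated with ``|``, rarity ties broken by declared level order).
    Binary variables are untouched.  A variable that collapses to a single
    level is marked ``collapsed`` in the metadata for the filter stage.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    out = data.copy()
    out.meta["collapsed"] = False
    for var in out.categorical_vars:
        levels = list(out.levels(var))
        if len(levels) <= 2 or var == out.outcome_name:
            continue
        col = out.values[var].copy()
        while True:
            counts = {lv: int((col == lv).sum()) for lv in levels}
            too_small = min(counts.values()) < min_count
            too_many = len(levels) > 3
            if not (too_small or too_many) or len(levels) == 1:
                break
            ordered = sorted(levels, key=lambda lv: (counts[lv], levels.index(lv)))
            rarest, target = ordered[0], ordered[1]
            merged = f"{target}|{rarest}"
            col = col.replace({rarest: merged, target: merged})
            levels = [merged if lv == target else lv for lv in levels if lv != rarest]
        out.values[var] = col
        out.meta.at[var, "levels"] = tuple(levels)
        if len(levels) == 1:
            out.meta.at[var, "collapsed"] = True
            logger.warning("variable %r collapsed to a single level", var)
    return out


# ---------------------------------------------------------------------------
# Gower distance


def continuous_ranges(data: MixedDataset) -> dict[str, float]:
    """Observed min-max range per continuous variable (for Gower scaling).

    Computed on a training partition and reused for held-out records so the
    transform carries no information from evaluation data.
    """
    ranges = {}
    for var in data.continuous_vars:
        col = data.values[var].dropna().to_numpy(dtype=float)
        ranges[var] = float(col.max() - col.min()) if len(col) else 0.0
    return ranges


def gower_distance(a: pd.Series, b: pd.Series, ranges: dict, kinds: dict) -> float:
    """Gower dissimilarity between two records, in [0, 1].

    Mean over variables observed in both records of the range-normalized
    absolute difference (continuous) or the mismatch indicator
    (categorical).  Raises when no variable is commonly observed.
    """
    num = 0.0
    count = 0
    for var in a.index:
        va, vb = a[var], b[var]
        if pd.isna(va) or pd.isna(vb):
            continue
        if kinds[var] == CONTINUOUS:
            rng = ranges[var]
            if rng <= 0:
                raise ValueError(f"non-positive range for {var!r}")
            num += abs(float(va) - float(vb)) / rng
        else:
            num += float(va != vb)
        count += 1
    if count == 0:
        raise ValueError("no commonly observed variable between records")
    return num / count


def gower_matrix(
    frame: pd.DataFrame,
    other: pd.DataFrame,
    ranges: dict,
    kinds: dict,
) -> np.ndarray:
    """Pairwise Gower distances between the rows of two tables (vectorized).

    Variables missing in either member of a pair are excluded from that
    pair's mean.  Entries with no commonly observed variable are NaN.
    """
    n, m = len(frame), len(other)
    num = np.zeros((n, m))
    cnt = np.zeros((n, m))
    for var in frame.columns:
        a = frame[var].to_numpy()
        b = other[var].to_numpy()
        if kinds[var] == CONTINUOUS:
            a = a.astype(float)
            b = b.astype(float)
            ok = ~np.isnan(a)[:, None] & ~np.isnan(b)[None, :]
            rng = ranges[var]
            if rng <= 0:
                continue  # zero-range variable carries no distance signal
            d = np.abs(a[:, None] - b[None, :]) / rng
            d = np.where(ok, d, 0.0)
        else:
            obs_a = pd.notna(a)
            obs_b = pd.notna(b)
            ok = obs_a[:, None] & obs_b[None, :]
            d = np.where(ok, (a[:, None] != b[None, :]).astype(float), 0.0)
        num += d
        cnt += ok
    with np.errstate(invalid="ignore"):
        out = num / cnt
    return out


# ---------------------------------------------------------------------------
# KNN imputation


def knn_impute(data: MixedDataset, k: int = 5) -> MixedDataset:
    """Fill missing cells from the ``k`` Gower-nearest donor records.

    Donors must be observed in the target variable; continuous cells take
    the unweighted donor mean, categorical cells the donor mode (mode ties
    broken by smaller Gower distance, then declared level order).  Observed
    cells are never altered.  With fewer than ``k`` donors all available
    donors are used (with a warning); zero donors is an error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out = data.copy()
    if data.is_complete():
        return out
    kinds = {v: data.kind(v) for v in data.variables}
    ranges = continuous_ranges(data)
    dist = gower_matrix(data.values, data.values, ranges, kinds)
    np.fill_diagonal(dist, np.inf)
    dist = np.where(np.isnan(dist), np.inf, dist)

    for var in data.variables:
        col = out.values[var]
        missing_rows = np.flatnonzero(col.isna().to_numpy())
        if len(missing_rows) == 0:
            continue
        donors = np.flatnonzero(col.notna().to_numpy())
        if len(donors) == 0:
            raise ValueError(f"no donor records observed in {var!r}")
        if len(donors) < k:
            warnings.warn(
                f"variable {var!r}: only {len(donors)} donors available (k={k})"
            )
        filled = col.copy()
        for row in missing_rows:
            d = dist[row, donors]
            order = np.argsort(d, kind="stable")[: min(k, len(donors))]
            chosen = donors[order]
            if kinds[var] == CONTINUOUS:
                filled.iloc[row] = float(col.iloc[chosen].astype(float).mean())
            else:
                vals = col.iloc[chosen].to_numpy()
                dists = dist[row, chosen]
                counts: dict = {}
                best: dict = {}
                for v, dd in zip(vals, dists):
                    counts[v] = counts.get(v, 0) + 1
                    best[v] = min(best.get(v, np.inf), dd)
                top = max(counts.values())
                levels = list(data.levels(var))
                cands = [v for v in counts if counts[v] == top]
                cands.sort(key=lambda v: (best[v], levels.index(v)))
                filled.iloc[row] = cands[0]
        out.values[var] = filled
    return out


# ---------------------------------------------------------------------------
# SMOTE-NC


def smote_nc(data: MixedDataset, k: int = 5, seed: int = 0) -> MixedDataset:
    """Oversample the minority outcome class to exact balance.

    Each synthetic record interpolates a random minority seed record toward
    one of its ``k`` Gower-nearest minority neighbours (continuous features:
    ``seed + u * (neighbour - seed)`` with ``u ~ U(0, 1)``; categorical
    features: the mode among the ``k`` neighbours, ties keeping the seed's
    value).  Original records are preserved unchanged as a prefix; synthetic
    rows are flagged in ``synthetic``.
    """
    if data.outcome_name is None:
        raise ValueError("smote_nc needs an outcome column")
    if not data.is_complete():
        raise ValueError("smote_nc requires complete data; run knn_impute first")
    y = data.outcome_values()
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    if n0 == n1:
        return data.copy()
    minority = 1 if n1 < n0 else 0
    need = abs(n0 - n1)
    idx_min = np.flatnonzero(y == minority)
    if len(idx_min) <= k:
        raise ValueError(
            f"minority count {len(idx_min)} <= k={k}; lower k to oversample"
        )
    rng = np.random.default_rng(seed)
    kinds = {v: data.kind(v) for v in data.variables}
    ranges = continuous_ranges(data)
    sub = data.values.iloc[idx_min].reset_index(drop=True)
    dist = gower_matrix(sub, sub, ranges, kinds)
    np.fill_diagonal(dist, np.inf)
    neighbours = np.argsort(dist, axis=1, kind="stable")[:, :k]

    feature_cols = [v for v in data.variables if v != data.outcome_name]
    new_rows = []
    seeds = rng.integers(0, len(idx_min), size=need)
    picks = rng.integers(0, k, size=need)
    us = rng.random(need)
    for s, p, u in zip(seeds, picks, us):
        nbrs = neighbours[s]
        nbr = nbrs[p]
        row = {}
        for var in feature_cols:
            if kinds[var] == CONTINUOUS:
                a = float(sub.at[s, var])
                b = float(sub.at[nbr, var])
                row[var] = a + u * (b - a)
            else:
                vals = sub[var].to_numpy()[nbrs]
                uniq, counts = np.unique(vals, return_counts=True)
                top = uniq[counts == counts.max()]
                row[var] = top[0] if len(top) == 1 else sub.at[s, var]
        row[data.outcome_name] = data.levels(data.outcome_name)[minority]
        new_rows.append(row)

    appended = pd.DataFrame(new_rows, columns=data.variables)
    values = pd.concat([data.values, appended], ignore_index=True)
    for var in data.continuous_vars:
        values[var] = values[var].astype(float)
    flags = np.concatenate([data.synthetic, np.ones(need, dtype=bool)])
    return MixedDataset(values, data.meta.copy(), data.outcome_name, flags)


# ---------------------------------------------------------------------------
# spirometry variable sets


def make_variable_sets(data: MixedDataset):
    """Build the two analysis variable sets used throughout.

    ``limited_spirometry`` drops direct derivatives of the outcome-defining
    indices (role ``spirometry-derived``); ``no_spirometry`` additionally
    drops all remaining spirometry variables (role ``spirometry``, e.g. the
    mid-range expiratory flow).  The outcome is retained in both.
    """
    if "role" not in data.meta.columns or data.meta["role"].isna().any():
        raise ValueError("variable roles must be annotated in metadata")
    derived = [v for v in data.variables if data.role(v) == "spirometry-derived"]
    spiro = [v for v in data.variables if data.role(v) == "spirometry"]
    limited = data.drop(derived)
    no_spiro = limited.drop(spiro)
    return limited, no_spiro
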