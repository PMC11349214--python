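"""Conditional-independence tests on mixed data.

Each test is a likelihood-ratio comparison of the conditional model of one
variable on the conditioning set versus the same model with the other
variable added, with the model family chosen by the response's kind:
linear-Gaussian for continuous responses, multinomial-logit for categorical
ones (categorical regressors are one-hot encoded with a reference level).
Symmetry is enforced by running the test in both directions and keeping the
larger p-value.

:class:`CITester` caches p-values across repeated queries -- during
skeleton pruning over a grid of significance levels the same (x, y, S)
triple is tested many times -- and counts the unique tests performed.
:class:`OracleCITester` answers the same interface from d-separation in a
ground-truth DAG (p-values 0 or 1), which substitutes exact knowledge for
sample tests in verification studies.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable

import numpy as np
from scipy import special

from ._glm import gaussian_rss, multinomial_loglik
from .dataset import CATEGORICAL, CONTINUOUS, MixedDataset

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CITestResult:
    x: str
    y: str
    cond: tuple
    pvalue: float
    independent: bool
    test_kind: str
    flags: tuple = ()


class CITester:
    """Cached likelihood-ratio CI tests on a complete mixed dataset."""

    def __init__(self, data: MixedDataset):
        if not data.is_complete():
            raise ValueError("CI tests require complete data")
        self.data = data
        self.n = data.n_subjects
        self._kinds = {v: data.kind(v) for v in data.variables}
        self._cols: dict[str, np.ndarray] = {}
        self._resp: dict[str, np.ndarray] = {}
        for v in data.variables:
            col = data.values[v].to_numpy()
            if self._kinds[v] == CONTINUOUS:
                x = col.astype(float)
                sd = x.std()
                self._cols[v] = ((x - x.mean()) / (sd if sd > 0 else 1.0))[:, None]
                self._resp[v] = self._cols[v][:, 0]
            else:
                levels = [lv for lv in data.levels(v) if (col == lv).any()]
                onehot = np.column_stack([(col == lv).astype(float) for lv in levels]) \
                    if levels else np.zeros((self.n, 0))
                self._cols[v] = onehot[:, 1:]  # reference-coded regressor
                self._resp[v] = onehot  # full one-hot response
        self._cache: dict = {}
        self._fit_cache: dict = {}
        self.n_tests = 0

    # -- public API ---------------------------------------------------------

    def pvalue(self, x: str, y: str, cond: Iterable[str]) -> float:
        key = (frozenset((x, y)), frozenset(cond))
        hit = self._cache.get(key)
        if hit is None:
            cond = tuple(cond)
            p1 = self._directional(y, x, cond)
            p2 = self._directional(x, y, cond)
            hit = max(p1, p2)
            self._cache[key] = hit
            self.n_tests += 1
        return hit

    def test(self, x: str, y: str, cond: Iterable[str], alpha: float) -> CITestResult:
        if x == y:
            raise ValueError("x and y must differ")
        cond = tuple(cond)
        if x in cond or y in cond:
            raise ValueError("conditioning set must exclude x and y")
        p = self.pvalue(x, y, cond)
        kx, ky = self._kinds[x], self._kinds[y]
        kind = {
            (CONTINUOUS, CONTINUOUS): "cont-cont",
            (CATEGORICAL, CATEGORICAL): "cat-cat",
        }.get((kx, ky), "cont-cat")
        return CITestResult(x, y, cond, p, p > alpha, kind)

    # -- internals ----------------------------------------------------------

    def _fit(self, y: str, regressors: tuple):
        """Fit (and cache) the conditional model of y on a regressor set.

        Returns (statistic, rank): residual sum of squares for continuous
        responses, maximized log-likelihood for categorical ones.  Designs
        are assembled in sorted variable order so nested fits can warm-start
        the Newton iterations.
        """
        key = (y, regressors)
        hit = self._fit_cache.get(key)
        if hit is not None:
            return hit
        ones = np.ones((self.n, 1))
        X = (
            np.hstack([ones] + [self._cols[v] for v in regressors])
            if regressors
            else ones
        )
        if self._kinds[y] == CONTINUOUS:
            rss, rank = gaussian_rss(X, self._resp[y])
            out = (rss, rank, None)
        else:
            Y = self._resp[y]
            warm = self._warm_start(y, regressors, X.shape[1], Y.shape[1] - 1)
            ll, rank, B = multinomial_loglik(X, Y, warm_start=warm)
            out = (ll, rank, B)
        self._fit_cache[key] = out
        return out

    def _warm_start(self, y, regressors, d, k):
        """Coefficients of a cached sub-model, padded to the new layout."""
        if k < 1:
            return None
        for i in range(len(regressors) - 1, -1, -1):
            sub = regressors[:i] + regressors[i + 1 :]
            hit = self._fit_cache.get((y, sub))
            if hit is None or hit[2] is None:
                continue
            B0 = hit[2]
            widths = [1] + [max(self._cols[v].shape[1], 0) for v in regressors]
            offsets = np.cumsum([0] + widths)
            if offsets[-1] != d or B0.shape[1] != k:
                return None
            sub_positions = [0] + [
                j + 1 for j, v in enumerate(regressors) if v != regressors[i]
            ]
            rows = []
            for pos in sub_positions:
                rows.extend(range(offsets[pos], offsets[pos + 1]))
            if len(rows) != B0.shape[0]:
                return None
            B = np.zeros((d, k))
            B[rows] = B0
            return B
        return None

    def _directional(self, y: str, x: str, cond: tuple) -> float:
        """LRT p-value for adding x to the conditional model of y on cond."""
        n = self.n
        base = tuple(sorted(cond))
        full = tuple(sorted(cond + (x,)))
        if self._kinds[y] == CONTINUOUS:
            rss0, rank0, _ = self._fit(y, base)
            rss1, rank1, _ = self._fit(y, full)
            df = rank1 - rank0
            if df <= 0:
                return 1.0
            if rss1 <= 0:
                return 0.0
            # F form of the Gaussian likelihood ratio: exact finite-sample
            # null distribution (monotone in n*log(rss0/rss1))
            df2 = n - rank1
            if df2 <= 0:
                return 1.0
            fstat = (rss0 - rss1) / df / (rss1 / df2)
            return float(special.fdtrc(df, df2, max(fstat, 0.0)))
        L = self._resp[y].shape[1]
        if L < 2:
            logger.debug("response %r constant; p-value forced to 1", y)
            return 1.0
        ll0, rank0, _ = self._fit(y, base)
        ll1, rank1, _ = self._fit(y, full)
        df = (rank1 - rank0) * (L - 1)
        if df <= 0:
            return 1.0
        lr = 2.0 * (ll1 - ll0)
        return float(special.chdtrc(df, max(lr, 0.0)))


class OracleCITester:
    """CI-test interface answered by m-separation in a ground-truth DAG."""

    def __init__(self, dag):
        from .simulate import d_separated

        self._dsep = d_separated
        self.dag = dag
        self._cache: dict = {}
        self.n_tests = 0

    def pvalue(self, x: str, y: str, cond: Iterable[str]) -> float:
        key = (frozenset((x, y)), frozenset(cond))
        hit = self._cache.get(key)
        if hit is None:
            hit = 1.0 if self._dsep(self.dag.graph, x, y, set(cond)) else 0.0
            self._cache[key] = hit
            self.n_tests += 1
        return hit

    def test(self, x: str, y: str, cond: Iterable[str], alpha: float) -> CITestResult:
        p = self.pvalue(x, y, tuple(cond))
        return CITestResult(x, y, tuple(cond), p, p > alpha, "oracle")


def ci_test(
    data: MixedDataset, x: str, y: str, cond: Iterable[str] = (), alpha: float = 0.05
) -> CITestResult:
    """One-shot symmetric likelihood-ratio CI test (see :class:`CITester`)."""
    return CITester(data).test(x, y, cond, alpha)
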