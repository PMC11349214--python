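"""Sparse pairwise mixed graphical model (MGM).

Learns an undirected graph over continuous and categorical variables by
minimizing a group-lasso-penalized negative log *pseudo-likelihood*: the sum
over variables of each variable's conditional negative log-likelihood given
all others, with Gaussian conditionals (unit conditional variance on
standardized data) for continuous variables and multinomial-logit
conditionals for categorical variables.  Pairwise parameters are shared
symmetrically between the two conditionals they enter, so the objective is
convex in the symmetric parameter matrix.

The penalty is a group lasso over pairwise blocks -- a scalar for a
continuous-continuous pair, a level-length vector for continuous-categorical
and a level-by-level matrix for categorical-categorical -- driving whole
edges to zero.  The resulting edge set is intended as a *superset* of the
adjacencies of the true directed graph; the constraint-based orientation
stage prunes and orients it.

Categorical variables are one-hot encoded internally.  Identifiability
(sum-to-zero of level-wise parameters) is not imposed explicitly: because
per-level intercepts are unpenalized and a uniform shift across levels can
be absorbed by them, the group penalty selects the centered representative
at the optimum.  The encoding is an internal contract and never appears in
outputs.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import networkx as nx
import numpy as np

from .dataset import CATEGORICAL, CONTINUOUS, MixedDataset

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# encoding


@dataclasses.dataclass
class _Encoding:
    """Internal one-hot design for a mixed table."""

    variables: list
    kinds: dict
    slices: dict  # var -> slice into the design columns
    levels: dict  # categorical var -> tuple of levels
    means: dict  # continuous var -> mean used for standardization
    sds: dict  # continuous var -> SD used for standardization
    dim: int

    @classmethod
    def from_data(cls, data: MixedDataset) -> "_Encoding":
        slices, levels, means, sds = {}, {}, {}, {}
        kinds = {}
        pos = 0
        for var in data.variables:
            kinds[var] = data.kind(var)
            if kinds[var] == CONTINUOUS:
                col = data.values[var].to_numpy(dtype=float)
                means[var] = float(col.mean())
                sd = float(col.std())
                sds[var] = sd if sd > 0 else 1.0
                slices[var] = slice(pos, pos + 1)
                pos += 1
            else:
                lv = data.levels(var)
                levels[var] = lv
                slices[var] = slice(pos, pos + len(lv))
                pos += len(lv)
        return cls(list(data.variables), kinds, slices, levels, means, sds, pos)

    def design(self, data: MixedDataset) -> np.ndarray:
        if not data.is_complete():
            raise ValueError(
                "MGM requires complete data: impute missing cells first "
                "(see knn_impute)"
            )
        n = data.n_subjects
        X = np.zeros((n, self.dim))
        for var in self.variables:
            sl = self.slices[var]
            if self.kinds[var] == CONTINUOUS:
                col = data.values[var].to_numpy(dtype=float)
                X[:, sl.start] = (col - self.means[var]) / self.sds[var]
            else:
                col = data.values[var].to_numpy()
                for i, lv in enumerate(self.levels[var]):
                    X[:, sl.start + i] = col == lv
        return X


# ---------------------------------------------------------------------------
# parameters


@dataclasses.dataclass
class MGMParams:
    """Pairwise MGM parameters.

    ``theta`` is the symmetric (dim x dim) interaction matrix over encoded
    columns with zero within-variable blocks; ``intercepts`` holds node
    terms (one per encoded column).  Pairwise blocks are retrieved on the
    original variable scale via :meth:`block`.
    """

    encoding: _Encoding
    theta: np.ndarray
    intercepts: np.ndarray
    lam: float = 0.0
    converged: bool = True
    n_iter: int = 0

    @classmethod
    def zeros(cls, data: MixedDataset) -> "MGMParams":
        enc = _Encoding.from_data(data)
        return cls(enc, np.zeros((enc.dim, enc.dim)), np.zeros(enc.dim))

    def block(self, a: str, b: str) -> np.ndarray:
        """Interaction block between two variables (beta / rho / phi)."""
        return self.theta[self.encoding.slices[a], self.encoding.slices[b]]

    def edge_weight(self, a: str, b: str) -> float:
        return float(np.linalg.norm(self.block(a, b)))


# ---------------------------------------------------------------------------
# objective


def _conditional_losses(X, enc, theta, intercepts, grad=False):
    """Mean negative conditional log-likelihood and optional gradient wrt the
    linear predictors, summed over all variables' conditionals."""
    n = X.shape[0]
    eta = intercepts[None, :] + X @ theta
    loss = 0.0
    deta = np.zeros_like(eta) if grad else None
    for var in enc.variables:
        sl = enc.slices[var]
        if enc.kinds[var] == CONTINUOUS:
            x = X[:, sl.start]
            r = x - eta[:, sl.start]
            loss += 0.5 * _LOG2PI + 0.5 * float(r @ r) / n
            if grad:
                deta[:, sl.start] = -r / n
        else:
            logits = eta[:, sl]
            m = logits.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(logits - m).sum(axis=1))
            obs = X[:, sl]
            loss += float(lse.mean() - (logits * obs).sum() / n)
            if grad:
                P = np.exp(logits - lse[:, None])
                deta[:, sl] = (P - obs) / n
    return (loss, deta) if grad else loss


def neg_pseudolikelihood(data: MixedDataset, params: MGMParams) -> float:
    """Total (summed over records) negative log pseudo-likelihood.

    Continuous conditionals are unit-variance Gaussians on the standardized
    scale stored in ``params`` (so stacking a dataset twice exactly doubles
    the value); categorical conditionals are multinomial logits.
    """
    X = params.encoding.design(data)
    mean_loss = _conditional_losses(X, params.encoding, params.theta, params.intercepts)
    return float(mean_loss * data.n_subjects)


def _pair_blocks(enc):
    out = []
    for i, a in enumerate(enc.variables):
        for b in enc.variables[i + 1 :]:
            out.append((enc.slices[a], enc.slices[b]))
    return out


def _zero_diag_blocks(mat, enc):
    for var in enc.variables:
        sl = enc.slices[var]
        mat[sl, sl] = 0.0


def _group_norms(theta, pairs):
    return np.array([np.linalg.norm(theta[sa, sb]) for sa, sb in pairs])


def _prox(theta, pairs, thresh):
    out = theta.copy()
    for sa, sb in pairs:
        block = out[sa, sb]
        nrm = np.linalg.norm(block)
        scale = 0.0 if nrm <= thresh else 1.0 - thresh / nrm
        out[sa, sb] = block * scale
        out[sb, sa] = block.T * scale
    return out


def _center_blocks(theta, icpt, enc):
    """Project level-wise blocks onto their sum-to-zero representative.

    A uniform shift across the levels of a categorical block is absorbed
    exactly by the unpenalized intercepts, leaving every conditional
    unchanged, so the centered representative is the group-lasso optimum.
    """
    cats = [v for v in enc.variables if enc.kinds[v] != CONTINUOUS]
    conts = [v for v in enc.variables if enc.kinds[v] == CONTINUOUS]
    for c in cats:
        sc = enc.slices[c]
        for v in conts:
            sv = enc.slices[v].start
            rho = theta[sv, sc]
            m = rho.mean()
            if m != 0.0:
                theta[sv, sc] = rho - m
                theta[sc, sv] = rho - m
                icpt[sv] += m  # one-hot rows sum to 1
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            sa, sb = enc.slices[a], enc.slices[b]
            phi = theta[sa, sb].copy()
            row_means = phi.mean(axis=1, keepdims=True)
            phi -= row_means
            icpt[sa] += row_means[:, 0]
            col_means = phi.mean(axis=0, keepdims=True)
            phi -= col_means
            icpt[sb] += col_means[0, :]
            theta[sa, sb] = phi
            theta[sb, sa] = phi.T


# ---------------------------------------------------------------------------
# skeleton


@dataclasses.dataclass
class Skeleton:
    """Undirected weighted graph from the MGM stage."""

    nodes: list
    weights: dict  # frozenset pair -> weight > edge_tol

    @property
    def edges(self) -> list:
        return [tuple(sorted(p)) for p in self.weights]

    def has_edge(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.weights

    def neighbors(self, v: str) -> list:
        return sorted(
            next(iter(p - {v})) for p in self.weights if v in p
        )

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for pair, w in self.weights.items():
            a, b = sorted(pair)
            g.add_edge(a, b, weight=w)
        return g

    @classmethod
    def complete(cls, nodes) -> "Skeleton":
        nodes = list(nodes)
        weights = {
            frozenset((a, b)): 1.0
            for i, a in enumerate(nodes)
            for b in nodes[i + 1 :]
        }
        return cls(nodes, weights)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for a, b in sorted(self.edges):
                fh.write(f"{a}\t{b}\t{self.weights[frozenset((a, b))]:.6g}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, nodes=None) -> "Skeleton":
        weights = {}
        seen = set()
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                a, b, w = line.rstrip("\n").split("\t")
                weights[frozenset((a, b))] = float(w)
                seen.update((a, b))
        return cls(sorted(seen) if nodes is None else list(nodes), weights)


# ---------------------------------------------------------------------------
# fitting


def default_lambda(n: int, p: int, c: float = 1.5) -> float:
    """Group-lasso scaling ``c * sqrt(log p / n)`` used when no penalty is
    given; the sparsity-controlling knob exposed to users is the CI-test
    alpha, not this penalty."""
    return c * math.sqrt(math.log(max(p, 2)) / n)


def fit_mgm(
    data: MixedDataset,
    lam: float | None = None,
    max_iter: int = 500,
    tol: float = 1e-5,
    edge_tol: float = 1e-6,
):
    """Fit the group-lasso MGM by accelerated proximal gradient (FISTA).

    Continuous columns are standardized internally.  Returns the fitted
    :class:`MGMParams` and the thresholded :class:`Skeleton` whose edge
    weights are the Frobenius norms of the pairwise blocks.
    """
    enc = _Encoding.from_data(data)
    X = enc.design(data)
    n, d = X.shape
    if lam is None:
        lam = default_lambda(n, len(enc.variables))
    pairs = _pair_blocks(enc)

    theta = np.zeros((d, d))
    icpt = np.zeros(d)
    theta_prev, icpt_prev = theta, icpt
    t_acc = 1.0
    step = 1.0
    fy = None
    obj_prev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        t_next = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t_acc**2))
        mom = (t_acc - 1.0) / t_next
        y_theta = theta + mom * (theta - theta_prev)
        y_icpt = icpt + mom * (icpt - icpt_prev)
        fy, deta = _conditional_losses(X, enc, y_theta, y_icpt, grad=True)
        g_raw = X.T @ deta
        # gradient restricted to the symmetric parameter manifold
        g_theta = 0.5 * (g_raw + g_raw.T)
        _zero_diag_blocks(g_theta, enc)
        g_icpt = deta.sum(axis=0)

        # backtracking line search on the smooth part; the prox threshold
        # carries a factor 1/2 because each pair block appears twice in the
        # full-matrix Frobenius norm
        while True:
            cand_theta = _prox(y_theta - step * g_theta, pairs, 0.5 * step * lam)
            cand_icpt = y_icpt - step * g_icpt
            f_new = _conditional_losses(X, enc, cand_theta, cand_icpt)
            dth = cand_theta - y_theta
            dic = cand_icpt - y_icpt
            quad = (
                fy
                + float((g_theta * dth).sum()) + float(g_icpt @ dic)
                + (float((dth * dth).sum()) + float(dic @ dic)) / (2.0 * step)
            )
            if f_new <= quad + 1e-12 or step < 1e-8:
                break
            step *= 0.5

        theta_prev, icpt_prev = theta, icpt
        theta, icpt = cand_theta, cand_icpt
        t_acc = t_next
        obj = f_new + lam * float(_group_norms(theta, pairs).sum())
        if abs(obj_prev - obj) <= tol * max(1.0, abs(obj)):
            converged = True
            break
        obj_prev = obj

    _center_blocks(theta, icpt, enc)
    params = MGMParams(enc, theta, icpt, lam=lam, converged=converged, n_iter=it)
    weights = {}
    for (sa, sb), (a, b) in zip(pairs, _pair_names(enc)):
        w = float(np.linalg.norm(theta[sa, sb]))
        if w > edge_tol:
            weights[frozenset((a, b))] = w
    return params, Skeleton(list(enc.variables), weights)


def _pair_names(enc):
    out = []
    for i, a in enumerate(enc.variables):
        for b in enc.variables[i + 1 :]:
            out.append((a, b))
    return out


# ---------------------------------------------------------------------------
# superset diagnostics


def true_markov_graph(dag) -> set:
    """Adjacencies of the conditional-dependence (Markov) graph over the
    observed nodes of a ground-truth DAG: pairs not m-separated given all
    remaining observed variables.  Test oracle, not a pipeline stage."""
    from .simulate import oracle_independent

    observed = dag.observed_nodes
    edges = set()
    for i, a in enumerate(observed):
        for b in observed[i + 1 :]:
            rest = [v for v in observed if v not in (a, b)]
            if not oracle_independent(dag, a, b, rest):
                edges.add(frozenset((a, b)))
    return edges


def skeleton_superset_check(skeleton: Skeleton, dag) -> dict:
    """Compare an MGM skeleton with the moralized latent projection of the
    generating DAG; reports missing (false-negative) and extra edges."""
    truth = true_markov_graph(dag)
    got = set(skeleton.weights)
    return {
        "true_edges": sorted(tuple(sorted(e)) for e in truth),
        "missing": sorted(tuple(sorted(e)) for e in truth - got),
        "extra": sorted(tuple(sorted(e)) for e in got - truth),
        "false_negative_rate": (len(truth - got) / len(truth)) if truth else 0.0,
    }
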