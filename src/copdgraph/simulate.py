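"""Synthetic mixed-type cohorts with known causal ground truth.

Every downstream stage of the pipeline (undirected skeleton learning,
constraint-based orientation, Markov-blanket extraction, prediction) is
validated against cohorts generated here, where the data-generating DAG --
including latent confounders -- is known exactly.

Two generators are provided:

* :func:`sample_dag` + :func:`simulate_mixed` -- generic random acyclic
  structural-equation models over continuous (linear-Gaussian) and
  categorical (multinomial-logit) variables, with the outcome node's true
  Markov blanket fixed to a requested size.
* :func:`make_copd_like` -- a structured cohort emulating a smoking cohort
  with normal baseline spirometry: demographic, CT-derived and small-airway
  variables feed two latent follow-up spirometric axes (FEV1 %predicted and
  FEV1/FVC); thresholding the axes at 0.80 and 0.70 defines the binary
  outcome (losing GOLD 0 status) and its COPD-type / PRISm-type subtypes.

The generators are deterministic functions of their inputs and a seed.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from .dataset import CATEGORICAL, CONTINUOUS, MixedDataset, build_meta

LATENT = "latent"

# ---------------------------------------------------------------------------
# ground-truth DAG


@dataclasses.dataclass
class GroundTruthDAG:
    """A causal DAG over observed and latent nodes with structural equations.

    ``graph`` node attributes: ``kind`` in {continuous, categorical, latent}
    and ``levels`` (tuple) for categorical nodes.  ``params`` maps each
    non-root child to its structural equation:

    * continuous child: ``{"intercept", "coefs", "noise_sd"}`` where
      ``coefs[parent]`` is a scalar (continuous parent) or a per-level offset
      array (categorical parent);
    * categorical child with L levels: ``{"intercepts": (L,), "coefs"}``
      where ``coefs[parent]`` is shape ``(L,)`` (continuous parent) or
      ``(L_parent, L)`` (categorical parent);
    * the special outcome of :func:`make_copd_like` stores an
      :class:`AxisModel` under ``params[outcome]``.
    """

    graph: nx.DiGraph
    params: dict
    outcome: str | None = None

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("edge set must be acyclic")
        for node in self.latent_nodes:
            nbrs = set(self.graph.successors(node)) | set(self.graph.predecessors(node))
            observed_nbrs = [v for v in nbrs if self.kind(v) != LATENT]
            if len(observed_nbrs) < 2:
                raise ValueError(
                    f"latent {node!r} touches <2 observed nodes; it is "
                    "marginalizable noise"
                )
        for node in self.graph.nodes:
            if self.kind(node) == CATEGORICAL:
                levels = self.graph.nodes[node].get("levels")
                if levels is None or len(levels) not in (2, 3):
                    raise ValueError(f"categorical {node!r} must have 2 or 3 levels")

    def kind(self, node: str) -> str:
        return self.graph.nodes[node]["kind"]

    def levels(self, node: str) -> tuple[str, ...]:
        return tuple(self.graph.nodes[node]["levels"])

    @property
    def observed_nodes(self) -> list[str]:
        return [v for v in self.graph.nodes if self.kind(v) != LATENT]

    @property
    def latent_nodes(self) -> list[str]:
        return [v for v in self.graph.nodes if self.kind(v) == LATENT]

    def markov_blanket(self, node: str) -> set[str]:
        """Parents, children and co-parents of children, observed nodes only."""
        g = self.graph
        mb = set(g.predecessors(node)) | set(g.successors(node))
        for child in g.successors(node):
            mb |= set(g.predecessors(child))
        mb.discard(node)
        return {v for v in mb if self.kind(v) != LATENT}

    # -- serialization ------------------------------------------------------

    def write_edges(self, path: str | Path) -> None:
        """Directed edge list, one ``parent<TAB>child`` per line; latent
        nodes flagged with a trailing ``*``."""
        latent = set(self.latent_nodes)

        def tag(v: str) -> str:
            return f"{v}*" if v in latent else v

        with open(path, "w") as fh:
            for a, b in sorted(self.graph.edges):
                fh.write(f"{tag(a)}\t{tag(b)}\n")


# ---------------------------------------------------------------------------
# generic random SEM


def sample_dag(
    n_observed: int,
    n_latent: int,
    edge_prob: float,
    mb_size: int,
    seed: int,
    frac_categorical: float = 0.4,
    effect_floor: float = 0.3,
    effect_ceil: float = 0.9,
) -> GroundTruthDAG:
    """Draw a random acyclic SEM whose outcome has a Markov blanket of
    exactly ``mb_size`` observed variables.

    The outcome is a binary sink node (mirroring a follow-up measurement
    that cannot cause baseline variables), so its Markov blanket equals its
    parent set.  Latent nodes are continuous roots with at least two
    observed children.  All pairwise effects are bounded away from zero
    (``|coef| >= effect_floor``).
    """
    if mb_size > n_observed - 1:
        raise ValueError(
            f"mb_size={mb_size} infeasible for n_observed={n_observed}: "
            "the outcome cannot have more blanket members than other variables"
        )
    rng = np.random.default_rng(seed)
    covs = [f"x{i:02d}" for i in range(n_observed - 1)]
    outcome = "outcome"
    latents = [f"L{i}" for i in range(n_latent)]

    g = nx.DiGraph()
    for v in covs:
        if rng.random() < frac_categorical:
            L = int(rng.choice([2, 3]))
            g.add_node(v, kind=CATEGORICAL, levels=tuple(f"c{j}" for j in range(L)))
        else:
            g.add_node(v, kind=CONTINUOUS)
    g.add_node(outcome, kind=CATEGORICAL, levels=("stay", "leave"))
    for v in latents:
        g.add_node(v, kind=LATENT)

    # edges among covariates follow their index order (a topological order)
    for i in range(len(covs)):
        for j in range(i + 1, len(covs)):
            if rng.random() < edge_prob:
                g.add_edge(covs[i], covs[j])
    mb = list(rng.choice(covs, size=mb_size, replace=False))
    for v in mb:
        g.add_edge(v, outcome)
    for lat in latents:
        n_children = 2 + rng.binomial(2, 0.3)
        children = rng.choice(covs, size=min(n_children, len(covs)), replace=False)
        for c in children:
            g.add_edge(lat, c)

    params = {
        child: _draw_equation(g, child, rng, effect_floor, effect_ceil)
        for child in g.nodes
        if g.in_degree(child) > 0 or g.nodes[child]["kind"] != LATENT
    }
    return GroundTruthDAG(g, params, outcome=outcome)


def _draw_coef(rng: np.random.Generator, floor: float, ceil: float) -> float:
    return float(rng.uniform(floor, ceil) * rng.choice([-1.0, 1.0]))


def _draw_equation(g: nx.DiGraph, child: str, rng, floor: float, ceil: float) -> dict:
    kind = g.nodes[child]["kind"]
    parents = list(g.predecessors(child))
    if kind in (CONTINUOUS, LATENT):
        coefs = {}
        for p in parents:
            if g.nodes[p]["kind"] == CATEGORICAL:
                Lp = len(g.nodes[p]["levels"])
                offs = np.array([_draw_coef(rng, floor, ceil) for _ in range(Lp)])
                coefs[p] = offs - offs.mean()
            else:
                coefs[p] = _draw_coef(rng, floor, ceil)
        return {
            "intercept": float(rng.normal(0, 0.3)),
            "coefs": coefs,
            "noise_sd": float(rng.uniform(0.6, 1.0)),
        }
    L = len(g.nodes[child]["levels"])
    coefs = {}
    for p in parents:
        if g.nodes[p]["kind"] == CATEGORICAL:
            Lp = len(g.nodes[p]["levels"])
            mat = np.array(
                [[_draw_coef(rng, floor, ceil) for _ in range(L)] for _ in range(Lp)]
            )
            coefs[p] = mat - mat.mean(axis=1, keepdims=True)
        else:
            vec = np.array([_draw_coef(rng, floor, ceil) for _ in range(L)])
            coefs[p] = vec - vec.mean()
    icpt = rng.normal(0, 0.3, size=L)
    return {"intercepts": icpt - icpt.mean(), "coefs": coefs}


def simulate_mixed(
    dag: GroundTruthDAG,
    n: int,
    seed: int,
    return_latent: bool = False,
):
    """Ancestral sampling from the structural equations.

    Returns a :class:`MixedDataset` without latent columns; with
    ``return_latent=True`` additionally returns the full frame (observed +
    latent columns) as a debug view.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    g = dag.graph
    columns: dict[str, np.ndarray] = {}
    for node in nx.topological_sort(g):
        kind = dag.kind(node)
        eq = dag.params.get(node)
        if isinstance(eq, AxisModel):
            axes = _axes_from_model(eq, columns, n, rng)
            columns[node] = np.where(axes.event, dag.levels(node)[1], dag.levels(node)[0])
            continue
        if kind in (CONTINUOUS, LATENT):
            if eq is None:
                columns[node] = rng.normal(0.0, 1.0, size=n)
            else:
                lin = np.full(n, eq["intercept"])
                for p, c in eq["coefs"].items():
                    lin += _parent_contribution(dag, p, columns[p], c)
                columns[node] = lin + rng.normal(0.0, eq["noise_sd"], size=n)
        else:
            levels = dag.levels(node)
            L = len(levels)
            if eq is None:
                probs = np.full((n, L), 1.0 / L)
            else:
                logits = np.tile(eq["intercepts"], (n, 1))
                for p, c in eq["coefs"].items():
                    logits += _parent_logits(dag, p, columns[p], c)
                logits -= logits.max(axis=1, keepdims=True)
                probs = np.exp(logits)
                probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(n)
            idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
            columns[node] = np.asarray(levels, dtype=object)[idx]

    full = pd.DataFrame({v: columns[v] for v in g.nodes})
    observed = dag.observed_nodes
    kinds = {v: dag.kind(v) for v in observed}
    levels = {v: dag.levels(v) for v in observed if dag.kind(v) == CATEGORICAL}
    roles = {v: g.nodes[v].get("role", "baseline") for v in observed}
    if dag.outcome is not None:
        roles[dag.outcome] = "outcome"
    meta = build_meta(kinds, levels, roles)
    values = full[observed].copy()
    for v in observed:
        if kinds[v] == CONTINUOUS:
            values[v] = values[v].astype(float)
    data = MixedDataset(values, meta, outcome_name=dag.outcome)
    if return_latent:
        return data, full
    return data


def _parent_contribution(dag, parent, col, coef):
    if dag.kind(parent) == CATEGORICAL:
        levels = dag.levels(parent)
        lut = {lv: coef[i] for i, lv in enumerate(levels)}
        return np.array([lut[v] for v in col])
    return np.asarray(coef) * col


def _parent_logits(dag, parent, col, coef):
    coef = np.asarray(coef)
    if dag.kind(parent) == CATEGORICAL:
        levels = dag.levels(parent)
        idx = np.array([levels.index(v) for v in col])
        return coef[idx]
    return np.outer(col, coef)


# ---------------------------------------------------------------------------
# d-separation oracle


def d_separated(g: nx.DiGraph, x: str, y: str, cond: Iterable[str]) -> bool:
    """Reachability-based d-separation test (Bayes-ball style).

    Independent of :mod:`networkx`'s implementation; the two are
    cross-checked in the test suite.
    """
    cond = set(cond)
    # ancestors of the conditioning set (including itself)
    anc = set(cond)
    stack = list(cond)
    while stack:
        v = stack.pop()
        for p in g.predecessors(v):
            if p not in anc:
                anc.add(p)
                stack.append(p)
    # traverse trails from x; direction "up" = arrived from a child
    visited = set()
    stack = [(x, "up")]
    while stack:
        v, d = stack.pop()
        if (v, d) in visited:
            continue
        visited.add((v, d))
        if v == y and v not in cond:
            return False
        if d == "up" and v not in cond:
            for p in g.predecessors(v):
                stack.append((p, "up"))
            for c in g.successors(v):
                stack.append((c, "down"))
        elif d == "down":
            if v not in cond:
                for c in g.successors(v):
                    stack.append((c, "down"))
            if v in anc:
                for p in g.predecessors(v):
                    stack.append((p, "up"))
    return True


def oracle_independent(
    dag: GroundTruthDAG, x: str, y: str, cond: Iterable[str] = ()
) -> bool:
    """m-separation status of two observed variables given ``cond``.

    Latent nodes are treated as unobserved: they may never appear in the
    conditioning set.  Equivalent to d-separation in the full DAG.
    """
    cond = set(cond)
    if x == y:
        raise ValueError("x and y must differ")
    if x in cond or y in cond:
        raise ValueError("conditioning set must exclude x and y")
    for v in {x, y} | cond:
        if v not in dag.graph:
            raise KeyError(f"unknown variable {v!r}")
    bad = [v for v in cond if dag.kind(v) == LATENT]
    if bad:
        raise ValueError(f"latent variables cannot be conditioned on: {bad}")
    return d_separated(dag.graph, x, y, cond)


# ---------------------------------------------------------------------------
# COPD-like structured cohort


@dataclasses.dataclass
class CohortSpec:
    """Study-condition parameters for :func:`make_copd_like`.

    Defaults mirror the training cohort the pipeline is designed around:
    2,114 subjects, ~30 retained mixed-type variables, a 20.3% minority
    class (subjects losing normal spirometry over 5 years) and a true
    Markov blanket of 6 baseline variables.
    """

    n_subjects: int = 2114
    n_observed: int = 30
    n_latent: int = 3
    mb_size: int = 6
    minority_rate: float = 0.203
    missing_rate: float = 0.0
    seed: int = 0
    effect_floor: float = 0.3
    #: SD of the Gaussian noise on each follow-up spirometric axis, on the
    #: standardized axis scale.  The default puts the Bayes-optimal AUROC of
    #: the outcome near 0.78, the operating regime the pipeline targets.
    #: Set to 0 for a deterministic outcome.
    axis_noise_sd: float = 2.9

    def __post_init__(self) -> None:
        if not 0 < self.minority_rate < 0.5:
            raise ValueError("minority_rate must lie in (0, 0.5)")
        if not 0 <= self.missing_rate < 0.3:
            raise ValueError("missing_rate must lie in [0, 0.3)")
        if self.mb_size >= self.n_observed:
            raise ValueError("mb_size must be smaller than n_observed")


@dataclasses.dataclass
class AxisModel:
    """Structural model of the two follow-up spirometric axes.

    Each axis is a linear function of standardized baseline Markov-blanket
    variables plus Gaussian noise, mapped affinely onto its clinical scale
    (FEV1 %predicted as a fraction; FEV1/FVC ratio).  ``shift`` is the
    intercept found by event-rate calibration.
    """

    contrib_f: dict
    contrib_r: dict
    noise_sd: float
    shift: float = 0.0
    loc_f: float = 0.974
    scale_f: float = 0.115
    thr_f: float = 0.80
    loc_r: float = 0.786
    scale_r: float = 0.052
    thr_r: float = 0.70

    def linear_predictors(self, frame: Mapping[str, np.ndarray]):
        n = len(next(iter(frame.values())))
        lin_f = np.zeros(n)
        lin_r = np.zeros(n)
        for lin, contrib in ((lin_f, self.contrib_f), (lin_r, self.contrib_r)):
            for var, spec in contrib.items():
                col = np.asarray(frame[var])
                if spec[0] == "cont":
                    _, mean, sd, w = spec
                    lin += w * (col.astype(float) - mean) / sd
                else:
                    _, lut = spec
                    lin += np.array([lut[v] for v in col])
        return lin_f, lin_r

    def bayes_risk(self, frame: Mapping[str, np.ndarray]) -> np.ndarray:
        """True event probability given the baseline variables."""
        lin_f, lin_r = self.linear_predictors(frame)
        t_f = (self.thr_f - self.loc_f) / self.scale_f
        t_r = (self.thr_r - self.loc_r) / self.scale_r
        if self.noise_sd == 0:
            p_ok_f = ((lin_f + self.shift) >= t_f).astype(float)
            p_ok_r = ((lin_r + self.shift) >= t_r).astype(float)
        else:
            p_ok_f = norm.sf(t_f, loc=lin_f + self.shift, scale=self.noise_sd)
            p_ok_r = norm.sf(t_r, loc=lin_r + self.shift, scale=self.noise_sd)
        return 1.0 - p_ok_f * p_ok_r


@dataclasses.dataclass
class SpiroAxes:
    """Per-subject follow-up spirometric axes and derived labels."""

    fev1pp: np.ndarray
    ratio: np.ndarray
    thr_f: float = 0.80
    thr_r: float = 0.70

    @property
    def event(self) -> np.ndarray:
        return (self.ratio < self.thr_r) | (self.fev1pp < self.thr_f)

    @property
    def copd_type(self) -> np.ndarray:
        """Leavers via an FEV1/FVC reduction (obstructive trajectory)."""
        return self.ratio < self.thr_r

    @property
    def prism_type(self) -> np.ndarray:
        """Leavers via FEV1 %predicted only, ratio preserved (PRISm)."""
        return (self.fev1pp < self.thr_f) & (self.ratio >= self.thr_r)


class CalibrationError(RuntimeError):
    pass


#: Markov-blanket variables of the outcome in priority order; the first
#: ``mb_size`` are wired into the follow-up axes.
_MB_PRIORITY = ("fef2575", "age", "pi10", "sex", "height", "perc15", "sgrq", "bmi")

#: standardized axis weights. pi10 (airway-wall analog) feeds only the FEV1
#: %predicted axis; perc15 (emphysema analog) feeds only the FEV1/FVC axis,
#: so the two outcome subtypes have distinct mechanisms.
_AXIS_WEIGHTS = {
    "fef2575": {"f": 0.65, "r": 0.65},
    "age": {"f": -0.55, "r": -0.55},
    "pi10": {"f": -0.85, "r": 0.0},
    "sex": {"f": 0.55, "r": 0.55},  # offset magnitude; female negative
    "height": {"f": 0.5, "r": 0.5},
    "perc15": {"f": 0.0, "r": 0.85},
    "sgrq": {"f": -0.4, "r": -0.4},
    "bmi": {"f": -0.4, "r": -0.4},
}


def _build_copd_dag(spec: CohortSpec, rng: np.random.Generator) -> GroundTruthDAG:
    g = nx.DiGraph()
    params: dict = {}

    def cont(name, role="baseline"):
        g.add_node(name, kind=CONTINUOUS, role=role)

    def cat(name, levels, role="baseline"):
        g.add_node(name, kind=CATEGORICAL, levels=tuple(levels), role=role)

    cat("sex", ("male", "female"))
    cont("age")
    cont("height")
    cont("packyears")
    cat("current_smoker", ("no", "yes"))
    cont("bmi")
    cont("pi10")
    cont("perc15")
    cont("fef2575", role="spirometry")
    cont("sgrq")
    cont("fev1pp_bl", role="spirometry-derived")
    cont("ratio_bl", role="spirometry-derived")

    params["sex"] = {"intercepts": np.array([-0.02, 0.02]), "coefs": {}}
    params["age"] = {"intercept": 60.0, "coefs": {}, "noise_sd": 9.0}
    g.add_edge("sex", "height")
    params["height"] = {
        "intercept": 168.5,
        "coefs": {"sex": np.array([6.5, -6.5])},
        "noise_sd": 7.0,
    }
    g.add_edge("age", "packyears")
    params["packyears"] = {
        "intercept": 40.0 - 0.4 * 60.0,
        "coefs": {"age": 0.4},
        "noise_sd": 18.0,
    }
    g.add_edge("age", "current_smoker")
    params["current_smoker"] = {
        "intercepts": np.array([0.0, 0.0]),
        "coefs": {"age": np.array([0.04, -0.04])},  # younger -> more current
    }
    params["bmi"] = {"intercept": 28.0, "coefs": {}, "noise_sd": 5.0}
    g.add_edge("packyears", "pi10")
    g.add_edge("current_smoker", "pi10")
    params["pi10"] = {
        "intercept": 3.7,
        "coefs": {"packyears": 0.004, "current_smoker": np.array([-0.05, 0.05])},
        "noise_sd": 0.12,
    }
    g.add_edge("packyears", "perc15")
    g.add_edge("age", "perc15")
    params["perc15"] = {
        "intercept": -890.0 + 0.15 * 40 + 0.6 * 60,
        "coefs": {"packyears": -0.15, "age": -0.6},
        "noise_sd": 18.0,
    }
    for p in ("age", "height", "sex", "pi10"):
        g.add_edge(p, "fef2575")
    # pi10 slope: about -0.2 SD of fef (total SD ~0.7 L/s) per SD of pi10 (0.12)
    pi10_slope = -0.2 * 0.7 / 0.12
    params["fef2575"] = {
        "intercept": 2.6 + 0.014 * 60 - 0.006 * 168.5 - pi10_slope * 3.7,
        "coefs": {
            "age": -0.014,
            "height": 0.006,
            "sex": np.array([0.09, -0.09]),
            "pi10": pi10_slope,
        },
        "noise_sd": 0.62,
    }
    g.add_edge("current_smoker", "sgrq")
    params["sgrq"] = {
        "intercept": 15.0,
        "coefs": {"current_smoker": np.array([-4.0, 4.0])},
        "noise_sd": 12.0,
    }
    for p in ("fef2575", "age"):
        g.add_edge(p, "fev1pp_bl")
    params["fev1pp_bl"] = {
        "intercept": 0.974 - 0.09 * 2.6,
        "coefs": {"fef2575": 0.09, "age": 0.0005},
        "noise_sd": 0.07,
    }
    g.add_edge("fef2575", "ratio_bl")
    params["ratio_bl"] = {
        "intercept": 0.786 - 0.045 * 2.6,
        "coefs": {"fef2575": 0.045},
        "noise_sd": 0.03,
    }

    named = list(g.nodes)
    n_fill = spec.n_observed - len(named) - 1  # -1 for the outcome
    if n_fill < 0:
        raise ValueError(
            f"n_observed={spec.n_observed} too small; the structured cohort "
            f"has {len(named) + 1} named variables"
        )
    n_snp = min(n_fill, max(0, n_fill // 2))
    snps = [f"snp{i:02d}" for i in range(n_snp)]
    for s in snps:
        cat(s, ("AA", "Aa", "aa"), role="snp")
        p_allele = rng.uniform(0.15, 0.45)
        freqs = np.array(
            [(1 - p_allele) ** 2, 2 * p_allele * (1 - p_allele), p_allele**2]
        )
        icpt = np.log(freqs)
        params[s] = {"intercepts": icpt - icpt.mean(), "coefs": {}}
    covs = [f"cov{i:02d}" for i in range(n_fill - n_snp)]
    cont_named = [v for v in named if g.nodes[v]["kind"] == CONTINUOUS]
    for c in covs:
        if rng.random() < 0.35:
            L = int(rng.choice([2, 3]))
            cat(c, tuple(f"c{j}" for j in range(L)))
        else:
            cont(c)
        n_par = int(rng.integers(0, 3))
        for p in rng.choice(cont_named, size=n_par, replace=False):
            g.add_edge(p, c)
        params[c] = None  # drawn below, once latent parents are wired

    # latent confounders: continuous roots, each touching >=2 observed nodes
    latent_targets = ["pi10", "sgrq", "perc15", "bmi"] + covs
    for i in range(spec.n_latent):
        name = f"Lat{i}"
        g.add_node(name, kind=LATENT)
        params[name] = {"intercept": 0.0, "coefs": {}, "noise_sd": 1.0}
        targets = rng.choice(latent_targets, size=2, replace=False)
        for t in targets:
            g.add_edge(name, t)

    # draw filler equations with moderate *standardized* effects: divide the
    # drawn coefficient by the parent's approximate marginal SD
    approx_sd = {
        "age": 9.0, "height": 7.2, "packyears": 18.5, "bmi": 5.0, "pi10": 0.13,
        "perc15": 18.5, "fef2575": 0.7, "sgrq": 12.5, "fev1pp_bl": 0.095,
        "ratio_bl": 0.043,
    }
    for c in covs:
        eq = _draw_equation(g, c, rng, spec.effect_floor, 0.7)
        if g.nodes[c]["kind"] == CONTINUOUS:
            for p in list(eq["coefs"]):
                if g.nodes[p]["kind"] == CONTINUOUS:
                    eq["coefs"][p] /= approx_sd.get(p, 1.0)
        else:
            for p in list(eq["coefs"]):
                if g.nodes[p]["kind"] == CONTINUOUS:
                    eq["coefs"][p] = eq["coefs"][p] / approx_sd.get(p, 1.0)
        params[c] = eq
    for t in ("pi10", "sgrq", "perc15", "bmi"):
        lat_parents = [p for p in g.predecessors(t) if g.nodes[p]["kind"] == LATENT]
        for p in lat_parents:
            scale = {"pi10": 0.12, "sgrq": 12.0, "perc15": 18.0, "bmi": 5.0}[t]
            params[t]["coefs"][p] = _draw_coef(rng, spec.effect_floor, 0.6) * scale

    # outcome node: thresholded follow-up axes (AxisModel filled later)
    g.add_node("dgold0", kind=CATEGORICAL, levels=("stay", "leave"), role="outcome")
    mb = list(_MB_PRIORITY[: spec.mb_size])
    for v in mb:
        g.add_edge(v, "dgold0")
    return GroundTruthDAG(g, params, outcome="dgold0")


def _axes_from_model(model: AxisModel, frame, n, rng) -> SpiroAxes:
    lin_f, lin_r = model.linear_predictors(frame)
    if model.noise_sd > 0:
        z_f = lin_f + rng.normal(0, model.noise_sd, size=n)
        z_r = lin_r + rng.normal(0, model.noise_sd, size=n)
    else:
        z_f, z_r = lin_f.copy(), lin_r.copy()
    z_f += model.shift
    z_r += model.shift
    return SpiroAxes(
        model.loc_f + model.scale_f * z_f,
        model.loc_r + model.scale_r * z_r,
        model.thr_f,
        model.thr_r,
    )


def make_copd_like(spec: CohortSpec):
    """Generate a COPD-like cohort with a thresholded spirometric outcome.

    Returns ``(data, dag, axes)``: the observed mixed-type table (latent
    columns dropped; outcome column ``dgold0``), the ground-truth DAG whose
    outcome equation stores the fitted :class:`AxisModel`, and the
    per-subject follow-up axes with COPD-type / PRISm-type sub-labels.

    The axis intercept is calibrated by bisection so the realized event
    rate lies within 2 percentage points of ``spec.minority_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    dag = _build_copd_dag(spec, rng)
    g = dag.graph

    # sample baseline variables (everything upstream of the outcome)
    baseline_nodes = [v for v in g.nodes if v != "dgold0"]
    sub = GroundTruthDAG(
        g.subgraph(baseline_nodes).copy(),
        {k: v for k, v in dag.params.items() if k != "dgold0"},
        outcome=None,
    )
    base_data, full = simulate_mixed(sub, spec.n_subjects, int(rng.integers(2**31)),
                                     return_latent=True)
    frame = {v: full[v].to_numpy() for v in baseline_nodes}

    # standardized axis contributions over the true Markov blanket
    mb = list(_MB_PRIORITY[: spec.mb_size])
    contrib_f: dict = {}
    contrib_r: dict = {}
    for var in mb:
        w = _AXIS_WEIGHTS[var]
        if dag.kind(var) == CATEGORICAL:
            levels = dag.levels(var)
            for key, contrib in (("f", contrib_f), ("r", contrib_r)):
                if w[key] == 0:
                    continue
                offs = np.linspace(w[key], -w[key], len(levels))
                contrib[var] = ("cat", {lv: float(o) for lv, o in zip(levels, offs)})
        else:
            col = frame[var].astype(float)
            mean, sd = float(col.mean()), float(col.std())
            if w["f"] != 0:
                contrib_f[var] = ("cont", mean, sd, w["f"])
            if w["r"] != 0:
                contrib_r[var] = ("cont", mean, sd, w["r"])
    model = AxisModel(contrib_f, contrib_r, noise_sd=spec.axis_noise_sd)

    # pre-draw axis noise once; bisection shifts the shared intercept
    lin_f, lin_r = model.linear_predictors(frame)
    if model.noise_sd > 0:
        eps_f = rng.normal(0, model.noise_sd, size=spec.n_subjects)
        eps_r = rng.normal(0, model.noise_sd, size=spec.n_subjects)
    else:
        eps_f = eps_r = np.zeros(spec.n_subjects)
    t_f = (model.thr_f - model.loc_f) / model.scale_f
    t_r = (model.thr_r - model.loc_r) / model.scale_r

    def rate(shift: float) -> float:
        ev = ((lin_f + eps_f + shift) < t_f) | ((lin_r + eps_r + shift) < t_r)
        return float(ev.mean())

    lo, hi = -8.0, 8.0  # rate(lo) ~ 1, rate(hi) ~ 0
    shift = 0.0
    for _ in range(50):
        shift = 0.5 * (lo + hi)
        r = rate(shift)
        if abs(r - spec.minority_rate) <= 0.02:
            break
        if r > spec.minority_rate:
            lo = shift
        else:
            hi = shift
    realized = rate(shift)
    if abs(realized - spec.minority_rate) > 0.02:
        raise CalibrationError(
            f"event-rate calibration failed: target {spec.minority_rate:.3f}, "
            f"achieved {realized:.3f} at shift {shift:.3f} "
            f"(rate range [{rate(8.0):.3f}, {rate(-8.0):.3f}])"
        )
    model.shift = shift
    dag.params["dgold0"] = model

    axes = SpiroAxes(
        model.loc_f + model.scale_f * (lin_f + eps_f + shift),
        model.loc_r + model.scale_r * (lin_r + eps_r + shift),
    )
    outcome_col = np.where(axes.event, "leave", "stay").astype(object)

    values = base_data.values.copy()
    values["dgold0"] = outcome_col
    meta = base_data.meta.copy()
    meta.loc["dgold0"] = {"kind": CATEGORICAL, "levels": ("stay", "leave"),
                          "role": "outcome"}
    data = MixedDataset(values, meta, outcome_name="dgold0")
    if spec.missing_rate > 0:
        data = inject_missing(data, spec.missing_rate, int(rng.integers(2**31)))
    return data, dag, axes


def simulate_followup(dag: GroundTruthDAG, data: MixedDataset, seed: int) -> SpiroAxes:
    """Draw fresh follow-up axes for given baseline records using the axis
    model stored in a :func:`make_copd_like` DAG."""
    model = dag.params[dag.outcome]
    if not isinstance(model, AxisModel):
        raise TypeError("dag does not carry an AxisModel outcome equation")
    rng = np.random.default_rng(seed)
    frame = {v: data.values[v].to_numpy() for v in data.variables if v != dag.outcome}
    return _axes_from_model(model, frame, data.n_subjects, rng)


def bayes_risk(dag: GroundTruthDAG, data: MixedDataset) -> np.ndarray:
    """True event probability for each record under the generating model."""
    model = dag.params[dag.outcome]
    if not isinstance(model, AxisModel):
        raise TypeError("dag does not carry an AxisModel outcome equation")
    frame = {v: data.values[v].to_numpy() for v in data.variables if v != dag.outcome}
    return model.bayes_risk(frame)


# ---------------------------------------------------------------------------
# missingness injection


def inject_missing(data: MixedDataset, rate: float, seed: int) -> MixedDataset:
    """Mask non-outcome cells completely at random with probability ``rate``.

    The outcome column is never masked.  The mask is recoverable from the
    returned dataset's ``mask`` property (and by comparison with the input),
    so imputation error is measurable.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    out = data.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    cols = [c for c in data.variables if c != data.outcome_name]
    mask = rng.random((data.n_subjects, len(cols))) < rate
    for j, c in enumerate(cols):
        col = out.values[c].copy()
        col[mask[:, j]] = np.nan
        out.values[c] = col
    return out
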