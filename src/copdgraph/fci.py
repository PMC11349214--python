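"""Constraint-based orientation of a mixed-model skeleton into a PAG.

The pipeline follows the FCI family with the *max-p* collider resolution:

1. PC-style edge deletion restricted to the MGM skeleton's adjacencies
   (conditioning sets of size 0..max_cond drawn from either endpoint's
   neighbourhood), recording a separating set for every removed edge.
2. A bounded possible-d-sep stage: after provisional collider orientation,
   additional conditioning sets are drawn from each node's possible-d-sep
   set (paths of limited length whose interior triples are colliders or
   triangles), as latent confounding can require separators outside the
   adjacency sets.
3. Orientation from scratch: every endpoint starts as a circle; for each
   unshielded triple x - z - y the candidate separating set with the
   *maximum* p-value decides collider status (z absent from the max-p set
   orients x *-> z <-* y); then Zhang's rules R1-R4 run to fixpoint.

With an oracle tester (d-separation in a ground-truth DAG) and unbounded
search the output reproduces the PAG of the latent projection; the test
suite verifies this against an independent brute-force construction.
"""

from __future__ import annotations

import logging
from itertools import combinations

from .citest import CITester, OracleCITester
from .dataset import MixedDataset
from .mgm import Skeleton, fit_mgm
from .pag import ARROW, CIRCLE, TAIL, PAG

logger = logging.getLogger(__name__)


def _as_tester(data_or_tester):
    if isinstance(data_or_tester, MixedDataset):
        return CITester(data_or_tester)
    return data_or_tester


def _subset_sizes(pool: int, max_cond: int | None) -> int:
    return pool if max_cond is None else min(max_cond, pool)


# ---------------------------------------------------------------------------
# stage 1: PC-style pruning over skeleton adjacencies


def prune_skeleton(
    skeleton: Skeleton,
    data_or_tester,
    alpha: float,
    max_cond: int | None = 3,
):
    """Delete skeleton edges that admit a separating set.

    For conditioning-set sizes 0..``max_cond``, each remaining edge (x, y)
    is tested against subsets of adj(x) \\ {y} and adj(y) \\ {x}; deletion
    on independence records the separating set.  Adjacency sets are frozen
    per size level and iteration order is lexicographic, so the result is
    order-independent and deterministic.
    """
    tester = _as_tester(data_or_tester)
    adj = {v: set(skeleton.neighbors(v)) for v in skeleton.nodes}
    sepsets: dict = {}
    depth = 0
    while True:
        frozen = {v: sorted(s) for v, s in adj.items()}
        if max_cond is not None and depth > max_cond:
            break
        if all(len(frozen[v]) - 1 < depth for v in skeleton.nodes):
            break
        edges = sorted(tuple(sorted(p)) for p in _current_edges(adj))
        for x, y in edges:
            if y not in adj[x]:
                continue
            removed = False
            for side, other in ((x, y), (y, x)):
                pool = [v for v in frozen[side] if v != other]
                if len(pool) < depth:
                    continue
                for S in combinations(pool, depth):
                    if tester.pvalue(x, y, S) > alpha:
                        adj[x].discard(y)
                        adj[y].discard(x)
                        sepsets[frozenset((x, y))] = tuple(S)
                        removed = True
                        break
                if removed:
                    break
        depth += 1
    return _subset_skeleton(skeleton, adj), sepsets


def _current_edges(adj):
    seen = set()
    for v, nbrs in adj.items():
        for u in nbrs:
            seen.add(frozenset((v, u)))
    return seen


def _subset_skeleton(skeleton: Skeleton, adj) -> Skeleton:
    weights = {
        pair: w
        for pair, w in skeleton.weights.items()
        if (lambda ab: ab[1] in adj[ab[0]])(tuple(pair))
    }
    return Skeleton(list(skeleton.nodes), weights)


# ---------------------------------------------------------------------------
# stage 2: possible-d-sep pruning


def _provisional_colliders(pag: PAG, sepsets: dict) -> None:
    for x, z, y in pag.unshielded_triples():
        S = sepsets.get(frozenset((x, y)))
        if S is not None and z not in S:
            pag.set_mark(x, z, ARROW)
            pag.set_mark(y, z, ARROW)


def possible_d_sep(pag: PAG, x: str, path_limit: int | None = None) -> set:
    """Nodes reachable from ``x`` along paths whose interior triples are
    colliders or triangles (candidates for separating sets under latent
    confounding), up to ``path_limit`` edges."""
    out: set = set()
    frontier = {(x, n) for n in pag.neighbors(x)}
    out.update(n for _, n in frontier)
    visited = set(frontier)
    depth = 1
    while frontier and (path_limit is None or depth < path_limit):
        new = set()
        for prev, cur in frontier:
            for nxt in pag.neighbors(cur):
                if nxt == prev or nxt == x or (cur, nxt) in visited:
                    continue
                collider = pag.is_arrow_into(prev, cur) and pag.is_arrow_into(nxt, cur)
                if collider or pag.has_edge(prev, nxt):
                    visited.add((cur, nxt))
                    new.add((cur, nxt))
                    out.add(nxt)
        frontier = new
        depth += 1
    out.discard(x)
    return out


def _pds_prune(
    skeleton: Skeleton,
    sepsets: dict,
    tester,
    alpha: float,
    max_cond: int | None,
    path_limit: int | None,
):
    """Second deletion pass with conditioning sets from possible-d-sep."""
    pag = _circles_pag(skeleton)
    _provisional_colliders(pag, sepsets)
    adj = {v: set(skeleton.neighbors(v)) for v in skeleton.nodes}
    pds = {v: possible_d_sep(pag, v, path_limit) for v in skeleton.nodes}
    for x, y in sorted(tuple(sorted(p)) for p in _current_edges(adj)):
        removed = False
        for side, other in ((x, y), (y, x)):
            pool = sorted(pds[side] - {x, y})
            kmax = _subset_sizes(len(pool), max_cond)
            for k in range(1, kmax + 1):
                for S in combinations(pool, k):
                    if tester.pvalue(x, y, S) > alpha:
                        adj[x].discard(y)
                        adj[y].discard(x)
                        sepsets[frozenset((x, y))] = tuple(S)
                        removed = True
                        break
                if removed:
                    break
            if removed:
                break
    return _subset_skeleton(skeleton, adj), sepsets


# ---------------------------------------------------------------------------
# stage 3: max-p collider orientation and rules R1-R4


def _circles_pag(skeleton: Skeleton) -> PAG:
    pag = PAG(list(skeleton.nodes))
    for a, b in skeleton.edges:
        pag.add_edge(a, b, CIRCLE, CIRCLE)
    return pag


def _max_p_sepset(x, y, adj, sepsets, tester, alpha, max_cond, memo=None):
    """Candidate separating set with the maximum p-value.

    Candidates are subsets of either endpoint's adjacency set plus the
    recorded separating set; ties break toward smaller then
    lexicographically earlier sets, so the choice is deterministic.  The
    search depends only on the pair, so results are memoized per pair.
    """
    if memo is not None:
        hit = memo.get(frozenset((x, y)))
        if hit is not None:
            return hit
    cands = []
    seen = set()
    for side in (x, y):
        pool = sorted(adj[side] - {x, y})
        kmax = _subset_sizes(len(pool), max_cond)
        for k in range(kmax + 1):
            for S in combinations(pool, k):
                if S not in seen:
                    seen.add(S)
                    cands.append(S)
    rec = sepsets.get(frozenset((x, y)))
    if rec is not None and tuple(rec) not in seen:
        cands.append(tuple(rec))
    best = None
    for S in cands:
        p = tester.pvalue(x, y, S)
        key = (-p, len(S), S)
        if best is None or key < best[0]:
            best = (key, S, p)
    out = (best[2], best[1])
    if memo is not None:
        memo[frozenset((x, y))] = out
    return out


def orient_max_p(
    skeleton: Skeleton,
    sepsets: dict,
    data_or_tester,
    alpha: float,
    max_cond: int | None = 3,
) -> PAG:
    """Orient a pruned skeleton into a PAG.

    All endpoints start as circles.  Unshielded triples become colliders
    when the max-p separating set of their endpoints excludes the middle
    node; collider orientations apply in order of decreasing separation
    confidence.  Zhang's rules R1-R4 then run to fixpoint.
    """
    tester = _as_tester(data_or_tester)
    pag = _circles_pag(skeleton)
    adj = {v: set(skeleton.neighbors(v)) for v in skeleton.nodes}
    sepsets = dict(sepsets)

    colliders = []
    memo: dict = {}
    for x, z, y in sorted(pag.unshielded_triples()):
        p, S = _max_p_sepset(x, y, adj, sepsets, tester, alpha, max_cond, memo)
        if p > alpha:
            sepsets[frozenset((x, y))] = tuple(S)
            if z not in S:
                colliders.append((p, x, z, y))
        else:
            logger.debug(
                "unshielded triple (%s, %s, %s): no separating set found "
                "(max p=%.3g)", x, z, y, p,
            )
    colliders.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    for p, x, z, y in colliders:
        for a in (x, y):
            if pag.mark(a, z) == TAIL:
                logger.warning(
                    "collider %s *-> %s <-* %s conflicts with existing tail",
                    x, z, y,
                )
                continue
            pag.set_mark(a, z, ARROW)

    sep_lookup = _SepsetLookup(sepsets, adj, tester, alpha, max_cond, memo)
    _apply_rules(pag, sep_lookup)
    pag.sepsets = sepsets
    return pag


class _SepsetLookup:
    """Separating-set membership resolver for rule R4."""

    def __init__(self, sepsets, adj, tester, alpha, max_cond, memo=None):
        self.sepsets = sepsets
        self.adj = adj
        self.tester = tester
        self.alpha = alpha
        self.max_cond = max_cond
        self.memo = memo if memo is not None else {}

    def contains(self, x, y, node) -> bool:
        S = self.sepsets.get(frozenset((x, y)))
        if S is None:
            p, S = _max_p_sepset(
                x, y, self.adj, self.sepsets, self.tester, self.alpha,
                self.max_cond, self.memo,
            )
            if p <= self.alpha:
                logger.debug("R4: no separating set for (%s, %s)", x, y)
                return False
            self.sepsets[frozenset((x, y))] = tuple(S)
        return node in S


def _apply_rules(pag: PAG, sep_lookup: _SepsetLookup) -> None:
    changed = True
    while changed:
        changed = False
        changed |= _rule_r1(pag)
        changed |= _rule_r2(pag)
        changed |= _rule_r3(pag)
        changed |= _rule_r4(pag, sep_lookup)


def _rule_r1(pag: PAG) -> bool:
    """x *-> z o-* y with x, y nonadjacent  =>  z --> y."""
    changed = False
    for x, z, y in list(pag.unshielded_triples()):
        for a, b in ((x, y), (y, x)):
            if pag.is_arrow_into(a, z) and pag.mark(b, z) == CIRCLE:
                pag.set_mark(b, z, TAIL)
                pag.set_mark(z, b, ARROW)
                changed = True
    return changed


def _rule_r2(pag: PAG) -> bool:
    """x --> z *-> y or x *-> z --> y, and x *-o y  =>  x *-> y."""
    changed = False
    for x in pag.nodes:
        for y in pag.neighbors(x):
            if pag.mark(x, y) != CIRCLE:
                continue
            for z in pag.neighbors(x):
                if z == y or not pag.has_edge(z, y):
                    continue
                chain1 = pag.is_directed(x, z) and pag.is_arrow_into(z, y)
                chain2 = pag.is_arrow_into(x, z) and pag.is_directed(z, y)
                if chain1 or chain2:
                    pag.set_mark(x, y, ARROW)
                    changed = True
                    break
    return changed


def _rule_r3(pag: PAG) -> bool:
    """x *-> z <-* y, x *-o w o-* y, x, y nonadjacent, w *-o z  =>  w *-> z."""
    changed = False
    for x, w, y in list(pag.unshielded_triples()):
        if not (pag.mark(x, w) == CIRCLE and pag.mark(y, w) == CIRCLE):
            continue
        for z in pag.neighbors(w):
            if z in (x, y) or pag.mark(w, z) != CIRCLE:
                continue
            if pag.is_arrow_into(x, z) and pag.is_arrow_into(y, z):
                pag.set_mark(w, z, ARROW)
                changed = True
    return changed


def _rule_r4(pag: PAG, sep_lookup: _SepsetLookup) -> bool:
    """Discriminating-path rule.

    For a path theta, ..., a, b, c where theta and c are nonadjacent and
    every interior vertex is a collider on the path and a parent of c: if b
    lies in the separating set of (theta, c) the b-c edge orients b --> c,
    otherwise the triple a, b, c becomes a double collider (a <-> b <-> c).
    """
    changed = False
    for b in pag.nodes:
        for c in pag.neighbors(b):
            if pag.mark(c, b) != CIRCLE:  # need b o-* c
                continue
            for a in pag.neighbors(b):
                if a == c or not pag.has_edge(a, c):
                    continue
                # a must be a collider candidate: b *-> a and a --> c
                if not (pag.is_arrow_into(b, a) and pag.is_directed(a, c)):
                    continue
                theta = _find_discriminating_origin(pag, a, b, c)
                if theta is None:
                    continue
                if sep_lookup.contains(theta, c, b):
                    pag.set_mark(c, b, TAIL)
                    pag.set_mark(b, c, ARROW)
                else:
                    pag.set_mark(b, a, ARROW)
                    pag.set_mark(a, b, ARROW)
                    pag.set_mark(b, c, ARROW)
                    pag.set_mark(c, b, ARROW)
                changed = True
                break
            else:
                continue
            break
    return changed


def _find_discriminating_origin(pag: PAG, a, b, c):
    """DFS for the far endpoint of a discriminating path ending <.., a, b, c>."""
    visited = {a, b, c}
    stack = [a]
    while stack:
        v = stack.pop()
        for p in sorted(pag.neighbors(v)):
            if p in visited or not pag.is_arrow_into(p, v):
                continue
            if not pag.has_edge(p, c):
                return p  # theta found
            if pag.is_directed(p, c) and pag.is_arrow_into(v, p):
                visited.add(p)
                stack.append(p)
    return None


# ---------------------------------------------------------------------------
# composition


def learn_pag(
    data: MixedDataset,
    alpha: float,
    lam: float | None = None,
    max_cond: int | None = 3,
    pds_max_cond: int | None = 1,
    pds_path_limit: int | None = 3,
    skeleton: Skeleton | None = None,
    tester: CITester | None = None,
) -> PAG:
    """Full pipeline on data: MGM skeleton, pruning, max-p orientation.

    ``skeleton`` and ``tester`` may be supplied to reuse work across a grid
    of significance levels (the MGM fit and the CI-test cache are
    alpha-independent).
    """
    if skeleton is None:
        _, skeleton = fit_mgm(data, lam=lam)
    if tester is None:
        tester = CITester(data)
    return _learn_from_tester(
        skeleton, tester, alpha, max_cond, pds_max_cond, pds_path_limit
    )


def learn_pag_oracle(
    dag,
    alpha: float = 0.5,
    max_cond: int | None = None,
    pds_path_limit: int | None = None,
) -> PAG:
    """Run the constraint-based stages with exact d-separation answers.

    Starts from the complete skeleton over the observed nodes; with
    unbounded search this recovers the PAG of the DAG's latent projection.
    """
    tester = OracleCITester(dag)
    skeleton = Skeleton.complete(dag.observed_nodes)
    return _learn_from_tester(
        skeleton, tester, alpha, max_cond, max_cond, pds_path_limit
    )


def _learn_from_tester(
    skeleton, tester, alpha, max_cond, pds_max_cond, pds_path_limit
) -> PAG:
    n0 = getattr(tester, "n_tests", 0)
    pruned, sepsets = prune_skeleton(skeleton, tester, alpha, max_cond)
    n1 = getattr(tester, "n_tests", 0)
    if pds_max_cond is None or pds_max_cond > 0:
        pruned, sepsets = _pds_prune(
            pruned, sepsets, tester, alpha, pds_max_cond, pds_path_limit
        )
    n2 = getattr(tester, "n_tests", 0)
    pag = orient_max_p(pruned, sepsets, tester, alpha, max_cond)
    logger.info(
        "alpha=%.3g: CI tests prune=%d pds=%d orient=%d (cache-unique)",
        alpha, n1 - n0, n2 - n1, getattr(tester, "n_tests", 0) - n2,
    )
    return pag
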