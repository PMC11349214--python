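"""Independent brute-force PAG construction used as a test oracle.

Given a ground-truth DAG with latent nodes, this module builds the PAG of
its latent projection from first principles, sharing no code with the
package's FCI implementation:

1. The maximal ancestral graph (MAG) over the observed nodes: two observed
   nodes are adjacent iff no subset of the remaining observed nodes
   d-separates them (d-separation via networkx, not the package's own
   reachability routine); an adjacency is directed x -> y when x is an
   ancestor of y in the DAG and bidirected otherwise.
2. The PAG: MAG adjacencies with circle marks, unshielded colliders copied
   from the MAG's arrowheads, then an independent restatement of Zhang's
   orientation rules R1-R4 run to fixpoint.  The R4 separating-set query is
   answered by exhaustive search over observed subsets.
"""

from itertools import chain, combinations

import networkx as nx

TAIL, ARROW, CIRCLE = "-", ">", "o"


def _dsep(g, x, y, S):
    return nx.is_d_separator(g, {x}, {y}, set(S))


def _all_subsets(items):
    items = sorted(items)
    return chain.from_iterable(combinations(items, k) for k in range(len(items) + 1))


def project_to_mag(g: nx.DiGraph, observed):
    """MAG of the latent projection: dict (a, b) -> mark at b, for a < b
    stored both ways."""
    observed = sorted(observed)
    anc = {v: nx.ancestors(g, v) | {v} for v in observed}
    marks = {}
    for i, a in enumerate(observed):
        for b in observed[i + 1 :]:
            rest = [v for v in observed if v not in (a, b)]
            if any(_dsep(g, a, b, S) for S in _all_subsets(rest)):
                continue
            if a in anc[b]:
                ma, mb = TAIL, ARROW  # a --> b
            elif b in anc[a]:
                ma, mb = ARROW, TAIL
            else:
                ma, mb = ARROW, ARROW
            marks[(a, b)] = mb
            marks[(b, a)] = ma
    return marks


def bruteforce_pag(g: nx.DiGraph, observed):
    """PAG marks dict (a, b) -> mark at b, computed via the MAG."""
    mag = project_to_mag(g, observed)
    pag = {key: CIRCLE for key in mag}

    def adjacent(a, b):
        return (a, b) in pag

    def nbrs(v):
        return sorted(b for (a, b) in pag if a == v)

    # unshielded colliders from the MAG's arrowheads
    for z in observed:
        zn = nbrs(z)
        for i, x in enumerate(zn):
            for y in zn[i + 1 :]:
                if adjacent(x, y):
                    continue
                if mag[(x, z)] == ARROW and mag[(y, z)] == ARROW:
                    pag[(x, z)] = ARROW
                    pag[(y, z)] = ARROW

    def sepset_contains(theta, c, beta):
        rest = [v for v in observed if v not in (theta, c)]
        return any(
            beta in S and _dsep(g, theta, c, S) for S in _all_subsets(rest)
        )

    changed = True
    while changed:
        changed = False
        # R1: a *-> b o-* c, a and c nonadjacent => b --> c
        for b in observed:
            for a in nbrs(b):
                if pag[(a, b)] != ARROW:
                    continue
                for c in nbrs(b):
                    if c == a or adjacent(a, c):
                        continue
                    if pag[(c, b)] == CIRCLE:
                        pag[(c, b)] = TAIL
                        pag[(b, c)] = ARROW
                        changed = True
        # R2: a --> b *-> c or a *-> b --> c, a *-o c => a *-> c
        for a in observed:
            for c in nbrs(a):
                if pag[(a, c)] != CIRCLE:
                    continue
                for b in nbrs(a):
                    if b == c or not adjacent(b, c):
                        continue
                    ab_dir = pag[(a, b)] == ARROW and pag[(b, a)] == TAIL
                    bc_arrow = pag[(b, c)] == ARROW
                    ab_arrow = pag[(a, b)] == ARROW
                    bc_dir = pag[(b, c)] == ARROW and pag[(c, b)] == TAIL
                    if (ab_dir and bc_arrow) or (ab_arrow and bc_dir):
                        pag[(a, c)] = ARROW
                        changed = True
                        break
        # R3: a *-> b <-* c, a *-o d o-* c, a and c nonadjacent, d *-o b
        #     => d *-> b
        for d in observed:
            for b in nbrs(d):
                if pag[(d, b)] != CIRCLE:
                    continue
                hit = False
                dn = nbrs(d)
                for a in dn:
                    if a == b or pag[(a, d)] != CIRCLE:
                        continue
                    for c in dn:
                        if c in (a, b) or adjacent(a, c) or pag[(c, d)] != CIRCLE:
                            continue
                        if (
                            adjacent(a, b)
                            and adjacent(c, b)
                            and pag[(a, b)] == ARROW
                            and pag[(c, b)] == ARROW
                        ):
                            pag[(d, b)] = ARROW
                            changed = True
                            hit = True
                            break
                    if hit:
                        break
        # R4: discriminating paths
        for b in observed:
            for c in nbrs(b):
                if pag[(c, b)] != CIRCLE:
                    continue
                done = False
                for a in nbrs(b):
                    if a == c or not adjacent(a, c):
                        continue
                    a_coll = pag[(b, a)] == ARROW
                    a_par = pag[(a, c)] == ARROW and pag[(c, a)] == TAIL
                    if not (a_coll and a_par):
                        continue
                    theta = _disc_origin(pag, adjacent, nbrs, a, b, c)
                    if theta is None:
                        continue
                    if sepset_contains(theta, c, b):
                        pag[(c, b)] = TAIL
                        pag[(b, c)] = ARROW
                    else:
                        pag[(a, b)] = ARROW
                        pag[(b, a)] = ARROW
                        pag[(b, c)] = ARROW
                        pag[(c, b)] = ARROW
                    changed = True
                    done = True
                    break
                if done:
                    break
    return pag


def _disc_origin(pag, adjacent, nbrs, a, b, c):
    seen = {a, b, c}
    stack = [a]
    while stack:
        v = stack.pop()
        for p in nbrs(v):
            if p in seen or pag[(p, v)] != ARROW:
                continue
            if not adjacent(p, c):
                return p
            p_par = pag[(p, c)] == ARROW and pag[(c, p)] == TAIL
            if p_par and pag[(v, p)] == ARROW:
                seen.add(p)
                stack.append(p)
    return None
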