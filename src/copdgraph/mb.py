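"""Markov-blanket extraction from PAGs and cross-fold stability counts.

On a DAG the Markov blanket of a target is its parents, children and
co-parents of children.  On a PAG ancestry is only partially decided, so
the extraction here is deliberately permissive: any neighbour of the
target is included, and a node counts as a *possible child* when the mark
at its end of the target edge is an arrowhead or a circle; co-parents
(possible spouses) are nodes with an edge into a possible child.  This
favours recall, matching the blanket's use as a feature-selection superset
for the outcome.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .pag import ARROW, CIRCLE, PAG


@dataclasses.dataclass
class MarkovBlanket:
    """The outcome's informative-variable set with its induced PAG edges."""

    target: str
    members: list
    edges: list  # (a, mark_at_a, mark_at_b, b) among members + target

    def __contains__(self, var: str) -> bool:
        return var in self.members

    def __len__(self) -> int:
        return len(self.members)


def extract_mb(pag: PAG, target: str) -> MarkovBlanket:
    """Adjacent nodes plus possible spouses of the target."""
    if target not in pag.nodes:
        raise KeyError(f"target {target!r} not in PAG")
    members = set(pag.neighbors(target))
    possible_children = {
        c for c in pag.neighbors(target) if pag.mark(target, c) in (ARROW, CIRCLE)
    }
    for c in possible_children:
        for x in pag.neighbors(c):
            if x != target and pag.mark(x, c) in (ARROW, CIRCLE):
                members.add(x)
    members.discard(target)
    keep = members | {target}
    edges = [
        (a, ma, mb, b) for a, ma, mb, b in pag.edges() if a in keep and b in keep
    ]
    return MarkovBlanket(target, sorted(members), edges)


@dataclasses.dataclass
class StabilityTable:
    """Cross-validation appearance counts per (variable, alpha)."""

    counts: dict  # (variable, alpha) -> number of folds
    n_folds: int
    alphas: list

    def to_frame(self) -> pd.DataFrame:
        """Variables x alphas count table, ordered by total count descending."""
        variables = sorted({v for v, _ in self.counts})
        frame = pd.DataFrame(0, index=variables, columns=list(self.alphas))
        for (v, a), c in self.counts.items():
            frame.loc[v, a] = c
        order = frame.sum(axis=1).sort_values(ascending=False, kind="stable").index
        return frame.loc[order]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_folds": self.n_folds,
            "alphas": [float(a) for a in self.alphas],
            "counts": [
                {"variable": v, "alpha": float(a), "folds": int(c)}
                for (v, a), c in sorted(self.counts.items())
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def stability_table(fold_mbs: dict, n_folds: int, alphas) -> StabilityTable:
    """Count how often each variable enters the blanket per sparsity level.

    ``fold_mbs`` maps (fold, alpha) to a :class:`MarkovBlanket`; variables
    never selected anywhere are absent from the table.
    """
    counts: dict = {}
    for (fold, alpha), mb in fold_mbs.items():
        for v in mb.members:
            counts[(v, alpha)] = counts.get((v, alpha), 0) + 1
    bad = [c for c in counts.values() if c > n_folds]
    if bad:
        raise ValueError("appearance count exceeds the number of folds")
    return StabilityTable(counts, n_folds, sorted(set(a for _, a in fold_mbs)))
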