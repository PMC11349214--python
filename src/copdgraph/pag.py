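"""Partial ancestral graphs (PAGs).

A PAG summarizes the equivalence class of causal structures (allowing
latent confounders) compatible with a set of conditional-independence
facts.  Each edge carries a mark at either endpoint: a tail (``-``), an
arrowhead (``>``) or a circle (``o``, undecided).  The resulting edge kinds
are ``-->``, ``<->``, ``o->``, ``o-o`` and ``---``; an arrowhead pointing
at a variable means that variable is *not* an ancestor of the other, so a
``<->`` edge indicates latent confounding and ``o`` marks leave ancestry
open (a direct causal link and/or an unmeasured common cause).
"""

from __future__ import annotations

from pathlib import Path

TAIL = "-"
ARROW = ">"
CIRCLE = "o"
MARKS = (TAIL, ARROW, CIRCLE)


class PAG:
    """Mixed graph with three endpoint-mark kinds.

    Marks are stored per ordered pair: ``mark(a, b)`` is the mark at ``b``'s
    end of the ``a - b`` edge.
    """

    def __init__(self, nodes):
        self.nodes = list(nodes)
        self._marks: dict = {}
        self.sepsets: dict = {}

    # -- structure ----------------------------------------------------------

    def add_edge(self, a, b, mark_a=CIRCLE, mark_b=CIRCLE):
        if a == b:
            raise ValueError("self-edges are not allowed")
        self._marks[(a, b)] = mark_b
        self._marks[(b, a)] = mark_a

    def remove_edge(self, a, b):
        self._marks.pop((a, b), None)
        self._marks.pop((b, a), None)

    def has_edge(self, a, b) -> bool:
        return (a, b) in self._marks

    def mark(self, a, b):
        """Mark at ``b``'s end of the a-b edge."""
        return self._marks[(a, b)]

    def set_mark(self, a, b, mark):
        if mark not in MARKS:
            raise ValueError(f"unknown mark {mark!r}")
        if (a, b) not in self._marks:
            raise ValueError(f"no edge {a!r} - {b!r}")
        self._marks[(a, b)] = mark

    def neighbors(self, v) -> list:
        return sorted(b for (a, b) in self._marks if a == v)

    def edges(self) -> list:
        """Sorted list of (a, mark_at_a, mark_at_b, b) with a < b."""
        out = []
        for (a, b) in self._marks:
            if a < b:
                out.append((a, self._marks[(b, a)], self._marks[(a, b)], b))
        return sorted(out)

    @property
    def n_edges(self) -> int:
        return len(self._marks) // 2

    def copy(self) -> "PAG":
        out = PAG(self.nodes)
        out._marks = dict(self._marks)
        out.sepsets = dict(self.sepsets)
        return out

    # -- queries used by orientation rules ----------------------------------

    def is_arrow_into(self, a, b) -> bool:
        """True if the a-b edge has an arrowhead at b (a *-> b)."""
        return self.has_edge(a, b) and self.mark(a, b) == ARROW

    def is_directed(self, a, b) -> bool:
        """True for a --> b (tail at a, arrow at b)."""
        return (
            self.has_edge(a, b)
            and self.mark(a, b) == ARROW
            and self.mark(b, a) == TAIL
        )

    def unshielded_triples(self):
        """Yield (x, z, y) with x-z and z-y adjacent, x-y not, x < y."""
        for z in self.nodes:
            nbrs = self.neighbors(z)
            for i, x in enumerate(nbrs):
                for y in nbrs[i + 1 :]:
                    if not self.has_edge(x, y):
                        yield (x, z, y)

    # -- comparison and IO --------------------------------------------------

    def same_adjacencies(self, other: "PAG") -> bool:
        return set(self._marks) == set(other._marks)

    def same_marks(self, other: "PAG") -> bool:
        return self._marks == other._marks

    def __eq__(self, other):
        return isinstance(other, PAG) and self._marks == other._marks \
            and set(self.nodes) == set(other.nodes)

    def write_tsv(self, path: str | Path) -> None:
        """``varA<TAB>markA<TAB>markB<TAB>varB`` per edge (sorted)."""
        with open(path, "w") as fh:
            for a, ma, mb, b in self.edges():
                fh.write(f"{a}\t{ma}\t{mb}\t{b}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, nodes=None) -> "PAG":
        edges = []
        seen = set()
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                a, ma, mb, b = line.rstrip("\n").split("\t")
                edges.append((a, ma, mb, b))
                seen.update((a, b))
        out = cls(sorted(seen) if nodes is None else list(nodes))
        for a, ma, mb, b in edges:
            out.add_edge(a, b, mark_a=ma, mark_b=mb)
        return out
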