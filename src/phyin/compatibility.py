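"""Pairwise phylogenetic compatibility of alignment columns.

Two characters are *compatible* when some tree exists on which both can
evolve without homoplasy (no convergence or reversal; no changes beyond the
number of observed states minus one).  For unordered multistate characters
this is decided without any tree search: form the bipartite *state-pair
graph* whose left vertices are the states of one column, right vertices the
states of the other, and edges the state combinations actually observed
among the taxa.  The pair is incompatible exactly when that graph contains
a cycle.

The module also ships :func:`brute_force_compatible`, a literal tree
enumeration oracle (all unrooted binary topologies, Fitch parsimony) used
by the test suite to verify the graph test; it is deliberately independent
of it.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np

from .alignment import (
    Alignment,
    INTERNAL_GAP,
    MISSING as MISSING_CLASS,
    OBSERVED,
    TERMINAL_GAP,
)

__all__ = [
    "ColumnStates",
    "StatePairGraph",
    "encode_column",
    "build_state_pair_graph",
    "are_incompatible",
    "brute_force_compatible",
    "A",
    "C",
    "G",
    "T",
    "GAP",
    "MISSING",
]

# state codes
A, C, G, T, GAP, MISSING = 0, 1, 2, 3, 4, 5
_BASE_CODE = {"A": A, "C": C, "G": G, "T": T}
STATE_NAMES = ("A", "C", "G", "T", "GAP", "MISSING")


@dataclass(frozen=True)
class ColumnStates:
    """Encoded states of one alignment column under a chosen gap mode.

    Terminal gaps are always MISSING (they record failure to sequence, not
    indel events).  Internal gaps are GAP when ``fifth_state`` encoding was
    requested, MISSING otherwise.  ``?`` and ambiguity letters are MISSING.
    """

    site_index: int
    states: np.ndarray  # int8 codes, one per taxon
    fifth_state: bool

    def __post_init__(self):
        object.__setattr__(self, "states", np.asarray(self.states, dtype=np.int8))

    @property
    def n_taxa(self) -> int:
        return int(self.states.size)


def encode_column(
    alignment: Alignment, gaps: np.ndarray, site: int, fifth_state: bool
) -> ColumnStates:
    """Encode one column given its per-cell gap classification."""
    if not 0 <= site < alignment.n_sites:
        raise IndexError(f"site {site} out of range for {alignment.n_sites} sites")
    col = alignment.matrix[:, site]
    cls = gaps[:, site]
    out = np.empty(alignment.n_taxa, dtype=np.int8)
    for i in range(alignment.n_taxa):
        c = cls[i]
        if c == OBSERVED:
            out[i] = _BASE_CODE[col[i]]
        elif c == INTERNAL_GAP:
            out[i] = GAP if fifth_state else MISSING
        else:  # TERMINAL_GAP or MISSING
            out[i] = MISSING
    return ColumnStates(site, out, fifth_state)


@dataclass(frozen=True)
class StatePairGraph:
    """Bipartite graph of observed state combinations between two columns."""

    left_vertices: frozenset
    right_vertices: frozenset
    edges: frozenset  # of (left_state, right_state) pairs

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_cycle(self) -> bool:
        """True iff some connected component has as many edges as vertices.

        Union-find over the (side-tagged) vertices: an edge whose endpoints
        are already connected closes a cycle.
        """
        parent = {}

        def find(x):
            root = x
            while parent[root] != root:
                root = parent[root]
            while parent[x] != root:  # path compression
                parent[x], x = root, parent[x]
            return root

        for s in self.left_vertices:
            parent[("L", s)] = ("L", s)
        for s in self.right_vertices:
            parent[("R", s)] = ("R", s)
        for u, v in self.edges:
            ru, rv = find(("L", u)), find(("R", v))
            if ru == rv:
                return True
            parent[ru] = rv
        return False


def build_state_pair_graph(ci: ColumnStates, cj: ColumnStates) -> StatePairGraph:
    """Collect the distinct state pairs over taxa non-missing in both columns."""
    if ci.n_taxa != cj.n_taxa:
        raise ValueError(
            f"columns have {ci.n_taxa} and {cj.n_taxa} taxa; must match"
        )
    both = (ci.states != MISSING) & (cj.states != MISSING)
    edges = frozenset(zip(ci.states[both].tolist(), cj.states[both].tolist()))
    return StatePairGraph(
        left_vertices=frozenset(e[0] for e in edges),
        right_vertices=frozenset(e[1] for e in edges),
        edges=edges,
    )


def are_incompatible(ci: ColumnStates, cj: ColumnStates) -> bool:
    """Graph cycle test: True iff no tree fits both columns homoplasy-free."""
    return build_state_pair_graph(ci, cj).has_cycle()


# ---------------------------------------------------------------------------
# brute-force oracle: enumerate all unrooted binary topologies, score with
# Fitch (unordered) parsimony, demand zero homoplasy for both characters


@lru_cache(maxsize=None)
def _unrooted_topologies(n: int) -> tuple:
    """All unrooted binary trees on leaves 0..n-1 (n >= 2).

    Each tree is represented rooted along the edge to leaf 0, i.e. as the
    nested-tuple rooted tree on leaves 1..n-1; the full tree is
    ``(0, subtree)``.  Counts follow (2n-5)!!: 3 trees for n=4, 15 for 5,
    105 for 6.
    """

    def rooted(leaves):
        if len(leaves) == 1:
            yield leaves[0]
            return
        head, rest = leaves[0], leaves[1:]
        for t in rooted(rest):
            yield from _insert(t, head)

    def _insert(t, x):
        yield (x, t)
        if isinstance(t, tuple):
            a, b = t
            for a2 in _insert(a, x):
                yield (a2, b)
            for b2 in _insert(b, x):
                yield (a, b2)

    return tuple((0, t) for t in rooted(tuple(range(1, n))))


def _fitch_changes(tree, states) -> int:
    """Minimum unordered-parsimony changes of one character on a binary tree."""

    def walk(node):
        if not isinstance(node, tuple):
            return frozenset([states[node]]), 0
        (sa, ca) = walk(node[0])
        (sb, cb) = walk(node[1])
        inter = sa & sb
        if inter:
            return inter, ca + cb
        return sa | sb, ca + cb + 1

    return walk(tree)[1]


def brute_force_compatible(ci: ColumnStates, cj: ColumnStates) -> bool:
    """Tree-enumeration oracle for pairwise compatibility.

    Restricted to the taxa non-missing in both columns, returns True iff
    some unrooted binary tree gives BOTH characters a parsimony length equal
    to their number of distinct observed states minus one (both
    homoplasy-free).  Enumeration is limited to 8 such taxa (10395 trees).
    """
    if ci.n_taxa != cj.n_taxa:
        raise ValueError("columns must have the same number of taxa")
    both = (ci.states != MISSING) & (cj.states != MISSING)
    a = ci.states[both].tolist()
    b = cj.states[both].tolist()
    n = len(a)
    if n > 8:
        raise ValueError(f"{n} doubly-observed taxa exceeds the enumeration bound of 8")
    ka, kb = len(set(a)), len(set(b))
    if n < 4 or ka < 2 or kb < 2:
        # too few taxa or a constant character: any tree works
        return True
    for tree in _unrooted_topologies(n):
        if _fitch_changes(tree, a) == ka - 1 and _fitch_changes(tree, b) == kb - 1:
            return True
    return False
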