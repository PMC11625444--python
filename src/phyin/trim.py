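"""Neighbour-conflict flagging and block-based deletion (the PhyIN criterion).

The procedure:

1. every column is compared with its neighbours up to ``d`` columns away;
   columns participating in at least one pairwise incompatibility are
   *conflicted* (both members of an incompatible pair are flagged);
2. every window of ``b`` consecutive sites is scanned; when the proportion
   of conflicted sites in a window is at least ``p``, the sites from the
   window's first conflicted to its last conflicted column are marked;
3. marked columns are deleted.

The whole pipeline is deterministic: the mask is a pure function of the
alignment and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, SiteMask, classify_gaps
from .compatibility import ColumnStates, MISSING, are_incompatible, encode_column

__all__ = [
    "PhyINParams",
    "TrimSummary",
    "conflicted_pairs",
    "find_conflicted",
    "select_blocks",
    "phyin_mask",
    "trim_report",
]


@dataclass(frozen=True)
class PhyINParams:
    """Tuning parameters of the neighbour-conflict trimmer.

    d : int, default 2
        Maximum distance (in columns) at which neighbour conflict is
        checked; conflict is always assessed pairwise.  Larger ``d`` trims
        more aggressively.
    e : bool, default True
        Treat internal gaps as a fifth character state.  Terminal gaps are
        never a state (they indicate missing sequence, not indels).
    b : int, default 10
        Window (block) size over which the proportion of conflicted sites
        is evaluated.
    p : float, default 0.5
        Threshold proportion: a window whose conflicted fraction is as
        great or greater than ``p`` triggers deletion.
    """

    d: int = 2
    e: bool = True
    b: int = 10
    p: float = 0.5

    def __post_init__(self):
        if self.d < 1:
            raise ValueError(f"d must be >= 1, got {self.d}")
        if self.b < 1:
            raise ValueError(f"b must be >= 1, got {self.b}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")


def _encode_all(alignment: Alignment, gaps: np.ndarray, fifth_state: bool) -> list:
    return [
        encode_column(alignment, gaps, k, fifth_state) for k in range(alignment.n_sites)
    ]


def _is_testable(col: ColumnStates) -> bool:
    # a column with <2 distinct non-missing states cannot join any cycle
    obs = col.states[col.states != MISSING]
    return obs.size >= 2 and np.unique(obs).size >= 2


def conflicted_pairs(
    alignment: Alignment, gaps: np.ndarray, d: int, e: bool
) -> list:
    """All 0-based column pairs ``(i, j)`` with ``1 <= j - i <= d`` that are
    phylogenetically incompatible."""
    cols = _encode_all(alignment, gaps, e)
    testable = [_is_testable(c) for c in cols]
    pairs = []
    n = alignment.n_sites
    for i in range(n):
        if not testable[i]:
            continue
        for j in range(i + 1, min(i + d, n - 1) + 1):
            if testable[j] and are_incompatible(cols[i], cols[j]):
                pairs.append((i, j))
    return pairs


def find_conflicted(
    alignment: Alignment, gaps: np.ndarray, d: int, e: bool
) -> np.ndarray:
    """Boolean per-site flags: site participates in >=1 incompatible pair
    within distance ``d``.  Both members of an incompatible pair are flagged."""
    flags = np.zeros(alignment.n_sites, dtype=bool)
    for i, j in conflicted_pairs(alignment, gaps, d, e):
        flags[i] = True
        flags[j] = True
    return flags


def select_blocks(flags: np.ndarray, b: int, p: float) -> SiteMask:
    """Scan windows of ``b`` consecutive sites and mark deletion spans.

    Windows slide one site at a time over every start position (a single
    window of the full length when the alignment is shorter than ``b``).
    A window triggers when its conflicted proportion is ``>= p``; it then
    marks the sites from its first to its last conflicted column,
    inclusive.  The final mask is the union over all triggering windows.
    """
    flags = np.asarray(flags, dtype=bool)
    if b < 1:
        raise ValueError(f"b must be >= 1, got {b}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    n = flags.size
    marked = np.zeros(n, dtype=bool)
    if n == 0:
        return SiteMask.from_flags(marked, "phyin")
    width = min(b, n)
    flagged_idx = np.flatnonzero(flags)
    counts = np.convolve(flags.astype(int), np.ones(width, dtype=int), mode="valid")
    # tolerance keeps the >= comparison exact for decimal p (e.g. 11/20 >= 0.55)
    threshold = p * width - 1e-9
    for start, count in enumerate(counts):
        if count == 0 or count < threshold:
            continue
        in_window = flagged_idx[(flagged_idx >= start) & (flagged_idx < start + width)]
        marked[in_window[0] : in_window[-1] + 1] = True
    return SiteMask.from_flags(marked, "phyin")


def phyin_mask(alignment: Alignment, params: PhyINParams = PhyINParams()) -> SiteMask:
    """Run the full conflict-flagging + block-scan procedure on an alignment."""
    gaps = classify_gaps(alignment)
    flags = find_conflicted(alignment, gaps, params.d, params.e)
    return select_blocks(flags, params.b, params.p)


@dataclass(frozen=True)
class TrimSummary:
    """Counts of sites deleted, broken down by provenance."""

    n_sites: int
    n_deleted: int
    n_phyin: int
    n_occupancy: int
    n_both: int

    @property
    def proportion_trimmed(self) -> float:
        return self.n_deleted / self.n_sites if self.n_sites else 0.0


def trim_report(alignment: Alignment, mask: SiteMask) -> TrimSummary:
    """Summarize a deletion mask against its alignment."""
    if mask.n_sites != alignment.n_sites:
        raise ValueError("mask length does not match alignment")
    n_phyin = sum(1 for r in mask.reasons if r == frozenset({"phyin"}))
    n_occ = sum(1 for r in mask.reasons if r == frozenset({"occupancy"}))
    n_both = sum(1 for r in mask.reasons if r == frozenset({"phyin", "occupancy"}))
    return TrimSummary(
        n_sites=alignment.n_sites,
        n_deleted=mask.n_deleted,
        n_phyin=n_phyin,
        n_occupancy=n_occ,
        n_both=n_both,
    )
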