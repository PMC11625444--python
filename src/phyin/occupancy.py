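"""Site-occupancy companion filter.

The neighbour-conflict criterion deliberately ignores gappiness: a column
that is mostly gaps offers few observed nucleotides and hence little
opportunity for conflict, so it sails through untouched.  Low-occupancy
columns are instead removed by this simple filter, which deletes any site
whose gap fraction (counting internal gaps, terminal gaps and ``?``)
exceeds a threshold — strictly "more than", so a column with exactly 50%
gaps survives the default setting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment, GAP_SYMBOL, SiteMask

__all__ = ["OccupancyParams", "site_gap_fraction", "occupancy_mask", "combine_masks"]


@dataclass(frozen=True)
class OccupancyParams:
    """``max_gap_fraction``: delete a site iff its gap fraction exceeds this
    (default 0.5, i.e. more than 50% gaps).  Set 0.18 for an 82% occupancy
    requirement."""

    max_gap_fraction: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.max_gap_fraction <= 1.0:
            raise ValueError(
                f"max_gap_fraction must be in [0, 1], got {self.max_gap_fraction}"
            )


def _gap_counts(alignment: Alignment) -> np.ndarray:
    mat = alignment.matrix
    return ((mat == GAP_SYMBOL) | (mat == "?")).sum(axis=0)


def site_gap_fraction(alignment: Alignment, site: int) -> float:
    """Fraction of taxa with ``-`` or ``?`` at a column (ambiguity letters
    count as occupied)."""
    if not 0 <= site < alignment.n_sites:
        raise IndexError(f"site {site} out of range")
    col = alignment.matrix[:, site]
    return float(((col == GAP_SYMBOL) | (col == "?")).sum()) / alignment.n_taxa


def occupancy_mask(
    alignment: Alignment, params: OccupancyParams = OccupancyParams()
) -> SiteMask:
    """Flag every site whose gap fraction strictly exceeds the threshold."""
    fractions = _gap_counts(alignment) / alignment.n_taxa
    # strict inequality with rounding guard: n/n_taxa == threshold must be kept
    flags = fractions > params.max_gap_fraction + 1e-9
    return SiteMask.from_flags(flags, "occupancy")


def combine_masks(a: SiteMask, b: SiteMask) -> SiteMask:
    """Site-wise union of two deletion masks; reasons are merged."""
    return a.union(b)
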