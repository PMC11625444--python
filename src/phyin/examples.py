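"""Small built-in example alignments.

The demo alignment here is a synthetic 8-taxon, 10-site matrix constructed
so that exactly three neighbour pairs of columns are phylogenetically
incompatible within distance 2 — columns (1,2), (2,3) and (7,9) in 1-based
coordinates — while column 1 also conflicts with columns 7 and 9 at
distances beyond 2.  Five columns are therefore conflicted, and under the
default trimming parameters (d=2, e=True, b=10, p=0.5) the block scan
deletes columns 1 through 9, keeping only column 10.  It is the standard
walk-through input used by the README and the test suite.
"""

from __future__ import annotations

from .alignment import Alignment

__all__ = ["demo_alignment"]

_DEMO_ROWS = (
    ("t1", "TACGGGACGA"),
    ("t2", "TACGGGACGA"),
    ("t3", "TTCGGGACTA"),
    ("t4", "TTCGGGACTA"),
    ("t5", "AAGGGGTCGA"),
    ("t6", "AAGGGGTCGA"),
    ("t7", "ATGGGGTCTA"),
    ("t8", "ATCGGGTCTA"),
)


def demo_alignment() -> Alignment:
    """The 8-taxon, 10-site synthetic demo alignment described above."""
    return Alignment.from_sequences(_DEMO_ROWS)
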