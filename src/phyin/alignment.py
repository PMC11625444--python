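"""Nucleotide alignment container, gap classification, and site masking.

The trimming machinery in this package operates on columns of a multiple
sequence alignment.  This module provides the in-memory :class:`Alignment`
(taxa x sites character matrix), per-cell gap classification (internal vs
terminal gaps, which the compatibility test treats very differently), the
:class:`SiteMask` that records which columns are to be deleted and why, and
FASTA / report I/O.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "SiteMask",
    "AlignmentShapeError",
    "OBSERVED",
    "INTERNAL_GAP",
    "TERMINAL_GAP",
    "MISSING",
    "read_fasta",
    "write_fasta",
    "classify_gaps",
    "apply_mask",
    "write_mask_report",
]

GAP_SYMBOL = "-"
#: symbols carrying no usable state: unknown and IUPAC ambiguity letters
MISSING_SYMBOLS = frozenset("?NRYSWKMBDHV")
NUCLEOTIDES = frozenset("ACGT")
VALID_SYMBOLS = NUCLEOTIDES | MISSING_SYMBOLS | {GAP_SYMBOL}

# per-cell gap classes
OBSERVED = 0
INTERNAL_GAP = 1
TERMINAL_GAP = 2
MISSING = 3


class AlignmentShapeError(ValueError):
    """Rows of unequal length, duplicate labels, or other matrix-shape faults."""


@dataclass(frozen=True)
class Alignment:
    """A rectangular nucleotide alignment.

    Parameters
    ----------
    taxa : tuple of str
        Ordered, unique taxon labels.
    matrix : numpy.ndarray
        ``(n_taxa, n_sites)`` array of single upper-case characters drawn
        from ``{A, C, G, T, -, ?}`` plus IUPAC ambiguity letters.
    """

    taxa: tuple
    matrix: np.ndarray

    def __post_init__(self):
        mat = np.asarray(self.matrix, dtype="<U1")
        if mat.ndim != 2:
            raise AlignmentShapeError("alignment matrix must be 2-dimensional")
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "taxa", tuple(self.taxa))
        if len(self.taxa) != mat.shape[0]:
            raise AlignmentShapeError(
                f"{len(self.taxa)} labels but {mat.shape[0]} matrix rows"
            )
        if len(set(self.taxa)) != len(self.taxa):
            seen, dupes = set(), []
            for t in self.taxa:
                if t in seen:
                    dupes.append(t)
                seen.add(t)
            raise AlignmentShapeError(f"duplicate taxon labels: {sorted(set(dupes))}")
        if any(not t for t in self.taxa):
            raise AlignmentShapeError("empty taxon label")
        bad = set(np.unique(mat)) - VALID_SYMBOLS
        if bad:
            raise AlignmentShapeError(f"unrecognized symbols in alignment: {sorted(bad)}")

    @classmethod
    def from_sequences(cls, records: Iterable) -> "Alignment":
        """Build from ``(label, sequence)`` pairs, normalizing case and U->T."""
        labels, rows = [], []
        for label, seq in records:
            labels.append(str(label))
            rows.append(_normalize(str(seq), label))
        if not labels:
            raise AlignmentShapeError("no sequences provided")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            ref = len(rows[0])
            for label, r in zip(labels, rows):
                if len(r) != ref:
                    raise AlignmentShapeError(
                        f"sequence for {label!r} has length {len(r)}, "
                        f"expected {ref} (all rows must align)"
                    )
        matrix = np.array([list(r) for r in rows], dtype="<U1")
        return cls(tuple(labels), matrix)

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> str:
        return "".join(self.matrix[self.taxa.index(taxon)])

    def column(self, site: int) -> np.ndarray:
        """Characters of one 0-based column, in taxon order."""
        return self.matrix[:, site]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.taxa == other.taxa
            and self.matrix.shape == other.matrix.shape
            and bool((self.matrix == other.matrix).all())
        )


def _normalize(seq: str, label: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - VALID_SYMBOLS
    if bad:
        raise AlignmentShapeError(
            f"sequence for {label!r} contains unrecognized symbols: {sorted(bad)}"
        )
    return s


def read_fasta(path) -> Alignment:
    """Read a FASTA alignment; symbols are upper-cased and U is mapped to T.

    Raises
    ------
    AlignmentShapeError
        On unequal row lengths (naming the offending taxon), duplicate
        labels, an empty file, or symbols outside the nucleotide alphabet.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentShapeError(f"no FASTA records found in {path}")
    return Alignment.from_sequences((r.id, str(r.seq)) for r in records)


def write_fasta(alignment: Alignment, path) -> None:
    """Write the alignment as multi-record FASTA (round-trips losslessly)."""
    records = [
        SeqRecord(Seq("".join(row)), id=label, description="")
        for label, row in zip(alignment.taxa, alignment.matrix)
    ]
    SeqIO.write(records, str(path), "fasta")


def classify_gaps(alignment: Alignment) -> np.ndarray:
    """Classify every cell as observed / internal gap / terminal gap / missing.

    A ``-`` is *terminal* iff its contiguous run of ``-`` reaches either
    sequence end; otherwise it is *internal* (it implies an insertion or
    deletion event and may be treated as a fifth character state).  ``?``
    and IUPAC ambiguity letters are *missing*.  Classification is row-local:
    it never depends on other sequences.

    Returns an int8 array of the same shape as ``alignment.matrix``.
    """
    mat = alignment.matrix
    out = np.full(mat.shape, OBSERVED, dtype=np.int8)
    is_gap = mat == GAP_SYMBOL
    out[np.isin(mat, sorted(MISSING_SYMBOLS))] = MISSING
    out[is_gap] = INTERNAL_GAP
    n_sites = alignment.n_sites
    for i in range(alignment.n_taxa):
        row_gap = is_gap[i]
        # leading run of '-'
        k = 0
        while k < n_sites and row_gap[k]:
            out[i, k] = TERMINAL_GAP
            k += 1
        # trailing run of '-'
        k = n_sites - 1
        while k >= 0 and row_gap[k]:
            out[i, k] = TERMINAL_GAP
            k -= 1
    return out


@dataclass(frozen=True)
class SiteMask:
    """Per-site deletion flags with provenance.

    ``flags[k]`` is True where column ``k`` is to be deleted; ``reasons[k]``
    is a frozenset drawn from ``{"phyin", "occupancy"}``, non-empty exactly
    where the flag is set.
    """

    flags: np.ndarray
    reasons: tuple

    def __post_init__(self):
        flags = np.asarray(self.flags, dtype=bool)
        object.__setattr__(self, "flags", flags)
        reasons = tuple(frozenset(r) for r in self.reasons)
        object.__setattr__(self, "reasons", reasons)
        if len(reasons) != flags.size:
            raise ValueError("reasons length must equal flags length")
        for f, r in zip(flags, reasons):
            if f != bool(r):
                raise ValueError("reason must be non-empty exactly where flag is set")

    @classmethod
    def from_flags(cls, flags, reason: str) -> "SiteMask":
        flags = np.asarray(flags, dtype=bool)
        return cls(flags, tuple(frozenset([reason]) if f else frozenset() for f in flags))

    @classmethod
    def empty(cls, n_sites: int) -> "SiteMask":
        return cls(np.zeros(n_sites, dtype=bool), tuple(frozenset() for _ in range(n_sites)))

    @property
    def n_sites(self) -> int:
        return int(self.flags.size)

    @property
    def n_deleted(self) -> int:
        return int(self.flags.sum())

    def union(self, other: "SiteMask") -> "SiteMask":
        if self.n_sites != other.n_sites:
            raise ValueError(
                f"cannot combine masks of lengths {self.n_sites} and {other.n_sites}"
            )
        return SiteMask(
            self.flags | other.flags,
            tuple(a | b for a, b in zip(self.reasons, other.reasons)),
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SiteMask)
            and self.n_sites == other.n_sites
            and bool((self.flags == other.flags).all())
            and self.reasons == other.reasons
        )


def apply_mask(alignment: Alignment, mask: SiteMask) -> Alignment:
    """Delete the flagged columns; taxa and relative column order unchanged."""
    if mask.n_sites != alignment.n_sites:
        raise ValueError(
            f"mask length {mask.n_sites} != alignment n_sites {alignment.n_sites}"
        )
    return Alignment(alignment.taxa, alignment.matrix[:, ~mask.flags])


def _reason_label(reason: frozenset) -> str:
    if not reason:
        return "-"
    if reason == frozenset({"phyin", "occupancy"}):
        return "both"
    return next(iter(reason))


def write_mask_report(mask: SiteMask, path) -> None:
    """Write a TSV with 1-based site, action (keep|delete) and reason.

    The reason column is ``phyin``, ``occupancy`` or ``both`` for deleted
    sites and ``-`` for kept ones.
    """
    with open(str(path), "w") as fh:
        fh.write("site\taction\treason\n")
        for k, (flag, reason) in enumerate(zip(mask.flags, mask.reasons), start=1):
            action = "delete" if flag else "keep"
            fh.write(f"{k}\t{action}\t{_reason_label(reason)}\n")
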