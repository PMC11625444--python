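# phyin

Trim noisy regions of nucleotide multiple sequence alignments by
**phylogenetic incompatibility among neighbouring sites**.

Phylogenomic loci — ultraconserved elements in particular — tend to carry a
well-aligned conserved core flanked by ragged, effectively random regions
produced by rapid evolution, fragmentation, or assembly error. Most
trimmers judge each column by its own base frequencies, but phylogenetic
noise is only visible as *discord between* columns: a 50:50 split column
may be a perfect synapomorphy. `phyin` therefore flags columns that are
pairwise **phylogenetically incompatible** with their near neighbours and
deletes stretches where such conflicted columns are dense. No guide tree is
needed, and because the criterion is purely local, loci can be trimmed one
at a time — preserving genuine gene-tree/species-tree discord instead of
trimming it away as noise.

## The criterion

Two columns are *compatible* when some tree exists on which both can evolve
without homoplasy (no convergence or reversal, i.e. no more changes than
`number of observed states − 1`). For unordered multistate characters this
is decided without a tree search: build the bipartite **state-pair graph**
whose vertices are the observed states of the two columns and whose edges
are the state combinations actually seen among the taxa. The pair is
incompatible **iff that graph has a cycle** (for two binary characters this
reduces to the classical four-gamete test: all four combinations present).

The trimming procedure, with parameters `d`, `e`, `b`, `p`:

1. Compare every column with its neighbours up to `d` columns away
   (default 2); flag both members of every incompatible pair as
   *conflicted*.
2. Slide a window of `b` sites (default 10) along the alignment. A window
   whose conflicted proportion is ≥ `p` (default 0.5) marks the sites from
   its first to its last conflicted column for deletion.
3. Delete the union of the marked spans.

Gaps: internal gaps (`-` flanked by observed nucleotides on both sides)
imply indel events and are treated as a fifth character state when
`e=true` (the default); terminal gaps (runs of `-` reaching a sequence
end) mean "failed to sequence" and are always treated as missing data,
like `?` and IUPAC ambiguity letters.

Because mostly-gap columns offer little opportunity for conflict, the
package also ships the standard companion **site-occupancy filter**: delete
any column with *more than* a threshold fraction of gaps (default 0.5;
a column with exactly 50% gaps survives).

## Worked example

The package ships an 8-taxon, 10-site demo alignment
(`phyin.demo_alignment()`) in which columns 1–2, 2–3 and 7–9 are
incompatible neighbour pairs:

```text
t1  TACGGGACGA
t2  TACGGGACGA
t3  TTCGGGACTA
t4  TTCGGGACTA
t5  AAGGGGTCGA
t6  AAGGGGTCGA
t7  ATGGGGTCTA
t8  ATCGGGTCTA
```

Columns 1 and 2 are effectively binary, and all four state combinations
(TA, TT, AT, AA) occur — the four-gamete cycle — so they cannot agree on
any tree. Column 1 also conflicts with 7 and 9, but those are more than
`d=2` columns away, so the counted conflicts are 1 vs 2, 2 vs 3 and
7 vs 9, making columns {1, 2, 3, 7, 9} conflicted: 5 of the 10 in the
block. That reaches the threshold `p=0.5`, and the span from the first to
the last conflicted column (1 through 9) is deleted:

```text
$ phyin demo.fasta --occupancy off --mask-out mask.tsv
8 taxa, 10 sites; conflict-flagged for deletion: 9; low occupancy: 0; total deleted: 9 (90.0%); kept: 1
>t1
A
>t2
A
...
```

Only column 10 survives. The same computation from Python:

```python
import numpy as np
import phyin

aln = phyin.demo_alignment()
gaps = phyin.classify_gaps(aln)
print(phyin.conflicted_pairs(aln, gaps, d=2, e=True))   # [(0, 1), (1, 2), (6, 8)]
mask = phyin.phyin_mask(aln, phyin.PhyINParams())        # d=2, e=True, b=10, p=0.5
print(mask.n_deleted)                                    # 9
trimmed = phyin.apply_mask(aln, mask)                    # 1 remaining column
```

(0-based indices in the library; reports and the CLI are 1-based.)

## Command line

```text
phyin <input.fasta> [-o out.fasta] [-d INT] [-e true|false] [-b INT]
      [-p FLOAT] [--occupancy FLOAT|off] [--mask-out FILE]
      [--mask-only] [--report FILE]
```

One locus per invocation (the internal/terminal gap distinction — and any
gene-tree discord — is only meaningful per locus); loop in the shell for
batches. Logs go to standard error, trimmed FASTA to `-o` or standard out,
and `--mask-out` writes a TSV of 1-based sites with keep/delete and the
reason (`phyin`, `occupancy`, or `both`).

## Synthetic fixtures

`phyin.synth` generates seeded alignments with a labelled tree-compatible
("clean") core and i.i.d.-random ("noise") flanks plus terminal-gap
erosion and sprinkled internal gaps, so boundary detection can be scored
against ground truth:

```python
from phyin.synth import SynthConfig, make_fixture
aln, labels = make_fixture(SynthConfig(seed=1))   # 16 taxa, 200+200 sites
```

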