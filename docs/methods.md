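# Methods

## The compatibility test

For two columns of a nucleotide alignment, restricted to the taxa with a
usable state in *both* (anything else is ignored), form the bipartite
*state-pair graph*: left vertices are the distinct states of the first
column, right vertices those of the second, and there is one edge per
distinct observed state combination (parallel edges collapse; at most
5 × 5 vertices — four nucleotides plus the internal-gap state). The two
columns can evolve homoplasy-free on a common tree **iff this graph is a
forest**; a cycle certifies that every tree forces an extra change in at
least one of the two characters. For two binary columns this is exactly
the four-gamete test. Cycle detection is a union–find pass over the edges
(an edge joining two already-connected vertices closes a cycle) — O(taxa)
per pair after edge collection, no graph library needed at this size.

Degenerate pairs — zero doubly-observed taxa, or a column constant among
them — are declared compatible: no cycle can exist, and mostly-gap regions
genuinely offer little opportunity for conflict. Consequently a column
with fewer than two distinct observed states is compatible with
everything, and such columns are skipped outright in the neighbour scan.

### Verification: an independent tree-enumeration oracle

`brute_force_compatible` implements the *definition* rather than the graph
characterization: it enumerates every unrooted binary topology on the
doubly-observed taxa (3, 15, 105, 945, 10 395 trees for 4–8 taxa; 8 is the
hard bound) and asks whether some topology gives *both* columns an
unordered (Fitch) parsimony length equal to their number of distinct
observed states minus one. Enumeration covers binary trees only, which is
sufficient: a character homoplasy-free on a multifurcating tree is
homoplasy-free on some resolution of it. The test suite checks the graph
test against this oracle on thousands of random column pairs (and the
acceptance suite on 10 000); the two code paths share nothing but the
`ColumnStates` container.

## Gap semantics

Within each row, a `-` whose contiguous gap run reaches a sequence end is
a **terminal gap**; all other `-` are **internal gaps**. Classification is
row-local. Terminal gaps record missing sequence, never an evolutionary
event, so they are treated as missing data in every mode. Internal gaps
imply insertion/deletion events; with `e=true` (default) they enter the
compatibility test as a fifth state, on equal footing with nucleotides
(including gap-vs-gap state combinations, which contribute edges like any
other pair — the state's identity is arbitrary, as a relabelling property
test confirms). `?` and the IUPAC ambiguity letters (N, R, Y, S, W, K, M,
B, D, H, V) are missing data throughout the conflict machinery: partial
information is conservatively discarded rather than guessed. `U` is
accepted on input and normalized to `T`.

This distinction is only meaningful when loci are trimmed separately; in
a concatenated matrix a taxon absent from one locus shows as a long
internal gap. Trim per locus first.

## The neighbour scan and block rule

Columns `i` and `j` are compared for every `1 ≤ j − i ≤ d` (default
`d=2`); both members of an incompatible pair are flagged, so the number of
conflicted columns can exceed the number of conflicts (each conflict flags
two columns) or fall short of it (four mutually conflicting columns yield
six conflicts). Flags are monotone in `d`.

Block evaluation uses a **window of `b` sites sliding one site at a
time** over every start position; an alignment shorter than `b` is
evaluated as a single window of its own length (otherwise short loci could
never be trimmed). A window triggers when its conflicted proportion is
`≥ p` — "as great or greater" — and then marks the sites from its first to
its last conflicted column, inclusive; the final mask is the union over
all triggering windows, so merged spans are permitted. Sliding placement
(rather than disjoint tiles) makes the result translation-invariant and
cannot miss a noisy stretch straddling a tile boundary. Edge cases pinned
by tests: `p=0` makes every window trigger but a span still requires a
flagged site (an all-clean alignment is never cut); a triggering window
whose only flag is a single site deletes exactly that site; the `≥`
comparison is guarded by a 1e-9 tolerance so decimal thresholds such as
`11/20 ≥ 0.55` behave exactly.

Every maximal deleted run therefore begins and ends at a conflicted site,
sites outside all triggering spans are retained, and the mask is monotone
in both `p` (smaller `p` ⇒ superset) and `d`. The whole pipeline is a
pure, deterministic function of the alignment and parameters.

### Parameters

| name | default | meaning |
|------|---------|---------|
| `d`  | 2       | max neighbour distance checked (pairwise even for d>1); larger trims more aggressively but blurs local boundaries |
| `e`  | true    | internal gaps as fifth state; more aggressive, only meaningful per locus |
| `b`  | 10      | window length in sites; larger gives more evidence per window but can miss short chaotic stretches |
| `p`  | 0.5     | proportion of conflicted sites at which a window triggers; larger is more permissive |
| occupancy `max_gap_fraction` | 0.5 | delete a column iff its fraction of `-`/`?` cells **strictly exceeds** this; 0.18 emulates an 82% occupancy requirement |

For the occupancy filter, ambiguity letters count as occupied (a base was
called); `?` counts as a gap. Occupancy is computed over whatever file is
given — filtering isolated single-locus files is less stringent than
filtering after all taxa are in one matrix, since absent taxa are invisible
to the former.

## Synthetic data generator

`phyin.synth.make_fixture` emulates the structure the method targets: a
conserved, tree-consistent core with randomized flanks.

* **Tree**: a uniformly random unrooted binary topology (sequential random
  leaf attachment), deterministic per seed, returned as a `dendropy.Tree`.
* **Clean region**: each column is one substitution on one random branch —
  the taxa on one side carry the derived base, the rest the ancestral
  base; with probability 0.3 a second substitution on a branch nested
  inside the derived clade adds a third state. Every column is convex on
  the shared tree, hence homoplasy-free, hence all clean columns are
  **pairwise compatible by construction** (asserted exhaustively in tests,
  against both code paths).
* **Noise region**: i.i.d. uniform draws over {A, C, G, T}. This is the
  simplest model of a fully randomized stretch and makes expected conflict
  rates derivable; it is *not* a model of saturated evolution (no GTR+Γ
  simulation, no gene-tree discordance).
* **Gap injection**: each row's two ends are eroded into terminal-gap runs
  (binomial draw with mean `terminal_gap_rate` of the row length in total,
  split randomly between the ends, capped so one nucleotide survives),
  emulating ragged sequence-capture coverage; internal gaps are sprinkled
  i.i.d. per cell at `internal_gap_rate`, strictly between each row's
  first and last surviving nucleotides so they never merge into the
  terminal runs.

Defaults — 16 taxa, a 200-site clean core with 200 noise sites split over
both flanks, `terminal_gap_rate=0.15`, `internal_gap_rate=0.02` — were
chosen once as a plausible single sequence-capture locus and define the
conditions of the boundary-detection checks: over seeds 1–20, the deleted
fraction in the noise region strictly exceeds that in the clean region in
every replicate (typically ≈0.75 vs ≈0.01).

One subtlety the generator makes visible: i.i.d. internal gaps are
*random with respect to the tree*, so with `e=true` they occasionally
create genuine state-pair-graph cycles between otherwise clean columns —
random gaps are conflicting signal, exactly as the criterion defines it.
The zero-deletion guarantee therefore holds for purely clean alignments
(no noise, no injected gaps), and that is what the tests assert; gapped
clean fixtures are only guaranteed to be trimmed *less* than noise. Real
indels are phylogenetically structured and would behave more like the
clean columns; the i.i.d. choice is deliberately pessimistic.

What passing these tests shows: the criterion separates i.i.d.-random
stretches from tree-consistent stretches under realistic gap erosion. What
it does not show: performance on saturated-but-structured evolution,
alignment error, amino-acid data (unsupported), or rogue single-taxon
subsequences (a per-row problem outside a column trimmer's reach).

## Numerical and design notes

* Coordinates are 0-based half-open internally; every user-facing report
  and the CLI are 1-based inclusive.
* No randomness anywhere in the trimming path; byte-identical reruns.
* The demo alignment (8 taxa × 10 sites) is a constructed walk-through
  whose conflict structure — pairs (1,2), (2,3), (7,9), five conflicted
  columns, nine deleted sites — is verified in the tests against the
  brute-force oracle, and is what `scripts/acceptance.py` recomputes.
* Problem sizes in the test suite (10 000 oracle pairs at 4–6 taxa, 100
  monotonicity fixtures of 10 × 120, 20 boundary fixtures of 16 × 400)
  keep the full suite around ten seconds while exercising every code
  path; all are generated at run time from seeds.
* Per-locus FASTA is the only input format; NEXUS/PHYLIP, amino acids,
  concatenation management, and whole-alignment (non-local) compatibility
  scoring are out of scope.
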