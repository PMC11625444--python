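"""Seeded synthetic alignments with labelled orderly and chaotic regions.

Sequence-capture loci (UCEs and the like) typically carry a well-aligned
conserved core flanked by fragmented, effectively random regions.  This
module generates test alignments with that structure, fully reproducible
from a seed:

* a *clean* region whose columns are all homoplasy-free on one shared
  random tree (hence pairwise compatible by construction);
* a *noise* region of i.i.d. uniform draws over {A, C, G, T}, the simplest
  model of a fully randomized stretch;
* terminal-gap erosion of row ends (emulating ragged sequencing coverage)
  and sprinkled internal gaps.

Each fixture comes with ground-truth per-site region labels so boundary
detection can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import dendropy
import numpy as np

from .alignment import Alignment

__all__ = [
    "SynthConfig",
    "random_tree",
    "clean_region",
    "noise_region",
    "make_fixture",
    "write_fixture",
]

_BASES = np.array(list("ACGT"))
NOISE_POSITIONS = ("left", "right", "both-flanks", "interior")


@dataclass(frozen=True)
class SynthConfig:
    """Recipe for one synthetic fixture.

    Defaults emulate a single sequence-capture locus: a 200-site conserved
    core flanked by two 100-site randomized regions, with moderate
    end-fragmentation (15% of each row eroded into terminal gaps on
    average) and sparse internal indels (2% of interior cells).
    """

    n_taxa: int = 16
    n_clean_sites: int = 200
    n_noise_sites: int = 200
    noise_position: str = "both-flanks"
    terminal_gap_rate: float = 0.15
    internal_gap_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.n_clean_sites < 0 or self.n_noise_sites < 0:
            raise ValueError("site counts must be >= 0")
        if self.noise_position not in NOISE_POSITIONS:
            raise ValueError(f"noise_position must be one of {NOISE_POSITIONS}")
        for rate in (self.terminal_gap_rate, self.internal_gap_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("gap rates must be in [0, 1]")


def _taxon_labels(n_taxa: int) -> list:
    return [f"t{i + 1}" for i in range(n_taxa)]


def random_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Uniformly random unrooted binary topology on labelled taxa.

    Built by sequential random leaf attachment: leaf k+1 joins a uniformly
    chosen edge of the current tree, which yields the uniform distribution
    over unrooted binary topologies.  Deterministic per seed.
    """
    if n_taxa < 4:
        raise ValueError(f"n_taxa must be >= 4, got {n_taxa}")
    rng = np.random.default_rng(seed)
    labels = _taxon_labels(n_taxa)
    # adjacency list; nodes 0..n_taxa-1 are leaves, higher ids internal
    edges = [(0, n_taxa), (1, n_taxa), (2, n_taxa)]
    next_internal = n_taxa + 1
    for leaf in range(3, n_taxa):
        u, v = edges.pop(int(rng.integers(len(edges))))
        mid = next_internal
        next_internal += 1
        edges.extend([(u, mid), (v, mid), (leaf, mid)])
    newick = _edges_to_newick(edges, labels)
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        taxon_namespace=dendropy.TaxonNamespace(labels),
    )
    tree.is_rooted = False
    return tree


def _edges_to_newick(edges: list, labels: list) -> str:
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    root = len(labels)  # first internal node; degree 3

    def render(node, parent):
        children = [x for x in adj[node] if x != parent]
        if not children:
            return labels[node]
        return "(" + ",".join(render(c, node) for c in children) + ")"

    return render(root, None) + ";"


def _tree_clades(tree: dendropy.Tree) -> list:
    """Leaf-label sets of every proper clade (rooted arbitrarily at the seed
    node); each is one side of a branch of the unrooted tree."""
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    clades = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 0 < len(clade) < len(all_labels):
            clades.append((node, clade))
    return clades


def clean_region(tree: dendropy.Tree, n_sites: int, seed: int) -> np.ndarray:
    """Columns jointly homoplasy-free on ``tree`` (pairwise compatible).

    Each character arises from a single substitution on one random branch:
    taxa on one side of the branch carry the derived base, the rest the
    ancestral base.  With probability 0.3 a second substitution is placed
    on a branch nested inside the derived clade, adding a third state while
    remaining homoplasy-free.  Rows follow the sorted taxon-label order
    t1..tn.
    """
    rng = np.random.default_rng(seed)
    labels = [t.label for t in tree.taxon_namespace]
    index = {lab: i for i, lab in enumerate(labels)}
    clades = _tree_clades(tree)
    block = np.empty((len(labels), n_sites), dtype="<U1")
    for s in range(n_sites):
        node, clade = clades[int(rng.integers(len(clades)))]
        ancestral, derived, third = rng.choice(4, size=3, replace=False)
        block[:, s] = _BASES[ancestral]
        for lab in clade:
            block[index[lab], s] = _BASES[derived]
        if len(clade) > 1 and rng.random() < 0.3:
            nested = [
                frozenset(lf.taxon.label for lf in child.leaf_iter())
                for child in node.child_nodes()
            ]
            nested = [c for c in nested if 0 < len(c) < len(clade)]
            if nested:
                sub = nested[int(rng.integers(len(nested)))]
                for lab in sub:
                    block[index[lab], s] = _BASES[third]
    return block


def noise_region(n_taxa: int, n_sites: int, seed: int) -> np.ndarray:
    """I.i.d. uniform draws over {A, C, G, T}; deterministic per seed."""
    if n_taxa < 1 or n_sites < 1:
        raise ValueError("n_taxa and n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    return _BASES[rng.integers(0, 4, size=(n_taxa, n_sites))]


def _layout(config: SynthConfig) -> list:
    """Ordered (region, n_sites) blocks according to noise_position."""
    c, z = config.n_clean_sites, config.n_noise_sites
    if config.noise_position == "left":
        return [("noise", z), ("clean", c)]
    if config.noise_position == "right":
        return [("clean", c), ("noise", z)]
    if config.noise_position == "both-flanks":
        return [("noise", z // 2), ("clean", c), ("noise", z - z // 2)]
    return [("clean", c // 2), ("noise", z), ("clean", c - c // 2)]


def make_fixture(config: SynthConfig) -> Tuple[Alignment, List[str]]:
    """Generate one labelled fixture: (alignment, per-site region labels).

    Terminal gaps are injected by eroding each row's two ends (binomial
    draw with mean ``terminal_gap_rate`` of the row length in total, capped
    so at least one nucleotide survives); internal gaps are sprinkled
    strictly between the first and last surviving nucleotides so they never
    merge into the terminal runs.
    """
    rng = np.random.default_rng(config.seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=4)
    tree = random_tree(config.n_taxa, int(sub_seeds[0]))
    blocks, labels = [], []
    block_offset = 0
    for region, width in _layout(config):
        if width == 0:
            continue
        if region == "clean":
            blocks.append(clean_region(tree, width, int(sub_seeds[1]) + block_offset))
        else:
            blocks.append(
                noise_region(config.n_taxa, width, int(sub_seeds[2]) + block_offset)
            )
        block_offset += 1
    if blocks:
        matrix = np.concatenate(blocks, axis=1)
    else:
        matrix = np.empty((config.n_taxa, 0), dtype="<U1")
    for region, width in _layout(config):
        labels.extend([region] * width)

    gap_rng = np.random.default_rng(int(sub_seeds[3]))
    n_sites = matrix.shape[1]
    if n_sites:
        for i in range(config.n_taxa):
            total = int(gap_rng.binomial(n_sites, config.terminal_gap_rate))
            total = min(total, n_sites - 1)
            left = int(gap_rng.integers(0, total + 1))
            right = total - left
            if left:
                matrix[i, :left] = "-"
            if right:
                matrix[i, n_sites - right :] = "-"
            if config.internal_gap_rate > 0:
                interior = np.arange(left + 1, n_sites - right - 1)
                if interior.size:
                    hits = interior[
                        gap_rng.random(interior.size) < config.internal_gap_rate
                    ]
                    matrix[i, hits] = "-"
    alignment = Alignment(tuple(_taxon_labels(config.n_taxa)), matrix)
    return alignment, labels


def write_fixture(alignment: Alignment, labels: List[str], fasta_path, labels_path) -> None:
    """Write a fixture as FASTA plus a TSV sidecar (1-based site, region)."""
    from .alignment import write_fasta

    write_fasta(alignment, fasta_path)
    with open(str(labels_path), "w") as fh:
        fh.write("site\tregion\n")
        for k, region in enumerate(labels, start=1):
            fh.write(f"{k}\t{region}\n")
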