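"""State-pair-graph compatibility test and its tree-enumeration oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phyin.alignment import classify_gaps
from phyin.compatibility import (
    A, C, G, T, GAP, MISSING,
    ColumnStates,
    are_incompatible,
    brute_force_compatible,
    build_state_pair_graph,
    encode_column,
    _unrooted_topologies,
)

from conftest import make_alignment


def col(*states):
    return ColumnStates(0, np.array(states, dtype=np.int8), True)


class TestEncodeColumn:
    def test_gap_modes(self):
        # middle column reads A / internal gap / terminal gap / C down the taxa
        aln = make_alignment("AAC", "A-C", "--C", "ACC")
        gaps = classify_gaps(aln)
        fifth = encode_column(aln, gaps, 1, fifth_state=True)
        assert list(fifth.states) == [A, GAP, MISSING, C]
        plain = encode_column(aln, gaps, 1, fifth_state=False)
        assert list(plain.states) == [A, MISSING, MISSING, C]

    def test_terminal_gap_never_a_state(self):
        aln = make_alignment("A-", "--", "T-")
        gaps = classify_gaps(aln)
        assert list(encode_column(aln, gaps, 1, True).states) == [
            MISSING, MISSING, MISSING,
        ]

    def test_constant_column(self):
        aln = make_alignment("A", "A", "A")
        gaps = classify_gaps(aln)
        assert list(encode_column(aln, gaps, 0, True).states) == [A, A, A]


class TestStatePairGraph:
    def test_all_four_combinations(self):
        g = build_state_pair_graph(col(T, T, A, A), col(A, T, A, T))
        assert g.n_edges == 4
        assert len(g.left_vertices) == 2 and len(g.right_vertices) == 2
        assert g.has_cycle()

    def test_missing_excluded(self):
        g = build_state_pair_graph(col(A, MISSING), col(C, G))
        assert g.edges == frozenset({(A, C)})

    def test_star_is_acyclic(self):
        g = build_state_pair_graph(col(A, C, G), col(T, T, T))
        assert g.n_edges == 3
        assert not g.has_cycle()

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            build_state_pair_graph(col(A, C), col(A, C, G))


class TestAreIncompatible:
    def test_four_gamete_binary(self):
        assert are_incompatible(col(T, T, A, A), col(A, T, A, T))

    def test_invariant_column_compatible_with_anything(self):
        assert not are_incompatible(col(A, C, G, T), col(C, C, C, C))

    def test_self_compatible(self):
        c = col(A, C, G, T, A, C)
        assert not are_incompatible(c, c)

    def test_path_graph_compatible(self):
        ci = col(T, T, T, T, A, A, A, A)
        cj = col(C, C, C, C, G, G, G, C)
        assert not are_incompatible(ci, cj)
        assert brute_force_compatible(ci, cj)

    def test_gap_participates_as_fifth_state(self):
        # GAP on both sides closes a 4-cycle exactly like a nucleotide
        assert are_incompatible(col(A, A, GAP, GAP), col(C, GAP, C, GAP))


class TestBruteForce:
    def test_topology_counts(self):
        assert [len(_unrooted_topologies(n)) for n in (4, 5, 6)] == [3, 15, 105]

    def test_invariant_always_compatible(self):
        assert brute_force_compatible(col(A, A, A, A, A), col(A, C, G, T, GAP))

    def test_four_gamete_rejected_on_all_three_topologies(self):
        assert not brute_force_compatible(col(T, T, A, A), col(A, T, A, T))

    def test_enumeration_bound(self):
        big = col(*([A, C] * 5))
        with pytest.raises(ValueError, match="enumeration bound"):
            brute_force_compatible(big, big)

    def test_small_pairs_always_compatible(self):
        # fewer than 4 doubly-observed taxa can never close a bipartite cycle
        assert brute_force_compatible(col(A, C, G), col(T, G, A))


@st.composite
def column_pairs(draw, min_taxa=4, max_taxa=6, missing=True):
    n = draw(st.integers(min_taxa, max_taxa))
    alphabet = [A, C, G, T, GAP] + ([MISSING] if missing else [])
    a = draw(st.lists(st.sampled_from(alphabet), min_size=n, max_size=n))
    b = draw(st.lists(st.sampled_from(alphabet), min_size=n, max_size=n))
    return col(*a), col(*b)


class TestProperties:
    @settings(max_examples=300, derandomize=True)
    @given(column_pairs())
    def test_symmetry(self, pair):
        ci, cj = pair
        assert are_incompatible(ci, cj) == are_incompatible(cj, ci)

    @settings(max_examples=300, derandomize=True)
    @given(column_pairs(), st.integers(0, 5))
    def test_taxon_removal_never_creates_incompatibility(self, pair, drop):
        ci, cj = pair
        if are_incompatible(ci, cj):
            return
        keep = [k for k in range(ci.n_taxa) if k != drop % ci.n_taxa]
        assert not are_incompatible(
            col(*ci.states[keep]), col(*cj.states[keep])
        )

    @settings(max_examples=300, derandomize=True)
    @given(column_pairs(missing=False), st.permutations(list(range(5))))
    def test_state_relabeling_invariance(self, pair, perm):
        """State identity is arbitrary: relabeling states (incl. which
        symbol plays the internal-gap role) cannot change the verdict."""
        ci, cj = pair
        relab = np.array(perm, dtype=np.int8)
        assert are_incompatible(ci, cj) == are_incompatible(
            col(*relab[ci.states]), col(*relab[cj.states])
        )

    @settings(max_examples=200, derandomize=True)
    @given(column_pairs())
    def test_few_state_columns_compatible_with_everything(self, pair):
        ci, cj = pair
        obs = ci.states[ci.states != MISSING]
        if len(set(obs.tolist())) < 2:
            assert not are_incompatible(ci, cj)

    @settings(max_examples=500, derandomize=True)
    @given(column_pairs())
    def test_graph_test_agrees_with_oracle(self, pair):
        ci, cj = pair
        assert are_incompatible(ci, cj) == (not brute_force_compatible(ci, cj))


def test_oracle_equivalence_seeded_sweep():
    """2,000 seeded random pairs: graph test == negation of tree oracle.

    (The full 10,000-pair sweep runs in the acceptance tests.)
    """
    rng = np.random.default_rng(20240)
    for _ in range(2000):
        n = int(rng.integers(4, 7))
        a = rng.integers(0, 5, size=n).astype(np.int8)
        b = rng.integers(0, 5, size=n).astype(np.int8)
        a[rng.random(n) < 0.15] = MISSING
        b[rng.random(n) < 0.15] = MISSING
        ci, cj = col(*a), col(*b)
        assert are_incompatible(ci, cj) == (not brute_force_compatible(ci, cj))
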