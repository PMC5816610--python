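"""Proximity-rule cassette assembly and its invariants."""

from dataclasses import replace

import pytest

from gencas.cassette_assembly import AssemblyParams, assemble_cassettes, gene_gap
from helpers import make_gene, random_gene_list
from oracles import boundary_check_partition


def genes_from_gaps(gaps, length=500):
    genes = []
    cursor = 0
    for i in range(len(gaps) + 1):
        genes.append(make_gene(f"g{i + 1}", cursor, cursor + length))
        if i < len(gaps):
            cursor += length + gaps[i]
    return genes


class TestGeneGap:
    def test_arithmetic(self):
        a, b = make_gene("a", 0, 500), make_gene("b", 799, 1000)
        assert gene_gap(a, b) == 299

    def test_overlap_is_negative(self):
        a, b = make_gene("a", 0, 500), make_gene("b", 450, 900)
        assert gene_gap(a, b) == -50

    def test_different_replicons_rejected(self):
        a = make_gene("a", 0, 500)
        b = make_gene("b", 600, 900, replicon_id="other")
        with pytest.raises(ValueError, match="replicon"):
            gene_gap(a, b)

    def test_against_interval_oracle(self, rng):
        for _ in range(1000):
            s1, s2 = sorted(int(x) for x in rng.integers(0, 10_000, 2))
            l1, l2 = (int(x) for x in rng.integers(1, 2_000, 2))
            a = make_gene("a", s1, s1 + l1)
            b = make_gene("b", s2, s2 + l2)
            if a.start > b.start:
                a, b = b, a
            # oracle: count of integer positions between the intervals, or
            # minus the width of the region both spans claim
            if b.start >= a.end:
                oracle = len(range(a.end, b.start))
            else:
                oracle = -len(range(b.start, a.end))
            assert gene_gap(a, b) == oracle


class TestAssembleCassettes:
    def test_strict_threshold_299_joins_300_splits(self):
        genes = genes_from_gaps([100, 299, 300, 50])
        cassettes = assemble_cassettes(genes)
        assert [[g.gene_id for g in c.genes] for c in cassettes] == [
            ["g1", "g2", "g3"],
            ["g4", "g5"],
        ]

    def test_isolated_gene_is_not_a_cassette(self):
        genes = genes_from_gaps([400, 400])
        assert assemble_cassettes(genes) == []
        singles = assemble_cassettes(genes, AssemblyParams(min_genes=1))
        assert len(singles) == 3

    def test_overlapping_genes_always_join(self):
        genes = genes_from_gaps([-50, 100])
        cassettes = assemble_cassettes(genes)
        assert len(cassettes) == 1 and len(cassettes[0]) == 3

    def test_unsorted_input_rejected(self):
        genes = genes_from_gaps([100])[::-1]
        with pytest.raises(ValueError, match="sorted"):
            assemble_cassettes(genes)

    def test_circular_wraparound_merges_terminal_runs(self):
        genes = genes_from_gaps([100, 400, 100])  # runs {g1,g2}, {g3,g4}
        length = genes[-1].end + 150  # wrap gap = 150 + g1.start(0) < 300
        params = AssemblyParams(circular=True)
        cassettes = assemble_cassettes(genes, params, replicon_length=length)
        assert len(cassettes) == 1 and len(cassettes[0]) == 4
        linear = assemble_cassettes(genes, AssemblyParams(), replicon_length=length)
        assert len(linear) == 2

    def test_matches_boundary_check_oracle_on_random_annotations(self, rng):
        for _ in range(200):
            genes = random_gene_list(rng, int(rng.integers(2, 50)))
            cassettes = assemble_cassettes(genes)
            oracle = boundary_check_partition(
                [(g.start, g.end) for g in genes], max_gap=300, min_genes=2
            )
            got = [[genes.index(g) for g in c.genes] for c in cassettes]
            assert got == oracle


class TestInvariants:
    def test_partition_and_maximality(self, rng):
        params = AssemblyParams()
        for _ in range(50):
            genes = random_gene_list(rng, 30)
            cassettes = assemble_cassettes(genes, params)
            seen = [g.gene_id for c in cassettes for g in c.genes]
            assert len(seen) == len(set(seen))  # disjoint
            for c in cassettes:
                gaps = [gene_gap(a, b) for a, b in zip(c.genes, c.genes[1:])]
                assert all(g < params.max_gap for g in gaps)
            # maximality: gap to the nearest excluded neighbour >= max_gap
            for c in cassettes:
                first, last = c.genes[0], c.genes[-1]
                i, j = genes.index(first), genes.index(last)
                if i > 0:
                    assert gene_gap(genes[i - 1], first) >= params.max_gap
                if j < len(genes) - 1:
                    assert gene_gap(last, genes[j + 1]) >= params.max_gap

    def test_strand_blindness(self, rng):
        genes = random_gene_list(rng, 40)
        flipped = [replace(g, strand="-" if g.strand == "+" else "+") for g in genes]
        a = assemble_cassettes(genes)
        b = assemble_cassettes(flipped)
        assert [[g.gene_id for g in c.genes] for c in a] == [
            [g.gene_id for g in c.genes] for c in b
        ]

    def test_idempotence(self, rng):
        genes = random_gene_list(rng, 40)
        cassettes = assemble_cassettes(genes)
        again = assemble_cassettes([g for c in cassettes for g in c.genes])
        assert [[g.gene_id for g in c.genes] for c in again] == [
            [g.gene_id for g in c.genes] for c in cassettes
        ]
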