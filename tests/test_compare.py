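"""Cassette matching and conserved-combination search."""

import itertools

import networkx as nx
import pytest

from gencas.cassette_assembly import Cassette
from gencas.cassette_compare import (
    covers_combination,
    gene_compatible,
    match_cassettes,
    search_conserved_combinations,
)
from gencas.fingerprint import Fingerprint, FunctionLabel
from gencas.fixtures import fixture_cassette, load_cassette_fixtures
from helpers import LABEL_POOL, make_gene
from oracles import brute_force_match_size


def make_cassette(label_sets, cassette_id="c", taxon_group="G", species="S"):
    genes = tuple(
        make_gene(f"{cassette_id}_g{i}", i * 1000, i * 1000 + 900, taxon_group=taxon_group, species=species)
        for i in range(len(label_sets))
    )
    return Cassette(
        cassette_id=cassette_id,
        replicon_id=cassette_id,
        species=species,
        taxon_group=taxon_group,
        genes=genes,
        fingerprint=Fingerprint(tuple(frozenset(s) for s in label_sets)),
    )


def random_cassette(rng, n, cassette_id="c", **kw):
    sets = [LABEL_POOL[rng.integers(len(LABEL_POOL))] for _ in range(n)]
    return make_cassette(sets, cassette_id, **kw)


class TestGeneCompatible:
    def test_shared_ec_wins_over_cog(self):
        a = {FunctionLabel("ec3", "4.1.2")}
        b = {FunctionLabel("ec3", "4.1.2"), FunctionLabel("cog", "COG3684")}
        assert gene_compatible(a, b) == FunctionLabel("ec3", "4.1.2")

    def test_disjoint_sets_have_no_shared_label(self):
        assert gene_compatible({FunctionLabel("ec3", "3.2.1")}, {FunctionLabel("ec3", "2.7.1")}) is None

    def test_priority_on_all_kind_pairs(self):
        labels = {
            "ec3": FunctionLabel("ec3", "1.1.1"),
            "cog": FunctionLabel("cog", "COG0001"),
            "role": FunctionLabel("role", "transporter"),
        }
        priority = ["ec3", "cog", "role"]
        for kinds in itertools.chain.from_iterable(
            itertools.combinations(priority, r) for r in range(1, 4)
        ):
            shared = {labels[k] for k in kinds}
            expected = labels[min(kinds, key=priority.index)]
            assert gene_compatible(shared, shared | {FunctionLabel("ec3", "9.9.9")}) == expected


class TestMatchCassettes:
    def test_six_gene_yih_lac_match(self):
        m = match_cassettes(
            fixture_cassette("yih_Escherichia_coli"),
            fixture_cassette("lac_Streptococcus_gallolyticus"),
        )
        assert m.match_size == 6
        assert sorted(str(l) for l in m.matched_combination) == [
            "ec3:2.3.1",
            "ec3:2.7.1",
            "ec3:3.2.1",
            "ec3:4.1.2",
            "role:transcription_factor",
            "role:transporter",
        ]

    def test_self_match_counts_labelled_genes(self):
        c = fixture_cassette("yih_Escherichia_coli")
        labelled = sum(1 for s in c.fingerprint.gene_labels if s)
        assert match_cassettes(c, c).match_size == labelled == 9

    def test_pairs_are_one_to_one_and_labels_shared(self):
        a = fixture_cassette("yih_Escherichia_coli")
        b = fixture_cassette("lac_Staphylococcus_aureus")
        m = match_cassettes(a, b)
        assert len({i for i, _, _ in m.pairs}) == len(m.pairs)
        assert len({j for _, j, _ in m.pairs}) == len(m.pairs)
        for i, j, lab in m.pairs:
            assert lab in a.fingerprint[i] and lab in b.fingerprint[j]

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(100):
            a = random_cassette(rng, int(rng.integers(1, 8)), "a")
            b = random_cassette(rng, int(rng.integers(1, 8)), "b")
            m = match_cassettes(a, b)
            oracle = brute_force_match_size(
                [set(s) for s in a.fingerprint.gene_labels],
                [set(s) for s in b.fingerprint.gene_labels],
            )
            assert m.match_size == oracle

    def test_matches_networkx_maximum_matching(self, rng):
        for _ in range(50):
            a = random_cassette(rng, int(rng.integers(1, 10)), "a")
            b = random_cassette(rng, int(rng.integers(1, 10)), "b")
            graph = nx.Graph()
            graph.add_nodes_from((0, i) for i in range(len(a)))
            graph.add_nodes_from((1, j) for j in range(len(b)))
            for i in range(len(a)):
                for j in range(len(b)):
                    if gene_compatible(a.fingerprint[i], b.fingerprint[j]):
                        graph.add_edge((0, i), (1, j))
            nx_size = len(
                nx.bipartite.maximum_matching(graph, top_nodes=[(0, i) for i in range(len(a))])
            ) // 2
            assert match_cassettes(a, b).match_size == nx_size

    def test_symmetry_bound_and_monotonicity(self, rng):
        for _ in range(50):
            a = random_cassette(rng, int(rng.integers(1, 9)), "a")
            b = random_cassette(rng, int(rng.integers(1, 9)), "b")
            size = match_cassettes(a, b).match_size
            assert size == match_cassettes(b, a).match_size
            assert size <= min(len(a), len(b))
            if len(a) > 1:
                shorter = make_cassette(list(a.fingerprint.gene_labels)[:-1], "a2")
                assert match_cassettes(shorter, b).match_size <= size

    def test_identical_fingerprints_match_completely(self, rng):
        sets = [LABEL_POOL[k % len(LABEL_POOL)] for k in range(1, 6)]
        a, b = make_cassette(sets, "a"), make_cassette(sets, "b")
        assert match_cassettes(a, b).match_size == len(sets)


class TestSearchConservedCombinations:
    def test_fixture_db_yields_six_label_combination_across_groups(self):
        combos = search_conserved_combinations(load_cassette_fixtures(), min_size=6, min_groups=2)
        assert len(combos) == 1
        combo = combos[0]
        assert [str(l) for l in combo.combination] == [
            "ec3:2.3.1",
            "ec3:2.7.1",
            "ec3:3.2.1",
            "ec3:4.1.2",
            "role:transcription_factor",
            "role:transporter",
        ]
        assert combo.group_count == 2
        assert len(combo.supporting) == 4  # every fixture cassette covers it

    def test_disjoint_labels_yield_nothing(self):
        db = [
            make_cassette([{FunctionLabel("ec3", "1.1.1")}] * 3, "a", taxon_group="G1"),
            make_cassette([{FunctionLabel("ec3", "2.2.2")}] * 3, "b", taxon_group="G2"),
        ]
        assert search_conserved_combinations(db, min_size=1, min_groups=2) == []

    def test_planted_combination_recovered_with_subset_check(self, rng):
        from gencas.cassette_assembly import assemble_cassettes
        from gencas.simulate import PlantedCassette, SimConfig, simulate_genomes

        planted_labels = (
            ("ec3:3.2.1",),
            ("ec3:4.1.2",),
            ("ec3:2.7.1",),
            ("role:transporter",),
            ("role:transcription_factor",),
        )
        planted = PlantedCassette(
            fingerprint=planted_labels, groups=("Enterobacteriaceae", "Bacilli", "Clostridia")
        )
        truth = simulate_genomes(
            SimConfig(
                seed=9,
                n_species=6,
                genes_per_replicon=20,
                taxon_groups=("Enterobacteriaceae", "Bacilli", "Clostridia"),
                planted_cassettes=(planted,),
            )
        )
        db = []
        for sp in truth.species:
            db.extend(assemble_cassettes(truth.genes[sp]))
        assert len(db) <= 12 * 6
        combos = search_conserved_combinations(db, min_size=5, min_groups=3)
        expected = tuple(sorted(FunctionLabel.parse(t) for ls in planted_labels for t in ls))
        assert any(c.combination == expected for c in combos)
        # no false maximal combination of the planted size or larger: every
        # reported combination of size >= 5 must be covered, brute-force
        # checked, by cassettes of >= 3 groups
        for c in combos:
            groups = set()
            for cassette in db:
                if covers_combination(cassette, c.combination):
                    groups.add(cassette.taxon_group)
            assert len(groups) >= 3
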