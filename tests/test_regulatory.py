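"""Intergenic extraction, conservation, PWM scanning and site ranking."""

import numpy as np
import pytest

from gencas.alignment import MultipleAlignment
from gencas.annotation_io import Replicon
from gencas.motifs import MotifModel, reverse_complement
from gencas.regulatory import (
    ColumnProfile,
    IntergenicRegion,
    TssAnchor,
    conservation_profile,
    extract_intergenic,
    rank_sites,
    scan_pwm,
)
from helpers import make_gene


def make_region(sequence, region_id="r", offset=0):
    return IntergenicRegion(
        region_id=region_id,
        replicon_id="chr",
        core_start=offset,
        core_end=offset + len(sequence),
        extended_start=offset,
        extended_end=offset + len(sequence),
        sequence=sequence,
        upstream_gene="u",
        downstream_gene="d",
    )


def replicon_with(sequence):
    return Replicon(replicon_id="chr", length=len(sequence), sequence=sequence)


class TestExtractIntergenic:
    def test_extension_arithmetic(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 1000))
        genes = [make_gene("a", 0, 500), make_gene("b", 560, 900)]
        regions = extract_intergenic(genes, replicon_with(seq))
        assert len(regions) == 1
        r = regions[0]
        assert (r.core_start, r.core_end) == (500, 560)
        assert (r.extended_start, r.extended_end) == (400, 660)
        assert r.sequence == seq[400:660]
        assert r.region_id == "a/b"

    def test_short_gaps_and_overlaps_are_skipped(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 2000))
        genes = [make_gene("a", 0, 500), make_gene("b", 530, 900), make_gene("c", 880, 1200)]
        assert extract_intergenic(genes, replicon_with(seq)) == []

    def test_extension_clipped_at_replicon_ends(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 700))
        genes = [make_gene("a", 0, 50), make_gene("b", 650, 700)]
        (r,) = extract_intergenic(genes, replicon_with(seq))
        assert (r.extended_start, r.extended_end) == (0, 700)

    def test_missing_sequence_rejected(self):
        genes = [make_gene("a", 0, 500), make_gene("b", 560, 900)]
        with pytest.raises(ValueError, match="sequence"):
            extract_intergenic(genes, Replicon(replicon_id="chr", length=1000))

    def test_coordinates_match_interval_oracle(self, rng):
        from gencas.simulate import SimConfig, simulate_genomes

        truth = simulate_genomes(SimConfig(seed=13, n_species=1, genes_per_replicon=30))
        sp = truth.species[0]
        genes, replicon = truth.genes[sp], truth.replicons[sp]
        regions = extract_intergenic(genes, replicon)
        # oracle: recompute from adjacent pairs with plain interval arithmetic
        expected = []
        for a, b in zip(genes, genes[1:]):
            if b.start - a.end >= 40:
                expected.append(
                    (max(0, a.end - 100), min(replicon.length, b.start + 100))
                )
        assert [(r.extended_start, r.extended_end) for r in regions] == expected


class TestTssCoordinates:
    def test_no_position_zero_and_plus_one_is_tss(self):
        anchor = TssAnchor(tss_position=100, strand="+")
        assert anchor.to_relative(100) == 1
        assert anchor.to_relative(99) == -1
        assert anchor.to_relative(149) == 50
        with pytest.raises(ValueError):
            anchor.to_replicon(0)

    def test_round_trip_is_bijective_on_both_strands(self):
        for strand in "+-":
            anchor = TssAnchor(tss_position=500, strand=strand)
            for rel in list(range(-260, 0)) + list(range(1, 61)):
                assert anchor.to_relative(anchor.to_replicon(rel)) == rel
            for pos in range(250, 750):
                assert anchor.to_replicon(anchor.to_relative(pos)) == pos


class TestConservationProfile:
    def test_identical_rows_are_fully_conserved(self):
        msa = MultipleAlignment(("ACGT", "ACGT", "ACGT"))
        profile = conservation_profile(msa)
        assert np.allclose(profile.identity, 1.0)

    def test_single_mismatch_column_fraction(self):
        msa = MultipleAlignment(("ACGT", "ACGT", "ACGT", "AGGT"))
        profile = conservation_profile(msa)
        assert profile.identity.tolist() == [1.0, 0.75, 1.0, 1.0]

    def test_gap_counts_as_mismatch_and_reference_columns_only(self):
        msa = MultipleAlignment(("AC-GT", "ACTGT", "AC--T"))
        profile = conservation_profile(msa)
        assert len(profile) == 4  # reference has 4 ungapped columns
        assert profile.identity.tolist() == [1.0, 1.0, pytest.approx(2 / 3), 1.0]


class TestScanPwm:
    def test_planted_consensus_is_unique_top_hit_with_max_score(self):
        motif = MotifModel.from_consensus("TGTGACGTGGTCACA")
        rng = np.random.default_rng(5)
        background = "".join(rng.choice(list("AC"), 300))  # no T/G runs
        site = "TGTGACGTGGTCACA"
        seq = background[:200] + site + background[200 + len(site):]
        region = make_region(seq)
        anchor = TssAnchor(tss_position=249, strand="+")
        hits = scan_pwm(region, anchor, motif)
        best = max(hits, key=lambda h: h.pwm_score)
        assert best.start == 200
        assert best.pwm_score == pytest.approx(motif.max_score)

    def test_strand_symmetry_mirrors_hits(self):
        motif = MotifModel.from_consensus("TGACGTCAAAGT")  # not palindromic
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), 200))
        seq = seq[:90] + "TGACGTCAAAGT" + seq[102:]
        region = make_region(seq)
        anchor = TssAnchor(tss_position=150, strand="+", window_up=140, window_down=45)
        hits = scan_pwm(region, anchor, motif, threshold_fraction=0.5)

        rc_seq = reverse_complement(seq)
        rc_region = make_region(rc_seq)
        rc_anchor = TssAnchor(tss_position=len(seq) - 1 - 150, strand="-", window_up=140, window_down=45)
        rc_hits = scan_pwm(rc_region, rc_anchor, motif, threshold_fraction=0.5)

        flip = {"+": "-", "-": "+"}
        assert sorted((h.span, round(h.pwm_score, 9), h.strand) for h in hits) == sorted(
            (h.span, round(h.pwm_score, 9), flip[h.strand]) for h in rc_hits
        )

    def test_site_center_convention_minus_41_point_5(self):
        # a 22-bp site spanning TSS-relative [-52, -31] has center -41.5
        motif = MotifModel.from_consensus("TGTGA" + "N" * 12 + "TCACA")
        assert motif.length == 22
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), 300))
        anchor = TssAnchor(tss_position=249, strand="+")
        start = anchor.to_replicon(-52)
        site = "TGTGA" + "".join(rng.choice(list("ACGT"), 12)) + "TCACA"
        seq = seq[:start] + site + seq[start + 22:]
        region = make_region(seq)
        hits = scan_pwm(region, anchor, motif)
        best = max(hits, key=lambda h: h.pwm_score)
        assert best.span == (-52, -31)
        assert best.center == -41.5

    def test_motif_longer_than_window_rejected(self):
        motif = MotifModel.from_consensus("ACGTACGTAC")
        region = make_region("ACGTAC")
        anchor = TssAnchor(tss_position=3, strand="+", window_up=3, window_down=2)
        with pytest.raises(ValueError, match="longer than"):
            scan_pwm(region, anchor, motif)


class TestRankSites:
    def make_profile(self, n, value=1.0):
        return ColumnProfile(identity=np.full(n, value), residues=tuple("A" * n))

    def run_rank(self, seq_len, sites):
        """sites: list of (offset, score) fabricated hits."""
        from gencas.regulatory import SiteHit

        hits = [
            SiteHit(
                region_id="r",
                strand="+",
                span=(-(seq_len - off), -(seq_len - off - 9)),
                center=0.0,
                pwm_score=score,
                start=off,
                end=off + 10,
                ref_start=off,
                ref_end=off + 10,
            )
            for off, score in sites
        ]
        return hits

    def test_single_hit_gets_rank_one(self):
        hits = self.run_rank(100, [(10, 5.0)])
        ranked = rank_sites(hits, self.make_profile(100))
        assert ranked[0].combined_rank == 1
        assert ranked[0].conservation == 1.0

    def test_equal_conservation_higher_score_ranks_first(self):
        hits = self.run_rank(100, [(10, 5.0), (40, 8.0)])
        ranked = rank_sites(hits, self.make_profile(100))
        by_rank = sorted(ranked, key=lambda h: h.combined_rank)
        assert by_rank[0].pwm_score == 8.0

    def test_conservation_is_mean_identity_over_span(self):
        profile = ColumnProfile(
            identity=np.concatenate([np.full(10, 0.5), np.full(90, 1.0)]),
            residues=tuple("A" * 100),
        )
        hits = self.run_rank(100, [(5, 5.0)])
        ranked = rank_sites(hits, profile)
        assert ranked[0].conservation == pytest.approx((5 * 0.5 + 5 * 1.0) / 10)

    def test_span_outside_profile_rejected(self):
        hits = self.run_rank(100, [(95, 5.0)])
        with pytest.raises(ValueError, match="outside"):
            rank_sites(hits, self.make_profile(100))
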