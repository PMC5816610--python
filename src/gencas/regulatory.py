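"""Regulatory-region analysis: intergenic extraction, conservation, PWM
scanning in a TSS-anchored window, and score/conservation ranking.

Coordinates
-----------
Replicon coordinates are 0-based half-open.  Positions relative to a
transcription start site (TSS) follow promoter convention: the transcribed
base is +1, the base immediately upstream is -1, and there is no position 0.
A site occupying TSS-relative positions -52..-31 (22 bp) has its center at
-41.5; half-integer centers arise exactly for even site lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from gencas.alignment import MultipleAlignment
from gencas.annotation_io import GeneRecord, Replicon
from gencas.motifs import MotifModel


@dataclass(frozen=True)
class IntergenicRegion:
    """An intergenic interval with flanking-gene extension.

    ``core`` is the gap between the flanking genes; ``extended`` reaches
    ``extension`` bp into each gene body (clipped only at replicon ends) to
    tolerate mis-annotated start codons.  ``sequence`` covers the extended
    span on the + strand.
    """

    region_id: str
    replicon_id: str
    core_start: int
    core_end: int
    extended_start: int
    extended_end: int
    sequence: str
    upstream_gene: str
    downstream_gene: str


@dataclass(frozen=True)
class TssAnchor:
    """A mapped transcription start with its scan window (default -250/+50)."""

    tss_position: int  # 0-based replicon coordinate of the +1 base
    strand: str
    window_up: int = 250
    window_down: int = 50

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.window_up <= 0 or self.window_down <= 0:
            raise ValueError("window bounds must be positive")

    def to_relative(self, pos: int) -> int:
        """Replicon position (0-based) -> TSS-relative (no zero, +1 = TSS)."""
        d = pos - self.tss_position if self.strand == "+" else self.tss_position - pos
        return d + 1 if d >= 0 else d

    def to_replicon(self, rel: int) -> int:
        """Inverse of :meth:`to_relative`."""
        if rel == 0:
            raise ValueError("TSS-relative coordinates have no position 0")
        d = rel - 1 if rel > 0 else rel
        return self.tss_position + d if self.strand == "+" else self.tss_position - d


@dataclass(frozen=True)
class SiteHit:
    """A PWM hit with TSS-relative span, score and (once ranked) conservation."""

    region_id: str
    strand: str
    span: tuple[int, int]  # TSS-relative, inclusive, span[0] <= span[1]
    center: float
    pwm_score: float
    start: int  # replicon, 0-based half-open
    end: int
    ref_start: int  # offsets into the region's extended sequence
    ref_end: int
    conservation: float = float("nan")
    combined_rank: int = 0


@dataclass(frozen=True)
class ColumnProfile:
    """Per-column conservation of an alignment, on reference coordinates.

    ``identity[i]`` is the fraction of sequences (reference included) whose
    residue in the column of reference position ``i`` equals the reference
    residue; gaps count as mismatches.
    """

    identity: np.ndarray
    residues: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.identity)


def extract_intergenic(
    genes: Sequence[GeneRecord],
    replicon: Replicon,
    min_length: int = 40,
    extension: int = 100,
) -> list[IntergenicRegion]:
    """Intergenic regions of at least ``min_length`` bp between adjacent
    genes, extended ``extension`` bp into the flanking gene bodies."""
    if replicon.sequence is None:
        raise ValueError(f"replicon {replicon.replicon_id!r} has no sequence")
    regions = []
    for a, b in zip(genes, genes[1:]):
        gap = b.start - a.end
        if gap < min_length:
            continue
        ext_start = max(0, a.end - extension)
        ext_end = min(replicon.length, b.start + extension)
        regions.append(
            IntergenicRegion(
                region_id=f"{a.gene_id}/{b.gene_id}",
                replicon_id=replicon.replicon_id,
                core_start=a.end,
                core_end=b.start,
                extended_start=ext_start,
                extended_end=ext_end,
                sequence=replicon.sequence[ext_start:ext_end],
                upstream_gene=a.gene_id,
                downstream_gene=b.gene_id,
            )
        )
    return regions


def conservation_profile(alignment: MultipleAlignment) -> ColumnProfile:
    """Identity fraction per reference column; gap counts as mismatch."""
    ref_cols = alignment.reference_columns()
    n = alignment.n_rows
    identity = np.empty(len(ref_cols))
    residues = []
    for k, c in enumerate(ref_cols):
        ref_ch = alignment.rows[0][c]
        matches = sum(1 for row in alignment.rows if row[c] == ref_ch)
        identity[k] = matches / n
        residues.append(ref_ch)
    return ColumnProfile(identity=identity, residues=tuple(residues))


def scan_pwm(
    region: IntergenicRegion,
    anchor: TssAnchor,
    motif: MotifModel,
    threshold_fraction: float = 0.6,
    threshold_bits: float | None = None,
) -> list[SiteHit]:
    """Score every window of the TSS-anchored scan window on both strands.

    The window spans TSS-relative ``-window_up .. +window_down``, clipped to
    the region's extended span; hits at or above the threshold (by default
    60% of the motif's maximum bit score) are returned sorted by position.
    """
    L = motif.length
    threshold = threshold_bits if threshold_bits is not None else threshold_fraction * motif.max_score
    lo = anchor.to_replicon(-anchor.window_up)
    hi = anchor.to_replicon(anchor.window_down)
    if lo > hi:
        lo, hi = hi, lo
    win_start = max(region.extended_start, lo)
    win_end = min(region.extended_end, hi + 1)  # half-open
    if win_end - win_start < L:
        raise ValueError(
            f"motif ({L} bp) longer than scan window ({win_end - win_start} bp)"
        )
    subseq = region.sequence[win_start - region.extended_start : win_end - region.extended_start]
    hits: list[SiteHit] = []
    for strand in "+-":
        scores = motif.score_all(subseq, reverse=(strand == "-"))
        for k in np.nonzero(scores >= threshold)[0]:
            start = win_start + int(k)
            end = start + L
            rel_a = anchor.to_relative(start)
            rel_b = anchor.to_relative(end - 1)
            first, last = min(rel_a, rel_b), max(rel_a, rel_b)
            hits.append(
                SiteHit(
                    region_id=region.region_id,
                    strand=strand,
                    span=(first, last),
                    center=(first + last) / 2,
                    pwm_score=float(scores[k]),
                    start=start,
                    end=end,
                    ref_start=start - region.extended_start,
                    ref_end=end - region.extended_start,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def rank_sites(hits: Sequence[SiteHit], profile: ColumnProfile) -> list[SiteHit]:
    """Attach conservation and a combined score/conservation rank to hits.

    A hit's conservation is the mean column identity over its span.  Hits are
    ranked separately by PWM score and by conservation (rank 1 = best); the
    combined order is by the sum of the two ranks, ties broken by higher PWM
    score, then by the most upstream position, then by strand.
    """
    if not hits:
        return []
    conserved = []
    for h in hits:
        if h.ref_start < 0 or h.ref_end > len(profile):
            raise ValueError(
                f"hit {h.region_id} span [{h.ref_start},{h.ref_end}) outside "
                f"conservation profile of length {len(profile)}"
            )
        cons = float(profile.identity[h.ref_start : h.ref_end].mean())
        conserved.append(replace(h, conservation=cons))
    scores = np.array([h.pwm_score for h in conserved])
    cons = np.array([h.conservation for h in conserved])
    rank_pwm = rankdata(-scores, method="min")
    rank_cons = rankdata(-cons, method="min")
    order = sorted(
        range(len(conserved)),
        key=lambda i: (
            rank_pwm[i] + rank_cons[i],
            -scores[i],
            conserved[i].span[0],
            conserved[i].strand,
        ),
    )
    ranked = [replace(conserved[i], combined_rank=r + 1) for r, i in enumerate(order)]
    return ranked


def phylogenetic_footprint(
    seqs: Sequence[str],
    anchor: TssAnchor,
    motif: MotifModel,
    region_id: str = "region",
    threshold_fraction: float = 0.6,
    threshold_bits: float | None = None,
) -> tuple[ColumnProfile, list[SiteHit]]:
    """Full footprinting of one ortholog set: align, profile, scan, rank.

    ``seqs[0]`` is the reference region (plus strand); ``anchor`` positions
    the TSS on it.  Returns the conservation profile and the ranked hits.
    """
    from gencas.alignment import align_orthologous_regions

    alignment = align_orthologous_regions(seqs)
    profile = conservation_profile(alignment)
    region = IntergenicRegion(
        region_id=region_id,
        replicon_id=region_id,
        core_start=0,
        core_end=len(seqs[0]),
        extended_start=0,
        extended_end=len(seqs[0]),
        sequence=seqs[0].upper(),
        upstream_gene="",
        downstream_gene="",
    )
    hits = scan_pwm(region, anchor, motif, threshold_fraction, threshold_bits)
    return profile, rank_sites(hits, profile)


def hits_to_frame(hits: Sequence[SiteHit]):
    """Hit table with both replicon (0-based, BED-style) and TSS-relative
    coordinates."""
    import pandas as pd

    rows = [
        {
            "region_id": h.region_id,
            "strand": h.strand,
            "start": h.start,
            "end": h.end,
            "tss_first": h.span[0],
            "tss_last": h.span[1],
            "center": h.center,
            "pwm_score": round(h.pwm_score, 4),
            "conservation": round(h.conservation, 4) if not math.isnan(h.conservation) else "",
            "combined_rank": h.combined_rank,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "region_id", "strand", "start", "end", "tss_first", "tss_last",
            "center", "pwm_score", "conservation", "combined_rank",
        ],
    )
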