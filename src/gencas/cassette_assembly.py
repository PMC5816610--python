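"""Proximity-based cassette assembly.

Genes are chained left to right along the chromosome: a gene joins the
current cassette iff its distance to the previous gene is below ``max_gap``
(strictly — a 299 bp gap joins, a 300 bp gap splits at the default).  Strand
and gene order within the run are ignored; overlapping genes (negative gaps)
always join.  Runs shorter than ``min_genes`` are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from gencas.annotation_io import GeneRecord
from gencas.fingerprint import DEFAULT_ROLE_RULES, Fingerprint, fingerprint_cassette


@dataclass(frozen=True)
class AssemblyParams:
    """Cassette assembly parameters.

    max_gap is an exclusive threshold in bp; min_genes filters short runs;
    circular additionally tests the wrap-around gap and merges the terminal
    runs when it passes.
    """

    max_gap: int = 300
    min_genes: int = 2
    circular: bool = False

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_genes < 1:
            raise ValueError("min_genes must be >= 1")


@dataclass(frozen=True)
class Cassette:
    """A maximal run of adjacent genes satisfying the gap rule."""

    cassette_id: str
    replicon_id: str
    species: str
    taxon_group: str
    genes: tuple[GeneRecord, ...]
    fingerprint: Fingerprint

    def __len__(self) -> int:
        return len(self.genes)


def gene_gap(a: GeneRecord, b: GeneRecord) -> int:
    """Distance in bp between two genes, ``b.start - a.end``.

    Measured on chromosome coordinates regardless of strand; negative when
    the genes overlap.  ``a`` must not start after ``b``.
    """
    if a.replicon_id != b.replicon_id:
        raise ValueError(
            f"genes on different replicons: {a.replicon_id!r} vs {b.replicon_id!r}"
        )
    if a.start > b.start:
        raise ValueError("gene_gap requires a.start <= b.start")
    return b.start - a.end


def assemble_cassettes(
    genes: Sequence[GeneRecord],
    params: AssemblyParams = AssemblyParams(),
    role_rules: Mapping = DEFAULT_ROLE_RULES,
    replicon_length: int | None = None,
) -> list[Cassette]:
    """Partition a sorted gene list into cassettes by the proximity rule.

    ``replicon_length`` is only consulted for circular wrap-around testing.
    Cassette ids are ``<replicon>:cas<k>`` numbered left to right.
    """
    genes = list(genes)
    for prev, cur in zip(genes, genes[1:]):
        if cur.start < prev.start:
            raise ValueError("genes must be sorted by start coordinate")
    if not genes:
        return []

    runs: list[list[GeneRecord]] = [[genes[0]]]
    for prev, cur in zip(genes, genes[1:]):
        if gene_gap(prev, cur) < params.max_gap:
            runs[-1].append(cur)
        else:
            runs.append([cur])

    if params.circular and len(runs) > 1 and replicon_length:
        last, first = runs[-1][-1], runs[0][0]
        wrap_gap = (replicon_length - last.end) + first.start
        if wrap_gap < params.max_gap:
            runs[0] = runs.pop() + runs[0]

    cassettes = []
    k = 0
    for run in runs:
        if len(run) < params.min_genes:
            continue
        k += 1
        g0 = run[0]
        cassettes.append(
            Cassette(
                cassette_id=f"{g0.replicon_id}:cas{k}",
                replicon_id=g0.replicon_id,
                species=g0.species,
                taxon_group=g0.taxon_group,
                genes=tuple(run),
                fingerprint=fingerprint_cassette(run, role_rules),
            )
        )
    return cassettes


def cassettes_to_frame(cassettes: Sequence[Cassette]):
    """Cassette database as a DataFrame: one row per cassette.

    Gene lists and label lists are semicolon-joined so the table round-trips
    through TSV.
    """
    import pandas as pd

    rows = []
    for c in cassettes:
        rows.append(
            {
                "cassette_id": c.cassette_id,
                "replicon_id": c.replicon_id,
                "species": c.species,
                "taxon_group": c.taxon_group,
                "n_genes": len(c.genes),
                "genes": ";".join(g.gene_id for g in c.genes),
                "labels": ";".join(
                    ",".join(str(l) for l in sorted(labels)) for labels in c.fingerprint.gene_labels
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cassette_id", "replicon_id", "species", "taxon_group", "n_genes", "genes", "labels"],
    )
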