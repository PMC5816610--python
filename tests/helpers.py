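"""Shared builders for test instances."""

from gencas.annotation_io import GeneRecord
from gencas.fingerprint import FunctionLabel

LABEL_POOL = [
    {FunctionLabel("ec3", "3.2.1")},
    {FunctionLabel("ec3", "4.1.2")},
    {FunctionLabel("ec3", "2.7.1")},
    {FunctionLabel("ec3", "2.3.1")},
    {FunctionLabel("ec3", "5.1.3")},
    {FunctionLabel("role", "transporter")},
    {FunctionLabel("role", "transcription_factor")},
    {FunctionLabel("cog", "COG3684")},
    {FunctionLabel("ec3", "4.1.2"), FunctionLabel("cog", "COG3684")},
    set(),
]


def make_gene(
    gene_id: str,
    start: int,
    end: int,
    strand: str = "+",
    replicon_id: str = "chr",
    **kw,
) -> GeneRecord:
    return GeneRecord(
        gene_id=gene_id,
        locus_tag=gene_id,
        replicon_id=replicon_id,
        species=kw.pop("species", "Test species"),
        taxon_group=kw.pop("taxon_group", "TestGroup"),
        start=start,
        end=end,
        strand=strand,
        **kw,
    )


def random_gene_list(rng, n_genes: int, replicon_id: str = "chr") -> list[GeneRecord]:
    """Random annotation with gaps concentrated around the 300 bp threshold
    (including exact 299/300 gaps and overlaps)."""
    genes = []
    cursor = int(rng.integers(0, 500))
    for i in range(n_genes):
        length = int(rng.integers(100, 900))
        genes.append(make_gene(f"g{i + 1}", cursor, cursor + length, replicon_id=replicon_id))
        gap_kind = rng.random()
        if gap_kind < 0.15:
            gap = 299
        elif gap_kind < 0.3:
            gap = 300
        elif gap_kind < 0.4:
            gap = -int(rng.integers(1, min(80, length)))
        else:
            gap = int(rng.integers(0, 700))
        cursor = cursor + length + gap
        cursor = max(cursor, genes[-1].start + 1)  # keep start order
    return genes
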