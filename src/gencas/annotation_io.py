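"""Reading annotated replicons and writing result tables.

Internal coordinates are 0-based half-open ``[start, end)`` on the forward
strand, regardless of the input format's convention (GFF3 and GenBank are
1-based inclusive on disk).  All downstream gap and interval arithmetic relies
on this convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


class AnnotationError(ValueError):
    """Raised when an annotation file cannot be parsed or is inconsistent."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene (coding feature) on a replicon.

    ``start``/``end`` are 0-based half-open; ``strand`` is ``'+'`` or ``'-'``.
    ``ec_numbers`` may contain partial EC strings with ``-`` placeholders, as
    found in genome annotations.
    """

    gene_id: str
    locus_tag: str
    replicon_id: str
    species: str
    taxon_group: str
    start: int
    end: int
    strand: str
    product: str = ""
    ec_numbers: tuple[str, ...] = ()
    cog: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Replicon:
    """A DNA molecule carrying genes; sequence is optional."""

    replicon_id: str
    species: str = ""
    taxon_group: str = ""
    length: int = 0
    sequence: str | None = None
    topology: str = "linear"

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValueError("topology must be 'linear' or 'circular'")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"replicon {self.replicon_id!r}: sequence length "
                f"{len(self.sequence)} != declared length {self.length}"
            )


_GENE_FEATURE_TYPES = ("CDS", "gene")


def read_annotation(
    path: str | Path,
    fmt: str | None = None,
    fasta: str | Path | None = None,
    species: str | None = None,
    taxon_group: str | None = None,
) -> tuple[Replicon, list[GeneRecord]]:
    """Read one annotated replicon into a uniform gene table.

    Parameters
    ----------
    path
        GenBank flat file or GFF3 file.
    fmt
        ``"genbank"`` or ``"gff3"``; inferred from the suffix when ``None``.
    fasta
        FASTA with the replicon sequence; required alongside GFF3 when the
        sequence is needed downstream (GenBank files embed their sequence).
    species, taxon_group
        Override/declare organism metadata (GFF3 has no standard slot for a
        taxonomic group; the simulator stores both in ``##species`` /
        ``##taxon-group`` pragmas which are honoured here).

    Returns
    -------
    (replicon, genes) with genes sorted by start coordinate.  Where both a
    ``gene`` and a ``CDS`` feature share a locus_tag, the CDS coordinates win.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix in (".gb", ".gbk", ".gbff", ".genbank"):
            fmt = "genbank"
        elif suffix in (".gff", ".gff3"):
            fmt = "gff3"
        else:
            raise AnnotationError(f"cannot infer format from suffix {suffix!r}")
    if fmt == "genbank":
        replicon, genes = _read_genbank(path)
    elif fmt == "gff3":
        replicon, genes = _read_gff3(path, fasta)
    else:
        raise AnnotationError(f"unknown format {fmt!r}")

    if species or taxon_group:
        replicon = replace(
            replicon,
            species=species or replicon.species,
            taxon_group=taxon_group or replicon.taxon_group,
        )
        genes = [
            replace(
                g,
                species=species or g.species,
                taxon_group=taxon_group or g.taxon_group,
            )
            for g in genes
        ]
    genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise AnnotationError(f"duplicate gene_id {g.gene_id!r} in {path.name}")
        seen.add(g.gene_id)
        if replicon.length and g.end > replicon.length:
            raise AnnotationError(
                f"gene {g.gene_id!r} extends past replicon end ({g.end} > {replicon.length})"
            )
    return replicon, genes


def _read_genbank(path: Path) -> tuple[Replicon, list[GeneRecord]]:
    from Bio import SeqIO

    try:
        record = next(SeqIO.parse(str(path), "genbank"))
    except (StopIteration, ValueError) as exc:
        raise AnnotationError(f"cannot parse GenBank file {path}: {exc}") from exc

    species = record.annotations.get("organism", "") or record.annotations.get("source", "")
    taxonomy = record.annotations.get("taxonomy", [])
    taxon_group = taxonomy[-1] if taxonomy else ""
    topology = record.annotations.get("topology", "linear")
    if topology not in ("linear", "circular"):
        topology = "linear"
    sequence = str(record.seq).upper() if len(record.seq) else None
    replicon = Replicon(
        replicon_id=record.id,
        species=species,
        taxon_group=taxon_group,
        length=len(record.seq),
        sequence=sequence,
        topology=topology,
    )

    raw: dict[str, dict] = {}
    for feat in record.features:
        if feat.type not in _GENE_FEATURE_TYPES:
            continue
        quals = feat.qualifiers
        locus = (quals.get("locus_tag") or quals.get("gene") or [""])[0]
        key = locus or f"{feat.type}_{int(feat.location.start)}"
        entry = raw.setdefault(key, {"gene": None, "CDS": None})
        entry[feat.type] = feat
    genes: list[GeneRecord] = []
    for key, entry in raw.items():
        feat = entry["CDS"] or entry["gene"]
        quals = feat.qualifiers
        ec = tuple(quals.get("EC_number", ()))
        cog_vals = quals.get("db_xref", [])
        cog = next((x.split(":", 1)[1] for x in cog_vals if x.upper().startswith("COG:")), None)
        genes.append(
            GeneRecord(
                gene_id=key,
                locus_tag=key,
                replicon_id=replicon.replicon_id,
                species=replicon.species,
                taxon_group=replicon.taxon_group,
                start=int(feat.location.start),
                end=int(feat.location.end),
                strand="+" if feat.location.strand != -1 else "-",
                product=(quals.get("product") or [""])[0],
                ec_numbers=ec,
                cog=cog,
            )
        )
    return replicon, genes


def _read_gff3(path: Path, fasta: str | Path | None) -> tuple[Replicon, list[GeneRecord]]:
    import gffutils

    pragmas = {"species": "", "taxon-group": ""}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            parts = line[2:].strip().split(None, 1)
            if len(parts) == 2 and parts[0] in pragmas:
                pragmas[parts[0]] = parts[1]

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:
        raise AnnotationError(f"cannot parse GFF3 file {path}: {exc}") from exc

    sequence = None
    length = 0
    replicon_id = ""
    if fasta is not None:
        from Bio import SeqIO

        fasta = Path(fasta)
        if not fasta.exists():
            raise AnnotationError(f"GFF3 companion FASTA not found: {fasta}")
        rec = next(SeqIO.parse(str(fasta), "fasta"))
        sequence = str(rec.seq).upper()
        length = len(sequence)
        replicon_id = rec.id

    raw: dict[str, dict] = {}
    for ftype in _GENE_FEATURE_TYPES:
        for feat in db.features_of_type(ftype):
            locus = feat.attributes.get("locus_tag", [feat.id])[0]
            entry = raw.setdefault(locus, {"gene": None, "CDS": None})
            entry[ftype] = feat
            replicon_id = replicon_id or feat.seqid
    if not raw:
        raise AnnotationError(f"no gene/CDS features in {path}")

    # sequence-region pragma supplies length when no FASTA is given
    if length == 0:
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    parts = line.split()
                    if len(parts) >= 4:
                        length = int(parts[3])
                    break

    replicon = Replicon(
        replicon_id=replicon_id,
        species=pragmas["species"],
        taxon_group=pragmas["taxon-group"],
        length=length or max(f["CDS"].end if f["CDS"] else f["gene"].end for f in raw.values()),
        sequence=sequence,
        topology="linear",
    )
    genes: list[GeneRecord] = []
    for locus, entry in raw.items():
        feat = entry["CDS"] or entry["gene"]
        attrs = feat.attributes
        ec = tuple(attrs.get("ec_number", ())) or tuple(attrs.get("EC_number", ()))
        cog = (attrs.get("cog") or attrs.get("COG") or [None])[0]
        genes.append(
            GeneRecord(
                gene_id=locus,
                locus_tag=locus,
                replicon_id=replicon.replicon_id,
                species=replicon.species,
                taxon_group=replicon.taxon_group,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                strand="-" if feat.strand == "-" else "+",
                product=(attrs.get("product") or [""])[0],
                ec_numbers=ec,
                cog=cog,
            )
        )
    return replicon, genes


def genes_to_frame(genes: Iterable[GeneRecord]) -> pd.DataFrame:
    """Gene records as a DataFrame (EC numbers comma-joined)."""
    rows = [
        {
            "gene_id": g.gene_id,
            "locus_tag": g.locus_tag,
            "replicon_id": g.replicon_id,
            "species": g.species,
            "taxon_group": g.taxon_group,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "product": g.product,
            "ec_numbers": ",".join(g.ec_numbers),
            "cog": g.cog or "",
        }
        for g in genes
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "locus_tag",
            "replicon_id",
            "species",
            "taxon_group",
            "start",
            "end",
            "strand",
            "product",
            "ec_numbers",
            "cog",
        ],
    )


def frame_to_genes(frame: pd.DataFrame) -> list[GeneRecord]:
    """Inverse of :func:`genes_to_frame`."""
    genes = []
    for row in frame.itertuples(index=False):
        ec = tuple(s for s in str(row.ec_numbers).split(",") if s) if pd.notna(row.ec_numbers) else ()
        cog = str(row.cog) if pd.notna(row.cog) and str(row.cog) else None
        genes.append(
            GeneRecord(
                gene_id=str(row.gene_id),
                locus_tag=str(row.locus_tag),
                replicon_id=str(row.replicon_id),
                species=str(row.species) if pd.notna(row.species) else "",
                taxon_group=str(row.taxon_group) if pd.notna(row.taxon_group) else "",
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                product=str(row.product) if pd.notna(row.product) else "",
                ec_numbers=ec,
                cog=cog,
            )
        )
    return genes


def write_table(records, path: str | Path) -> None:
    """Write any tabular result as tab-delimited text with a header row.

    Accepts a DataFrame, a sequence of dicts, or a sequence of GeneRecord.
    """
    if records is None:
        raise ValueError("records must not be None")
    if isinstance(records, pd.DataFrame):
        frame = records
    elif isinstance(records, Sequence) and records and isinstance(records[0], GeneRecord):
        frame = genes_to_frame(records)
    else:
        frame = pd.DataFrame(list(records))
    path = Path(path)
    os.makedirs(path.parent, exist_ok=True) if str(path.parent) not in ("", ".") else None
    frame.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
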