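"""Packaged fixtures: the yih / lac cassette encodings and the CRP motif.

The cassette file is a synthetic reconstruction of the two
carbohydrate-utilisation cassettes (sulphoquinovose degradation in
Enterobacteriaceae, lactose catabolism in Bacilli) with the published
per-gene function labels; labels are read verbatim from the file, never
re-derived from the product text.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from gencas.annotation_io import GeneRecord
from gencas.cassette_assembly import Cassette
from gencas.fingerprint import Fingerprint, FunctionLabel
from gencas.motifs import MotifModel

CASSETTE_FIXTURE = "yih_lac_cassettes.yaml"
CRP_MOTIF_FIXTURE = "crp_consensus.txt"

_GENE_LENGTH = 900
_GENE_GAP = 100  # below the 300 bp cassette threshold


def _data_path(name: str) -> Path:
    return Path(str(resources.files("gencas").joinpath("data", name)))


def load_cassette_fixtures(path: str | Path | None = None) -> list[Cassette]:
    """The packaged cassette database (or one in the same YAML schema)."""
    path = Path(path) if path is not None else _data_path(CASSETTE_FIXTURE)
    spec = yaml.safe_load(path.read_text())
    cassettes = []
    for entry in spec["cassettes"]:
        genes = []
        label_sets = []
        pos = 0
        for gspec in entry["genes"]:
            genes.append(
                GeneRecord(
                    gene_id=gspec["gene_id"],
                    locus_tag=gspec["gene_id"],
                    replicon_id=entry["replicon_id"],
                    species=entry["species"],
                    taxon_group=entry["taxon_group"],
                    start=pos,
                    end=pos + _GENE_LENGTH,
                    strand="+",
                    product=gspec.get("product", ""),
                )
            )
            label_sets.append(
                frozenset(FunctionLabel.parse(t) for t in gspec.get("labels", ()))
            )
            pos += _GENE_LENGTH + _GENE_GAP
        cassettes.append(
            Cassette(
                cassette_id=entry["cassette_id"],
                replicon_id=entry["replicon_id"],
                species=entry["species"],
                taxon_group=entry["taxon_group"],
                genes=tuple(genes),
                fingerprint=Fingerprint(tuple(label_sets)),
            )
        )
    return cassettes


def fixture_cassette(cassette_id: str) -> Cassette:
    for c in load_cassette_fixtures():
        if c.cassette_id == cassette_id:
            return c
    raise KeyError(cassette_id)


def load_crp_motif() -> MotifModel:
    """The default CRP position weight matrix (from the packaged consensus)."""
    return MotifModel.from_file(_data_path(CRP_MOTIF_FIXTURE), name="CRP")
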