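"""Functional fingerprints: truncated EC labels, role labels, COG labels.

Enzymes are grouped by reaction type via the first three fields of the
Enzyme Commission code (class.subclass.sub-subclass); transport and
regulatory proteins, which carry no EC number, are labelled by
keyword-derived roles; COG identifiers refine matches when annotated on
both sides.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from gencas.annotation_io import GeneRecord

_KIND_ORDER = {"ec3": 0, "cog": 1, "role": 2}
_EC3_RE = re.compile(r"^\d+\.\d+\.\d+$")


@dataclass(frozen=True, order=True)
class FunctionLabel:
    """One function label of kind ``ec3``, ``cog`` or ``role``.

    Ordering is lexicographic on (kind, value) so label multisets sort
    deterministically; matching priority between kinds is handled separately
    (see :func:`gencas.cassette_compare.gene_compatible`).
    """

    kind: str
    value: str

    def __post_init__(self) -> None:
        if self.kind not in _KIND_ORDER:
            raise ValueError(f"unknown label kind {self.kind!r}")
        if self.kind == "ec3" and not _EC3_RE.match(self.value):
            raise ValueError(f"ec3 label must be three numeric fields, got {self.value!r}")

    def __str__(self) -> str:  # e.g. "ec3:4.1.2"
        return f"{self.kind}:{self.value}"

    @classmethod
    def parse(cls, text: str) -> "FunctionLabel":
        kind, _, value = text.partition(":")
        return cls(kind, value)


@dataclass(frozen=True)
class Fingerprint:
    """Per-gene label sets of a cassette, in gene order."""

    gene_labels: tuple[frozenset[FunctionLabel], ...]

    def __len__(self) -> int:
        return len(self.gene_labels)

    def __getitem__(self, i: int) -> frozenset[FunctionLabel]:
        return self.gene_labels[i]

    def all_labels(self) -> list[FunctionLabel]:
        """All labels over all genes, sorted (a multiset in list form)."""
        out: list[FunctionLabel] = []
        for labels in self.gene_labels:
            out.extend(labels)
        return sorted(out)


#: Default keyword rules mapping product-text substrings to roles.  The
#: regulator-family names cover the DeoR/LacI/GntR/AraC/TetR/ROK families
#: typical of carbohydrate-utilisation loci.  Fully overridable via config.
DEFAULT_ROLE_RULES: dict[str, tuple[str, ...]] = {
    "transporter": ("transporter", "permease", "PTS", "symporter"),
    "transcription_factor": (
        "transcriptional regulator",
        "transcription factor",
        "repressor",
        "activator",
        "DeoR",
        "LacI",
        "GntR",
        "AraC",
        "TetR",
        "ROK",
    ),
}


def truncate_ec(ec: str) -> FunctionLabel | None:
    """Truncate an EC number to its first three fields.

    Returns an ``ec3`` label when the class, subclass and sub-subclass fields
    are all numeric; returns ``None`` when any of the three is missing or a
    ``-`` placeholder.  Total function: never raises on odd input.

    >>> str(truncate_ec("4.1.2.17"))
    'ec3:4.1.2'
    >>> truncate_ec("2.7.-.-") is None
    True
    """
    fields = ec.strip().split(".")
    if len(fields) < 3:
        return None
    head = fields[:3]
    if not all(f.isdigit() for f in head):
        return None
    return FunctionLabel("ec3", ".".join(head))


def assign_roles(
    product: str,
    role_rules: Mapping[str, Sequence[str]] = DEFAULT_ROLE_RULES,
) -> frozenset[FunctionLabel]:
    """Assign role labels by case-insensitive substring match on product text."""
    text = product.lower()
    hits = {
        FunctionLabel("role", role)
        for role, keywords in role_rules.items()
        if any(kw.lower() in text for kw in keywords)
    }
    return frozenset(hits)


def gene_labels(
    gene: GeneRecord,
    role_rules: Mapping[str, Sequence[str]] = DEFAULT_ROLE_RULES,
) -> frozenset[FunctionLabel]:
    """Union of truncated-EC, role and COG labels for one gene."""
    labels: set[FunctionLabel] = set()
    for ec in gene.ec_numbers:
        lab = truncate_ec(ec)
        if lab is not None:
            labels.add(lab)
    labels |= assign_roles(gene.product, role_rules)
    if gene.cog:
        labels.add(FunctionLabel("cog", gene.cog))
    return frozenset(labels)


def fingerprint_cassette(
    genes: Iterable[GeneRecord],
    role_rules: Mapping[str, Sequence[str]] = DEFAULT_ROLE_RULES,
) -> Fingerprint:
    """Fingerprint of a cassette: one label-set per gene, in gene order."""
    return Fingerprint(tuple(gene_labels(g, role_rules) for g in genes))
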