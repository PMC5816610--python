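"""Synthetic data with recorded ground truth.

Three generators replace the external inputs of the pipeline:

* :func:`simulate_genomes` — annotated linear replicons (GFF3 + FASTA) whose
  intergenic gaps follow a configurable two-component mixture (a short
  component below the cassette threshold and a long component above it), with
  function-labelled cassettes planted as contiguous runs flanked by long
  gaps;
* :func:`simulate_ortholog_regions` — sets of orthologous intergenic
  sequences diverged from a common reference by independent per-site
  substitution (star phylogeny centred on the reference), with a motif
  planted under stronger conservation at a TSS-relative span;
* :func:`simulate_ct_table` — qPCR Ct tables with planted fold changes and
  Gaussian technical noise.

Every generator is deterministic given its seed and returns ground truth
sufficient to score recovery without re-deriving it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from gencas.annotation_io import GeneRecord, Replicon
from gencas.fingerprint import FunctionLabel
from gencas.motifs import CRP_CONSENSUS, IUPAC
from gencas.regulatory import TssAnchor

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class GapMixture:
    """Two-component intergenic gap mixture (bp).

    ``frac_short`` of gaps fall in ``short_range`` (below the 300 bp cassette
    threshold), the rest in ``long_range``; both ranges inclusive.
    """

    frac_short: float = 0.6
    short_range: tuple[int, int] = (1, 299)
    long_range: tuple[int, int] = (300, 1500)

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_short <= 1.0:
            raise ValueError("frac_short must be in [0, 1]")


@dataclass(frozen=True)
class PlantedCassette:
    """A cassette to plant: per-gene label sets (as ``kind:value`` strings)
    and the taxon groups whose replicons receive a copy."""

    fingerprint: tuple[tuple[str, ...], ...]
    groups: tuple[str, ...]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for all three generators."""

    seed: int = 0
    # genomes
    n_species: int = 4
    genes_per_replicon: int = 40
    taxon_groups: tuple[str, ...] = ("Enterobacteriaceae", "Bacilli")
    gap_mixture: GapMixture = GapMixture()
    gene_length_range: tuple[int, int] = (300, 900)
    planted_cassettes: tuple[PlantedCassette, ...] = ()
    background_label_prob: float = 0.5
    # ortholog regions
    n_orthologs: int = 6
    region_length: int = 300
    divergence_outside: float = 0.2
    divergence_inside: float = 0.02
    motif_consensus: str = CRP_CONSENSUS
    planted_span_tss: tuple[int, int] = (-49, -34)
    tss_offset_from_end: int = 51
    indel_rate: float = 0.0
    # ct tables
    ct_genes: tuple[str, ...] = ("yihT", "yihS", "yihV")
    ct_conditions: tuple[str, ...] = ("glucose", "lactose")
    true_folds: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "yihT": {"lactose": 4.0},
            "yihS": {"lactose": 0.5},
            "yihV": {"lactose": 1.0},
        }
    )
    reference_genes: tuple[str, ...] = ("hns", "ysaA")
    n_replicates: int = 9  # three biological x three technical, flattened
    ct_noise_sd: float = 0.2


#: Background annotation pool the simulator draws from; includes the six
#: labels of the carbohydrate-cassette study so simulated databases and the
#: packaged fixtures interoperate.
BACKGROUND_POOL: tuple[tuple[str, ...], ...] = (
    ("ec3:3.2.1",),
    ("ec3:4.1.2",),
    ("ec3:2.7.1",),
    ("ec3:2.3.1",),
    ("ec3:5.1.3",),
    ("ec3:1.1.1",),
    ("ec3:2.7.7",),
    ("ec3:5.3.1",),
    ("role:transporter",),
    ("role:transcription_factor",),
)

_ROLE_PRODUCTS = {
    "transporter": "sugar ABC transporter permease",
    "transcription_factor": "DeoR-family transcriptional regulator",
}


# ---------------------------------------------------------------------------
# genomes

@dataclass(frozen=True)
class PlantedCassetteTruth:
    species: str
    taxon_group: str
    replicon_id: str
    gene_ids: tuple[str, ...]
    fingerprint: tuple[tuple[str, ...], ...]


@dataclass
class GenomeGroundTruth:
    species: list[str]
    replicons: dict[str, Replicon]
    genes: dict[str, list[GeneRecord]]  # per species, sorted by start
    planted: list[PlantedCassetteTruth]
    gaps: dict[str, list[int]]  # realised intergenic gaps per species


def _labels_to_annotation(labels: Sequence[str], rng: np.random.Generator) -> dict:
    """Render ``kind:value`` labels as EC numbers / product text / COG."""
    ec, cog, products = [], None, []
    for text in labels:
        lab = FunctionLabel.parse(text)
        if lab.kind == "ec3":
            ec.append(f"{lab.value}.{rng.integers(1, 40)}")
        elif lab.kind == "cog":
            cog = lab.value
        else:
            products.append(_ROLE_PRODUCTS[lab.value])
    product = "; ".join(products) if products else ""
    if not product:
        product = "putative enzyme" if ec else "hypothetical protein"
    return {"ec_numbers": tuple(ec), "cog": cog, "product": product}


def simulate_genomes(
    config: SimConfig, outdir: str | Path | None = None
) -> GenomeGroundTruth:
    """Simulate annotated replicons; optionally write GFF3 + FASTA files.

    Species are assigned round-robin to ``taxon_groups``.  Each planted
    cassette is inserted once per replicon of its groups, as a contiguous run
    with internal gaps drawn below the threshold and flanking gaps above it;
    background gaps follow the configured mixture.
    """
    rng = np.random.default_rng(config.seed)
    mix = config.gap_mixture
    truth = GenomeGroundTruth(species=[], replicons={}, genes={}, planted=[], gaps={})

    for s in range(config.n_species):
        species = f"Species_{s + 1:02d}"
        group = config.taxon_groups[s % len(config.taxon_groups)]
        replicon_id = f"sim_{s + 1:02d}"
        planted_here = [p for p in config.planted_cassettes if group in p.groups]

        # gene skeleton: list of (labels, planted_index) entries in order
        n_background = config.genes_per_replicon
        entries: list[tuple[tuple[str, ...], int]] = []
        for _ in range(n_background):
            if rng.random() < config.background_label_prob:
                labels = BACKGROUND_POOL[rng.integers(len(BACKGROUND_POOL))]
            else:
                labels = ()
            entries.append((labels, -1))
        # insertion points for planted blocks, never adjacent to each other
        positions = sorted(
            rng.choice(n_background + 1, size=len(planted_here), replace=False),
            reverse=True,
        )
        blocks: list[tuple[int, int]] = []  # (entry index range) after insertion
        for p_idx, pos in enumerate(positions):
            block = [(labels, p_idx) for labels in planted_here[p_idx].fingerprint]
            entries[pos:pos] = block

        lo_len, hi_len = config.gene_length_range
        gaps_realised: list[int] = []
        genes: list[GeneRecord] = []
        cursor = int(rng.integers(200, 600))
        prev_planted = None
        for gi, (labels, p_idx) in enumerate(entries):
            if gi > 0:
                same_block = p_idx != -1 and p_idx == prev_planted
                boundary = (p_idx != -1) != (prev_planted != -1) or (
                    p_idx != -1 and prev_planted != -1 and p_idx != prev_planted
                )
                if same_block:
                    gap = int(rng.integers(1, 300))
                elif boundary:
                    gap = int(rng.integers(mix.long_range[0], mix.long_range[1] + 1))
                elif rng.random() < mix.frac_short:
                    gap = int(rng.integers(mix.short_range[0], mix.short_range[1] + 1))
                else:
                    gap = int(rng.integers(mix.long_range[0], mix.long_range[1] + 1))
                gaps_realised.append(gap)
                cursor += gap
            length = int(rng.integers(lo_len, hi_len + 1))
            ann = _labels_to_annotation(labels, rng)
            genes.append(
                GeneRecord(
                    gene_id=f"{replicon_id}_g{gi + 1:04d}",
                    locus_tag=f"{replicon_id}_g{gi + 1:04d}",
                    replicon_id=replicon_id,
                    species=species,
                    taxon_group=group,
                    start=cursor,
                    end=cursor + length,
                    strand="+" if rng.random() < 0.5 else "-",
                    **ann,
                )
            )
            cursor += length
            prev_planted = p_idx

        length_total = cursor + int(rng.integers(200, 600))
        seq = rng.choice(BASES, size=length_total).tobytes().decode()
        replicon = Replicon(
            replicon_id=replicon_id,
            species=species,
            taxon_group=group,
            length=length_total,
            sequence=seq,
            topology="linear",
        )
        truth.species.append(species)
        truth.replicons[species] = replicon
        truth.genes[species] = genes
        truth.gaps[species] = gaps_realised
        for p_idx, planted in enumerate(planted_here):
            gene_ids = tuple(
                g.gene_id for g, (_, idx) in zip(genes, entries) if idx == p_idx
            )
            truth.planted.append(
                PlantedCassetteTruth(
                    species=species,
                    taxon_group=group,
                    replicon_id=replicon_id,
                    gene_ids=gene_ids,
                    fingerprint=planted.fingerprint,
                )
            )

    if outdir is not None:
        write_simulated_genomes(truth, outdir)
    return truth


def write_simulated_genomes(truth: GenomeGroundTruth, outdir: str | Path) -> dict[str, tuple[Path, Path]]:
    """Write one GFF3 + FASTA pair per species plus a ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for species in truth.species:
        replicon = truth.replicons[species]
        genes = truth.genes[species]
        gff = outdir / f"{species}.gff3"
        fna = outdir / f"{species}.fna"
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##species {species}\n")
            fh.write(f"##taxon-group {replicon.taxon_group}\n")
            fh.write(f"##sequence-region {replicon.replicon_id} 1 {replicon.length}\n")
            for g in genes:
                attrs = [f"ID={g.gene_id}", f"locus_tag={g.locus_tag}", f"product={g.product}"]
                for ec in g.ec_numbers:
                    attrs.append(f"ec_number={ec}")
                if g.cog:
                    attrs.append(f"cog={g.cog}")
                fh.write(
                    "\t".join(
                        [
                            replicon.replicon_id,
                            "gencas-sim",
                            "CDS",
                            str(g.start + 1),  # GFF3 is 1-based inclusive
                            str(g.end),
                            ".",
                            g.strand,
                            "0",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )
        with open(fna, "w") as fh:
            fh.write(f">{replicon.replicon_id}\n")
            seq = replicon.sequence or ""
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
        paths[species] = (gff, fna)
    sidecar = {
        "planted": [
            {
                "species": p.species,
                "taxon_group": p.taxon_group,
                "replicon_id": p.replicon_id,
                "gene_ids": list(p.gene_ids),
                "fingerprint": [list(fs) for fs in p.fingerprint],
            }
            for p in truth.planted
        ]
    }
    (outdir / "ground_truth.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# ortholog regions

@dataclass
class OrthologGroundTruth:
    sequences: list[str]  # first is the reference (un-mutated ancestor)
    anchor: TssAnchor
    planted_span_region: tuple[int, int]  # half-open, region coordinates
    planted_span_tss: tuple[int, int]  # inclusive, TSS-relative
    planted_center: float
    motif_instance: str
    homology: list[dict[int, int | None]]  # reference pos -> ortholog pos


def _realise_consensus(consensus: str, rng: np.random.Generator) -> str:
    return "".join(
        ch if len(IUPAC[ch]) == 1 else IUPAC[ch][rng.integers(len(IUPAC[ch]))]
        for ch in consensus.upper()
    )


def simulate_ortholog_regions(config: SimConfig) -> OrthologGroundTruth:
    """Orthologous intergenic regions with a planted, conserved motif.

    The reference (first sequence) is the common ancestor itself; every other
    ortholog substitutes each site independently with probability
    ``divergence_outside`` (``divergence_inside`` within the planted motif).
    Optional indels (never inside the motif) at ``indel_rate`` per site.  The
    TSS sits ``tss_offset_from_end`` bp before the region end on the +
    strand, and the motif occupies ``planted_span_tss``.
    """
    rng = np.random.default_rng(config.seed)
    L = config.region_length
    tss_index = L - config.tss_offset_from_end
    anchor = TssAnchor(tss_position=tss_index, strand="+")
    first, last = config.planted_span_tss
    start = anchor.to_replicon(first)
    end = anchor.to_replicon(last) + 1
    if not (0 <= start < end <= L):
        raise ValueError("planted motif span falls outside the region")
    motif = _realise_consensus(config.motif_consensus, rng)
    if len(motif) != end - start:
        raise ValueError(
            f"planted span ({end - start} bp) does not fit motif ({len(motif)} bp)"
        )

    ancestor = np.empty(L, dtype=np.uint8)
    ancestor[:] = rng.choice(BASES, size=L)
    ancestor[start:end] = np.frombuffer(motif.encode(), dtype=np.uint8)

    inside = np.zeros(L, dtype=bool)
    inside[start:end] = True
    rate = np.where(inside, config.divergence_inside, config.divergence_outside)

    seqs = [ancestor.tobytes().decode()]
    homology: list[dict[int, int | None]] = [{i: i for i in range(L)}]
    for _ in range(config.n_orthologs - 1):
        mutated = ancestor.copy()
        hit = rng.random(L) < rate
        if hit.any():
            # substitute with one of the three other bases, uniformly
            shift = rng.integers(1, 4, size=int(hit.sum()))
            idx = np.nonzero(hit)[0]
            base_idx = np.searchsorted(BASES, mutated[idx])
            mutated[idx] = BASES[(base_idx + shift) % 4]
        if config.indel_rate > 0:
            chars: list[str] = []
            mapping: dict[int, int | None] = {}
            pos = 0
            for i in range(L):
                r = rng.random()
                if not inside[i] and r < config.indel_rate / 2:
                    mapping[i] = None  # deletion
                    continue
                if not inside[i] and r < config.indel_rate:
                    ins = rng.choice(BASES, size=int(rng.integers(1, 4)))
                    chars.append(ins.tobytes().decode())
                    pos += len(ins)
                mapping[i] = pos
                chars.append(chr(mutated[i]))
                pos += 1
            seqs.append("".join(chars))
            homology.append(mapping)
        else:
            seqs.append(mutated.tobytes().decode())
            homology.append({i: i for i in range(L)})

    return OrthologGroundTruth(
        sequences=seqs,
        anchor=anchor,
        planted_span_region=(start, end),
        planted_span_tss=(first, last),
        planted_center=(first + last) / 2,
        motif_instance=motif,
        homology=homology,
    )


def write_ortholog_fasta(truth: OrthologGroundTruth, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, seq in enumerate(truth.sequences):
            name = "reference" if k == 0 else f"ortholog_{k}"
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Ct tables

def simulate_ct_table(config: SimConfig) -> pd.DataFrame:
    """Ct table with planted fold changes.

    Reference genes keep a constant expected Ct across conditions; a target
    gene's Ct in a condition is shifted by ``-log2(fold)`` relative to the
    first (reference) condition.  Gaussian noise of ``ct_noise_sd`` cycles is
    added to every measurement.
    """
    rng = np.random.default_rng(config.seed)
    base_ct = {g: float(rng.uniform(20.0, 26.0)) for g in config.ct_genes}
    base_ct.update({g: float(rng.uniform(14.0, 18.0)) for g in config.reference_genes})
    rows = []
    for gene in list(config.ct_genes) + list(config.reference_genes):
        is_ref = gene in config.reference_genes
        for condition in config.ct_conditions:
            fold = 1.0
            if not is_ref:
                fold = float(config.true_folds.get(gene, {}).get(condition, 1.0))
            shift = -np.log2(fold)
            for rep in range(1, config.n_replicates + 1):
                noise = float(rng.normal(0.0, config.ct_noise_sd)) if config.ct_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "gene": gene,
                        "condition": condition,
                        "replicate": f"r{rep}",
                        "ct": base_ct[gene] + shift + noise,
                        "is_reference": is_ref,
                    }
                )
    return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct", "is_reference"])
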