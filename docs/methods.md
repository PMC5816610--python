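# Methods

This note documents the models and procedures implemented in `gencas`, the
parameters that matter, the design choices made where the problem was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Cassette assembly

A *cassette* is a maximal run of chromosomally adjacent genes whose
pairwise gaps fall below a distance threshold — a proxy for a functional
gene cluster. The gap between genes `a` and `b` (with `a.start ≤ b.start`)
is `b.start − a.end` on chromosome coordinates, regardless of strand;
overlapping genes have negative gaps and always join. Assembly is a single
left-to-right chain: a gene joins the current cassette iff its gap to the
previous gene is strictly below `max_gap` (default 300 bp, so 299 joins and
300 splits). Runs shorter than `min_genes` (default 2; one gene is not a
cassette) are dropped. Internal coordinates are 0-based half-open
throughout, converted at the format boundary (GFF3/GenBank are 1-based
inclusive). Circular replicons are treated as linear unless the `circular`
flag is set, in which case the wrap-around gap is also tested and the two
terminal runs merged when it passes. Genes nested inside another gene are
handled as ordinary list members in start order — a deterministic choice
for messy annotations. Where both `gene` and `CDS` features carry one
locus_tag, CDS coordinates win, since the distances of interest concern
coding regions.

## Functional fingerprints and matching

Gene function labels come in three kinds:

* **ec3** — an EC number truncated to its first three fields
  (class.subclass.sub-subclass), grouping enzymes by reaction type; the
  truncation returns nothing when any of the three fields is missing or a
  `-` placeholder. A gene may carry several EC numbers; all truncations are
  kept (set semantics).
* **role** — transporter / transcription-factor labels assigned by
  case-insensitive substring rules on the product text. The default
  vocabulary maps "transporter", "permease", "PTS", "symporter" to
  *transporter* and "transcriptional regulator", "transcription factor",
  "repressor", "activator" plus the DeoR/LacI/GntR/AraC/TetR/ROK family
  names to *transcription_factor*; both are fully overridable, since any
  keyword rule is a judgment call.
* **cog** — COG identifiers, used as corroborating refinements when
  present, never required for a match.

Two genes are *compatible* when their label sets intersect; when several
labels are shared, the most specific kind wins (ec3 > cog > role), then the
lexicographically smallest value. The match size of two cassettes is the
cardinality of a **maximum bipartite matching** on the compatibility graph,
computed with an ordered augmenting-path algorithm (left genes processed in
index order, partners scanned in index order), which makes the reported
pairing deterministic. Maximum matching, rather than greedy multiset
intersection, is required because genes can carry multiple labels and a
cassette with two transporters must not match a single transporter twice.
The packaged fixture encodes the yih and lac cassettes with their published
label sets; the lac PTS EIIA component carries no label, so the maximum
yih/lac match is exactly six.

The conserved-combination search generates candidate combinations by
intersecting observed cassette fingerprints (the matched combination of
every cassette pair — never a blind powerset), checks which cassettes cover
each candidate (coverage is itself a bipartite matching of label instances
into genes), and reports the maximal multisets supported by at least
`min_groups` distinct taxon groups (defaults: `min_size` 4, `min_groups` 2;
the six-gene result uses `min_size` 6). Group diversity uses the
`taxon_group` field, family-level by default (Enterobacteriaceae vs
Bacilli in the fixtures).

## Regulatory regions

Intergenic regions of at least `min_length` bp (default 40, the lower end
of the usable range for promoter mapping) between adjacent genes are
extended 100 bp into both flanking gene bodies — tolerating mis-annotated
start codons — and clipped only at replicon ends.

**Alignment.** Orthologous regions are aligned with a built-in center-star
progressive aligner: the first sequence is the designated reference; every
other sequence is globally aligned to it by affine-gap dynamic programming
(match +1, mismatch −1, a gap of length L costs −5 − L), and the pairwise
alignments are merged on reference coordinates with per-position maximum
insertion lengths. Traceback ties prefer the diagonal, then the vertical,
then the horizontal move, so alignments are deterministic. The DP rows are
numpy-vectorised; the horizontal-gap matrix uses a prefix-maximum scan that
is exact whenever the gap-open penalty is non-positive (splitting one gap
into two adjacent gaps can then never win). The aligner is cross-checked in
the test suite against exhaustive enumeration on short strings and against
Biopython's `PairwiseAligner` (whose open=−6/extend=−1 convention equals
this cost model) on random pairs. A dedicated aligner, not a wrapper around
an external multiple-alignment tool, keeps the whole procedure
self-contained and reproducible.

**Conservation.** The column profile reports, for each reference-ungapped
column, the fraction of sequences (reference included) whose residue equals
the reference residue, gaps counting as mismatches. A site's conservation
is the *mean* identity over its span — robust to single-column noise,
unlike the minimum. Because the reference is included in the denominator,
the profile's expected mean is `(1 + (n−1)(1−d))/n` for `n` orthologs at
per-site divergence `d`, which approaches `1 − d` as `n` grows; the
parameter-recovery check therefore uses 12 orthologs, where the inclusion
bias (d/n ≈ 0.008 at d = 0.1) is well inside the ±0.03 tolerance.

**PWM scanning.** A motif is a 4×L log-odds matrix in bits against a
uniform background, or an IUPAC consensus expanded to one by giving each
allowed base an equal share of one count per column, adding a pseudocount
of 0.25 per base and normalising. The default CRP model is the palindromic
consensus TGTGA-N6-TCACA (16 bp; N columns contribute 0 bits). Scanning
covers every window of the −250/+50 TSS-anchored region on both strands
(the − strand score is the score of the window's reverse complement);
hits at or above 60% of the motif's maximum bit score are reported — a
configurable default, chosen as a permissive screen that still keeps the
expected number of random hits per window below one.

**Coordinates and ranking.** TSS-relative coordinates put +1 at the
transcribed base with no position 0; the conversion is a bijection on
non-zero integers and is inverted exactly. A site's center is the midpoint
of its inclusive TSS-relative span — half-integer exactly for even site
lengths, e.g. a 22-bp site at −52..−31 is centred at −41.5, the Class II
CRP-promoter geometry. Hits are ranked separately by PWM score and by
conservation (rank 1 best, ties sharing the minimum rank); the combined
order is by rank sum, ties broken by higher PWM score, then the more
upstream position, then strand. Note the palindromic CRP consensus
produces mirror-image hits on both strands at the planted position; the
tie-break keeps the + strand hit first, and both report the same center.

## ΔΔCt quantification

Per replicate, ΔCt = Ct(target) − mean Ct(reference genes); two reference
genes are combined by the arithmetic mean of their Cts (the combination
rule is a package choice — per-control normalisation would differ only in
the noise model). Per gene and condition, ΔΔCt = mean ΔCt(condition) −
mean ΔCt(reference condition), fold = 2^−ΔΔCt with amplification
efficiency fixed at 2 (the classical assumption;
efficiency-corrected variants are out of scope). The standard deviation is
sd(ΔΔCt) = sqrt(var ΔCt(condition) + var ΔCt(reference condition)) over
replicates, mapped through the exponential at first order:
sd(fold) = ln 2 · fold · sd(ΔΔCt). With a single replicate the sd is
reported as absent, never as zero. Adding a constant to every Ct of one
sample (a gene-independent efficiency shift) provably cancels, and
reference genes recover fold 1 in every condition.

## Synthetic data

The generators define the study conditions; all randomness flows through
one seeded `numpy` generator per call, making outputs byte-identical across
runs and platforms.

* **Genomes** — linear replicons (default 4 species, 40 genes each,
  assigned round-robin to two family-level groups) with gene lengths
  uniform on 300–900 bp and intergenic gaps from a two-component mixture
  (60% short, uniform 1–299 bp; 40% long, uniform 300–1500 bp) straddling
  the cassette threshold. Planted cassettes are contiguous runs whose
  internal gaps are drawn below 300 bp and whose flanking gaps are drawn at
  or above it; their label sets are realised as EC_number attributes
  (random fourth field), role-typical product strings, and COG attributes.
  Background genes draw zero or one label set from a small pool that
  includes the six study labels, so simulated databases interoperate with
  the packaged fixtures.
* **Ortholog regions** — the reference (first) sequence *is* the common
  ancestor; each other ortholog substitutes every site independently with
  probability `divergence_outside` (default 0.2), except the planted motif
  span at `divergence_inside` (default 0.02), replacing a base by one of
  the other three uniformly — a star phylogeny centred on the reference,
  which makes the expected reference identity exactly 1 − divergence.
  Default geometry: 300 bp regions, 6 orthologs, TSS 51 bp before the
  region end on the + strand, CRP consensus planted at TSS-relative
  −49..−34 (center −41.5). An optional per-site indel rate (default 0,
  never inside the motif) exercises the aligner; the generator records the
  true reference-to-ortholog column homology.
* **Ct tables** — reference genes (hns, ysaA) hold constant expected Cts
  across conditions; a target's Ct is shifted by −log2(true fold) relative
  to the first condition; Gaussian noise (default sd 0.2 cycles) is added
  to every measurement. Defaults plant folds {yihT: 4, yihS: 0.5, yihV: 1}
  on lactose vs glucose with 9 replicate rows (three biological × three
  technical, flattened — the ΔΔCt arithmetic treats replicates as
  exchangeable, so the hierarchy is not modelled).

What the simulations do **not** emulate: tree-structured phylogenies
(orthologs are conditionally independent given the reference), indel
evolution inside motifs, GC bias and codon structure (background sequence
is i.i.d. uniform), operon structure and strand correlation of real gene
neighbourhoods, hierarchical biological-vs-technical qPCR variance, and
amplification-efficiency differences between primer pairs. Passing recovery
tests therefore demonstrates correctness of the algorithms under the stated
generative models, not performance on real annotation or expression data.

## Problem sizes

The verification suites use 1,000 random annotations for the
assembly-vs-oracle check, 500 random cassette pairs (≤ 7 genes each, where
exhaustive enumeration of injective assignments is feasible) for the
matching oracle, 200 seeded simulations for motif recovery, 500 for ΔΔCt
coverage, and 1,000 alignment columns for conservation recovery — sizes at
which the binomial uncertainty of each measured rate is comfortably below
the margins being checked.

## Known limitations

* The cassette database here is fixture- and simulation-scale; the
  genome-scale numbers of a full annotation-database build (10^5 genes,
  10^4 cassettes) require bulk downloads and are out of scope.
* Promoter *prediction* is out of scope: TSS positions are inputs
  (mapped elsewhere), and the footprinting stage assumes them.
* The center-star alignment is a heuristic for the multiple-alignment
  problem; with the shallow divergences used here it recovers ≥ 95% of true
  homologous column pairs, but deep or indel-rich divergence would need a
  profile-based aligner.
* The isomerase label is encoded as the printed value "2.3.1" in the
  fixtures; the matching rule is label-agnostic, so the choice does not
  affect match sizes, but users comparing against external EC annotations
  (where galactose-6-phosphate isomerase is 5.3.1) should supply their own
  labels.
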