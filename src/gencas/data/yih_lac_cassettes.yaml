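# Synthetic reconstruction of two carbohydrate-utilisation gene cassettes
# with per-gene function labels:
#   * the yih (sulphoquinovose degradation) cassette of Enterobacteriaceae,
#   * the lac (lactose catabolism) cassette of Streptococcus/Staphylococcus
#     (Bacilli).
# Labels are the published functional assignments: three-field EC classes
# (hydrolase 3.2.1, aldolase 4.1.2, kinase 2.7.1, isomerase 2.3.1), the
# transporter / transcription-factor roles, and COG3684 on the
# tagatose-bisphosphate-aldolase-like genes.  Genes without labels have no
# functional match between the cassettes.  Coordinates are placeholders
# consistent with the <300 bp cassette gap rule.
cassettes:
  - cassette_id: yih_Escherichia_coli
    species: Escherichia coli
    taxon_group: Enterobacteriaceae
    replicon_id: yih_Ec
    genes:
      - {gene_id: ompL,  product: "outer membrane porin L", labels: []}
      - {gene_id: yihO,  product: "putative sulphoquinovose transporter", labels: ["role:transporter"]}
      - {gene_id: yihP,  product: "putative permease", labels: ["role:transporter"]}
      - {gene_id: yihQ,  product: "alpha-glucosidase", labels: ["ec3:3.2.1"]}
      - {gene_id: yihR,  product: "aldose 1-epimerase", labels: ["ec3:5.1.3"]}
      - {gene_id: yihS,  product: "sulphoquinovose isomerase", labels: ["ec3:2.3.1"]}
      - {gene_id: yihT,  product: "sulphofructosephosphate aldolase", labels: ["ec3:4.1.2", "cog:COG3684"]}
      - {gene_id: yihU,  product: "sulpholactaldehyde reductase", labels: ["ec3:1.1.1"]}
      - {gene_id: yihV,  product: "sulphofructose kinase", labels: ["ec3:2.7.1"]}
      - {gene_id: yihW,  product: "DeoR-family transcriptional regulator", labels: ["role:transcription_factor"]}
  - cassette_id: yih_Salmonella_enterica
    species: Salmonella enterica
    taxon_group: Enterobacteriaceae
    replicon_id: yih_Se
    genes:
      - {gene_id: ompL,  product: "outer membrane porin L", labels: []}
      - {gene_id: yihO,  product: "putative sulphoquinovose transporter", labels: ["role:transporter"]}
      - {gene_id: yihP,  product: "putative permease", labels: ["role:transporter"]}
      - {gene_id: yihQ,  product: "alpha-glucosidase", labels: ["ec3:3.2.1"]}
      - {gene_id: yihR,  product: "aldose 1-epimerase", labels: ["ec3:5.1.3"]}
      - {gene_id: yihS,  product: "sulphoquinovose isomerase", labels: ["ec3:2.3.1"]}
      - {gene_id: yihT,  product: "sulphofructosephosphate aldolase", labels: ["ec3:4.1.2", "cog:COG3684"]}
      - {gene_id: yihU,  product: "sulpholactaldehyde reductase", labels: ["ec3:1.1.1"]}
      - {gene_id: yihV,  product: "sulphofructose kinase", labels: ["ec3:2.7.1"]}
      - {gene_id: yihW,  product: "DeoR-family transcriptional regulator", labels: ["role:transcription_factor"]}
  - cassette_id: lac_Streptococcus_gallolyticus
    species: Streptococcus gallolyticus
    taxon_group: Bacilli
    replicon_id: lac_Sg
    genes:
      - {gene_id: lacR, product: "lactose phosphotransferase system repressor", labels: ["role:transcription_factor"]}
      - {gene_id: lacA, product: "galactose-6-phosphate isomerase subunit LacA", labels: ["ec3:2.3.1"]}
      - {gene_id: lacB, product: "galactose-6-phosphate isomerase subunit LacB", labels: ["ec3:2.3.1"]}
      - {gene_id: lacC, product: "tagatose-6-phosphate kinase", labels: ["ec3:2.7.1"]}
      - {gene_id: lacD, product: "tagatose 1,6-diphosphate aldolase", labels: ["ec3:4.1.2", "cog:COG3684"]}
      - {gene_id: lacF, product: "PTS lactose-specific enzyme IIA component", labels: []}
      - {gene_id: lacE, product: "PTS lactose-specific transporter, enzyme IICB", labels: ["role:transporter"]}
      - {gene_id: lacG, product: "6-phospho-beta-galactosidase", labels: ["ec3:3.2.1"]}
  - cassette_id: lac_Staphylococcus_aureus
    species: Staphylococcus aureus
    taxon_group: Bacilli
    replicon_id: lac_Sa
    genes:
      - {gene_id: lacR, product: "lactose phosphotransferase system repressor", labels: ["role:transcription_factor"]}
      - {gene_id: lacA, product: "galactose-6-phosphate isomerase subunit LacA", labels: ["ec3:2.3.1"]}
      - {gene_id: lacB, product: "galactose-6-phosphate isomerase subunit LacB", labels: ["ec3:2.3.1"]}
      - {gene_id: lacC, product: "tagatose-6-phosphate kinase", labels: ["ec3:2.7.1"]}
      - {gene_id: lacD, product: "tagatose 1,6-diphosphate aldolase", labels: ["ec3:4.1.2", "cog:COG3684"]}
      - {gene_id: lacF, product: "PTS lactose-specific enzyme IIA component", labels: []}
      - {gene_id: lacE, product: "PTS lactose-specific transporter, enzyme IICB", labels: ["role:transporter"]}
      - {gene_id: lacG, product: "6-phospho-beta-galactosidase", labels: ["ec3:3.2.1"]}
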