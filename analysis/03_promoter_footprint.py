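#!/usr/bin/env python
"""Phylogenetic footprinting of simulated orthologous promoter regions.

Finding: with the CRP motif planted under strong conservation (divergence
0.02 inside vs 0.2 outside), the footprinting chain — center-star alignment,
conservation profile, PWM scan in the -250/+50 TSS window, score +
conservation ranking — reports the planted site as rank 1 at its true
center (-41.5, the Class II CRP geometry).  Writes the ranked site table of
one representative simulation and a recovery summary.
"""

from pathlib import Path

from gencas.annotation_io import write_table
from gencas.fixtures import load_crp_motif
from gencas.regulatory import hits_to_frame, phylogenetic_footprint
from gencas.simulate import SimConfig, simulate_ortholog_regions

OUT = Path(__file__).resolve().parent.parent / "results"
N_SIMS = 50


def main() -> None:
    motif = load_crp_motif()
    rank1 = 0
    for seed in range(N_SIMS):
        truth = simulate_ortholog_regions(
            SimConfig(seed=seed, divergence_outside=0.2, divergence_inside=0.02)
        )
        _, hits = phylogenetic_footprint(truth.sequences, truth.anchor, motif)
        top = min(hits, key=lambda h: h.combined_rank)
        rank1 += top.span == truth.planted_span_tss
        if seed == 0:
            write_table(hits_to_frame(hits), OUT / "footprint_sites.tsv")
            print(
                f"representative run: top site at {top.span} (center {top.center}), "
                f"score {top.pwm_score:.2f} bits, conservation {top.conservation:.3f}"
            )
    print(f"planted site ranked 1 in {rank1}/{N_SIMS} simulations")


if __name__ == "__main__":
    main()
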