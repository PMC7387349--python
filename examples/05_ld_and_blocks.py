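"""LD decay and Gabriel haplotype blocks on a panel with background LD.

Uses the founder-haplotype mosaic background so that r^2 decays with
physical distance and |D'| confidence intervals can classify pairs into
strong LD / strong recombination, from which blocks are assembled.  Also
sizes a marker set for association mapping from the decay distance.
"""

import numpy as np

from gbspop.ld import (annotate_dprime, blocks_to_frame, gabriel_blocks,
                       ld_decay, min_markers_for_gwas, pairwise_r2)
from gbspop.simpanel import SimulationConfig, simulate_panel
from gbspop.variants import filter_snps

panel = simulate_panel(SimulationConfig(
    n_per_pop=(110, 10), n_chrom=1, chrom_length=10_000_000,
    n_loci_per_chrom=600, fst_param=0.05, selfing_rate=0.9,
    missing_rate=0.02, depth_mean=10, seed=11,
    n_founder_haplotypes=6, recomb_scale_bp=200_000, with_annotation=False))
gm, vt, _ = filter_snps(panel.genotypes, panel.variants)

pairs = pairwise_r2(gm, vt, window_bp=500_000)   # pairwise-complete, unimputed
print(f"{len(pairs)} same-chromosome pairs within 500 kb; mean r^2 = {pairs['r2'].mean():.3f}")

curve = ld_decay(pairs, bin_bp=25_000, r2_threshold=0.1, alpha=0.05)
print(f"LD decay distance at r^2 = 0.1: {curve.decay_distance_bp / 1000:.0f} kb")

pairs = annotate_dprime(gm, pairs)
blocks = gabriel_blocks(pairs, vt)
bf = blocks_to_frame(blocks)
print(f"{len(bf)} haplotype blocks; largest {bf['size_kb'].max():.1f} kb, "
      f"median {bf['size_kb'].median():.1f} kb")

# scale the decay distance to a full genome to size a GWAS marker set
genome_kb = 1_284_000
n_markers = min_markers_for_gwas(genome_kb, curve.decay_distance_bp / 1000)
print(f"markers needed for a {genome_kb / 1e6:.2f}-Gbp genome at this decay: {n_markers}")
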