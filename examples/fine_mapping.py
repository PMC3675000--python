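"""Fine-map a QTL by genotyping the selected segregants individually.

Simulates the default cross, takes the 22 top-trait segregants, and scores
every marker of the chromosome containing a planted QTL in those segregants
individually: per marker, an exact binomial test of the superior-allele
count against the 1:1 null, with Benjamini-Hochberg FDR adjustment. The
region of markers with q < 0.05 narrows the QTL around the causative
position. Also prints the Mendelian locus-count estimates implied by the
selection ratios.
"""

import numpy as np

from poolqtl import (
    CrossConfig,
    MarkerGenotypes,
    associate_markers,
    estimate_locus_count,
    select_pool,
    simulate_cross,
)

cfg = CrossConfig(seed=1)
pop = simulate_cross(cfg)
selected = select_pool(pop, 22)

chrom, qtl_pos = "chrII", 150_000
cols = np.flatnonzero(pop.marker_set.chrom == chrom)[::5]  # every 5th marker
markers = [
    MarkerGenotypes(
        chrom=chrom,
        pos=int(pop.marker_set.pos[j]),
        calls=tuple("S" if g else "I" for g in pop.genotypes[selected, j]),
    )
    for j in cols
]
table = associate_markers(markers)
sig = table[table.q_value < 0.05]
print(f"planted QTL at {chrom}:{qtl_pos}; markers tested: {len(table)}")
print(f"fine-mapped interval (q < 0.05): "
      f"{chrom}:{sig.pos.min()}-{sig.pos.max()} ({len(sig)} markers)")
print(table.iloc[::6].to_string(index=False,
                                float_format=lambda v: f"{v:.3g}"))

for n_sup, label in [(32, "tolerance-selected"), (22, "fermentation-selected")]:
    n_loci, ratio = estimate_locus_count(n_sup, 301)
    print(f"\n{n_sup}/301 {label} segregants: 1 superior in {ratio:.1f} "
          f"-> {n_loci} unlinked loci (fraction (1/2)^{n_loci})")
print("""
The association fraction is the share of selected segregants carrying the
superior allele; at the QTL it approaches 1 and the exact binomial p-value
collapses, while flanking markers decay back to the 0.5 null.""")
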