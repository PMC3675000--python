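# poolqtl

QTL mapping from pooled-segregant whole-genome sequencing (BSA-seq) in
two-parent crosses, built for experiments like the polygenic analysis of
yeast ethanol tolerance: a diploid hybrid of a superior (e.g. sake) and an
inferior (lab) parent is sporulated, hundreds of haploid segregants are
phenotyped, the extreme performers are pooled and sequenced, and genomic
regions where the pool's allele frequencies deviate from the 1:1 Mendelian
expectation mark quantitative trait loci (QTLs).

## What it computes

At marker *i* a pool yields *k_i* superior-parent allele calls out of
*n_i* reads. A three-state hidden Markov model assigns each marker a
posterior over {linked to superior parent, linked to inferior parent,
background}:

- **Emissions** are beta-binomial, `k_i ~ BetaBin(n_i, α_s, β_s)`, which
  absorbs the overdispersion a finite pool induces on the pool allele
  frequency. The superior state uses (α, β) = (10, 1), the inferior state
  (1, 10), and the background state a Beta fitted to all sites by the
  method of moments (on a proper cross it is near-symmetric with
  α ≈ β > 1, i.e. close to a fair binomial).
- **Transitions** between neighbouring markers at distance *d* use the
  recombination probability `r(d) = ½(1 − e^(−d/L))` (default
  L = 125 kb): stay with 1 − r, switch to each other state with r/2.
  Chromosomes are independent chains.
- **Posteriors** come from the forward-backward algorithm; the signed
  *linkage probability* of a marker is `P(sup|data) − P(inf|data)` in
  [−1, 1]. Runs of ≥10 same-sign markers beyond ±0.95 become QTL calls,
  annotated Yes/Weak/No for their presence in a second pool.

Around the HMM the package provides the rest of the workflow: parent SNP
discovery with inclusive coverage (≥20×) and allele-ratio (≥80%) filters;
raw and kernel-smoothed allele-frequency tracks; segregant-level
fine-mapping (exact binomial tests against the 1:1 null with
Benjamini–Hochberg FDR); Mendelian locus-count inference from segregation
ratios (`round(log2(total/superior))`); fermentation and plate-tolerance
trait metrics; and a meiotic cross-and-pool-sequencing simulator (Haldane
map, additive trait, truncation selection, Poisson depth + binomial
sequencing error) that makes every stage testable without external data.

## Worked example

```sh
python examples/simulate_and_map.py
```

simulates the default scaled cross (301 segregants, 3 × 300 kb
chromosomes, 900 markers, four planted QTLs, sequencing depth ~38) and
maps three pools:

```
pool1 (top 22): mean superior-allele frequency 0.771, background Beta(1.0, 1.0)
 chrom  start    end  n_significant_snps  mean_linkage   parent presence_in_other_pool
  chrI  49000 289000                 231      0.995702 superior                    Yes
 chrII  97000 166000                  70      0.996000 superior                    Yes
chrIII  92000 213000                 122      0.997848 superior                    Yes
...
pool3 (random 237): mean superior-allele frequency 0.503, background Beta(134.8, 134.8)
  no QTL calls (expected for the unselected pool)
```

The selected pools recover intervals containing all four planted QTLs (the
two on chrI merge into one call in pool1), each significant in both
selected pools, while the unselected control pool stays at frequency ~0.5
genome-wide and produces no calls. The other examples cover fine-mapping
(`fine_mapping.py`: the q < 0.05 interval narrows a QTL and the 22/301 and
32/301 selection ratios give 4- and 3-locus estimates), trait metrics
(`fermentation_traits.py`) and the built-in 36-genome ADE1/KIN3 allele
panel (`strain_panel.py`).

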