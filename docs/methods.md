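# Methods

## The mapping model

A cross of two homozygous parents segregates an ordered panel of biallelic
SNPs. In a pool of selected haploid segregants, the frequency of the
superior parent's allele at a marker is ~0.5 where the genome is neutral
and rises (or falls) where selection enriched one parent's haplotypes.
Sequencing the pool gives, per marker *i*, `k_i` superior-allele calls out
of `n_i` reads.

The linkage HMM has three hidden states per marker — superior-linked,
inferior-linked, background — with beta-binomial emissions
`k_i | state ~ BetaBin(n_i, α, β)`. The Beta prior on the pool frequency
captures two things a plain binomial misses: the pool holds finitely many
segregants (so its true frequency is itself random around the expectation)
and selection pushes linked frequencies toward, but not exactly to, 0 or 1.
The linked states use the fixed, deliberately asymmetric shapes (10, 1)
and (1, 10): mean 10/11 ≈ 0.91 with mass piled against the boundary,
matching a strongly but incompletely selected locus. The background shape
is estimated from the data (below).

Transitions encode recombination: for neighbouring markers at physical
distance *d*, `r(d) = ½(1 − exp(−d/L))`, with stay probability 1 − r and
r/2 to each other state. L defaults to 125,000 bp, the Haldane inverse of
a yeast-average 0.4 cM/kb (r ≈ 0.004 at 1 kb spacing); it is a tunable
`map_scale` on `HMMParams`. Chromosomes restart from the initial
distribution (uniform 1/3 by default — no prior parent bias; chains are
long enough that this only matters within a few markers of chromosome
ends).

Posteriors come from the forward-backward algorithm with per-site scaling
(per-site max-shift before exponentiation, renormalisation each step), so
chains of 10^5 sites cannot underflow; scaled linear-space recursions were
chosen over log-space because they are exactly checkable against path
enumeration and make the antisymmetry property (below) bitwise. The
signed linkage probability is defined as `p_sup − p_inf` ∈ [−1, 1]; it
reproduces the two-sided ±0.95 significance convention and gives QTLs
their parent sign. Markers with |score| strictly greater than 0.95 are
significant; same-sign significant markers with gaps ≤ 30 kb merge into a
QTL call, and calls with fewer than 10 significant markers are dropped
(both configurable; published pool analyses of this design report QTLs
with ≥ 26 significant SNPs, so the defaults are conservative).

### Background estimation

`estimate_background` fits a beta-binomial by the method of moments: each
site contributes `E[(k/n − m)²] = m(1−m)(1/n + (1 − 1/n)ρ)` with
`ρ = 1/(α+β+1)`; averaging over sites and solving for ρ gives α + β, and
the mean m splits it. If the data are no more dispersed than binomial the
moment equation has no finite solution and the near-binomial fallback
α = β = 50 is returned.

`forward_backward` uses a symmetry-constrained variant by default
(`symmetric=True`): the Beta mean is pinned at ½ (α = β) and only the
overdispersion is estimated, from the second moment about ½, floored at
α = β = 1 (never more informative than uniform). The pin encodes the
genetics — every marker in a haploid F1 cross segregates 1:1, so the
no-linkage state must be centred at 0.5 — and it matters on small genomes:
when planted QTLs cover much of a scaled genome, the unconstrained fit
absorbs the selection signal (mean ≈ 0.78) and then swallows moderately
selected QTLs into the "background". The unconstrained fit remains
available and is what the parameter-recovery tests exercise.

## The simulator

`simulate_cross` draws, per segregant and chromosome, a random starting
haplotype and a Poisson number of crossovers (Haldane model, no
interference) at 0.4 cM/kb, placed uniformly; the genotype is the parity
of crossovers left of each marker. The trait is additive over planted QTL
effects plus Gaussian noise. Selection is rank truncation (`top-trait`,
ties broken by segregant index) or uniform sampling without replacement
(`random`, the unselected control). Pooled sequencing draws depth
`n ~ Poisson(depth_mean)` resampled to ≥ 1 per site, and
`k ~ Binom(n, f(1−e) + (1−f)e)` with symmetric per-call error e = 0.002.

Defaults emulate the study conditions at a scaled genome: 3 chromosomes ×
300 kb with 1 marker/kb (900 markers), 301 segregants, pools of 22
(fermentation-selected), 32 (tolerance-selected) and 237 (unselected),
depth 38, four planted QTLs of equal effect 1.0 with noise SD 0.5 (so the
top-22 pool is essentially the all-superior-carrier class, reproducing
the ≈ 1-in-13.7 selection ratio). The full 16-chromosome layout is
reachable through `CrossConfig`.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: coverage autocorrelation and mappability
artifacts (depth is independent per site), crossover interference,
segregation distortion, genotyping/alignment error structure beyond a
symmetric per-call flip, DNA-pooling unevenness (each segregant
contributes equimolarly), and epistasis (the trait is strictly additive).

## Fine-mapping and locus counting

Per marker, the superior-allele count among individually genotyped
selected segregants is tested against Binomial(m, ½) with the exact
two-sided (minimum-likelihood) binomial test; missing calls are dropped
per marker, never imputed. Benjamini–Hochberg step-up q-values are
reported alongside raw p-values, since published "P < 0.05" interval
bounds do not always say which was thresholded. The locus-count estimate
is `round(log2(total/superior))` — the number of unlinked loci whose
joint-inheritance probability (½)^n best matches the observed superior
fraction — plus the raw ratio. It is reliable only when the expected
superior class is well populated; at 301 segregants the estimate resolves
up to ~4 loci, and the recovery tests use 2,000 segregants for the
5-locus case.

## Trait metrics

Ethanol yield is reported as a percentage of the 0.51 g/g stoichiometric
maximum; note 0.446 g/g evaluates to 87.45%, which prints as 87.5 under
round-half-up although such values are conventionally quoted as 87.4 —
the function returns full precision and leaves display rounding to the
caller. The % v/v → g/L conversion uses an ethanol density of 0.789 g/mL
(20 °C, configurable); published productivities computed from direct mass
measurements can differ from the titer-derived value in the second
decimal. Plate tolerance supports the two coexisting scoring schemes
(0–4 dilution count, and 0–5 with a bonus point for growth at the highest
ethanol level tested); callers choose explicitly. The score–titer
association uses Spearman rank correlation (average ranks for ties),
one-tailed for positive association by default; p-values are exact by
full permutation enumeration for n < 10 and use the large-sample t
approximation otherwise.

## Strain-panel counting

`count_variant_prevalence` counts heterozygous entries (token `both`)
toward both alleles, so `count(A) + count(B) = n_strains + n_het`.
`panel_summary` counts homozygous carriers only, which is the arithmetic
published summary rows of such panels actually use (the one heterozygous
panel strain is excluded from both rows). Both conventions are exposed
because they answer different questions: "how many strains carry the
allele" versus "how do the table's summary rows add up".

## Numerical choices and degenerate inputs

- Emission log-pmfs are computed from `gammaln` with terms grouped so that
  the parent-label swap (k → n−k, α ↔ β) is bitwise exact; posteriors and
  linkage scores are therefore exactly antisymmetric under relabelling.
- Sites with n = 0 have undefined raw frequency (NaN, never 0.0), carry
  zero weight in smoothing, and contribute a uniform emission in the HMM
  (transition information still flows through them).
- The kernel smoother truncates the Gaussian at ±5 SD (weights < 4·10⁻⁶
  of the peak); within a chromosome it is a convex combination of raw
  frequencies, hence bounded by their range.
- QTL interval ties: runs are split whenever sign flips or the inter-SNP
  gap exceeds `max_gap_bp`, whichever comes first; interval ends are the
  outermost significant markers (1-based inclusive; BED output converts
  to 0-based half-open).
- Problem sizes in the test and acceptance runs (900-marker genomes, 10
  seeds, 10,000-site background fits, 200 enumeration chains) were chosen
  so the full suite completes in well under a minute while keeping every
  statistical check at ≥ 3-SE resolution.

## Known limitations

The smoother is a stand-in: published analyses of this design smoothed
frequencies within a linear-mixed-model framework whose exact covariance
structure lives in external references; since QTL calls here come from
the HMM and the smooth is presentation-layer, a transparent
coverage-weighted Nadaraya–Watson estimator (default bandwidth 20 kb) is
used instead, and no attempt is made to replicate the LMM's output. The
HMM fixes its emission shapes rather than re-estimating them by EM, does
not provide Viterbi paths, and analyses one counts table per run (two
sequencing providers' datasets are compared by running each and
`compare_pools`, not jointly modelled). Parent SNP filtering applies the
coverage/ratio thresholds to the superior parent's evidence only, the
context in which those filters are defined; pool-level counts get no
additional site filter by default.
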