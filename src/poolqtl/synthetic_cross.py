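"""Simulation of a two-parent haploid yeast cross with pooled sequencing.

The generative model mirrors a bulk-segregant (BSA-seq) experiment: two
homozygous parents differ at an ordered panel of biallelic SNPs; haploid F1
segregants inherit a mosaic of the two parental haplotypes produced by
meiotic recombination (Haldane model, crossovers as a Poisson process along
each chromosome); a quantitative trait is an additive liability over planted
QTL alleles plus Gaussian environmental noise; pools are formed either by
rank truncation on the trait (selected pools) or by random sampling
(unselected control pool); pooled short-read sequencing of a pool is
emulated as, per marker, a Poisson read depth and a binomial draw of
superior-parent allele calls at the pool allele frequency perturbed by a
symmetric per-call sequencing error.

Defaults describe a scaled-down cross: 3 chromosomes x 300 kb at 1 marker
per kb, 301 segregants, selected pools of 22 and 32, an unselected pool of
237, mean depth 38, and a yeast-average map of 0.4 cM/kb.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .variant_qc import MarkerSet, PoolCounts

__all__ = [
    "CrossConfig",
    "SegregantPopulation",
    "default_qtls",
    "simulate_cross",
    "select_pool",
    "simulate_pool_counts",
    "write_fixture",
]


def default_qtls() -> list[tuple[str, int, float]]:
    """Four unlinked planted QTLs of equal effect on the default genome."""
    return [
        ("chrI", 75_000, 1.0),
        ("chrI", 225_000, 1.0),
        ("chrII", 150_000, 1.0),
        ("chrIII", 150_000, 1.0),
    ]


@dataclass(frozen=True)
class CrossConfig:
    """Layout and parameters of a simulated cross.

    Attributes
    ----------
    chromosomes : list of (name, length_bp)
        Genome layout. Default: 3 chromosomes of 300 kb.
    marker_spacing_bp : int
        Uniform inter-marker distance; markers sit at spacing, 2*spacing, ...
        Ignored when ``marker_positions`` is given.
    marker_positions : dict chrom -> sorted positions, optional
        Explicit 1-based marker positions per chromosome.
    qtls : list of (chrom, pos_bp, effect)
        Planted QTLs; each position must coincide with a marker. Effect is
        the trait increment conferred by the superior allele.
    n_segregants : int
        Haploid segregants genotyped (301 in the experiment emulated).
    pool_sizes : (selected_1, selected_2, unselected)
        Default pool sizes 22, 32 and 237.
    depth_mean : float
        Mean sequencing depth per marker (~38).
    noise_sd : float
        Environmental trait standard deviation.
    error_rate : float
        Symmetric per-call sequencing error probability.
    cm_per_kb : float
        Recombination rate of the Haldane map (yeast average ~0.4 cM/kb).
    seed : int
        Master seed; identical configs give bit-identical output.
    """

    chromosomes: tuple[tuple[str, int], ...] = (
        ("chrI", 300_000),
        ("chrII", 300_000),
        ("chrIII", 300_000),
    )
    marker_spacing_bp: int = 1_000
    marker_positions: dict[str, Sequence[int]] | None = None
    qtls: tuple[tuple[str, int, float], ...] = field(
        default_factory=lambda: tuple(default_qtls())
    )
    n_segregants: int = 301
    pool_sizes: tuple[int, int, int] = (22, 32, 237)
    depth_mean: float = 38.0
    noise_sd: float = 0.5
    error_rate: float = 0.002
    cm_per_kb: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.n_segregants <= 0:
            raise ValueError("n_segregants must be > 0")
        for size in self.pool_sizes:
            if size > self.n_segregants:
                raise ValueError("pool size exceeds n_segregants")
        lengths = dict(self.chromosomes)
        for chrom, pos, _ in self.qtls:
            if chrom not in lengths:
                raise ValueError(f"QTL chromosome {chrom!r} not in genome")
            if not 1 <= pos <= lengths[chrom]:
                raise ValueError(f"QTL position {chrom}:{pos} outside chromosome")

    def replace(self, **kw) -> "CrossConfig":
        return dataclasses.replace(self, **kw)


def _marker_set(config: CrossConfig) -> MarkerSet:
    chroms, positions = [], []
    for name, length in config.chromosomes:
        if config.marker_positions is not None:
            pos = np.asarray(sorted(config.marker_positions.get(name, ())), dtype=np.int64)
        else:
            pos = np.arange(
                config.marker_spacing_bp, length + 1, config.marker_spacing_bp,
                dtype=np.int64,
            )
        chroms.extend([name] * len(pos))
        positions.append(pos)
    if not chroms:
        raise ValueError("marker panel is empty")
    pos_all = np.concatenate(positions)
    # Parent alleles are placeholders: inferior parent fixed REF=C, superior ALT=T.
    return MarkerSet(
        chrom=np.asarray(chroms, dtype=object),
        pos=pos_all,
        inferior_allele=np.full(len(pos_all), "C", dtype=object),
        superior_allele=np.full(len(pos_all), "T", dtype=object),
    )


@dataclass
class SegregantPopulation:
    """A simulated haploid segregant population.

    ``genotypes`` is an (n_segregants, n_markers) uint8 matrix of
    parent-of-origin (1 = superior-parent allele, 0 = inferior), ``traits``
    the per-segregant trait values, ``marker_set`` the shared marker panel.
    """

    genotypes: np.ndarray
    traits: np.ndarray
    marker_set: MarkerSet
    config: CrossConfig

    @property
    def n_segregants(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]


def simulate_cross(config: CrossConfig) -> SegregantPopulation:
    """Simulate haploid segregants of a two-parent cross.

    Each segregant chromosome starts from a random parental haplotype and
    switches parent at crossover points drawn as a Poisson process with
    intensity ``cm_per_kb`` (Haldane: no interference). The trait is the sum
    of planted QTL effects over superior alleles carried plus N(0, noise_sd).
    """
    markers = _marker_set(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    morgans_per_bp = config.cm_per_kb / 100.0 / 1000.0

    n = config.n_segregants
    geno_blocks = []
    for name, length in config.chromosomes:
        sel = markers.chrom == name
        pos = markers.pos[sel].astype(float)
        block = np.empty((n, len(pos)), dtype=np.uint8)
        mean_xo = length * morgans_per_bp
        start = rng.integers(0, 2, size=n)
        n_xo = rng.poisson(mean_xo, size=n)
        for i in range(n):
            if n_xo[i] == 0:
                block[i] = start[i]
                continue
            cuts = np.sort(rng.uniform(0, length, size=n_xo[i]))
            # parent-of-origin = start XOR (number of crossovers left of marker) mod 2
            k_left = np.searchsorted(cuts, pos)
            block[i] = (start[i] + k_left) % 2
        geno_blocks.append(block)
    genotypes = np.concatenate(geno_blocks, axis=1)

    traits = rng.normal(0.0, config.noise_sd, size=n)
    key = {(c, p): i for i, (c, p) in enumerate(zip(markers.chrom, markers.pos))}
    for chrom, pos, effect in config.qtls:
        idx = key.get((chrom, int(pos)))
        if idx is None:
            raise ValueError(f"QTL position {chrom}:{pos} does not match any marker")
        traits = traits + effect * genotypes[:, idx]

    return SegregantPopulation(genotypes=genotypes, traits=traits,
                               marker_set=markers, config=config)


def select_pool(
    pop: SegregantPopulation,
    pool_size: int,
    mode: Literal["top-trait", "random"] = "top-trait",
    seed: int | None = None,
) -> np.ndarray:
    """Return sorted segregant indices forming a pool.

    ``top-trait`` takes the ``pool_size`` highest trait values (ties broken
    by segregant index, ascending); ``random`` samples without replacement,
    emulating an unselected control pool.
    """
    if pool_size <= 0:
        raise ValueError("pool_size must be > 0")
    if pool_size > pop.n_segregants:
        raise ValueError("pool_size exceeds population size")
    if mode == "top-trait":
        # lexsort: primary key -trait (descending trait), secondary index ascending
        order = np.lexsort((np.arange(pop.n_segregants), -pop.traits))
        return np.sort(order[:pool_size])
    if mode == "random":
        if seed is None:
            seed = pop.config.seed
        rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
        return np.sort(rng.choice(pop.n_segregants, size=pool_size, replace=False))
    raise ValueError(f"unknown mode {mode!r}")


def simulate_pool_counts(
    pop: SegregantPopulation,
    indices: np.ndarray,
    depth_mean: float | None = None,
    seed: int | None = None,
    error_rate: float | None = None,
) -> PoolCounts:
    """Emulate pooled sequencing of the segregants in ``indices``.

    Per marker the true pool frequency f of the superior allele is the mean
    genotype over the pool; the read depth is Poisson(depth_mean) resampled
    to >= 1 and the superior-allele call count is Binomial(n, f') with
    f' = f(1-e) + (1-f)e for per-call error e.
    """
    indices = np.asarray(indices)
    if indices.size == 0:
        raise ValueError("pool index list is empty")
    cfg = pop.config
    if depth_mean is None:
        depth_mean = cfg.depth_mean
    if seed is None:
        seed = cfg.seed
    if error_rate is None:
        error_rate = cfg.error_rate

    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    f = pop.genotypes[indices].mean(axis=0)
    f_obs = f * (1.0 - error_rate) + (1.0 - f) * error_rate

    n = rng.poisson(depth_mean, size=pop.n_markers)
    zero = n == 0
    while zero.any():  # depth conditioned on at least one read
        n[zero] = rng.poisson(depth_mean, size=int(zero.sum()))
        zero = n == 0
    k = rng.binomial(n, f_obs)
    return PoolCounts(marker_set=pop.marker_set, k=k.astype(np.int64),
                      n=n.astype(np.int64))


# ---------------------------------------------------------------------------
# fixture output

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=poolqtl-synthetic-cross
##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of pool samples">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">
"""


def write_fixture(
    pop: SegregantPopulation,
    pools: dict[str, PoolCounts],
    out_dir,
) -> dict[str, str]:
    """Write the marker panel with pooled counts as VCF and TSV, plus a BED
    of the planted QTLs, and return the paths.

    The VCF has one sample column per pool with ref,alt depths in AD
    (REF = inferior-parent allele, ALT = superior). The TSV dialect is
    ``chrom  pos  ref  alt  k  n`` per pool. BED intervals are 0-based
    half-open around each planted QTL position. These files round-trip
    through :func:`poolqtl.variant_qc.load_pool_counts`.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    ms = pop.marker_set
    paths: dict[str, str] = {}

    vcf_path = os.path.join(out_dir, "pools.vcf")
    with open(vcf_path, "w") as fh:
        fh.write(_VCF_HEADER)
        for name, length in pop.config.chromosomes:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        sample_names = list(pools)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
                 + "".join(f"\t{s}" for s in sample_names) + "\n")
        for i in range(len(ms)):
            fields = [
                str(ms.chrom[i]), str(ms.pos[i]), ".",
                str(ms.inferior_allele[i]), str(ms.superior_allele[i]),
                ".", "PASS", f"NS={len(sample_names)}", "AD:DP",
            ]
            for s in sample_names:
                k = int(pools[s].k[i])
                n = int(pools[s].n[i])
                fields.append(f"{n - k},{k}:{n}")
            fh.write("\t".join(fields) + "\n")
    paths["vcf"] = vcf_path

    for s, counts in pools.items():
        tsv_path = os.path.join(out_dir, f"{s}.counts.tsv")
        with open(tsv_path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\tk\tn\n")
            for i in range(len(ms)):
                fh.write(f"{ms.chrom[i]}\t{ms.pos[i]}\t{ms.inferior_allele[i]}"
                         f"\t{ms.superior_allele[i]}\t{int(counts.k[i])}"
                         f"\t{int(counts.n[i])}\n")
        paths[f"tsv:{s}"] = tsv_path

    bed_path = os.path.join(out_dir, "true_qtls.bed")
    with open(bed_path, "w") as fh:
        for j, (chrom, pos, effect) in enumerate(pop.config.qtls):
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\tqtl{j + 1}\t{effect}\n")
    paths["bed"] = bed_path
    return paths
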