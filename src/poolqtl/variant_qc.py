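"""Marker discovery, pooled-count loading and strain-panel prevalence.

Parent-distinguishing SNPs are discovered from sequencing evidence of the
superior parent against the reference genome of the inferior parent, with
inclusive coverage (>=20x) and alternative-allele ratio (>=80%) filters.
Pooled allele counts are loaded from either the VCF (AD field per pool
sample) or the plain TSV dialect written by the simulator, aligned to a
marker panel. Strain-panel queries count how many published genomes carry a
given allele at a site.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MarkerSet",
    "PoolCounts",
    "ParentSiteEvidence",
    "StrainAlleleMatrix",
    "discover_markers",
    "load_pool_counts",
    "load_strain_panel",
    "load_builtin_strain_panel",
    "ADE1_KIN3_SITES",
    "count_variant_prevalence",
    "panel_summary",
]

HET_TOKEN = "both"

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class ParentSiteEvidence:
    """Evidence at one candidate site in the superior parent's reads."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    coverage: int
    alt_ratio: float

    def __post_init__(self):
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if not 0.0 <= self.alt_ratio <= 1.0:
            raise ValueError("alt_ratio must be in [0, 1]")


@dataclass
class MarkerSet:
    """Ordered biallelic sites distinguishing the two parents.

    Sorted by chromosome (order of first appearance) then position;
    positions are 1-based and strictly increasing within a chromosome.
    """

    chrom: np.ndarray
    pos: np.ndarray
    inferior_allele: np.ndarray
    superior_allele: np.ndarray

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.inferior_allele = np.asarray(self.inferior_allele, dtype=object)
        self.superior_allele = np.asarray(self.superior_allele, dtype=object)
        for name in self.chromosome_names():
            p = self.pos[self.chrom == name]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(
                    f"positions not strictly increasing on {name}")

    def __len__(self) -> int:
        return len(self.pos)

    def chromosome_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "inferior_allele": self.inferior_allele,
                "superior_allele": self.superior_allele,
            }
        )

    def index_of(self) -> dict[tuple[str, int], int]:
        return {(c, int(p)): i for i, (c, p) in enumerate(zip(self.chrom, self.pos))}


@dataclass
class PoolCounts:
    """Superior-allele call counts k out of n per marker for one pool.

    Aligned to ``marker_set``; sites absent from the source file carry
    n = 0 and are listed in ``missing`` (boolean mask).
    """

    marker_set: MarkerSet
    k: np.ndarray
    n: np.ndarray
    missing: np.ndarray | None = None

    def __post_init__(self):
        self.k = np.asarray(self.k, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        if self.k.shape != self.n.shape or len(self.k) != len(self.marker_set):
            raise ValueError("k/n not aligned to marker set")
        if (self.k > self.n).any():
            raise ValueError("k > n at some site")
        if (self.k < 0).any() or (self.n < 0).any():
            raise ValueError("negative counts")
        if self.missing is None:
            self.missing = np.zeros(len(self.k), dtype=bool)

    def __len__(self) -> int:
        return len(self.k)


def discover_markers(
    evidence: list[ParentSiteEvidence],
    min_coverage: int = 20,
    min_ratio: float = 0.80,
) -> MarkerSet:
    """Filter candidate sites into a high-quality marker panel.

    A site is retained iff ``coverage >= min_coverage`` and
    ``alt_ratio >= min_ratio`` (both boundaries inclusive). The output is
    sorted and deduplicated; duplicated coordinates with conflicting alleles
    are an error.
    """
    if min_coverage < 0 or not 0.0 <= min_ratio <= 1.0:
        raise ValueError("thresholds out of range")
    kept: dict[tuple[str, int], ParentSiteEvidence] = {}
    for ev in evidence:
        if ev.coverage >= min_coverage and ev.alt_ratio >= min_ratio:
            key = (ev.chrom, ev.pos)
            prev = kept.get(key)
            if prev is not None and (
                prev.ref_allele != ev.ref_allele or prev.alt_allele != ev.alt_allele
            ):
                raise ValueError(
                    f"conflicting alleles at {key}: {prev} vs {ev}")
            kept[key] = ev
    # SNPs only: single-base ref and alt
    records = [
        ev for ev in kept.values()
        if ev.ref_allele in _BASES and ev.alt_allele in _BASES
    ]
    chrom_order: dict[str, int] = {}
    for ev in records:
        chrom_order.setdefault(ev.chrom, len(chrom_order))
    records.sort(key=lambda ev: (chrom_order[ev.chrom], ev.pos))
    return MarkerSet(
        chrom=np.array([ev.chrom for ev in records], dtype=object),
        pos=np.array([ev.pos for ev in records], dtype=np.int64),
        inferior_allele=np.array([ev.ref_allele for ev in records], dtype=object),
        superior_allele=np.array([ev.alt_allele for ev in records], dtype=object),
    )


def _load_tsv(path: str, marker_set: MarkerSet) -> PoolCounts:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "k", "n"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    known = set(marker_set.chromosome_names())
    index = marker_set.index_of()
    k = np.zeros(len(marker_set), dtype=np.int64)
    n = np.zeros(len(marker_set), dtype=np.int64)
    seen = np.zeros(len(marker_set), dtype=bool)
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        if row.chrom not in known:
            raise ValueError(f"{path}:{line_no}: unknown chromosome {row.chrom!r}")
        if row.k > row.n:
            raise ValueError(f"{path}:{line_no}: k={row.k} exceeds n={row.n}")
        idx = index.get((row.chrom, int(row.pos)))
        if idx is None:
            continue  # site not in the panel
        k[idx], n[idx], seen[idx] = int(row.k), int(row.n), True
    return PoolCounts(marker_set=marker_set, k=k, n=n, missing=~seen)


def _load_vcf(path: str, marker_set: MarkerSet, sample: str | None) -> PoolCounts:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns")
    if sample is None:
        if len(samples) > 1:
            raise ValueError(
                f"{path}: multiple samples {samples}; pass sample=")
        sample = samples[0]
    if sample not in samples:
        raise ValueError(f"{path}: sample {sample!r} not in {samples}")
    s_idx = samples.index(sample)

    known = set(marker_set.chromosome_names())
    index = marker_set.index_of()
    k = np.zeros(len(marker_set), dtype=np.int64)
    n = np.zeros(len(marker_set), dtype=np.int64)
    seen = np.zeros(len(marker_set), dtype=bool)
    for var in vcf:
        if var.CHROM not in known:
            raise ValueError(f"{path}: unknown chromosome {var.CHROM!r}")
        idx = index.get((var.CHROM, var.POS))
        if idx is None:
            continue
        ad = var.format("AD")
        ref_d, alt_d = int(ad[s_idx][0]), int(ad[s_idx][1])
        k[idx], n[idx], seen[idx] = alt_d, ref_d + alt_d, True
    vcf.close()
    return PoolCounts(marker_set=marker_set, k=k, n=n, missing=~seen)


def load_pool_counts(
    path: str,
    marker_set: MarkerSet,
    sample: str | None = None,
) -> PoolCounts:
    """Load pooled allele counts (VCF with AD, or TSV) aligned to a panel.

    Markers absent from the file get n = 0 and are flagged in ``missing``.
    Records with k > n or an unknown chromosome are rejected.
    """
    ext = os.path.splitext(path)[1].lower()
    if ext == ".vcf":
        return _load_vcf(path, marker_set, sample)
    return _load_tsv(path, marker_set)


# ---------------------------------------------------------------------------
# strain panels

@dataclass
class StrainAlleleMatrix:
    """Alleles of a set of strains at a set of sites.

    ``table`` is strains (rows) x site labels (columns); each cell is one of
    the two site alleles or the token ``"both"`` for a heterozygous strain.
    """

    table: pd.DataFrame

    @property
    def strains(self) -> list[str]:
        return list(self.table.index)

    @property
    def sites(self) -> list[str]:
        return list(self.table.columns)


# Parental alleles (inferior BY-lab variant, superior sake variant) of the
# five ADE1/KIN3 promoter/ORF SNPs covered by the built-in strain panel of
# 36 published S. cerevisiae genomes (chromosome I coordinates).
ADE1_KIN3_SITES: dict[str, tuple[str, str]] = {
    "169227": ("C", "T"),
    "170564": ("G", "A"),
    "170852": ("C", "T"),
    "170945": ("A", "G"),
    "171947": ("C", "T"),
}


def load_builtin_strain_panel() -> StrainAlleleMatrix:
    """The built-in ADE1/KIN3 allele panel of 36 published yeast genomes."""
    path = os.path.join(os.path.dirname(__file__), "data",
                        "ade1_kin3_strain_panel.csv")
    return load_strain_panel(path)


def load_strain_panel(path: str) -> StrainAlleleMatrix:
    """Read a strains-x-sites allele CSV (first column = strain name)."""
    df = pd.read_csv(path, index_col=0, dtype=str)
    df.columns = [str(c) for c in df.columns]
    return StrainAlleleMatrix(table=df)


def count_variant_prevalence(
    matrix: StrainAlleleMatrix,
    site: str,
    allele: str,
    include_heterozygous: bool = True,
) -> int:
    """Number of strains carrying ``allele`` at ``site``.

    Heterozygous entries (token ``"both"``) count toward both alleles by
    default; with ``include_heterozygous=False`` only homozygous carriers
    are counted, which matches the convention of published summary rows that
    exclude heterozygous strains.
    """
    site = str(site)
    if site not in matrix.table.columns:
        raise KeyError(f"unknown site {site!r}")
    col = matrix.table[site]
    count = int((col == allele).sum())
    if include_heterozygous:
        count += int((col == HET_TOKEN).sum())
    return count


def panel_summary(
    matrix: StrainAlleleMatrix,
    inferior_alleles: dict[str, str],
    superior_alleles: dict[str, str],
) -> pd.DataFrame:
    """Per-site homozygous carrier counts of each parental variant.

    Heterozygous strains are excluded from both rows, reproducing the
    arithmetic of published strain-panel summary tables.
    """
    rows = {}
    for site in matrix.sites:
        rows[site] = {
            "inferior_variant": count_variant_prevalence(
                matrix, site, inferior_alleles[site], include_heterozygous=False),
            "superior_variant": count_variant_prevalence(
                matrix, site, superior_alleles[site], include_heterozygous=False),
        }
    return pd.DataFrame(rows)
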