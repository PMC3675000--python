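"""Segregant-level fine-mapping and Mendelian locus-count inference.

Within a candidate QTL, individually genotyped selected segregants give per
marker a count of superior-parent alleles out of the scored segregants;
under the null of no linkage this is Binomial(m, 1/2) in a haploid F1
population, tested with a two-sided exact binomial test and adjusted by
Benjamini-Hochberg FDR. The number of unlinked causative loci is inferred
from the fraction of segregants reconstituting the superior phenotype:
with n loci segregating independently, a fraction (1/2)^n of segregants
inherits all superior alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MarkerGenotypes",
    "AssociationResult",
    "marker_association",
    "associate_markers",
    "fdr_adjust",
    "estimate_locus_count",
    "read_genotype_matrix",
]

SUPERIOR, INFERIOR, MISSING = "S", "I", "NA"


@dataclass(frozen=True)
class MarkerGenotypes:
    """Parent-of-origin calls of one marker in the selected segregants."""

    chrom: str
    pos: int
    calls: tuple[str, ...]  # each "S", "I" or "NA"

    def __post_init__(self):
        if len(self.calls) == 0:
            raise ValueError("no segregants")
        bad = set(self.calls) - {SUPERIOR, INFERIOR, MISSING}
        if bad:
            raise ValueError(f"unknown genotype codes {bad}")


@dataclass(frozen=True)
class AssociationResult:
    chrom: str
    pos: int
    n_superior: int
    n_scored: int
    association_fraction: float
    p_value: float
    q_value: float | None = None


def marker_association(genotypes: MarkerGenotypes) -> AssociationResult:
    """Two-sided exact binomial test of a marker against the 1/2 null.

    Missing calls are dropped; the p-value uses the minimum-likelihood
    two-sided convention of the exact binomial test.
    """
    n_sup = sum(c == SUPERIOR for c in genotypes.calls)
    n_scored = sum(c != MISSING for c in genotypes.calls)
    if n_scored == 0:
        raise ValueError(
            f"all calls missing at {genotypes.chrom}:{genotypes.pos}")
    p = binomtest(n_sup, n_scored, 0.5, alternative="two-sided").pvalue
    return AssociationResult(
        chrom=genotypes.chrom,
        pos=genotypes.pos,
        n_superior=n_sup,
        n_scored=n_scored,
        association_fraction=n_sup / n_scored,
        p_value=float(p),
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def associate_markers(markers: list[MarkerGenotypes]) -> pd.DataFrame:
    """Association table (n_superior, fraction, p, BH q) over a marker list."""
    results = [marker_association(m) for m in markers]
    q = fdr_adjust([r.p_value for r in results])
    return pd.DataFrame([
        {
            "chrom": r.chrom, "pos": r.pos, "n_superior": r.n_superior,
            "n_scored": r.n_scored,
            "association_fraction": r.association_fraction,
            "p_value": r.p_value, "q_value": qi,
        }
        for r, qi in zip(results, q)
    ])


def read_genotype_matrix(path: str) -> list[MarkerGenotypes]:
    """Read a markers-x-segregants CSV (index 'chrom:pos', cells S/I/NA)."""
    df = pd.read_csv(path, index_col=0, dtype=str).fillna(MISSING)
    out = []
    for label, row in df.iterrows():
        chrom, pos = str(label).split(":")
        out.append(MarkerGenotypes(chrom=chrom, pos=int(pos),
                                   calls=tuple(row.values)))
    return out


def estimate_locus_count(n_superior_segregants: int, n_total: int) -> tuple[int, float]:
    """Infer the number of unlinked causative loci from a segregation ratio.

    Returns (round(log2(n_total / n_superior)), n_total / n_superior): the
    locus count n whose expected superior fraction (1/2)^n best matches the
    observed one, together with the raw ratio.
    """
    if n_superior_segregants <= 0:
        raise ValueError("need at least one superior segregant")
    if n_total < n_superior_segregants:
        raise ValueError("n_total must be >= n_superior_segregants")
    ratio = n_total / n_superior_segregants
    return int(round(np.log2(ratio))), ratio
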