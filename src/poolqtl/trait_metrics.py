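"""Fermentation and ethanol-tolerance trait metrics.

Very-high-gravity fermentations are summarised by the final ethanol titer
(% v/v), the ethanol yield per glucose consumed (reported as a percentage
of the stoichiometric maximum of 0.51 g ethanol / g glucose), the
volumetric productivity, and the titer relative to a paired reference
strain run. Plate tolerance assays (four ten-fold serial dilutions spotted
on ethanol media) are condensed to an integer growth score under either of
two schemes in common use: the number of dilutions with growth at the
scored condition (0-4), or that count plus a bonus point for growth at the
highest ethanol level tested (0-5). The association between the plate
score and the fermentation titer is measured with a one-tailed Spearman
rank correlation (the titer distribution is not normal).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.stats import rankdata, spearmanr

__all__ = [
    "THEORETICAL_YIELD_G_PER_G",
    "FermentationRecord",
    "ToleranceAssay",
    "ethanol_yield_percent",
    "yield_and_productivity",
    "relative_accumulation",
    "tolerance_score",
    "trait_correlation",
]

#: stoichiometric maximum of alcoholic fermentation, g ethanol / g glucose
THEORETICAL_YIELD_G_PER_G = 0.51

#: density of ethanol at 20 degrees C, g/mL (used for % v/v -> g/L)
ETHANOL_DENSITY_G_PER_ML = 0.789

N_DILUTIONS = 4  # ten-fold serial dilutions spotted per condition


@dataclass(frozen=True)
class FermentationRecord:
    strain: str
    final_ethanol_pct_vv: float
    glucose_initial_gL: float
    glucose_leftover_gL: float
    glycerol_gL: float = 0.0
    duration_days: float = 0.0
    reference_ethanol_pct_vv: float | None = None

    def __post_init__(self):
        if self.glucose_leftover_gL > self.glucose_initial_gL:
            raise ValueError("glucose leftover exceeds initial glucose")
        for v in (self.final_ethanol_pct_vv, self.glucose_initial_gL,
                  self.glucose_leftover_gL, self.glycerol_gL,
                  self.duration_days):
            if v < 0:
                raise ValueError("fermentation quantities must be >= 0")


@dataclass(frozen=True)
class ToleranceAssay:
    """Observed growth per condition across the four serial dilutions.

    ``conditions`` maps (medium, ethanol % v/v) to a 4-tuple of booleans,
    one per dilution; growth is recorded as observed, never inferred from
    lower dilutions.
    """

    strain: str
    conditions: dict[tuple[str, float], tuple[bool, ...]]

    def __post_init__(self):
        if not self.conditions:
            raise ValueError("assay needs at least one condition")
        for cond, growth in self.conditions.items():
            if len(growth) != N_DILUTIONS:
                raise ValueError(f"{cond}: expected {N_DILUTIONS} dilutions")


def ethanol_yield_percent(yield_g_per_g: float) -> float:
    """Ethanol yield as percent of the 0.51 g/g stoichiometric maximum."""
    if yield_g_per_g < 0:
        raise ValueError("yield must be >= 0")
    return 100.0 * yield_g_per_g / THEORETICAL_YIELD_G_PER_G


def yield_and_productivity(
    record: FermentationRecord,
    ethanol_density: float = ETHANOL_DENSITY_G_PER_ML,
) -> tuple[float, float, float]:
    """(yield g/g, yield % of theoretical, productivity g/L/h).

    Ethanol g/L = titer(% v/v) * 10 * density; yield divides by glucose
    consumed; productivity by the fermentation duration in hours.
    """
    consumed = record.glucose_initial_gL - record.glucose_leftover_gL
    if consumed <= 0:
        raise ValueError("no glucose consumed")
    if record.duration_days <= 0:
        raise ValueError("duration must be > 0")
    ethanol_gL = record.final_ethanol_pct_vv * 10.0 * ethanol_density
    y = ethanol_gL / consumed
    productivity = ethanol_gL / (record.duration_days * 24.0)
    return y, ethanol_yield_percent(y), productivity


def relative_accumulation(strain_pct: float, reference_pct: float) -> float:
    """Strain titer as percent of the paired reference-strain titer."""
    if reference_pct <= 0:
        raise ValueError("reference titer must be > 0")
    return 100.0 * strain_pct / reference_pct


def tolerance_score(
    assay: ToleranceAssay,
    scheme: str = "dilution-count",
    condition: tuple[str, float] | None = None,
) -> int:
    """Integer plate-growth tolerance score.

    ``dilution-count`` counts the dilutions with growth at the scored
    condition (0-4; default condition = highest ethanol level present).
    ``0-to-5`` additionally awards one point when the strain grows at all
    at the highest ethanol level tested (capped at 5).
    """
    if scheme not in ("dilution-count", "0-to-5"):
        raise ValueError(f"unknown scheme {scheme!r}")
    hardest = max(assay.conditions, key=lambda c: c[1])
    if condition is None:
        condition = hardest
    if condition not in assay.conditions:
        raise KeyError(f"condition {condition!r} not in assay")
    base = sum(assay.conditions[condition])
    if scheme == "dilution-count":
        return base
    bonus = int(any(assay.conditions[hardest]))
    return min(base + bonus, 5)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho: float,
                      alternative: str) -> float:
    """Exact permutation p-value of Spearman's rho (small n)."""
    n = len(rx)
    rx_c = rx - rx.mean()
    denom = np.sqrt((rx_c ** 2).sum())
    stats = []
    for perm in permutations(range(n)):
        ry_p = ry[list(perm)]
        ry_c = ry_p - ry_p.mean()
        d = denom * np.sqrt((ry_c ** 2).sum())
        stats.append(np.dot(rx_c, ry_c) / d if d > 0 else 0.0)
    stats = np.asarray(stats)
    eps = 1e-12
    if alternative == "greater":
        return float((stats >= rho - eps).mean())
    if alternative == "less":
        return float((stats <= rho + eps).mean())
    return float((np.abs(stats) >= abs(rho) - eps).mean())


def trait_correlation(scores, titers, one_tailed: bool = True) -> tuple[float, float]:
    """Spearman rank correlation between tolerance scores and titers.

    Ties get average ranks. The p-value is one-tailed for positive
    association by default; exact by permutation for n < 10, large-sample
    t approximation otherwise.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(titers, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if len(x) < 5:
        raise ValueError("need at least 5 pairs")
    alternative = "greater" if one_tailed else "two-sided"
    if len(x) < 10:
        rx, ry = rankdata(x), rankdata(y)
        rho = float(np.corrcoef(rx, ry)[0, 1])
        return rho, _exact_spearman_p(rx, ry, rho, alternative)
    res = spearmanr(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
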