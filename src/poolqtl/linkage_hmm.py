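"""Three-state hidden Markov model for pooled-segregant linkage scoring.

At every ordered marker the hidden state is one of: linked to the superior
parent, linked to the inferior parent, or background (no linkage). The
emission of a state is the superior-allele call count k out of n reads,
modelled beta-binomially: the Beta prior absorbs the overdispersion that a
finite pool of segregants induces on the pool allele frequency. The
superior state uses (alpha, beta) = (10, 1) — pool frequencies piling up
near 1 — the inferior state the mirror (1, 10), and the background state a
Beta fitted to all sites by the method of moments (on a well-segregating
cross it comes out symmetric with alpha ~ beta > 1, i.e. close to a fair
binomial).

Transitions between neighbouring markers depend on their physical distance
d through the recombination probability r(d) = 0.5 (1 - exp(-d / L)): the
chain stays in its state with probability 1 - r and moves to each other
state with probability r/2. Chromosomes are independent chains. Posteriors
come from the forward-backward algorithm with per-site scaling.

The signed linkage probability of a marker is
``P(superior | data) - P(inferior | data)`` in [-1, 1]; markers beyond
+/-0.95 are significantly linked, and runs of same-sign significant
markers form QTL calls.

Implementation note: the arithmetic is arranged so that swapping parent
labels (k -> n-k together with swapping the state parameters) negates every
linkage score bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .variant_qc import MarkerSet, PoolCounts

__all__ = [
    "HMMParams",
    "QTLCall",
    "estimate_background",
    "recomb_prob",
    "transition_matrix",
    "emission_logprob",
    "forward_backward",
    "call_qtls",
    "compare_pools",
]

# state order used throughout
SUP, INF, BG = 0, 1, 2


@dataclass(frozen=True)
class HMMParams:
    """Emission, transition and calling parameters of the linkage HMM."""

    alpha_sup: float = 10.0
    beta_sup: float = 1.0
    alpha_inf: float = 1.0
    beta_inf: float = 10.0
    alpha_bg: float = 50.0
    beta_bg: float = 50.0
    map_scale: float = 125_000.0  # bp per unit in the exponent of r(d)
    initial_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    significance_threshold: float = 0.95

    def __post_init__(self):
        for a in (self.alpha_sup, self.beta_sup, self.alpha_inf,
                  self.beta_inf, self.alpha_bg, self.beta_bg):
            if a <= 0:
                raise ValueError("beta-binomial parameters must be > 0")
        if self.map_scale <= 0:
            raise ValueError("map_scale must be > 0")
        if abs(sum(self.initial_probs) - 1.0) > 1e-9:
            raise ValueError("initial_probs must sum to 1")
        if not 0 < self.significance_threshold < 1:
            raise ValueError("significance_threshold must be in (0, 1)")

    def with_background(self, alpha_bg: float, beta_bg: float) -> "HMMParams":
        return replace(self, alpha_bg=alpha_bg, beta_bg=beta_bg)

    def swapped(self) -> "HMMParams":
        """Parameters after a parent-label swap (sup/inf mirrored)."""
        return replace(
            self,
            alpha_sup=self.beta_inf, beta_sup=self.alpha_inf,
            alpha_inf=self.beta_sup, beta_inf=self.alpha_sup,
            alpha_bg=self.beta_bg, beta_bg=self.alpha_bg,
            initial_probs=(self.initial_probs[INF], self.initial_probs[SUP],
                           self.initial_probs[BG]),
        )


def estimate_background(
    counts: PoolCounts,
    symmetric: bool = False,
) -> tuple[float, float]:
    """Method-of-moments beta-binomial fit to (k, n) over all covered sites.

    With m the mean of p_hat = k/n and v its variance, each site contributes
    E[(p_hat - m)^2] = m(1-m)(1/n_i + (1 - 1/n_i) rho) where
    rho = 1/(alpha+beta+1) is the intra-class correlation; averaging over
    sites and solving for rho gives the moment estimate. If the data are
    at most binomially dispersed (rho <= 0) there is no finite solution and
    the near-binomial fallback alpha = beta = 50 is returned.

    With ``symmetric=True`` the Beta mean is pinned at 1/2 (alpha = beta)
    and only the overdispersion is estimated, from the second moment about
    1/2. This encodes the 1:1 segregation of every marker in a haploid F1
    cross: the no-linkage state must be centred at 0.5, and pinning it
    keeps the fit honest when much of a small genome is linked to selected
    loci. The common alpha = beta is floored at 1 so the background never
    becomes more informative than uniform.
    """
    mask = counts.n > 0
    if int(mask.sum()) < 30:
        raise ValueError(
            f"background fit needs >= 30 covered sites, got {int(mask.sum())}")
    k = counts.k[mask].astype(float)
    n = counts.n[mask].astype(float)
    p = k / n
    inv_n = (1.0 / n).mean()
    if symmetric:
        msq = ((p - 0.5) ** 2).mean()
        denom = 0.25 * (1.0 - inv_n)
        rho = (msq - 0.25 * inv_n) / denom
        if rho <= 0:
            return 50.0, 50.0
        rho = min(rho, 1.0 / 3.0)  # alpha = beta >= 1
        ab = max((1.0 / rho - 1.0) / 2.0, 1.0)
        return float(ab), float(ab)
    m = p.mean()
    v = p.var()
    denom = m * (1.0 - m) * (1.0 - inv_n)
    if denom <= 0:
        return 50.0, 50.0
    rho = (v - m * (1.0 - m) * inv_n) / denom
    if rho <= 0 or rho >= 1:
        return 50.0, 50.0
    s = 1.0 / rho - 1.0  # alpha + beta
    alpha = m * s
    beta = (1.0 - m) * s
    if alpha <= 0 or beta <= 0:
        return 50.0, 50.0
    return float(alpha), float(beta)


def recomb_prob(distance_bp, L: float):
    """Recombination probability between two markers ``distance_bp`` apart.

    r(d) = 0.5 (1 - exp(-d/L)); 0 at d = 0, saturating at 1/2.
    """
    if L <= 0:
        raise ValueError("L must be > 0")
    d = np.asarray(distance_bp, dtype=float)
    if (d < 0).any():
        raise ValueError("distance must be >= 0")
    r = 0.5 * (1.0 - np.exp(-d / L))
    return float(r) if np.isscalar(distance_bp) else r


def transition_matrix(r: float) -> np.ndarray:
    """3x3 transition matrix: stay with 1 - r, switch to each other state r/2."""
    if not 0 <= r <= 0.5:
        raise ValueError("r must be in [0, 0.5]")
    T = np.full((3, 3), r / 2.0)
    np.fill_diagonal(T, 1.0 - r)
    return T


def _betabinom_logpmf(k, n, alpha: float, beta: float):
    """Beta-binomial log-pmf written as three label-swap-invariant terms.

    Each bracketed term is unchanged (bitwise) under the simultaneous map
    k -> n-k, alpha <-> beta, which makes downstream linkage scores exactly
    antisymmetric under a parent-label swap.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    choose = gammaln(n + 1.0) - (gammaln(k + 1.0) + gammaln(n - k + 1.0))
    num = (gammaln(k + alpha) + gammaln(n - k + beta)) - gammaln(n + (alpha + beta))
    den = (gammaln(alpha) + gammaln(beta)) - gammaln(alpha + beta)
    return choose + num - den


def emission_logprob(k, n, state: int, params: HMMParams):
    """Log P(k superior-allele calls out of n | state), beta-binomial."""
    k_arr = np.asarray(k)
    n_arr = np.asarray(n)
    if (k_arr < 0).any() or (k_arr > n_arr).any() or (n_arr < 0).any():
        raise ValueError("need 0 <= k <= n")
    ab = {
        SUP: (params.alpha_sup, params.beta_sup),
        INF: (params.alpha_inf, params.beta_inf),
        BG: (params.alpha_bg, params.beta_bg),
    }
    try:
        alpha, beta = ab[state]
    except KeyError:
        raise ValueError(f"unknown state {state!r}") from None
    out = _betabinom_logpmf(k_arr, n_arr, alpha, beta)
    return float(out) if np.isscalar(k) else out


def _chain_posteriors(k, n, pos, params: HMMParams) -> np.ndarray:
    """Scaled forward-backward over one chromosome; returns (S, 3) posteriors.

    Matrix-vector products are expanded through the row-sum identity of the
    symmetric transition matrix (new[j] = e[j] (d x[j] + o (X - x[j]))),
    which keeps the computation elementwise and hence exactly equivariant
    under the sup/inf state permutation.
    """
    S = len(k)
    logE = np.stack([
        _betabinom_logpmf(k, n, params.alpha_sup, params.beta_sup),
        _betabinom_logpmf(k, n, params.alpha_inf, params.beta_inf),
        _betabinom_logpmf(k, n, params.alpha_bg, params.beta_bg),
    ], axis=1)
    # per-site shift before exponentiation: underflow-safe, cancels in posteriors
    E = np.exp(logE - logE.max(axis=1, keepdims=True))

    r = recomb_prob(np.diff(pos.astype(float)), params.map_scale)
    diag = 1.0 - r
    off = r / 2.0

    alpha = np.empty((S, 3))
    a = np.asarray(params.initial_probs) * E[0]
    alpha[0] = a / a.sum()
    for t in range(1, S):
        prev = alpha[t - 1]
        tot = prev.sum()  # = 1, kept explicit for the symmetric expansion
        a = E[t] * (diag[t - 1] * prev + off[t - 1] * (tot - prev))
        alpha[t] = a / a.sum()

    beta = np.empty((S, 3))
    beta[S - 1] = 1.0
    for t in range(S - 2, -1, -1):
        x = E[t + 1] * beta[t + 1]
        tot = x.sum()
        b = diag[t] * x + off[t] * (tot - x)
        beta[t] = b / b.sum()

    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post


def forward_backward(
    counts: PoolCounts,
    params: HMMParams | None = None,
    estimate_bg: bool = True,
) -> pd.DataFrame:
    """Per-marker posterior state probabilities and signed linkage scores.

    Each chromosome is decoded as an independent chain restarting from
    ``initial_probs``. Returns a DataFrame with columns chrom, pos, n, k,
    p_sup, p_inf, p_bg and linkage_score = p_sup - p_inf. When
    ``estimate_bg`` is true the background Beta is first fitted to all
    sites of this pool (the fitted values are attached as ``df.attrs``).
    Sites without reads contribute no emission information (uniform
    emission) but still pass transition mass along the chain.
    """
    if params is None:
        params = HMMParams()
    if estimate_bg:
        a_bg, b_bg = estimate_background(counts, symmetric=True)
        params = params.with_background(a_bg, b_bg)

    ms = counts.marker_set
    frames = []
    for name in ms.chromosome_names():
        sel = np.flatnonzero(ms.chrom == name)
        if sel.size == 0:
            continue
        post = _chain_posteriors(counts.k[sel], counts.n[sel], ms.pos[sel], params)
        frames.append(pd.DataFrame({
            "chrom": name,
            "pos": ms.pos[sel],
            "k": counts.k[sel],
            "n": counts.n[sel],
            "p_sup": post[:, SUP],
            "p_inf": post[:, INF],
            "p_bg": post[:, BG],
        }))
    df = pd.concat(frames, ignore_index=True)
    df["linkage_score"] = df["p_sup"] - df["p_inf"]
    df.attrs["alpha_bg"] = params.alpha_bg
    df.attrs["beta_bg"] = params.beta_bg
    df.attrs["params"] = params
    return df


@dataclass
class QTLCall:
    """A contiguous run of significantly linked markers."""

    chrom: str
    start: int  # 1-based inclusive, first significant marker
    end: int    # 1-based inclusive, last significant marker
    n_significant_snps: int
    mean_linkage: float
    parent: str  # "superior" | "inferior"
    presence_in_other_pool: str | None = None
    member_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int),
                                     repr=False)


def call_qtls(
    posteriors: pd.DataFrame,
    threshold: float = 0.95,
    min_snps: int = 10,
    max_gap_bp: int = 30_000,
) -> list[QTLCall]:
    """Merge significant markers into QTL intervals.

    Markers with |linkage_score| strictly above ``threshold`` and of the
    same sign, on the same chromosome, separated by at most ``max_gap_bp``
    are one interval; intervals with fewer than ``min_snps`` significant
    markers are dropped. The span runs from the first to the last
    significant marker; ``mean_linkage`` averages member scores.
    """
    calls: list[QTLCall] = []
    score = posteriors["linkage_score"].to_numpy()
    sig = np.abs(score) > threshold
    for name, grp_idx in posteriors.groupby("chrom", sort=False).indices.items():
        idx = np.asarray(grp_idx)[sig[np.asarray(grp_idx)]]
        if idx.size == 0:
            continue
        pos = posteriors["pos"].to_numpy()[idx]
        sgn = np.sign(score[idx])
        run = [0]
        for j in range(1, len(idx)):
            new_run = (pos[j] - pos[j - 1] > max_gap_bp) or (sgn[j] != sgn[j - 1])
            run.append(run[-1] + 1 if new_run else run[-1])
        run = np.asarray(run)
        for rid in np.unique(run):
            members = idx[run == rid]
            if len(members) < min_snps:
                continue
            mean_link = float(score[members].mean())
            calls.append(QTLCall(
                chrom=name,
                start=int(posteriors["pos"].to_numpy()[members[0]]),
                end=int(posteriors["pos"].to_numpy()[members[-1]]),
                n_significant_snps=int(len(members)),
                mean_linkage=mean_link,
                parent="superior" if mean_link > 0 else "inferior",
                member_index=members,
            ))
    return calls


def calls_to_dataframe(calls: list[QTLCall]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "chrom": c.chrom, "start": c.start, "end": c.end,
            "n_significant_snps": c.n_significant_snps,
            "mean_linkage": c.mean_linkage, "parent": c.parent,
            "presence_in_other_pool": c.presence_in_other_pool,
        }
        for c in calls
    ])


def compare_pools(
    calls_a: list[QTLCall],
    posteriors_b: pd.DataFrame,
    threshold: float = 0.95,
    weak_threshold: float = 0.5,
) -> list[QTLCall]:
    """Annotate each call with its presence in a second pool.

    "Yes" if the interval overlaps a same-sign significant marker
    (|score| > threshold) in the other pool, "Weak" if only a same-sign
    sub-threshold elevation (|score| > weak_threshold), else "No".
    Both analyses must share the marker panel.
    """
    out = []
    for call in calls_a:
        sel = (
            (posteriors_b["chrom"] == call.chrom)
            & (posteriors_b["pos"] >= call.start)
            & (posteriors_b["pos"] <= call.end)
        )
        if call.member_index.size and sel.sum() == 0:
            raise ValueError("marker panels of the two pools do not match")
        s = posteriors_b.loc[sel, "linkage_score"].to_numpy()
        sign = 1.0 if call.parent == "superior" else -1.0
        same = s * sign
        if (same > threshold).any():
            presence = "Yes"
        elif (same > weak_threshold).any():
            presence = "Weak"
        else:
            presence = "No"
        out.append(replace_call(call, presence))
    return out


def replace_call(call: QTLCall, presence: str) -> QTLCall:
    return QTLCall(
        chrom=call.chrom, start=call.start, end=call.end,
        n_significant_snps=call.n_significant_snps,
        mean_linkage=call.mean_linkage, parent=call.parent,
        presence_in_other_pool=presence, member_index=call.member_index,
    )
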