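"""Superior-allele ("SNP variant") frequency tracks and smoothing.

The raw track is simply k/n per marker (undefined where the pool has no
reads). The smoothed track is a coverage-weighted Nadaraya-Watson local
average with a Gaussian kernel along the chromosome — a transparent
presentation-layer smoother; QTL calls come from the HMM, not from the
smooth. Chromosome boundaries are hard edges: no borrowing across them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_qc import PoolCounts

__all__ = ["FrequencyTrack", "compute_frequencies", "smooth_track"]

# kernel support truncated at +/- 5 sd; weights beyond are < 4e-6 of the peak
_TRUNC_SD = 5.0


@dataclass
class FrequencyTrack:
    """Per-marker allele-frequency track.

    ``raw_freq`` is NaN where n = 0; ``smooth_freq`` is NaN until
    :func:`smooth_track` fills it (and stays NaN where no site within the
    kernel window has reads).
    """

    chrom: np.ndarray
    pos: np.ndarray
    raw_freq: np.ndarray
    smooth_freq: np.ndarray
    n: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "raw_freq": self.raw_freq,
                "smooth_freq": self.smooth_freq,
                "n": self.n,
            }
        )

    def to_bedgraph(self, path: str, column: str = "smooth_freq") -> None:
        df = self.to_dataframe()
        vals = df[column]
        with open(path, "w") as fh:
            for row, v in zip(df.itertuples(index=False), vals):
                if np.isfinite(v):
                    fh.write(f"{row.chrom}\t{row.pos - 1}\t{row.pos}\t{v:.6g}\n")


def compute_frequencies(counts: PoolCounts) -> FrequencyTrack:
    """Raw superior-allele frequency k/n per marker; NaN where n = 0."""
    ms = counts.marker_set
    n = counts.n.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(n > 0, counts.k / np.where(n > 0, n, 1.0), np.nan)
    return FrequencyTrack(
        chrom=ms.chrom.copy(),
        pos=ms.pos.copy(),
        raw_freq=raw,
        smooth_freq=np.full(len(ms), np.nan),
        n=counts.n.copy(),
    )


def smooth_track(track: FrequencyTrack, bandwidth_bp: float = 20_000) -> FrequencyTrack:
    """Fill ``smooth_freq`` with a depth-weighted Gaussian kernel estimate.

    Per chromosome, smooth(x_i) = sum_j w_ij f_j / sum_j w_ij with
    w_ij = n_j * exp(-(x_i - x_j)^2 / (2 bw^2)) over sites with reads.
    The estimate is a convex combination of raw frequencies, hence bounded
    by their chromosome-wise min and max, and exactly reproduces a constant
    track. Uniform depth rescaling leaves it unchanged.
    """
    if bandwidth_bp <= 0:
        raise ValueError("bandwidth must be > 0")
    smooth = np.full(len(track.pos), np.nan)
    for name in pd.unique(track.chrom):
        sel = np.flatnonzero(track.chrom == name)
        pos = track.pos[sel].astype(float)
        raw = track.raw_freq[sel]
        w_depth = track.n[sel].astype(float)
        valid = (w_depth > 0) & np.isfinite(raw)
        if not valid.any():
            continue
        vpos, vraw, vw = pos[valid], raw[valid], w_depth[valid]
        out = np.full(len(sel), np.nan)
        half = _TRUNC_SD * bandwidth_bp
        lo = np.searchsorted(vpos, pos - half, side="left")
        hi = np.searchsorted(vpos, pos + half, side="right")
        for i in range(len(sel)):
            if lo[i] == hi[i]:
                continue
            d = vpos[lo[i]:hi[i]] - pos[i]
            w = vw[lo[i]:hi[i]] * np.exp(-0.5 * (d / bandwidth_bp) ** 2)
            out[i] = np.dot(w, vraw[lo[i]:hi[i]]) / w.sum()
        smooth[sel] = out
    return FrequencyTrack(
        chrom=track.chrom.copy(),
        pos=track.pos.copy(),
        raw_freq=track.raw_freq.copy(),
        smooth_freq=smooth,
        n=track.n.copy(),
    )
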