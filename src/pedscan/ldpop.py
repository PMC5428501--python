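"""Pairwise r² linkage disequilibrium, distance-binned decay curve and
the half-maximum decay distance.

r² between two biallelic sites, over samples non-missing at both, is
D² / (p_i(1−p_i)·p_j(1−p_j)) with D = P(ALT,ALT) − p_i·p_j. Calls are
haploid (inbred lines), so two-site haplotype frequencies are direct
counts — no phasing or Hardy-Weinberg machinery applies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pedscan.genio import GenotypeMatrix

log = logging.getLogger(__name__)

_BLOCK = 256  # sites per block in the pairwise product


def pairwise_r2(matrix: GenotypeMatrix, samples=None,
                max_distance: int = 500_000,
                min_maf: float = 0.005) -> pd.DataFrame:
    """All intra-chromosome site pairs within max_distance bp.

    Sites first pass a minor-allele-frequency filter computed on
    non-missing calls. Pairs whose conditional (both-observed) call set
    is monomorphic at either site are skipped. Returns site_i, site_j,
    dist, r2.
    """
    if min_maf >= 0.5:
        raise ValueError("min_maf must be < 0.5")
    calls = matrix.calls
    if samples is not None:
        calls = calls[:, matrix.sample_indices(samples)]
    n_obs = (calls >= 0).sum(axis=1)
    n_alt = (calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        p = np.where(n_obs > 0, n_alt / np.maximum(n_obs, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    keep = (n_obs >= 2) & (maf >= min_maf)

    var = matrix.variants
    out_i, out_j, out_d, out_r2 = [], [], [], []
    for chrom in var["chrom"].unique():
        mask = (var["chrom"] == chrom).to_numpy() & keep
        idx = np.flatnonzero(mask)
        if len(idx) < 2:
            continue
        pos = var.loc[idx, "pos"].to_numpy()
        V = (calls[idx] >= 0).astype(np.float64)
        C = (calls[idx] == 1).astype(np.float64)
        m = len(idx)
        for b0 in range(0, m, _BLOCK):
            b1 = min(b0 + _BLOCK, m)
            # partners: strictly later sites within max_distance of any
            # site in the block
            j_hi = int(np.searchsorted(pos, pos[b1 - 1] + max_distance,
                                       side="right"))
            j0, j1 = b0, j_hi
            if j1 - j0 < 2:
                continue
            Vb, Cb = V[b0:b1], C[b0:b1]
            Vj, Cj = V[j0:j1], C[j0:j1]
            N = Vb @ Vj.T
            N11 = Cb @ Cj.T
            Ni = Cb @ Vj.T
            Nj = Vb @ Cj.T
            with np.errstate(divide="ignore", invalid="ignore"):
                pi_ = Ni / N
                pj_ = Nj / N
                p11 = N11 / N
                D = p11 - pi_ * pj_
                denom = pi_ * (1 - pi_) * pj_ * (1 - pj_)
                r2 = D * D / denom
            rows = np.arange(b0, b1)[:, None]
            cols = np.arange(j0, j1)[None, :]
            dist = pos[cols] - pos[rows]
            valid = (cols > rows) & (dist <= max_distance) & (N >= 2) & (
                denom > 0)
            ii, jj = np.nonzero(valid)
            out_i.append(idx[rows[ii, 0]])
            out_j.append(idx[cols[0, jj]])
            out_d.append(dist[ii, jj])
            out_r2.append(r2[ii, jj])
    if not out_i:
        return pd.DataFrame(columns=["site_i", "site_j", "dist", "r2"])
    return pd.DataFrame(
        {
            "site_i": np.concatenate(out_i),
            "site_j": np.concatenate(out_j),
            "dist": np.concatenate(out_d).astype(int),
            "r2": np.concatenate(out_r2),
        }
    )


def decay_curve(pairs: pd.DataFrame, bin_bp: int = 1000,
                max_distance: int | None = None) -> pd.DataFrame:
    """Mean r² in contiguous distance bins [k·bin_bp, (k+1)·bin_bp).

    Empty bins are reported with n_pairs=0 and NaN mean. Columns:
    dist_lo, dist_hi, mid, n_pairs, mean_r2.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    if len(pairs) == 0:
        raise ValueError("no pairs")
    d = pairs["dist"].to_numpy()
    r2 = pairs["r2"].to_numpy(dtype=float)
    top = int(max_distance) if max_distance is not None else int(d.max()) + 1
    n_bins = int(np.ceil(top / bin_bp))
    which = np.minimum(d // bin_bp, n_bins - 1).astype(int)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=r2, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    lo = np.arange(n_bins) * bin_bp
    return pd.DataFrame(
        {
            "dist_lo": lo,
            "dist_hi": lo + bin_bp,
            "mid": lo + bin_bp / 2.0,
            "n_pairs": counts,
            "mean_r2": means,
        }
    )


@dataclass
class HalfDecay:
    reached: bool
    distance_bp: float | None
    r2_at: float
    r2_max: float


def half_decay_distance(curve: pd.DataFrame) -> HalfDecay:
    """First bin whose mean r² falls to half the maximum binned mean.

    Returns the bin midpoint and the r² there; when no bin reaches
    half-maximum within range, signals not-reached with the final
    non-empty bin's r².
    """
    filled = curve[curve["n_pairs"] > 0]
    if len(filled) < 2:
        raise ValueError("decay curve needs ≥2 non-empty bins")
    r2max = float(filled["mean_r2"].max())
    half = r2max / 2.0
    hit = filled[filled["mean_r2"] <= half]
    if len(hit) == 0:
        return HalfDecay(False, None, float(filled["mean_r2"].iloc[-1]), r2max)
    first = hit.iloc[0]
    return HalfDecay(True, float(first["mid"]), float(first["mean_r2"]), r2max)
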