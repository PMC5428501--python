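"""Between-group divergence scans and SNP set comparisons.

Per-window Fst uses the Hudson ratio-of-sums estimator:
Fst = Σ_s (Hb_s − Hw_s) / Σ_s Hb_s with per-site between-group
heterozygosity Hb = p_a(1−p_b) + p_b(1−p_a) and within-group
Hw = [2p_a(1−p_a)·n_a/(n_a−1) + 2p_b(1−p_b)·n_b/(n_b−1)] / 2 over
non-missing haploid calls. ZFst is the genome-wide Z-standardization of
window Fst. Sweep candidates are windows in the right tails of BOTH the
log2 π ratio and ZFst distributions, merged into regions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from pedscan.diversity import (
    STEP_BP_DEFAULT,
    WINDOW_BP_DEFAULT,
    genome_windows,
    merge_windows,
    windowed_pi,
)
from pedscan.genio import GenotypeMatrix

log = logging.getLogger(__name__)

PSEUDO_POLICIES = ("drop", "inf")


def _group_counts(matrix: GenotypeMatrix, idx: np.ndarray):
    calls = matrix.calls[:, idx]
    n = (calls >= 0).sum(axis=1).astype(np.float64)
    c = (calls == 1).sum(axis=1).astype(np.float64)
    return n, c


def windowed_fst(matrix: GenotypeMatrix, group_a: list[str],
                 group_b: list[str], window_bp: int = WINDOW_BP_DEFAULT,
                 step_bp: int = STEP_BP_DEFAULT) -> pd.DataFrame:
    """Hudson-type window Fst between two disjoint sample groups.

    Sites need ≥2 non-missing calls in each group; windows whose
    between-group heterozygosity sums to 0 are dropped and logged.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap: "
                         f"{sorted(set(group_a) & set(group_b))}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs ≥2 samples")
    ia = matrix.sample_indices(group_a)
    ib = matrix.sample_indices(group_b)
    na, ca = _group_counts(matrix, ia)
    nb, cb = _group_counts(matrix, ib)

    ok = (na >= 2) & (nb >= 2)
    pa = np.where(ok, ca / np.maximum(na, 1), 0.0)
    pb = np.where(ok, cb / np.maximum(nb, 1), 0.0)
    hb = np.where(ok, pa * (1 - pb) + pb * (1 - pa), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        hw_a = 2 * pa * (1 - pa) * na / np.maximum(na - 1, 1)
        hw_b = 2 * pb * (1 - pb) * nb / np.maximum(nb - 1, 1)
    hw = np.where(ok, (hw_a + hw_b) / 2.0, 0.0)

    var = matrix.variants
    out = []
    for chrom, wdf in genome_windows(matrix.effective_chrom_sizes(),
                                     window_bp, step_bp).groupby("chrom",
                                                                 sort=True):
        in_chrom = (var["chrom"] == chrom).to_numpy()
        pos = var.loc[in_chrom, "pos"].to_numpy()
        hb_c = np.concatenate(([0.0], np.cumsum(hb[in_chrom])))
        hw_c = np.concatenate(([0.0], np.cumsum(hw[in_chrom])))
        n_c = np.concatenate(([0], np.cumsum(ok[in_chrom].astype(int))))
        lo = np.searchsorted(pos, wdf["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, wdf["end"].to_numpy(), side="right")
        res = wdf[["chrom", "start", "end"]].copy()
        res["n_sites"] = n_c[hi] - n_c[lo]
        sum_hb = hb_c[hi] - hb_c[lo]
        sum_hw = hw_c[hi] - hw_c[lo]
        with np.errstate(divide="ignore", invalid="ignore"):
            res["fst"] = np.where(sum_hb > 0,
                                  (sum_hb - sum_hw) / np.where(sum_hb > 0,
                                                               sum_hb, 1.0),
                                  np.nan)
        out.append(res)
    df = pd.concat(out, ignore_index=True)
    n_dropped = int(df["fst"].isna().sum())
    if n_dropped:
        log.info("windowed_fst: dropped %d windows with zero between-group "
                 "heterozygosity", n_dropped)
    df = df[df["fst"].notna()].reset_index(drop=True)
    return df


def zfst(windows: pd.DataFrame) -> pd.DataFrame:
    """Z-standardize window Fst genome-wide (sample sd, n−1)."""
    fst = windows["fst"].to_numpy(dtype=float)
    if len(fst) < 2:
        raise ValueError("zfst needs ≥2 retained windows")
    sd = float(np.std(fst, ddof=1))
    if sd == 0:
        raise ValueError("zfst undefined: zero variance in window Fst")
    out = windows.copy()
    out["zfst"] = (fst - float(np.mean(fst))) / sd
    return out


def pi_ratio(windows_a: pd.DataFrame, windows_b: pd.DataFrame,
             pseudo_policy: str = "drop") -> pd.DataFrame:
    """log2(π_a/π_b) on a shared window grid.

    Default policy drops (and logs) windows where either group's π is 0
    — a planted zero-diversity window would otherwise dominate the
    quantiles with an infinite ratio. Policy 'inf' keeps one-sided
    zeros as ±inf; 0/0 windows are always dropped.
    """
    if pseudo_policy not in PSEUDO_POLICIES:
        raise ValueError(f"pseudo_policy must be one of {PSEUDO_POLICIES}")
    key = ["chrom", "start", "end"]
    if len(windows_a) != len(windows_b) or not (
        windows_a[key].reset_index(drop=True)
        .equals(windows_b[key].reset_index(drop=True))
    ):
        raise ValueError("window grids differ between groups")
    df = windows_a[key].copy().reset_index(drop=True)
    pa = windows_a["pi"].to_numpy(dtype=float)
    pb = windows_b["pi"].to_numpy(dtype=float)
    df["pi_a"] = pa
    df["pi_b"] = pb
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((pa > 0) & (pb > 0), np.log2(
            np.where(pb > 0, pa, 1.0) / np.where(pb > 0, pb, 1.0)), np.nan)
        if pseudo_policy == "inf":
            ratio = np.where((pa > 0) & (pb == 0), np.inf, ratio)
            ratio = np.where((pa == 0) & (pb > 0), -np.inf, ratio)
    df["log2_ratio"] = ratio
    n_dropped = int(np.isnan(ratio).sum())
    if n_dropped:
        log.info("pi_ratio: %d windows without a defined ratio "
                 "(policy=%s)", n_dropped, pseudo_policy)
    return df[~np.isnan(ratio)].reset_index(drop=True)


def sweep_scan(matrix: GenotypeMatrix, group_a: list[str], group_b: list[str],
               window_bp: int = WINDOW_BP_DEFAULT,
               step_bp: int = STEP_BP_DEFAULT,
               pseudo_policy: str = "drop") -> pd.DataFrame:
    """Assemble the per-window sweep table: pi_a, pi_b, log2_ratio, fst,
    zfst. Windows lacking either statistic carry NaN in that column."""
    pi_a = windowed_pi(matrix, window_bp, step_bp, samples=group_a)
    pi_b = windowed_pi(matrix, window_bp, step_bp, samples=group_b)
    ratios = pi_ratio(pi_a, pi_b, pseudo_policy)
    fst_w = zfst(windowed_fst(matrix, group_a, group_b, window_bp, step_bp))
    key = ["chrom", "start", "end"]
    grid = pi_a[key].copy()
    grid["pi_a"] = pi_a["pi"].to_numpy()
    grid["pi_b"] = pi_b["pi"].to_numpy()
    merged = grid.merge(ratios[key + ["log2_ratio"]], on=key, how="left")
    merged = merged.merge(fst_w[key + ["fst", "zfst"]], on=key, how="left")
    return merged


def call_sweeps(windows: pd.DataFrame, tail: float = 0.05) -> pd.DataFrame:
    """Dual-tail sweep calling.

    Thresholds are the empirical (1−tail) quantiles of log2_ratio and
    zfst over the windows where each is defined; windows strictly above
    BOTH merge (overlap/abut) into candidate regions. An empty result
    is not an error.
    """
    ratio = windows["log2_ratio"].to_numpy(dtype=float)
    z = windows["zfst"].to_numpy(dtype=float)
    ratio_ok = np.isfinite(ratio)
    z_ok = np.isfinite(z)
    if ratio_ok.sum() == 0 or z_ok.sum() == 0:
        return merge_windows(windows.iloc[0:0].assign(score=[]), stat="score")
    thr_ratio = float(np.quantile(ratio[ratio_ok], 1 - tail))
    thr_z = float(np.quantile(z[z_ok], 1 - tail))
    passing = windows[
        ratio_ok & z_ok & (ratio > thr_ratio) & (z > thr_z)
    ].copy()
    passing["score"] = passing["zfst"]
    regions = merge_windows(passing, stat="score")
    regions.attrs["threshold_log2_ratio"] = thr_ratio
    regions.attrs["threshold_zfst"] = thr_z
    return regions


# ---------------------------------------------------------------------------
# SNP set comparisons between pedigrees
# ---------------------------------------------------------------------------

def segregating_sites(matrix: GenotypeMatrix, samples: list[str]) -> set:
    """(chrom, pos) of sites segregating within the given samples."""
    idx = matrix.sample_indices(samples)
    mask = matrix.segregating_mask(idx)
    var = matrix.variants
    return set(zip(var.loc[mask, "chrom"], var.loc[mask, "pos"].astype(int)))


def snp_set_compare(site_sets: dict[str, set]) -> dict[str, int]:
    """Venn counts over per-group segregating-site sets.

    Keys: '<name>' total per group, '<name>_unique', pairwise
    '<a>&<b>', the full intersection 'common_all', and 'union'.
    """
    names = sorted(site_sets)
    out: dict[str, int] = {}
    universe: set = set()
    for n in names:
        out[n] = len(site_sets[n])
        universe |= site_sets[n]
    for n in names:
        others: set = set()
        for m in names:
            if m != n:
                others |= site_sets[m]
        out[f"{n}_unique"] = len(site_sets[n] - others)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out[f"{a}&{b}"] = len(site_sets[a] & site_sets[b])
    common = set(site_sets[names[0]]) if names else set()
    for n in names[1:]:
        common &= site_sets[n]
    out["common_all"] = len(common)
    out["union"] = len(universe)
    return out


def pedigree_specific_genotypes(matrix: GenotypeMatrix,
                                groups: dict[str, list[str]],
                                min_call_rate: float = 0.8) -> pd.DataFrame:
    """Sites where one group exclusively and uniformly carries an allele.

    A site is specific to group G with allele a iff every non-missing
    call in G equals a and no non-missing call outside G equals a.
    Sites with call rate < min_call_rate in G or in the complement are
    skipped. Returns site_id, chrom, pos, group, allele.
    """
    if len(groups) < 2:
        raise ValueError("need ≥2 groups")
    var = matrix.variants
    rows = []
    all_idx = {g: matrix.sample_indices(s) for g, s in groups.items()}
    for g, idx in sorted(all_idx.items()):
        rest = np.array(
            sorted(set(range(matrix.n_samples)) - set(idx.tolist())), dtype=int
        )
        cg = matrix.calls[:, idx]
        cr = matrix.calls[:, rest]
        obs_g = cg >= 0
        obs_r = cr >= 0
        rate_g = obs_g.mean(axis=1)
        rate_r = obs_r.mean(axis=1) if rest.size else np.ones(matrix.n_sites)
        for allele in (0, 1):
            uniform_g = obs_g.sum(axis=1) > 0
            uniform_g &= ((cg == allele) | ~obs_g).all(axis=1)
            absent_r = ~((cr == allele) & obs_r).any(axis=1) if rest.size else \
                np.ones(matrix.n_sites, dtype=bool)
            hit = uniform_g & absent_r & (rate_g >= min_call_rate) & (
                rate_r >= min_call_rate)
            for s in np.flatnonzero(hit):
                rows.append(
                    {
                        "site_id": int(s),
                        "chrom": var.at[s, "chrom"],
                        "pos": int(var.at[s, "pos"]),
                        "group": g,
                        "allele": var.at[s, "ref"] if allele == 0
                        else var.at[s, "alt"],
                    }
                )
    df = pd.DataFrame(rows, columns=["site_id", "chrom", "pos", "group",
                                     "allele"])
    return df.sort_values(["group", "site_id"]).reset_index(drop=True)
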