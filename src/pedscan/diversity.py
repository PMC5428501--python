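"""Windowed nucleotide diversity (π) and low/zero-diversity detection.

π is the average pairwise per-bp nucleotide diversity. Per site s with
c_s ALT calls among n_s non-missing haploid calls, the unbiased
per-site pairwise diversity is 2·c_s·(n_s−c_s)/(n_s·(n_s−1)); window π
sums these over sites in the window and divides by the full window
length in bp (monomorphic positions count in the denominator, which is
what gives genome-scale magnitudes like 0.002).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from pedscan.genio import GeneModel, GenotypeMatrix

log = logging.getLogger(__name__)

WINDOW_BP_DEFAULT = 100_000
STEP_BP_DEFAULT = 10_000


def genome_windows(chrom_sizes: dict[str, int], window_bp: int,
                   step_bp: int) -> pd.DataFrame:
    """Sliding-window grid: 1-based inclusive spans per chromosome.

    Terminal windows may be shorter than window_bp; they are kept and
    flagged (``truncated``) and their π uses the actual length.
    """
    if window_bp < step_bp:
        raise ValueError(
            f"window_bp ({window_bp}) < step_bp ({step_bp}): grid would skip bases"
        )
    rows = []
    for chrom in sorted(chrom_sizes):
        size = int(chrom_sizes[chrom])
        start = 1
        while start <= size:
            end = min(start + window_bp - 1, size)
            rows.append((chrom, start, end, end - start + 1 < window_bp))
            if end == size:
                break
            start += step_bp
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "truncated"])


def per_site_diversity(matrix: GenotypeMatrix,
                       sample_idx: np.ndarray | None = None) -> np.ndarray:
    """Per-site unbiased pairwise diversity 2c(n−c)/(n(n−1)); 0 when n<2."""
    calls = matrix.calls if sample_idx is None else matrix.calls[:, sample_idx]
    n = (calls >= 0).sum(axis=1).astype(np.float64)
    c = (calls == 1).sum(axis=1).astype(np.float64)
    d = np.zeros(len(calls), dtype=np.float64)
    ok = n >= 2
    d[ok] = 2.0 * c[ok] * (n[ok] - c[ok]) / (n[ok] * (n[ok] - 1.0))
    return d


def _window_sums(values: np.ndarray, positions: np.ndarray,
                 windows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Sum of per-site values and count of nonzero sites per window.

    ``positions`` must be sorted; windows are (start, end) inclusive.
    """
    cum = np.concatenate(([0.0], np.cumsum(values)))
    cnt = np.concatenate(([0], np.cumsum(values > 0)))
    lo = np.searchsorted(positions, windows["start"].to_numpy(), side="left")
    hi = np.searchsorted(positions, windows["end"].to_numpy(), side="right")
    return cum[hi] - cum[lo], cnt[hi] - cnt[lo]


def windowed_pi(matrix: GenotypeMatrix, window_bp: int = WINDOW_BP_DEFAULT,
                step_bp: int = STEP_BP_DEFAULT,
                samples=None) -> pd.DataFrame:
    """π per sliding window; columns chrom, start, end, n_sites, pi, truncated."""
    if matrix.n_sites == 0:
        raise ValueError("empty genotype matrix")
    sample_idx = None if samples is None else matrix.sample_indices(samples)
    d = per_site_diversity(matrix, sample_idx)

    out = []
    sizes = matrix.effective_chrom_sizes()
    var = matrix.variants
    for chrom, wdf in genome_windows(sizes, window_bp, step_bp).groupby(
            "chrom", sort=True):
        in_chrom = (var["chrom"] == chrom).to_numpy()
        pos = var.loc[in_chrom, "pos"].to_numpy()
        vals = d[in_chrom]
        sums, counts = _window_sums(vals, pos, wdf)
        length = (wdf["end"] - wdf["start"] + 1).to_numpy().astype(float)
        res = wdf.copy()
        res["n_sites"] = counts
        res["pi"] = sums / length
        out.append(res)
    return pd.concat(out, ignore_index=True)[
        ["chrom", "start", "end", "n_sites", "pi", "truncated"]
    ]


def merge_windows(windows: pd.DataFrame, stat: str = "pi") -> pd.DataFrame:
    """Merge overlapping/abutting windows into maximal regions.

    Returns chrom, start, end, n_windows, mean_<stat>, min_<stat>,
    max_<stat>.
    """
    rows = []
    for chrom, wdf in windows.groupby("chrom", sort=True):
        wdf = wdf.sort_values(["start", "end"])
        cur = None
        for _, w in wdf.iterrows():
            if cur is not None and w["start"] <= cur["end"] + 1:
                cur["end"] = max(cur["end"], w["end"])
                cur["vals"].append(w[stat])
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {"chrom": chrom, "start": int(w["start"]),
                       "end": int(w["end"]), "vals": [w[stat]]}
        if cur is not None:
            rows.append(cur)
    return pd.DataFrame(
        [
            {
                "chrom": r["chrom"],
                "start": r["start"],
                "end": r["end"],
                "n_windows": len(r["vals"]),
                f"mean_{stat}": float(np.mean(r["vals"])),
                f"min_{stat}": float(np.min(r["vals"])),
                f"max_{stat}": float(np.max(r["vals"])),
            }
            for r in rows
        ],
        columns=["chrom", "start", "end", "n_windows",
                 f"mean_{stat}", f"min_{stat}", f"max_{stat}"],
    )


def call_low_diversity(windows: pd.DataFrame, quantile: float = 0.01,
                       threshold: float | None = None
                       ) -> tuple[float, pd.DataFrame]:
    """Select the left-tail π windows and merge them into regions.

    The threshold is the empirical ``quantile`` of window π (linear
    interpolation); windows with π ≤ threshold (ties included) that
    overlap or abut merge into maximal regions. An explicit numeric
    ``threshold`` overrides the quantile rule (the study reported
    absolute cutoffs alongside the top-1% rule).
    """
    if len(windows) == 0:
        raise ValueError("empty window list")
    if len(windows) < 100 and threshold is None:
        log.warning("call_low_diversity: only %d windows; a %g quantile is "
                    "poorly resolved", len(windows), quantile)
    if threshold is None:
        threshold = float(np.quantile(windows["pi"].to_numpy(), quantile))
    passing = windows[windows["pi"] <= threshold]
    regions = merge_windows(passing, stat="pi")
    return threshold, regions


def zero_diversity_genes(matrix: GenotypeMatrix, genes: list[GeneModel],
                         samples=None, upstream_bp: int = 1000) -> list[str]:
    """Genes with no segregating SNP in the body or 1 kb strand-aware
    upstream flank, among the given samples.

    A site segregates when it has ≥1 ALT and ≥1 REF non-missing call.
    A gene with several transcripts qualifies only if every transcript
    span (plus flank) is clean.
    """
    sample_idx = None if samples is None else matrix.sample_indices(samples)
    seg = matrix.segregating_mask(sample_idx)
    var = matrix.variants
    seg_pos_by_chrom = {
        chrom: np.sort(var.loc[(var["chrom"] == chrom).to_numpy() & seg,
                               "pos"].to_numpy())
        for chrom in var["chrom"].unique()
    }

    bad_genes: set[str] = set()
    all_genes: dict[str, None] = {}
    for g in genes:
        all_genes.setdefault(g.gene_id)
        pos = seg_pos_by_chrom.get(g.chrom)
        flank_lo, flank_hi = g.upstream_flank(upstream_bp)
        spans = [(g.tx_start, g.tx_end)]
        if flank_hi >= flank_lo:
            spans.append((flank_lo, flank_hi))
        if pos is None or len(pos) == 0:
            continue
        for lo, hi in spans:
            i = np.searchsorted(pos, lo, side="left")
            j = np.searchsorted(pos, hi, side="right")
            if j > i:
                bad_genes.add(g.gene_id)
                break
    return [gid for gid in all_genes if gid not in bad_genes]
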