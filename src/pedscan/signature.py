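"""Pedigree breeding-signature scan.

Along the generation-ordered chain of immediate varieties, a SNP is a
breeding signature when its genotype string changes state exactly once
and retains the new state to the terminal variety (two-block pattern,
e.g. AATTTT with the incoming allele appearing at one generation and
preserved thereafter; AATTAT or AATTTA are rejected). Either allele may
be the incoming one. Monomorphic chains carry no evidence of a
selection event and are rejected (an ``allow_monomorphic`` switch is
provided for sensitivity analysis).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from pedscan.genio import GeneModel, GenotypeMatrix

log = logging.getLogger(__name__)

MISSING_POLICIES = ("exclude", "impute-bridge")


def scan_signatures(matrix: GenotypeMatrix, chain: list[str],
                    missing_policy: str = "exclude",
                    allow_monomorphic: bool = False) -> pd.DataFrame:
    """Signature SNPs along one immediate-variety chain.

    Returns a DataFrame with site_id, chrom, pos, pattern (allele
    letters along the chain, '.' for missing) and transition_index (the
    0-based chain position of the first variety carrying the incoming
    state).

    missing_policy:
      exclude (default) — any missing call along the chain disqualifies
        the site.
      impute-bridge — missing calls are wildcards; the site qualifies
        when the observed subsequence is a two-block pattern, with the
        transition index taken at the first observed derived call.
    """
    if len(chain) < 3:
        raise ValueError(f"chain must have ≥3 varieties, got {len(chain)}")
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
    idx = matrix.sample_indices(chain)
    sub = matrix.calls[:, idx]  # (n_sites, k)
    n_sites, k = sub.shape

    observed_any = sub >= 0
    if missing_policy == "exclude":
        valid = observed_any.all(axis=1)
        diffs = sub[:, 1:] != sub[:, :-1]
        n_trans = diffs.sum(axis=1)
        is_sig = valid & (n_trans == 1)
        trans_idx = np.where(is_sig, diffs.argmax(axis=1) + 1, -1)
    else:
        # forward-compare consecutive *observed* calls per site
        is_sig = np.zeros(n_sites, dtype=bool)
        trans_idx = np.full(n_sites, -1, dtype=int)
        for i in range(n_sites):
            obs = np.flatnonzero(observed_any[i])
            if len(obs) < 2:
                continue
            vals = sub[i, obs]
            changes = np.flatnonzero(vals[1:] != vals[:-1])
            if len(changes) == 1:
                is_sig[i] = True
                trans_idx[i] = int(obs[changes[0] + 1])

    if not allow_monomorphic:
        pass  # two-block patterns are polymorphic by construction
    else:
        # monomorphic (fully observed) chains admitted with no transition
        if missing_policy == "exclude":
            mono = observed_any.all(axis=1) & (
                (sub[:, 1:] == sub[:, :-1]).all(axis=1))
            is_sig = is_sig | mono

    sites = np.flatnonzero(is_sig)
    var = matrix.variants
    refs = var["ref"].to_numpy()
    alts = var["alt"].to_numpy()
    rows = []
    for s in sites:
        letters = []
        for c in sub[s]:
            letters.append("." if c < 0 else (refs[s] if c == 0 else alts[s]))
        rows.append(
            {
                "site_id": int(s),
                "chrom": var.at[s, "chrom"],
                "pos": int(var.at[s, "pos"]),
                "pattern": "".join(letters),
                "transition_index": int(trans_idx[s]),
            }
        )
    return pd.DataFrame(
        rows, columns=["site_id", "chrom", "pos", "pattern", "transition_index"]
    )


def _cds_trees(genes: list[GeneModel]):
    from intervaltree import IntervalTree

    trees: dict[str, "IntervalTree"] = {}
    for tx in genes:
        for s, e, _ in tx.cds_segments:
            trees.setdefault(tx.chrom, IntervalTree()).addi(s, e + 1, tx.gene_id)
    return trees


def _span_trees(genes: list[GeneModel], flank_bp: int):
    from intervaltree import IntervalTree

    trees: dict[str, "IntervalTree"] = {}
    for tx in genes:
        lo, hi = tx.tx_start, tx.tx_end
        flo, fhi = tx.upstream_flank(flank_bp)
        if fhi >= flo:
            lo, hi = min(lo, flo), max(hi, fhi)
        trees.setdefault(tx.chrom, IntervalTree()).addi(lo, hi + 1, tx.gene_id)
    return trees


def signature_genes(calls: pd.DataFrame, genes: list[GeneModel],
                    cds_only: bool = True) -> pd.DataFrame:
    """Per-gene signature-SNP counts (CDS-restricted by default).

    A SNP inside overlapping CDS of two genes counts in both. Returns
    gene_id, n_signature_snps and the mean SNPs/gene density column.
    """
    trees = _cds_trees(genes) if cds_only else _span_trees(genes, 0)
    counts: dict[str, int] = {}
    for row in calls.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for iv in tree[int(row.pos)]:
            counts[iv.data] = counts.get(iv.data, 0) + 1
    df = pd.DataFrame(
        sorted(counts.items()), columns=["gene_id", "n_signature_snps"]
    )
    df["snps_per_gene"] = (
        float(df["n_signature_snps"].mean()) if len(df) else np.nan
    )
    return df


def intergenic_fraction(calls: pd.DataFrame, genes: list[GeneModel],
                        flank_bp: int = 1000) -> float:
    """Fraction of signature SNPs outside all gene spans and upstream
    flanks. With no genes every SNP is intergenic (fraction 1.0)."""
    if len(calls) == 0:
        return 0.0
    trees = _span_trees(genes, flank_bp)
    n_out = 0
    for row in calls.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None or not tree[int(row.pos)]:
            n_out += 1
    return n_out / len(calls)
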