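"""SNP coding-effect classification, large-effect extraction and the
dn/ds count ratio.

Categories follow standard annotator vocabulary. Large-effect SNPs are
splice_acceptor, splice_donor, start_lost, stop_gained and stop_lost.
Splice sites are the canonical first/last 2 bp of each intron. When a
SNP hits several transcripts, the most severe category wins. dn/ds is
a raw count ratio (nonsynonymous / synonymous), not a per-site rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from pedscan.genio import GeneModel, GenotypeMatrix

log = logging.getLogger(__name__)

UPSTREAM_BP = 1000
SPLICE_BP = 2

LARGE_EFFECT = frozenset(
    {"splice_acceptor", "splice_donor", "start_lost", "stop_gained", "stop_lost"}
)

# Most severe first; ties between splice/start/stop classes are ordered
# but all sit above missense.
SEVERITY = [
    "splice_acceptor",
    "splice_donor",
    "start_lost",
    "stop_gained",
    "stop_lost",
    "missense",
    "synonymous",
    "utr5",
    "utr3",
    "noncoding_exon",
    "intron",
    "upstream",
    "intergenic",
]
_SEV_RANK = {c: i for i, c in enumerate(SEVERITY)}

# Table-style regional partition: every SNP maps to exactly one region.
REGION_OF_CATEGORY = {
    "synonymous": "CDS",
    "missense": "CDS",
    "stop_gained": "CDS",
    "stop_lost": "CDS",
    "start_lost": "CDS",
    "splice_acceptor": "intron",
    "splice_donor": "intron",
    "utr5": "5'UTR",
    "utr3": "3'UTR",
    "intron": "intron",
    "noncoding_exon": "noncoding_exon",
    "upstream": "intergenic",
    "intergenic": "intergenic",
}

NONSYNONYMOUS = frozenset({"missense", "stop_gained", "stop_lost", "start_lost"})

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class EffectCall:
    site_id: int
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str | None
    transcript_id: str | None
    category: str
    codon_ref: str | None = None
    codon_alt: str | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None

    @property
    def large_effect(self) -> bool:
        return self.category in LARGE_EFFECT


class RefMismatchError(ValueError):
    """VCF REF allele disagrees with the reference sequence."""


def _fetch(ref_seq, chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice from a dict of strings or a pyfaidx.Fasta."""
    seq = ref_seq[chrom]
    if isinstance(seq, str):
        return seq[start - 1:end].upper()
    return str(seq[start - 1:end]).upper()  # pyfaidx FastaRecord slice


def _introns(tx: GeneModel) -> list[tuple[int, int]]:
    """Genomic-order intron spans: gaps between exons when exon features
    exist, otherwise gaps between CDS segments."""
    segs = tx.exon_segments or sorted((s, e) for s, e, _ in tx.cds_segments)
    return [
        (a_end + 1, b_start - 1)
        for (_, a_end), (b_start, _) in zip(segs, segs[1:])
        if b_start - a_end > 1
    ]


def _cds_span(tx: GeneModel) -> tuple[int, int]:
    starts = [s for s, _, _ in tx.cds_segments]
    ends = [e for _, e, _ in tx.cds_segments]
    return min(starts), max(ends)


def _classify_coding(pos: int, ref: str, alt: str, tx: GeneModel,
                     ref_seq) -> tuple[str, str, str, str, str]:
    """Category plus (codon_ref, codon_alt, aa_ref, aa_alt) for a CDS hit."""
    segs_genomic = sorted((s, e) for s, e, _ in tx.cds_segments)
    cds = "".join(_fetch(ref_seq, tx.chrom, s, e) for s, e in segs_genomic)
    offset = 0
    plus_index = None
    for s, e in segs_genomic:
        if s <= pos <= e:
            plus_index = offset + (pos - s)
        offset += e - s + 1
    assert plus_index is not None
    total = len(cds)
    if tx.strand == "-":
        cds = cds[::-1].translate(_COMPLEMENT)
        index = total - 1 - plus_index
        ref_c = ref.translate(_COMPLEMENT)
        alt_c = alt.translate(_COMPLEMENT)
    else:
        index = plus_index
        ref_c, alt_c = ref, alt
    if cds[index] != ref_c:
        raise RefMismatchError(
            f"CDS base mismatch at {tx.chrom}:{pos} ({tx.transcript_id}): "
            f"expected {ref_c}, reference has {cds[index]}"
        )
    ci = index // 3
    within = index % 3
    codon_ref = cds[ci * 3:ci * 3 + 3]
    codon_alt = codon_ref[:within] + alt_c + codon_ref[within + 1:]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    n_codons = total // 3
    if ci == 0 and codon_ref == "ATG" and codon_alt != "ATG":
        cat = "start_lost"
    elif aa_ref == "*" and aa_alt != "*":
        cat = "stop_lost"
    elif aa_alt == "*" and aa_ref != "*":
        cat = "stop_gained"
    elif aa_ref == aa_alt:
        cat = "synonymous"
    else:
        cat = "missense"
    if ci == n_codons - 1 and aa_ref == "*" and aa_alt == "*":
        cat = "synonymous"
    return cat, codon_ref, codon_alt, aa_ref, aa_alt


def classify_effect(variant, tx: GeneModel, ref_seq) -> EffectCall:
    """Classify one SNP against one transcript.

    ``variant`` is a mapping (or namedtuple/Series) with chrom, pos,
    ref, alt and optionally site_id. Raises RefMismatchError when the
    reference sequence disagrees with the REF allele, and ValueError
    for flagged transcripts.
    """
    get = variant.get if hasattr(variant, "get") else variant.__getitem__
    chrom, pos = get("chrom"), int(get("pos"))
    ref, alt = get("ref").upper(), get("alt").upper()
    site_id = int(get("site_id")) if "site_id" in variant else -1
    if tx.flagged:
        raise ValueError(f"transcript {tx.transcript_id} is flagged; "
                         "cannot classify effects")
    if chrom == tx.chrom and tx.tx_start <= pos <= tx.tx_end:
        base = _fetch(ref_seq, chrom, pos, pos)
        if base != ref:
            raise RefMismatchError(
                f"REF mismatch at {chrom}:{pos}: VCF {ref}, FASTA {base}"
            )

    def call(cat, **kw):
        return EffectCall(site_id, chrom, pos, ref, alt,
                          tx.gene_id, tx.transcript_id, cat, **kw)

    if chrom != tx.chrom:
        return call("intergenic")

    flank_lo, flank_hi = tx.upstream_flank(UPSTREAM_BP)
    if flank_lo <= pos <= flank_hi:
        return call("upstream")
    if not (tx.tx_start <= pos <= tx.tx_end):
        return call("intergenic")

    for s, e in _introns(tx):
        if s <= pos <= e:
            if tx.strand == "+":
                donor = (s, min(e, s + SPLICE_BP - 1))
                acceptor = (max(s, e - SPLICE_BP + 1), e)
            else:
                donor = (max(s, e - SPLICE_BP + 1), e)
                acceptor = (s, min(e, s + SPLICE_BP - 1))
            if donor[0] <= pos <= donor[1]:
                return call("splice_donor")
            if acceptor[0] <= pos <= acceptor[1]:
                return call("splice_acceptor")
            return call("intron")

    if not tx.cds_segments:
        return call("noncoding_exon")

    cds_lo, cds_hi = _cds_span(tx)
    if cds_lo <= pos <= cds_hi:
        in_cds = any(s <= pos <= e for s, e, _ in tx.cds_segments)
        if in_cds:
            cat, cref, calt, aref, aalt = _classify_coding(pos, ref, alt, tx, ref_seq)
            return call(cat, codon_ref=cref, codon_alt=calt,
                        aa_ref=aref, aa_alt=aalt)
        # exonic position between CDS segments cannot occur (introns
        # handled above); fall through defensively
        return call("intron")
    if (tx.strand == "+" and pos < cds_lo) or (tx.strand == "-" and pos > cds_hi):
        return call("utr5")
    return call("utr3")


def _gene_interval_trees(genes: list[GeneModel], flank_bp: int = UPSTREAM_BP):
    from intervaltree import IntervalTree

    trees: dict[str, "IntervalTree"] = {}
    for tx in genes:
        lo = tx.tx_start
        hi = tx.tx_end
        flo, fhi = tx.upstream_flank(flank_bp)
        if fhi >= flo:
            lo, hi = min(lo, flo), max(hi, fhi)
        trees.setdefault(tx.chrom, IntervalTree()).addi(lo, hi + 1, tx)
    return trees


def classify_variants(matrix_or_variants, genes: list[GeneModel],
                      ref_seq) -> pd.DataFrame:
    """Most-severe effect per SNP across all overlapping transcripts.

    Flagged transcripts are skipped. Returns one row per SNP with
    category, gene/transcript of the winning call and codon details
    when coding.
    """
    if isinstance(matrix_or_variants, GenotypeMatrix):
        variants = matrix_or_variants.variants
    else:
        variants = matrix_or_variants
    usable = [g for g in genes if not g.flagged]
    trees = _gene_interval_trees(usable)

    rows = []
    for site_id, v in enumerate(variants.itertuples(index=False)):
        var = {"chrom": v.chrom, "pos": int(v.pos), "ref": v.ref,
               "alt": v.alt, "site_id": site_id}
        tree = trees.get(v.chrom)
        hits = tree[int(v.pos)] if tree is not None else ()
        best: EffectCall | None = None
        for iv in hits:
            ec = classify_effect(var, iv.data, ref_seq)
            if best is None or _SEV_RANK[ec.category] < _SEV_RANK[best.category]:
                best = ec
        if best is None:
            best = EffectCall(site_id, v.chrom, int(v.pos), v.ref, v.alt,
                              None, None, "intergenic")
        rows.append(
            {
                "site_id": best.site_id,
                "chrom": best.chrom,
                "pos": best.pos,
                "ref": best.ref,
                "alt": best.alt,
                "gene_id": best.gene_id,
                "transcript_id": best.transcript_id,
                "category": best.category,
                "region": REGION_OF_CATEGORY[best.category],
                "large_effect": best.large_effect,
                "codon_ref": best.codon_ref,
                "codon_alt": best.codon_alt,
                "aa_ref": best.aa_ref,
                "aa_alt": best.aa_alt,
            }
        )
    return pd.DataFrame(rows)


def dn_ds(effect_calls: pd.DataFrame) -> float:
    """Nonsynonymous / synonymous count ratio over coding calls."""
    n_syn = int((effect_calls["category"] == "synonymous").sum())
    if n_syn == 0:
        raise ValueError("dn/ds undefined: zero synonymous calls")
    n_nonsyn = int(effect_calls["category"].isin(NONSYNONYMOUS).sum())
    return n_nonsyn / n_syn


def large_effect_table(effect_calls: pd.DataFrame) -> pd.DataFrame:
    """Per-gene counts of large-effect SNPs with a category breakdown.

    A SNP counts once per gene even when several transcripts of the
    gene are hit (the table is built from the per-SNP winning call).
    """
    le = effect_calls[effect_calls["large_effect"]]
    if len(le) == 0:
        return pd.DataFrame(columns=["gene_id", "n_large_effect", "categories"])
    rows = []
    for gene_id, grp in le.groupby("gene_id", sort=True):
        counts = grp["category"].value_counts().sort_index()
        rows.append(
            {
                "gene_id": gene_id,
                "n_large_effect": int(len(grp)),
                "categories": ",".join(f"{k}:{v}" for k, v in counts.items()),
            }
        )
    return pd.DataFrame(rows)


def region_summary(effect_calls: pd.DataFrame) -> pd.Series:
    """SNP counts per regional category (exhaustive, disjoint)."""
    return effect_calls["region"].value_counts().sort_index()
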