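"""Readers/writers for VCF, GFF3, BED and pedigree TSV, plus the shared
in-memory genotype and gene-model containers.

Internal coordinates are 1-based inclusive (VCF/GFF native); the BED
writer converts at the boundary. Genotypes are haploid allele codes:
REF=0, ALT=1, MISSING=-1. Inbred varieties are effectively homozygous,
so diploid VCF genotypes collapse to haploid codes at load time.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING: int = -1

_BASES = {"A", "C", "G", "T"}

HET_POLICIES = ("missing", "ref", "alt", "fail")


class HetGenotypeError(ValueError):
    """Raised when het_policy='fail' meets a heterozygous call."""


@dataclass
class GenotypeMatrix:
    """Sites × samples haploid allele codes.

    variants: DataFrame with columns chrom, pos (1-based), ref, alt,
        sorted by (chrom, pos), no duplicates; row position is the
        stable site_id.
    samples: ordered unique sample names (columns of ``calls``).
    calls: int8 array of shape (n_sites, n_samples); -1 is missing.
    chrom_sizes: optional contig lengths (bp), e.g. from VCF headers.
    """

    variants: pd.DataFrame
    samples: list[str]
    calls: np.ndarray
    chrom_sizes: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.variants)}, {len(self.samples)})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample names")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, names) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise KeyError(f"unknown sample(s): {', '.join(missing)}")
        return np.array([pos[n] for n in names], dtype=int)

    def subset_samples(self, names) -> "GenotypeMatrix":
        idx = self.sample_indices(names)
        return GenotypeMatrix(
            variants=self.variants.copy(),
            samples=list(names),
            calls=self.calls[:, idx].copy(),
            chrom_sizes=self.chrom_sizes,
        )

    def effective_chrom_sizes(self) -> dict[str, int]:
        """Contig lengths from the header if present, else max variant pos."""
        if self.chrom_sizes:
            return dict(self.chrom_sizes)
        return self.variants.groupby("chrom", sort=True)["pos"].max().to_dict()

    def segregating_mask(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Boolean per-site mask: ≥1 ALT and ≥1 REF non-missing call."""
        calls = self.calls if sample_idx is None else self.calls[:, sample_idx]
        n_alt = (calls == 1).sum(axis=1)
        n_ref = (calls == 0).sum(axis=1)
        return (n_alt > 0) & (n_ref > 0)


@dataclass
class GeneModel:
    """One transcript: strand-aware span, CDS and exon geometry.

    ``cds_segments`` are (start, end, phase) 1-based inclusive, ordered
    5'→3' along the strand. ``exon_segments`` (genomic order) are kept
    when the GFF3 provides exon features; otherwise empty. A model whose
    concatenated CDS length is not divisible by 3 is ``flagged`` and
    excluded from effect classification (kept for zero-diversity scans).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_segments: list[tuple[int, int, int]] = field(default_factory=list)
    exon_segments: list[tuple[int, int]] = field(default_factory=list)
    flagged: bool = False

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds_segments)

    def upstream_flank(self, upstream_bp: int = 1000) -> tuple[int, int]:
        """Strand-aware flank upstream of the TSS, 1-based inclusive, clipped ≥1."""
        if self.strand == "+":
            return max(1, self.tx_start - upstream_bp), self.tx_start - 1
        return self.tx_end + 1, self.tx_end + upstream_bp


@dataclass
class PedigreeRecord:
    variety: str
    pedigree: str
    generation: int
    female_parent: str | None
    male_parent: str | None
    status: str  # immediate | collateral


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, sample_subset=None, het_policy: str = "missing") -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF 4.x file into haploid codes.

    Diploid homozygous genotypes collapse (0/0→0, 1/1→1, ./.→missing);
    heterozygous calls are handled per ``het_policy`` (default: treated
    as missing — residual heterozygosity in fixed inbred lines is
    noise). Multiallelic and non-SNP records are dropped with a logged
    count, as are sites left with no non-missing call.
    """
    from cyvcf2 import VCF

    if het_policy not in HET_POLICIES:
        raise ValueError(f"het_policy must be one of {HET_POLICIES}")

    vcf = VCF(str(path), gts012=True)
    if sample_subset is not None:
        unknown = [s for s in sample_subset if s not in vcf.samples]
        if unknown:
            raise KeyError(f"unknown sample(s) in subset: {', '.join(unknown)}")
        vcf.set_samples(list(sample_subset))
    samples = list(vcf.samples)

    chrom_sizes = None
    if vcf.seqnames and vcf.seqlens:
        chrom_sizes = dict(zip(vcf.seqnames, vcf.seqlens))

    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    n_dropped_nonbiallelic = 0
    n_dropped_allmissing = 0

    for rec in vcf:
        if (
            len(rec.ALT) != 1
            or len(rec.REF) != 1
            or len(rec.ALT[0]) != 1
            or rec.REF.upper() not in _BASES
            or rec.ALT[0].upper() not in _BASES
            or rec.REF.upper() == rec.ALT[0].upper()
        ):
            n_dropped_nonbiallelic += 1
            continue
        gt = rec.gt_types  # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        codes = np.full(gt.shape, MISSING, dtype=np.int8)
        codes[gt == 0] = 0
        codes[gt == 2] = 1
        het = gt == 1
        if het.any():
            if het_policy == "fail":
                raise HetGenotypeError(
                    f"heterozygous call at {rec.CHROM}:{rec.POS}"
                )
            if het_policy == "ref":
                codes[het] = 0
            elif het_policy == "alt":
                codes[het] = 1
            # "missing": already MISSING
        if (codes != MISSING).sum() == 0:
            n_dropped_allmissing += 1
            continue
        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        refs.append(rec.REF.upper())
        alts.append(rec.ALT[0].upper())
        rows.append(codes)
    vcf.close()

    if n_dropped_nonbiallelic:
        log.info("read_vcf: dropped %d non-biallelic/non-SNP records",
                 n_dropped_nonbiallelic)
    if n_dropped_allmissing:
        log.info("read_vcf: dropped %d all-missing sites", n_dropped_allmissing)

    variants = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": refs, "alt": alts}
    )
    calls = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    if len(variants):
        order = np.lexsort((variants["pos"].to_numpy(),
                            variants["chrom"].to_numpy()))
        variants = variants.iloc[order].reset_index(drop=True)
        calls = calls[order]
        dup = variants.duplicated(["chrom", "pos"]).to_numpy()
        if dup.any():
            log.info("read_vcf: dropped %d duplicate-position records", dup.sum())
            variants = variants[~dup].reset_index(drop=True)
            calls = calls[~dup]

    gm = GenotypeMatrix(variants, samples, calls, chrom_sizes)
    gm.dropped_nonbiallelic = n_dropped_nonbiallelic  # type: ignore[attr-defined]
    return gm


def _open_text(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write haploid codes back out as a minimal diploid GT-only VCF 4.2."""
    with _open_text(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pedscan\n")
        for chrom, size in sorted(matrix.effective_chrom_sizes().items()):
            fh.write(f"##contig=<ID={chrom},length={int(size)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "1/1", MISSING: "./."}
        var = matrix.variants
        chroms = var["chrom"].to_numpy()
        poss = var["pos"].to_numpy()
        refs = var["ref"].to_numpy()
        alts = var["alt"].to_numpy()
        for i in range(matrix.n_sites):
            gts = "\t".join(gt_map[int(c)] for c in matrix.calls[i])
            fh.write(
                f"{chroms[i]}\t{poss[i]}\t.\t{refs[i]}\t{alts[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = ("mRNA", "transcript", "ncRNA")


def read_gene_models(path) -> list[GeneModel]:
    """Parse gene/mRNA/CDS (and exon, when present) features into GeneModels.

    One model per transcript; minus-strand transcripts have tss =
    tx_end. CDS totals not divisible by 3 flag the model.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for ttype in _TRANSCRIPT_TYPES:
        for tx in db.features_of_type(ttype):
            parents = tx.attributes.get("Parent", [])
            gene_id = parents[0] if parents else tx.id
            cds = sorted(
                (c.start, c.end, int(c.frame) if c.frame not in (None, ".") else 0)
                for c in db.children(tx, featuretype="CDS")
            )
            exons = sorted((e.start, e.end) for e in db.children(tx, featuretype="exon"))
            if tx.strand == "-":
                cds = cds[::-1]  # 5'→3' along the strand
            model = GeneModel(
                gene_id=gene_id,
                transcript_id=tx.id,
                chrom=tx.seqid,
                strand=tx.strand,
                tx_start=tx.start,
                tx_end=tx.end,
                cds_segments=cds,
                exon_segments=exons,
            )
            if model.cds_segments and model.cds_length % 3 != 0:
                model.flagged = True
                log.info("gene model %s flagged: CDS length %d not divisible by 3",
                         tx.id, model.cds_length)
            models.append(model)
    models.sort(key=lambda m: (m.chrom, m.tx_start, m.transcript_id))
    return models


# ---------------------------------------------------------------------------
# Pedigree TSV
# ---------------------------------------------------------------------------

PEDIGREE_COLUMNS = ["variety", "pedigree", "generation",
                    "female_parent", "male_parent", "status"]


def read_pedigree(path) -> list[PedigreeRecord]:
    """Read the pedigree TSV and validate the immediate-chain invariants."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing_cols = [c for c in PEDIGREE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"pedigree TSV missing column(s): {missing_cols}")

    records = []
    for _, row in df.iterrows():
        fp = row["female_parent"]
        mp = row["male_parent"]
        records.append(
            PedigreeRecord(
                variety=row["variety"],
                pedigree=row["pedigree"],
                generation=int(row["generation"]),
                female_parent=None if pd.isna(fp) or fp in (".", "") else fp,
                male_parent=None if pd.isna(mp) or mp in (".", "") else mp,
                status=row["status"],
            )
        )

    gen_of = {r.variety: r.generation for r in records}
    for r in records:
        for parent in (r.female_parent, r.male_parent):
            if parent is not None and parent in gen_of:
                if gen_of[parent] >= r.generation:
                    raise ValueError(
                        f"parent {parent} (generation {gen_of[parent]}) not older "
                        f"than child {r.variety} (generation {r.generation})"
                    )
    immediate_chains(records)  # validates chain structure
    return records


def immediate_chains(records: list[PedigreeRecord]) -> dict[str, list[str]]:
    """Generation-ordered immediate-variety chain per pedigree.

    Each non-root immediate variety must name the preceding immediate
    variety as a parent; two immediates at the same generation without
    such a link break the chain.
    """
    chains: dict[str, list[str]] = {}
    by_ped: dict[str, list[PedigreeRecord]] = {}
    for r in records:
        if r.status == "immediate":
            by_ped.setdefault(r.pedigree, []).append(r)
    for ped, recs in by_ped.items():
        recs = sorted(recs, key=lambda r: r.generation)
        for a, b in zip(recs, recs[1:]):
            if a.generation == b.generation:
                raise ValueError(
                    f"broken chain in pedigree {ped}: immediate varieties "
                    f"{a.variety} and {b.variety} share generation {a.generation}"
                )
            if a.variety not in (b.female_parent, b.male_parent):
                raise ValueError(
                    f"broken chain in pedigree {ped}: {b.variety} does not "
                    f"descend from preceding immediate variety {a.variety}"
                )
        chains[ped] = [r.variety for r in recs]
    return chains


def write_pedigree(records: list[PedigreeRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "variety": r.variety,
                "pedigree": r.pedigree,
                "generation": r.generation,
                "female_parent": r.female_parent or ".",
                "male_parent": r.male_parent or ".",
                "status": r.status,
            }
            for r in records
        ],
        columns=PEDIGREE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(regions, path) -> None:
    """Write 1-based inclusive regions as sorted BED6 (0-based half-open).

    ``regions`` is an iterable of mappings (or a DataFrame) carrying
    chrom, start, end and optionally name, score.
    """
    if isinstance(regions, pd.DataFrame):
        regions = regions.to_dict("records")
    rows = []
    for r in regions:
        start, end = int(r["start"]), int(r["end"])
        if end < start:
            raise ValueError(f"region end {end} < start {start}")
        rows.append(
            (
                str(r["chrom"]),
                start - 1,
                end,
                str(r.get("name", ".")),
                r.get("score", 0),
                "+",
            )
        )
    rows.sort(key=lambda t: (t[0], t[1], t[2]))
    with _open_text(path, "w") as fh:
        fh.write("# BED6: chrom start end name score strand (pedscan)\n")
        for row in rows:
            score = row[4]
            score_s = f"{score:.6g}" if isinstance(score, float) else str(score)
            fh.write(f"{row[0]}\t{row[1]}\t{row[2]}\t{row[3]}\t{score_s}\t{row[5]}\n")


def read_bed(path) -> pd.DataFrame:
    """Read BED back into 1-based inclusive internal coordinates."""
    rows = []
    with _open_text(path, "r") as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append(
                {
                    "chrom": parts[0],
                    "start": int(parts[1]) + 1,
                    "end": int(parts[2]),
                    "name": parts[3] if len(parts) > 3 else ".",
                    "score": float(parts[4]) if len(parts) > 4 else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
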