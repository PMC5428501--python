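"""Pedigree breeding simulator with planted, recoverable ground truth.

Varieties are fully inbred lines represented as single fixed haploid
genomes: each cross performs one meiosis (Poisson crossovers, uniform
breakpoints, no interference) and the recombinant is fixed immediately.
All polymorphism is standing variation among the founders — a breeding
timescale, not a mutation-driven one.

Planted truth:
  * low-diversity regions — founder site density scaled down by
    ``diversity_scale`` inside the region;
  * introgression events — single-transition allele patterns along an
    immediate chain (the chain carries the root state up to the
    transition generation and the incoming allele thereafter);
  * sweep regions — the restorer-side group is fixed, per site with
    probability ``divergence_boost``, for the allele opposite the other
    group's majority; an optional central ``both_fixed_frac`` core also
    fixes the other group, producing complete fixed differences there.

With ``signature_noiseless`` (default), accidental two-block
transmission patterns at non-planted sites are scrubbed by flipping the
terminal variety's call — which always destroys the two-block property
— so the planted introgressions are exactly the signature truth set.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pedscan.genio import (
    GeneModel,
    GenotypeMatrix,
    PedigreeRecord,
    write_bed,
    write_pedigree,
    write_vcf,
)

log = logging.getLogger(__name__)

# mean per-site pairwise diversity 2p(1-p) for p ~ Uniform(0.1, 0.9)
_FREQ_LO, _FREQ_HI = 0.1, 0.9
_MEAN_SITE_HET = 2 * (0.5 - (_FREQ_HI**3 - _FREQ_LO**3) / (3 * (_FREQ_HI - _FREQ_LO)))

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_SAFE_CODONS = [
    c1 + c2 + c3
    for c1 in "ACGT" for c2 in "ACGT" for c3 in "ACGT"
    if c1 + c2 + c3 not in _STOPS
]


@dataclass
class PedigreeSpec:
    name: str
    chain_length: int
    n_collateral: int
    n_introgressions: int = 0


@dataclass
class LowDivRegion:
    chrom: str
    start: int
    end: int
    diversity_scale: float


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    divergence_boost: float = 1.0
    both_fixed_frac: float = 0.0


@dataclass
class SimConfig:
    n_chrom: int = 2
    chrom_length_bp: int = 5_000_000
    n_founders: int = 8
    founder_pi: float = 0.002
    recomb_rate: float = 2.0
    pedigrees: list[PedigreeSpec] = field(default_factory=list)
    group_a: list[str] = field(default_factory=list)  # conventional side
    group_b: list[str] = field(default_factory=list)  # restorer (swept) side
    lowdiv_regions: list[LowDivRegion] = field(default_factory=list)
    sweep_regions: list[SweepRegion] = field(default_factory=list)
    gene_spacing_bp: int = 50_000
    signature_noiseless: bool = True
    seed: int = 0

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chrom_names()}

    def validate(self) -> None:
        if self.founder_pi <= 0:
            raise ValueError("founder_pi must be positive")
        if self.n_founders < 2:
            raise ValueError("need ≥2 founders")
        names = set(self.chrom_names())
        for r in list(self.lowdiv_regions) + list(self.sweep_regions):
            if r.chrom not in names:
                raise ValueError(f"region on unknown chromosome {r.chrom}")
            if not (1 <= r.start <= r.end <= self.chrom_length_bp):
                raise ValueError(
                    f"region {r.chrom}:{r.start}-{r.end} outside chromosome")
        for r in self.lowdiv_regions:
            if not 0.0 <= r.diversity_scale <= 1.0:
                raise ValueError("diversity_scale must be in [0, 1]")
        for p in self.pedigrees:
            if p.chain_length < 3:
                raise ValueError(f"pedigree {p.name}: chain_length must be ≥3")
        known = {p.name for p in self.pedigrees}
        for g in list(self.group_a) + list(self.group_b):
            if g not in known:
                raise ValueError(f"group references unknown pedigree {g}")


@dataclass
class SimTruth:
    lowdiv_regions: pd.DataFrame   # chrom, start, end, name, score
    sweep_regions: pd.DataFrame    # chrom, start, end, name, score
    introgressed_snps: pd.DataFrame  # chrom, pos, pedigree, transition_generation


@dataclass
class SimResult:
    matrix: GenotypeMatrix
    records: list[PedigreeRecord]
    truth: SimTruth
    genes: list[GeneModel]
    ref_seqs: dict[str, str]
    founders: GenotypeMatrix
    config: SimConfig


# ---------------------------------------------------------------------------
# Reference sequence + tiled synthetic gene models
# ---------------------------------------------------------------------------

def _revcomp(s: str) -> str:
    return s[::-1].translate(str.maketrans("ACGT", "TGCA"))


def _make_reference(config: SimConfig, rng: np.random.Generator
                    ) -> dict[str, bytearray]:
    return {
        chrom: bytearray(
            _BASE_ARR[rng.integers(0, 4, config.chrom_length_bp)].tobytes())
        for chrom in config.chrom_names()
    }


def _write_cds_into_ref(ref: bytearray, segs_genomic: list[tuple[int, int]],
                        strand: str, rng: np.random.Generator) -> None:
    """Overwrite the reference so the concatenated CDS is a clean ORF:
    ATG + non-stop internal codons + TAA."""
    total = sum(e - s + 1 for s, e in segs_genomic)
    n_codons = total // 3
    internal = rng.integers(0, len(_SAFE_CODONS), n_codons - 2)
    cds = "ATG" + "".join(_SAFE_CODONS[i] for i in internal) + "TAA"
    if strand == "-":
        genomic_seq = _revcomp(cds)
    else:
        genomic_seq = cds
    off = 0
    for s, e in segs_genomic:
        seg_len = e - s + 1
        ref[s - 1:e] = genomic_seq[off:off + seg_len].encode()
        off += seg_len


def _splice_motifs(ref: bytearray, introns: list[tuple[int, int]],
                   strand: str) -> None:
    for s, e in introns:
        if strand == "+":
            ref[s - 1:s + 1] = b"GT"
            ref[e - 2:e] = b"AG"
        else:
            ref[e - 2:e] = b"AC"
            ref[s - 1:s + 1] = b"CT"


def tile_genes(config: SimConfig, rng: np.random.Generator,
               ref: dict[str, bytearray]) -> list[GeneModel]:
    """Synthetic gene models tiled across the genome, editing the
    reference so every CDS is a valid ORF; every 7th gene is an ncRNA
    (exons, no CDS)."""
    genes: list[GeneModel] = []
    counter = 0
    for chrom in config.chrom_names():
        start = 10_001
        while start + 2400 < config.chrom_length_bp - 10_000:
            strand = "+" if counter % 2 == 0 else "-"
            gid = f"G{counter:05d}"
            tid = f"{gid}.1"
            if counter % 7 == 6:
                # ncRNA: two exons, no CDS
                exons = [(start, start + 599), (start + 900, start + 1499)]
                model = GeneModel(
                    gene_id=gid, transcript_id=tid, chrom=chrom, strand=strand,
                    tx_start=start, tx_end=start + 1499,
                    cds_segments=[], exon_segments=exons,
                )
                _splice_motifs(ref[chrom], [(start + 600, start + 899)], strand)
            else:
                # exon1 = 200 UTR + 300 CDS, intron 400, exon2 = 600 CDS,
                # intron 400, exon3 = 300 CDS + 200 UTR  (CDS 1200 bp)
                e1 = (start, start + 499)
                i1 = (start + 500, start + 899)
                e2 = (start + 900, start + 1499)
                i2 = (start + 1500, start + 1899)
                e3 = (start + 1900, start + 2399)
                if strand == "+":
                    cds_genomic = [(start + 200, start + 499),
                                   (start + 900, start + 1499),
                                   (start + 1900, start + 2199)]
                else:
                    cds_genomic = [(start + 200, start + 499),
                                   (start + 900, start + 1499),
                                   (start + 1900, start + 2199)]
                _write_cds_into_ref(ref[chrom], cds_genomic, strand, rng)
                _splice_motifs(ref[chrom], [i1, i2], strand)
                # 5'→3' segment order with phases
                ordered = cds_genomic if strand == "+" else cds_genomic[::-1]
                segs = []
                cum = 0
                for s, e in ordered:
                    segs.append((s, e, (3 - cum % 3) % 3))
                    cum += e - s + 1
                model = GeneModel(
                    gene_id=gid, transcript_id=tid, chrom=chrom, strand=strand,
                    tx_start=e1[0], tx_end=e3[1],
                    cds_segments=segs, exon_segments=[e1, e2, e3],
                )
            genes.append(model)
            counter += 1
            start += config.gene_spacing_bp
    return genes


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------

def simulate_founders(config: SimConfig, rng: np.random.Generator | None = None,
                      ref_seqs: dict[str, str] | None = None) -> GenotypeMatrix:
    """Founder haplotypes with expected genome-wide per-bp diversity ≈
    founder_pi, thinned by diversity_scale inside planted low-diversity
    regions. Site positions uniform; allele frequencies ~ U(0.1, 0.9)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.chrom_length_bp
    density = config.founder_pi / _MEAN_SITE_HET
    n_target = int(round(density * L))

    chroms_all, pos_all, ref_all, alt_all, calls_all = [], [], [], [], []
    for chrom in config.chrom_names():
        raw = np.unique(rng.integers(1, L + 1, size=n_target + 500))
        if len(raw) > n_target:
            keep_idx = np.sort(rng.choice(len(raw), n_target, replace=False))
            raw = raw[keep_idx]
        pos = raw
        keep = np.ones(len(pos), dtype=bool)
        for region in config.lowdiv_regions:
            if region.chrom != chrom:
                continue
            inside = (pos >= region.start) & (pos <= region.end)
            u = rng.random(len(pos))
            keep &= ~inside | (u < region.diversity_scale)
        pos = pos[keep]
        n_sites = len(pos)
        p = rng.uniform(_FREQ_LO, _FREQ_HI, n_sites)
        calls = (rng.random((n_sites, config.n_founders)) < p[:, None]).astype(
            np.int8)
        if ref_seqs is not None:
            seq = ref_seqs[chrom]
            refs = np.array([seq[x - 1] for x in pos])
        else:
            refs = np.array(list("ACGT"))[rng.integers(0, 4, n_sites)]
        base_idx = np.array(["ACGT".index(b) for b in refs])
        alt_idx = (base_idx + rng.integers(1, 4, n_sites)) % 4
        alts = np.array(list("ACGT"))[alt_idx]
        chroms_all.extend([chrom] * n_sites)
        pos_all.append(pos)
        ref_all.append(refs)
        alt_all.append(alts)
        calls_all.append(calls)

    variants = pd.DataFrame(
        {
            "chrom": chroms_all,
            "pos": np.concatenate(pos_all),
            "ref": np.concatenate(ref_all),
            "alt": np.concatenate(alt_all),
        }
    )
    samples = [f"F{i:02d}" for i in range(config.n_founders)]
    return GenotypeMatrix(variants, samples, np.vstack(calls_all),
                          config.chrom_sizes())


# ---------------------------------------------------------------------------
# Breeding
# ---------------------------------------------------------------------------

def _chrom_slices(variants: pd.DataFrame) -> dict[str, slice]:
    out = {}
    chroms = variants["chrom"].to_numpy()
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            out[chroms[start]] = slice(start, i)
            start = i
    return out


def _recombine(hap_a: np.ndarray, hap_b: np.ndarray,
               positions: np.ndarray, slices: dict[str, slice],
               chrom_len: int, recomb_rate: float,
               rng: np.random.Generator) -> np.ndarray:
    """One meiosis between two haploid genomes, immediately fixed."""
    child = np.empty_like(hap_a)
    for chrom, sl in slices.items():
        pos = positions[sl]
        n_co = rng.poisson(recomb_rate)
        first = int(rng.integers(0, 2))
        if n_co == 0:
            child[sl] = hap_a[sl] if first == 0 else hap_b[sl]
            continue
        bp = np.sort(rng.uniform(1, chrom_len + 1, n_co))
        seg = np.searchsorted(bp, pos)
        use_a = (first + seg) % 2 == 0
        child[sl] = np.where(use_a, hap_a[sl], hap_b[sl])
    return child


def breed_pedigree(founders: GenotypeMatrix, config: SimConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[GenotypeMatrix, list[PedigreeRecord], SimTruth]:
    """Breed every configured pedigree from the shared founders.

    Returns the study-sample genotype matrix (immediate + collateral
    varieties, no founders), the pedigree records, and the planted
    truth (low-diversity regions, sweep regions, introgressed SNPs).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    variants = founders.variants
    positions = variants["pos"].to_numpy()
    slices = _chrom_slices(variants)
    L = config.chrom_length_bp
    fcalls = founders.calls

    sample_names: list[str] = []
    haplotypes: list[np.ndarray] = []
    records: list[PedigreeRecord] = []
    chain_cols: dict[str, list[int]] = {}
    ped_cols: dict[str, list[int]] = {}

    def add_sample(name: str, hap: np.ndarray, ped: str) -> int:
        sample_names.append(name)
        haplotypes.append(hap)
        ped_cols.setdefault(ped, []).append(len(sample_names) - 1)
        return len(sample_names) - 1

    for pi_, ped in enumerate(config.pedigrees):
        root_col = pi_ % founders.n_samples
        coll_haps = []
        coll_names = []
        for j in range(ped.n_collateral):
            a, b = rng.choice(founders.n_samples, 2, replace=False)
            hap = _recombine(fcalls[:, a], fcalls[:, b], positions, slices,
                             L, config.recomb_rate, rng)
            name = f"{ped.name}_C{j:02d}"
            coll_haps.append(hap)
            coll_names.append(name)

        chain_cols[ped.name] = []
        prev_name = None
        prev_hap = fcalls[:, root_col].copy()
        for g in range(ped.chain_length):
            name = f"{ped.name}_I{g:02d}"
            if g == 0:
                hap = prev_hap
                female = male = None
            else:
                if coll_haps:
                    di = (g - 1) % len(coll_haps)
                    donor_hap, donor_name = coll_haps[di], coll_names[di]
                else:
                    a, b = rng.choice(founders.n_samples, 2, replace=False)
                    donor_hap = _recombine(fcalls[:, a], fcalls[:, b],
                                           positions, slices, L,
                                           config.recomb_rate, rng)
                    donor_name = None
                hap = _recombine(prev_hap, donor_hap, positions, slices, L,
                                 config.recomb_rate, rng)
                female, male = prev_name, donor_name
            col = add_sample(name, hap, ped.name)
            chain_cols[ped.name].append(col)
            records.append(PedigreeRecord(name, ped.name, g, female, male,
                                          "immediate"))
            prev_name, prev_hap = name, hap
        for j, (name, hap) in enumerate(zip(coll_names, coll_haps)):
            add_sample(name, hap, ped.name)
            records.append(PedigreeRecord(name, ped.name, 0, None, None,
                                          "collateral"))

    calls = np.column_stack(haplotypes).astype(np.int8)

    # --- introgression events (single-transition chain patterns) ----------
    in_sweep = np.zeros(len(variants), dtype=bool)
    for r in config.sweep_regions:
        in_sweep |= ((variants["chrom"] == r.chrom).to_numpy()
                     & (positions >= r.start) & (positions <= r.end))
    founder_seg = founders.segregating_mask()
    intro_rows = []
    planted: dict[str, set[int]] = {p.name: set() for p in config.pedigrees}
    for ped in config.pedigrees:
        if ped.n_introgressions == 0:
            continue
        candidates = np.flatnonzero(founder_seg & ~in_sweep)
        if len(candidates) < ped.n_introgressions:
            raise ValueError(
                f"pedigree {ped.name}: only {len(candidates)} sites segregate "
                f"in the donor pool, {ped.n_introgressions} introgressions "
                "requested")
        sites = rng.choice(candidates, ped.n_introgressions, replace=False)
        cols = chain_cols[ped.name]
        k = len(cols)
        for s in np.sort(sites):
            g = int(rng.integers(1, k))
            a0 = int(calls[s, cols[0]])
            for t, col in enumerate(cols):
                calls[s, col] = a0 if t < g else 1 - a0
            planted[ped.name].add(int(s))
            intro_rows.append(
                {"chrom": variants.at[int(s), "chrom"],
                 "pos": int(variants.at[int(s), "pos"]),
                 "pedigree": ped.name,
                 "transition_generation": g}
            )

    # --- sweep regions ----------------------------------------------------
    a_cols = np.array(
        sorted(c for p in config.group_a for c in ped_cols.get(p, [])),
        dtype=int)
    b_cols = np.array(
        sorted(c for p in config.group_b for c in ped_cols.get(p, [])),
        dtype=int)
    for r in config.sweep_regions:
        if a_cols.size == 0 or b_cols.size == 0:
            raise ValueError("sweep regions require non-empty group_a and "
                             "group_b pedigree lists")
        mask = ((variants["chrom"] == r.chrom).to_numpy()
                & (positions >= r.start) & (positions <= r.end))
        sites = np.flatnonzero(mask)
        forced = sites[rng.random(len(sites)) < r.divergence_boost]
        maj_a = (calls[np.ix_(forced, a_cols)].mean(axis=1) >= 0.5).astype(
            np.int8)
        calls[np.ix_(forced, b_cols)] = (1 - maj_a)[:, None]
        if r.both_fixed_frac > 0:
            span = r.end - r.start + 1
            core_len = int(round(r.both_fixed_frac * span))
            core_lo = r.start + (span - core_len) // 2
            core_hi = core_lo + core_len - 1
            fpos = positions[forced]
            in_core = (fpos >= core_lo) & (fpos <= core_hi)
            calls[np.ix_(forced[in_core], a_cols)] = \
                maj_a[in_core][:, None]

    # --- scrub accidental two-block patterns ------------------------------
    if config.signature_noiseless:
        for ped in config.pedigrees:
            cols = chain_cols[ped.name]
            sub = calls[:, cols]
            diffs = sub[:, 1:] != sub[:, :-1]
            two_block = diffs.sum(axis=1) == 1
            accidental = np.flatnonzero(two_block)
            accidental = np.array(
                [s for s in accidental if s not in planted[ped.name]],
                dtype=int)
            if accidental.size:
                last = cols[-1]
                calls[accidental, last] = 1 - calls[accidental, last]
                log.info("pedigree %s: scrubbed %d accidental two-block "
                         "patterns", ped.name, accidental.size)

    matrix = GenotypeMatrix(variants.copy(), sample_names, calls,
                            config.chrom_sizes())
    truth = SimTruth(
        lowdiv_regions=pd.DataFrame(
            [
                {"chrom": r.chrom, "start": r.start, "end": r.end,
                 "name": f"lowdiv{i}", "score": r.diversity_scale}
                for i, r in enumerate(config.lowdiv_regions)
            ],
            columns=["chrom", "start", "end", "name", "score"],
        ),
        sweep_regions=pd.DataFrame(
            [
                {"chrom": r.chrom, "start": r.start, "end": r.end,
                 "name": f"sweep{i}", "score": r.divergence_boost}
                for i, r in enumerate(config.sweep_regions)
            ],
            columns=["chrom", "start", "end", "name", "score"],
        ),
        introgressed_snps=pd.DataFrame(
            intro_rows,
            columns=["chrom", "pos", "pedigree", "transition_generation"],
        ),
    )
    return matrix, records, truth


def simulate_dataset(config: SimConfig) -> SimResult:
    """Full simulation: reference + genes, founders, breeding."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ref_raw = _make_reference(config, rng)
    genes = tile_genes(config, rng, ref_raw)
    ref_seqs = {c: bytes(b).decode() for c, b in ref_raw.items()}
    founders = simulate_founders(config, rng, ref_seqs)
    matrix, records, truth = breed_pedigree(founders, config, rng)
    return SimResult(matrix, records, truth, genes, ref_seqs, founders, config)


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in genes:
            ttype = "mRNA" if m.cds_segments else "ncRNA"
            fh.write(f"{m.chrom}\tpedsim\tgene\t{m.tx_start}\t{m.tx_end}\t.\t"
                     f"{m.strand}\t.\tID={m.gene_id}\n")
            fh.write(f"{m.chrom}\tpedsim\t{ttype}\t{m.tx_start}\t{m.tx_end}\t.\t"
                     f"{m.strand}\t.\tID={m.transcript_id};Parent={m.gene_id}\n")
            for i, (s, e) in enumerate(m.exon_segments):
                fh.write(f"{m.chrom}\tpedsim\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                         f"ID={m.transcript_id}.e{i};Parent={m.transcript_id}\n")
            for i, (s, e, phase) in enumerate(m.cds_segments):
                fh.write(f"{m.chrom}\tpedsim\tCDS\t{s}\t{e}\t.\t{m.strand}\t"
                         f"{phase}\tID={m.transcript_id}.c{i};"
                         f"Parent={m.transcript_id}\n")


def write_fasta(ref_seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(ref_seqs):
            fh.write(f">{chrom}\n")
            seq = ref_seqs[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def emit_dataset(result: SimResult, outdir, overwrite: bool = False,
                 gzip_vcf: bool = False) -> dict[str, str]:
    """Write the simulated dataset: VCF, pedigree TSV, truth BEDs/TSV,
    synthetic gene GFF3 and reference FASTA. Returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    vcf_name = "sim.vcf.gz" if gzip_vcf else "sim.vcf"
    paths = {
        "vcf": os.path.join(outdir, vcf_name),
        "pedigree": os.path.join(outdir, "pedigree.tsv"),
        "lowdiv_bed": os.path.join(outdir, "truth.lowdiv.bed"),
        "sweep_bed": os.path.join(outdir, "truth.sweep.bed"),
        "signature_tsv": os.path.join(outdir, "truth.signature.tsv"),
        "gff3": os.path.join(outdir, "genes.gff3"),
        "fasta": os.path.join(outdir, "ref.fa"),
    }
    if not overwrite:
        existing = [p for p in paths.values() if os.path.exists(p)]
        if existing:
            raise FileExistsError(
                f"output exists (pass overwrite=True): {existing[0]}")
    write_vcf(result.matrix, paths["vcf"])
    write_pedigree(result.records, paths["pedigree"])
    write_bed(result.truth.lowdiv_regions, paths["lowdiv_bed"])
    write_bed(result.truth.sweep_regions, paths["sweep_bed"])
    result.truth.introgressed_snps.to_csv(paths["signature_tsv"], sep="\t",
                                          index=False)
    write_gff3(result.genes, paths["gff3"])
    write_fasta(result.ref_seqs, paths["fasta"])
    return paths


# ---------------------------------------------------------------------------
# The standard study-scale configuration
# ---------------------------------------------------------------------------

def standard_config(seed: int = 0) -> SimConfig:
    """Three pedigrees, 52 varieties, ~50k SNPs over 2 × 5 Mb.

    Mirrors the study's structure: two conventional pedigrees (GC2H,
    HHZ) with planted introgressions along their immediate chains, one
    restorer pedigree (SH527) with planted sweep regions of lost
    diversity, founder π 0.002 (the conventional-pedigree range), and
    three planted low-diversity regions.
    """
    return SimConfig(
        n_chrom=2,
        chrom_length_bp=5_000_000,
        n_founders=8,
        founder_pi=0.002,
        recomb_rate=2.0,
        pedigrees=[
            PedigreeSpec("GC2H", chain_length=6, n_collateral=5,
                         n_introgressions=40),
            PedigreeSpec("HHZ", chain_length=8, n_collateral=10,
                         n_introgressions=40),
            PedigreeSpec("SH527", chain_length=8, n_collateral=15,
                         n_introgressions=0),
        ],
        group_a=["GC2H", "HHZ"],
        group_b=["SH527"],
        lowdiv_regions=[
            LowDivRegion("chr1", 1_000_001, 1_150_000, 0.01),
            LowDivRegion("chr1", 3_200_001, 3_350_000, 0.01),
            LowDivRegion("chr2", 2_000_001, 2_150_000, 0.01),
        ],
        sweep_regions=[
            SweepRegion("chr1", 4_000_001, 4_300_000, 1.0,
                        both_fixed_frac=0.35),
            SweepRegion("chr2", 3_500_001, 3_800_000, 1.0,
                        both_fixed_frac=0.35),
        ],
        seed=seed,
    )
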