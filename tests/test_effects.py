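import numpy as np
import pandas as pd
import pytest

from pedscan import effects as fx
from pedscan.genio import GeneModel

# Independent genetic-code oracle (standard table, hand-entered).
CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

RC = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s[::-1].translate(RC)


def single_exon_gene(cds, chrom="chr1", offset=100, strand="+",
                     gene_id="g1"):
    """Gene whose CDS occupies [offset+1, offset+len(cds)] (plus strand
    sequence given 5'→3')."""
    start, end = offset + 1, offset + len(cds)
    return GeneModel(gene_id, f"{gene_id}.1", chrom, strand, start, end,
                     cds_segments=[(start, end, 0)],
                     exon_segments=[(start, end)])


def chrom_with(cds, offset=100, total=1000, strand="+"):
    pad = "C" * offset
    genomic = cds if strand == "+" else revcomp(cds)
    return {"chr1": pad + genomic + "C" * (total - offset - len(cds))}


def variant(pos, ref, alt, chrom="chr1"):
    return {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "site_id": 0}


def expected_category(codon_index, n_codons, aa_ref, aa_alt, codon_ref,
                      codon_alt):
    if codon_index == 0 and codon_ref == "ATG" and codon_alt != "ATG":
        return "start_lost"
    if aa_ref == "*" and aa_alt != "*":
        return "stop_lost"
    if aa_alt == "*" and aa_ref != "*":
        return "stop_gained"
    return "synonymous" if aa_ref == aa_alt else "missense"


class TestCodonOracle:
    def test_exhaustive_codon_translation_and_category(self):
        """All 64 codons × 3 positions × 3 alternate bases, mid-CDS,
        against the independent genetic-code table."""
        for codon in CODE:
            cds = "ATG" + codon + "GGT" + "TAA"
            gene = single_exon_gene(cds)
            ref_seq = chrom_with(cds)
            for within in range(3):
                ref_base = codon[within]
                for alt_base in "ACGT":
                    if alt_base == ref_base:
                        continue
                    pos = 100 + 3 + within + 1  # after the ATG
                    ec = fx.classify_effect(
                        variant(pos, ref_base, alt_base), gene, ref_seq)
                    codon_alt = codon[:within] + alt_base + codon[within + 1:]
                    assert ec.codon_ref == codon
                    assert ec.codon_alt == codon_alt
                    assert ec.aa_ref == CODE[codon]
                    assert ec.aa_alt == CODE[codon_alt]
                    assert ec.category == expected_category(
                        1, 4, CODE[codon], CODE[codon_alt], codon, codon_alt)

    def test_strand_mirror_gives_identical_categories(self):
        """A minus-strand gene on the reverse-complemented chromosome
        classifies every variant identically to its plus-strand mirror."""
        total = 400
        cds = "ATG" + "TGG" + "CAT" + "TCA" + "TAA"
        plus_gene = single_exon_gene(cds, offset=100)
        plus_seq = chrom_with(cds, offset=100, total=total)
        minus_seq = {"chr1": revcomp(plus_seq["chr1"])}
        m_end = total - 100
        m_start = m_end - len(cds) + 1
        minus_gene = GeneModel("g1", "g1.1", "chr1", "-", m_start, m_end,
                               cds_segments=[(m_start, m_end, 0)],
                               exon_segments=[(m_start, m_end)])
        for off in range(len(cds)):
            pos_p = 101 + off
            ref_p = plus_seq["chr1"][pos_p - 1]
            for alt_p in "ACGT":
                if alt_p == ref_p:
                    continue
                ec_p = fx.classify_effect(variant(pos_p, ref_p, alt_p),
                                          plus_gene, plus_seq)
                pos_m = total - pos_p + 1
                ec_m = fx.classify_effect(
                    variant(pos_m, ref_p.translate(RC), alt_p.translate(RC)),
                    minus_gene, minus_seq)
                assert ec_p.category == ec_m.category
                assert ec_p.aa_ref == ec_m.aa_ref
                assert ec_p.aa_alt == ec_m.aa_alt


class TestNamedEffects:
    def test_stop_gained_tgg_to_tag(self):
        cds = "ATGTGGGGTTAA"
        gene = single_exon_gene(cds)
        ec = fx.classify_effect(variant(105, "G", "A"), gene, chrom_with(cds))
        assert (ec.codon_ref, ec.codon_alt) == ("TGG", "TAG")
        assert ec.category == "stop_gained"
        assert ec.large_effect

    def test_stop_lost_terminal_taa_to_caa(self):
        cds = "ATGGGTTAA"
        gene = single_exon_gene(cds)
        ec = fx.classify_effect(variant(107, "T", "C"), gene, chrom_with(cds))
        assert (ec.codon_ref, ec.codon_alt) == ("TAA", "CAA")
        assert ec.category == "stop_lost"

    def test_start_lost_atg_to_acg(self):
        cds = "ATGGGTTAA"
        gene = single_exon_gene(cds)
        ec = fx.classify_effect(variant(102, "T", "C"), gene, chrom_with(cds))
        assert ec.category == "start_lost"

    def test_splice_donor_and_acceptor(self):
        # two exons with a 100 bp intron; CDS 3+3 with stop in exon2
        seq = "C" * 1000
        ref = {"chr1": seq[:110] + "GT" + seq[112:208] + "AG" + seq[210:]}
        gene = GeneModel("g1", "g1.1", "chr1", "+", 101, 216,
                         cds_segments=[(101, 110, 0), (211, 216, 0)],
                         exon_segments=[(101, 110), (211, 216)])
        donor = fx.classify_effect(variant(111, "G", "A"), gene, ref)
        assert donor.category == "splice_donor"
        acceptor = fx.classify_effect(variant(210, "G", "C"), gene, ref)
        assert acceptor.category == "splice_acceptor"
        mid = fx.classify_effect(variant(150, "C", "A"), gene, ref)
        assert mid.category == "intron"

    def test_utr_and_upstream_and_intergenic(self):
        cds = "ATGGGTTAA"
        seq = "C" * 2000
        # tx 501..700, CDS 601..609
        ref = {"chr1": seq[:600] + cds + seq[609:]}
        gene = GeneModel("g1", "g1.1", "chr1", "+", 501, 700,
                         cds_segments=[(601, 609, 0)],
                         exon_segments=[(501, 700)])
        assert fx.classify_effect(variant(550, "C", "A"), gene,
                                  ref).category == "utr5"
        assert fx.classify_effect(variant(650, "C", "A"), gene,
                                  ref).category == "utr3"
        assert fx.classify_effect(variant(400, "C", "A"), gene,
                                  ref).category == "upstream"
        assert fx.classify_effect(variant(1900, "C", "A"), gene,
                                  ref).category == "intergenic"

    def test_ref_mismatch_raises_with_coordinates(self):
        cds = "ATGGGTTAA"
        gene = single_exon_gene(cds)
        with pytest.raises(fx.RefMismatchError, match="chr1:104"):
            fx.classify_effect(variant(104, "T", "A"), gene, chrom_with(cds))


class TestAggregation:
    def _calls(self, categories, genes=None):
        genes = genes or ["g1"] * len(categories)
        return pd.DataFrame(
            {
                "category": categories,
                "gene_id": genes,
                "large_effect": [c in fx.LARGE_EFFECT for c in categories],
                "region": [fx.REGION_OF_CATEGORY[c] for c in categories],
            }
        )

    def test_dn_ds_count_ratio(self):
        calls = self._calls(["missense"] * 12 + ["stop_gained"]
                            + ["synonymous"] * 10)
        assert fx.dn_ds(calls) == pytest.approx(1.30)

    def test_dn_ds_zero_numerator(self):
        assert fx.dn_ds(self._calls(["synonymous"] * 5)) == 0.0

    def test_dn_ds_undefined_without_synonymous(self):
        with pytest.raises(ValueError):
            fx.dn_ds(self._calls(["missense"] * 5))

    def test_start_lost_counts_as_nonsynonymous(self):
        calls = self._calls(["start_lost", "synonymous"])
        assert fx.dn_ds(calls) == 1.0

    def test_large_effect_table_counts_per_gene(self):
        calls = self._calls(
            ["stop_gained", "stop_gained", "splice_donor", "missense"],
            genes=["g1", "g1", "g1", "g1"])
        table = fx.large_effect_table(calls)
        assert len(table) == 1
        assert table["n_large_effect"][0] == 3
        assert "stop_gained:2" in table["categories"][0]

    def test_large_effect_table_empty(self):
        assert len(fx.large_effect_table(self._calls(["missense"]))) == 0

    def test_region_partition_exhaustive_and_disjoint(self):
        # every category maps to exactly one region
        assert set(fx.REGION_OF_CATEGORY) == set(fx.SEVERITY)
        calls = self._calls(list(fx.SEVERITY))
        assert fx.region_summary(calls).sum() == len(fx.SEVERITY)


class TestMostSevereAcrossTranscripts:
    def test_severe_transcript_wins(self):
        cds = "ATGTGGGGTTAA"
        ref = chrom_with(cds, offset=100, total=1000)
        coding = single_exon_gene(cds, gene_id="g1")
        # second transcript of the same gene covering the site as intron
        noncoding = GeneModel("g1", "g1.2", "chr1", "+", 50, 400,
                              cds_segments=[],
                              exon_segments=[(50, 60), (390, 400)])
        variants = pd.DataFrame(
            [{"chrom": "chr1", "pos": 105, "ref": "G", "alt": "A"}])
        out = fx.classify_variants(variants, [coding, noncoding], ref)
        assert out["category"][0] == "stop_gained"
        assert out["transcript_id"][0] == "g1.1"

    def test_flagged_transcript_skipped(self):
        cds = "ATGTGGGGTTAA"
        ref = chrom_with(cds)
        gene = single_exon_gene(cds)
        gene.flagged = True
        variants = pd.DataFrame(
            [{"chrom": "chr1", "pos": 105, "ref": "G", "alt": "A"}])
        out = fx.classify_variants(variants, [gene], ref)
        assert out["category"][0] == "intergenic"

    def test_simulated_genes_classify_without_ref_mismatch(self, standard_sim):
        sub = standard_sim.matrix.variants.head(2000)
        calls = fx.classify_variants(sub, standard_sim.genes,
                                     standard_sim.ref_seqs)
        assert len(calls) == 2000
        assert set(calls["region"]).issubset(
            {"CDS", "intron", "5'UTR", "3'UTR", "intergenic",
             "noncoding_exon"})
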