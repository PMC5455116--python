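"""Region assignment, coding-effect prediction and keyword gene filtering."""

import pytest

from domesticscan.gene_annotation import (
    GeneIndex,
    assign_region,
    filter_genes_by_keyword,
    genic_ratio,
    predict_effect,
)
from domesticscan.variant_io import GeneModel, ReferenceGenome, VariantKey, reverse_complement

from _oracles import effect_by_retranslation, region_by_linear_scan


def _codon_gene(seq_5p="", coding="ATGTGGTAA", seq_3p="", utr5=10, utr3=10, chrom="c"):
    """Single-exon plus-strand gene embedded in UTR/flank sequence."""
    seq = seq_5p + "T" * utr5 + coding + "A" * utr3 + seq_3p
    start = len(seq_5p) + 1
    cds_start = len(seq_5p) + utr5 + 1
    gene = GeneModel(
        "g1",
        chrom,
        "+",
        start,
        len(seq_5p) + utr5 + len(coding) + utr3,
        cds=((cds_start, cds_start + len(coding) - 1, 0),),
    )
    return ReferenceGenome({chrom: seq}), gene, cds_start


class TestAssignRegion:
    GENES = [
        GeneModel("small", "c", "+", 5000, 6000, cds=((5200, 5800, 0),)),
        GeneModel("minus", "c", "-", 20000, 26000, cds=((21000, 21500, 0), (24000, 24600, 0))),
    ]

    @pytest.fixture()
    def index(self):
        return GeneIndex(self.GENES)

    def test_position_inside_span_is_genic(self, index):
        ann = assign_region(VariantKey("c", 5500, "A", "G"), index)
        assert ann.region == "CDS" and ann.gene_id == "small"

    def test_intron_between_cds_segments(self, index):
        ann = assign_region(VariantKey("c", 22000, "A", "G"), index)
        assert ann.region == "intron" and ann.gene_id == "minus"

    def test_utr_is_genic_other(self, index):
        assert assign_region(VariantKey("c", 5100, "A", "G"), index).region == "genic_other"

    def test_immediately_upstream_is_flank_up(self, index):
        assert assign_region(VariantKey("c", 4999, "A", "G"), index).region == "flank_up_2kb"
        # minus strand: upstream lies to the right of the span
        assert assign_region(VariantKey("c", 26001, "A", "G"), index).region == "flank_up_2kb"

    def test_beyond_flank_is_intergenic(self, index):
        assert assign_region(VariantKey("c", 2999, "A", "G"), index).region == "intergenic"

    def test_matches_linear_scan_on_random_positions(self, small_cohort, rng):
        genes = small_cohort.genes
        index = GeneIndex(genes)
        chroms = list(small_cohort.config.chrom_lengths)
        for _ in range(1000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(1, small_cohort.config.chrom_lengths[chrom]))
            key = VariantKey(chrom, pos, "A", "G")
            ann = assign_region(key, index)
            region, gene_id = region_by_linear_scan(key, genes)
            assert (ann.region, ann.gene_id) == (region, gene_id)


class TestPredictEffect:
    def test_tgg_to_tga_is_stop_gained_high(self):
        ref, gene, cds_start = _codon_gene(coding="ATGTGGTAA")
        key = VariantKey("c", cds_start + 5, "G", "A")  # TGG codon, third base
        ann = predict_effect(key, gene, ref)
        assert (ann.effect, ann.impact) == ("stop_gained", "HIGH")

    def test_terminal_taa_to_caa_is_stop_lost(self):
        ref, gene, cds_start = _codon_gene(coding="ATGTGGTAA")
        key = VariantKey("c", cds_start + 6, "T", "C")
        ann = predict_effect(key, gene, ref)
        assert (ann.effect, ann.impact) == ("stop_lost", "HIGH")

    def test_initiator_atg_destroyed_is_start_lost(self):
        ref, gene, cds_start = _codon_gene(coding="ATGTGGTAA")
        ann = predict_effect(VariantKey("c", cds_start, "A", "G"), gene, ref)
        assert (ann.effect, ann.impact) == ("start_lost", "HIGH")

    def test_synonymous_and_missense(self):
        ref, gene, cds_start = _codon_gene(coding="ATGCTGTTATAA")  # Met-Leu-Leu-stop
        syn = predict_effect(VariantKey("c", cds_start + 5, "G", "A"), gene, ref)  # CTG->CTA (Leu)
        mis = predict_effect(VariantKey("c", cds_start + 4, "T", "A"), gene, ref)  # CTG->CAG (Gln)
        assert (syn.effect, syn.impact) == ("synonymous", "LOW")
        assert (mis.effect, mis.impact) == ("missense", "MODERATE")

    def test_intronic_base_near_boundary_is_splice_site(self):
        ref = ReferenceGenome({"c": "A" * 200})
        gene = GeneModel("g", "c", "+", 10, 150, cds=((20, 49, 0), (90, 119, 0)))
        for pos in (50, 51, 88, 89):
            ann = predict_effect(VariantKey("c", pos, "A", "G"), gene, ref)
            assert (ann.effect, ann.impact) == ("splice_site", "HIGH")
        assert predict_effect(VariantKey("c", 60, "A", "G"), gene, ref).effect == "non_coding"

    def test_cds_indel_frame_rule(self):
        ref, gene, cds_start = _codon_gene(coding="ATGCTGCTGCTGTAA")
        pos = cds_start + 4
        base = ref["c"][pos - 1]
        fs = predict_effect(VariantKey("c", pos, base, base + "T"), gene, ref)
        assert (fs.effect, fs.impact) == ("frameshift", "HIGH")
        inframe = predict_effect(VariantKey("c", pos, base, base + "TTT"), gene, ref)
        assert (inframe.effect, inframe.impact) == ("inframe_indel", "MODERATE")

    def test_start_gained_in_frame_atg_in_5utr(self):
        # 5' UTR of TTT... : a T->A change 9 bp before the CDS creates ATG? need TG after
        ref0, gene, cds_start = _codon_gene(coding="ATGTGGTAA", utr5=12)
        seq = list(ref0["c"])
        seq[cds_start - 7 : cds_start - 4] = list("CTG")  # one sub away from ATG, in frame
        ref = ReferenceGenome({"c": "".join(seq)})
        key = VariantKey("c", cds_start - 6, "C", "A")
        ann = predict_effect(key, gene, ref, assess_start_gain=True)
        assert (ann.effect, ann.impact) == ("start_gained", "HIGH")
        off = predict_effect(key, gene, ref, assess_start_gain=False)
        assert off.effect == "non_coding"

    def test_matches_whole_cds_retranslation_on_random_snps(self, small_cohort, rng):
        """Incremental codon classification == whole-protein re-translation."""
        genes = [g for g in small_cohort.genes if g.complete]
        ref = small_cohort.reference
        strands = set()
        for _ in range(300):
            gene = genes[int(rng.integers(len(genes)))]
            strands.add(gene.strand)
            off = int(rng.integers(gene.cds_length))
            pos = gene.genomic_position(off)
            base = ref[gene.chrom][pos - 1]
            alt = "ACGT".replace(base, "")[int(rng.integers(3))]
            key = VariantKey(gene.chrom, pos, base, alt)
            ann = predict_effect(key, gene, ref)
            assert ann.effect == effect_by_retranslation(key, gene, ref), key
        assert strands == {"+", "-"}

    def test_strand_symmetry_of_effect_labels(self, small_cohort, rng):
        """Mirroring the genome (reverse complement, flipped strands) leaves
        every effect label unchanged."""
        genes = [g for g in small_cohort.genes if g.complete]
        ref = small_cohort.reference
        for _ in range(60):
            gene = genes[int(rng.integers(len(genes)))]
            L = len(ref[gene.chrom])
            mirrored_seq = reverse_complement(ref[gene.chrom])
            m_cds = tuple(
                sorted(((L - e + 1, L - s + 1, p) for s, e, p in gene.cds))
            )
            m_gene = GeneModel(
                gene.gene_id,
                gene.chrom,
                "-" if gene.strand == "+" else "+",
                L - gene.end + 1,
                L - gene.start + 1,
                cds=m_cds,
            )
            off = int(rng.integers(gene.cds_length))
            pos = gene.genomic_position(off)
            base = ref[gene.chrom][pos - 1]
            alt = "ACGT".replace(base, "")[int(rng.integers(3))]
            key = VariantKey(gene.chrom, pos, base, alt)
            m_key = VariantKey(
                gene.chrom,
                L - pos + 1,
                reverse_complement(base),
                reverse_complement(alt),
            )
            a = predict_effect(key, gene, ref)
            b = predict_effect(m_key, m_gene, {gene.chrom: mirrored_seq})
            assert a.effect == b.effect


class TestGenicRatioAndKeywords:
    def test_ratio_limits(self):
        genes = [GeneModel("g", "c", "+", 100, 200)]
        index = GeneIndex(genes)
        inside = [VariantKey("c", p, "A", "G") for p in (100, 150, 200)]
        outside = [VariantKey("c", p, "A", "G") for p in (10, 20)]
        assert genic_ratio(inside, index, "sp").ratio == 1.0
        assert genic_ratio(outside, index, "sp").ratio == 0.0
        assert genic_ratio(inside + outside, index, "sp").ratio == pytest.approx(3 / 5)
        assert genic_ratio([], index, "sp").ratio is None

    def test_keyword_filter_matches_planted_resistance_genes(self, small_cohort):
        hits = filter_genes_by_keyword(
            small_cohort.genes,
            ["resistance", "NBS-LRR", "kinase", "Mlo", "blight"],
        )
        assert sorted(g.gene_id for g in hits) == small_cohort.truth.resistance_genes

    def test_keyword_examples(self):
        g = GeneModel("x", "c", "+", 1, 10, annotation="Note=TMV resistance N-like protein")
        assert filter_genes_by_keyword([g], ["resistance"]) == [g]
        assert filter_genes_by_keyword([g], ["kinase"]) == []
        assert filter_genes_by_keyword([g], []) == []
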