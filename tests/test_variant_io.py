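"""VCF/GFF parsing, allele normalization and the high-confidence filter."""

from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from domesticscan.variant_io import (
    Call,
    FilterPolicy,
    GeneModel,
    Genotype,
    ReferenceGenome,
    VariantKey,
    VariantRecord,
    VcfParseError,
    apply_filter,
    normalize_variant,
    read_gene_models,
    read_vcf,
)

from conftest import make_vcf


class TestReadVcf:
    def test_multiallelic_row_splits_per_alt_with_recoded_genotypes(self, tmp_path):
        path = make_vcf(
            tmp_path / "m.vcf",
            ["ch01\t100\t.\tA\tG,T\t55.0\t.\t.\tGT:DP\t1/1:9"],
        )
        recs = list(read_vcf(path, "ACC1"))
        assert [(r.ref, r.alt) for r in recs] == [("A", "G"), ("A", "T")]
        assert recs[0].calls["ACC1"].genotype is Genotype.HOM_ALT
        assert recs[1].calls["ACC1"].genotype is Genotype.HOM_REF
        assert recs[0].calls["ACC1"].depth == 9
        assert recs[0].calls["ACC1"].qual == pytest.approx(55.0)

    def test_het_between_two_alts_is_het_for_both(self, tmp_path):
        path = make_vcf(
            tmp_path / "m.vcf",
            ["ch01\t100\t.\tA\tG,T\t55.0\t.\t.\tGT:DP\t1/2:9"],
        )
        recs = list(read_vcf(path, "ACC1"))
        assert all(r.calls["ACC1"].genotype is Genotype.HET for r in recs)

    def test_missing_genotype_and_ad_support(self, tmp_path):
        path = make_vcf(
            tmp_path / "m.vcf",
            [
                "ch01\t10\t.\tA\tG\t50.0\t.\t.\tGT:DP:AD\t./.:8:.",
                "ch01\t20\t.\tC\tT\t50.0\t.\t.\tGT:DP:AD\t1/1:8:2,6",
                "ch01\t30\t.\tC\tT\t50.0\t.\t.\tGT:DP:AD\t1/1:8:0,8",
            ],
        )
        recs = list(read_vcf(path, "ACC1"))
        assert recs[0].calls["ACC1"].genotype is Genotype.MISSING
        assert recs[1].calls["ACC1"].ref_support is True
        assert recs[2].calls["ACC1"].ref_support is False

    def test_empty_body_yields_empty_stream(self, tmp_path):
        path = make_vcf(tmp_path / "e.vcf", [])
        assert list(read_vcf(path, "ACC1")) == []

    def test_unsorted_positions_rejected(self, tmp_path):
        path = make_vcf(
            tmp_path / "u.vcf",
            [
                "ch01\t200\t.\tA\tG\t50.0\t.\t.\tGT:DP\t1/1:9",
                "ch01\t100\t.\tA\tG\t50.0\t.\t.\tGT:DP\t1/1:9",
            ],
        )
        with pytest.raises(VcfParseError, match="unsorted"):
            list(read_vcf(path, "ACC1"))

    def test_stream_order_is_nondecreasing(self, small_cohort_dir):
        path = sorted(small_cohort_dir["vcf_dir"].glob("WA*.vcf"))[0]
        last = None
        for rec in read_vcf(path):
            if last is not None and rec.chrom == last[0]:
                assert rec.pos >= last[1]
            last = (rec.chrom, rec.pos)

    def test_roundtrip_preserves_variant_key_multiset(self, small_cohort, small_cohort_dir):
        acc = small_cohort.cohort.wild_accessions[0]
        written = Counter(small_cohort.calls[acc].keys())
        read_back = Counter(r.key for r in read_vcf(small_cohort_dir["vcf_dir"] / f"{acc}.vcf", acc))
        assert read_back == written


class TestNormalize:
    REF = ReferenceGenome({"c": "GGCATTTACGTACGTAACCG"})

    def test_snp_unchanged(self):
        rec = VariantRecord("c", 4, "A", "G")
        assert normalize_variant(rec, self.REF) is rec

    def test_insertion_in_homopolymer_left_aligns(self):
        # context GGCATTT...: inserting a T anywhere in the TTT run is the
        # same haplotype; canonical form anchors at the A before the run
        rec = VariantRecord("c", 6, "T", "TT")
        norm = normalize_variant(rec, self.REF)
        assert (norm.pos, norm.ref, norm.alt) == (4, "A", "AT")

    def test_equivalent_representations_converge(self):
        a = normalize_variant(VariantRecord("c", 5, "TT", "T"), self.REF)
        b = normalize_variant(VariantRecord("c", 6, "TT", "T"), self.REF)
        c = normalize_variant(VariantRecord("c", 4, "AT", "A"), self.REF)
        assert a.key == b.key == c.key

    def test_padded_representation_trims(self):
        rec = VariantRecord("c", 8, "ACG", "AG")  # deletion of C written with suffix
        norm = normalize_variant(rec, self.REF)
        assert len(norm.ref) == 2 and len(norm.alt) == 1

    def test_reference_mismatch_raises(self):
        from domesticscan.variant_io import ReferenceMismatchError

        with pytest.raises(ReferenceMismatchError):
            normalize_variant(VariantRecord("c", 4, "T", "TG"), self.REF)

    def test_idempotence_on_random_indels(self, rng):
        bases = "ACGT"
        seq = "".join(rng.choice(list(bases), 500))
        ref_genome = ReferenceGenome({"c": seq})
        n_checked = 0
        for _ in range(200):
            pos = int(rng.integers(5, 480))
            span = int(rng.integers(1, 4))
            ref = seq[pos - 1 : pos + span]
            if rng.random() < 0.5:
                alt = ref[0]
            else:
                alt = ref + "".join(rng.choice(list(bases), span))
            if ref == alt:
                continue
            rec = VariantRecord("c", pos, ref, alt)
            once = normalize_variant(rec, ref_genome)
            twice = normalize_variant(once, ref_genome)
            assert once.key == twice.key
            n_checked += 1
        assert n_checked > 150


class TestFilterPolicy:
    def _rec(self, genotype=Genotype.HOM_ALT, depth=5, qual=30.0, ref_support=None):
        return VariantRecord(
            "c", 10, "A", "G", {"X": Call(genotype, depth, qual, ref_support=ref_support)}
        )

    def test_boundary_values_pass(self):
        assert apply_filter(self._rec(), "X", FilterPolicy.wild_default())

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"depth": 4},
            {"qual": 29.9},
            {"genotype": Genotype.HET},
            {"genotype": Genotype.HOM_REF},
            {"genotype": Genotype.MISSING},
            {"depth": None},
            {"qual": None},
            {"ref_support": True},
        ],
    )
    def test_any_single_criterion_below_threshold_fails(self, kwargs):
        assert not apply_filter(self._rec(**kwargs), "X", FilterPolicy.wild_default())

    def test_unfiltered_policy_passes_weak_calls(self):
        rec = self._rec(genotype=Genotype.HET, depth=1, qual=2.0)
        assert apply_filter(rec, "X", FilterPolicy.unfiltered())

    def test_absent_call_always_fails(self):
        assert not apply_filter(self._rec(), "Y", FilterPolicy.unfiltered())

    @given(
        depth=st.integers(0, 12),
        qual=st.floats(0, 60, allow_nan=False),
        relax_depth=st.integers(0, 5),
        relax_qual=st.floats(0, 30, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_relaxing_thresholds_never_shrinks_passing_set(
        self, depth, qual, relax_depth, relax_qual
    ):
        rec = self._rec(depth=depth, qual=qual)
        strict = FilterPolicy(min_depth=5, min_qual=30.0)
        relaxed = FilterPolicy(min_depth=5 - relax_depth, min_qual=30.0 - relax_qual)
        if apply_filter(rec, "X", strict):
            assert apply_filter(rec, "X", relaxed)


class TestGeneModels:
    def test_two_segment_cds_length(self):
        g = GeneModel("g1", "c", "+", 1, 40, cds=((11, 19, 0), (31, 36, 0)))
        assert g.cds_length == 15

    def test_minus_strand_cds_is_reverse_complemented(self):
        ref = ReferenceGenome({"c": "AAACATTTTCCC"})
        g = GeneModel("g1", "c", "-", 1, 12, cds=((4, 9, 0),))
        # genomic CATTTT -> reverse complement AAAATG read 3'->5'
        assert g.cds_sequence(ref) == "AAAATG"

    def test_gff_roundtrip_matches_generator_truth(self, small_cohort, small_cohort_dir):
        parsed = read_gene_models(small_cohort_dir["gff"], small_cohort.reference.lengths)
        truth = {g.gene_id: g for g in small_cohort.genes}
        assert len(parsed) == len(truth)
        for g in parsed:
            t = truth[g.gene_id]
            assert (g.chrom, g.strand, g.start, g.end) == (t.chrom, t.strand, t.start, t.end)
            assert [(s, e) for s, e, _ in g.cds] == [(s, e) for s, e, _ in t.cds]
            assert g.annotation == t.annotation

    def test_coding_offset_roundtrips_with_genomic_position(self, small_cohort):
        for g in small_cohort.genes[:10]:
            for off in (0, 1, g.cds_length // 2, g.cds_length - 1):
                assert g.coding_offset(g.genomic_position(off)) == off
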