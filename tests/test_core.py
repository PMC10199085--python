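"""Domain types, registry, VCF/TSV I/O and counting."""
import numpy as np
import pytest

from cholevar import core
from cholevar.core import (
    AnnotationError,
    GenotypeMatrix,
    VcfFormatError,
    carrier_and_allele_counts,
)

from conftest import make_vcf


class TestReadVcf:
    def test_het_plus_hom_counts_and_af(self, tmp_path):
        p = make_vcf(tmp_path / "t.vcf", "1\t100\trs1\tA\tT\t.\t.\t.\tGT\t0/1\t1/1\n")
        m = core.read_vcf(p)
        assert m.counts[:, 0].tolist() == [1, 2]
        assert m.alt_allele_frequency()[0] == pytest.approx(3 / 4)

    def test_multiallelic_split_matches_hand_split(self, tmp_path):
        multi = make_vcf(
            tmp_path / "m.vcf",
            "1\t200\t.\tC\tG,T\t.\t.\t.\tGT\t1/2\t0/1\n",
        )
        hand = make_vcf(
            tmp_path / "h.vcf",
            # same site split by hand into one biallelic record per alt
            "1\t200\t.\tC\tG\t.\t.\t.\tGT\t0/1\t0/1\n"
            "1\t200\t.\tC\tT\t.\t.\t.\tGT\t0/1\t0/0\n",
        )
        got = core.read_vcf(multi)
        want = core.read_vcf(hand)
        assert got.n_variants == 2
        assert (got.counts == want.counts).all()

    def test_empty_body_is_valid(self, tmp_path):
        m = core.read_vcf(make_vcf(tmp_path / "e.vcf", ""))
        assert m.n_variants == 0 and m.n_samples == 2
        assert m.alt_allele_frequency().shape == (0,)

    def test_missing_gt_format_rejected(self, tmp_path):
        p = tmp_path / "nogt.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\n"
        )
        with pytest.raises(VcfFormatError, match="GT"):
            core.read_vcf(p)

    def test_missing_genotypes_excluded_from_af(self, tmp_path):
        p = make_vcf(
            tmp_path / "mis.vcf",
            "1\t1\t.\tA\tT\t.\t.\t.\tGT\t./.\t0/1\n",
        )
        m = core.read_vcf(p)
        assert m.counts[:, 0].tolist() == [-1, 1]
        # one called sample: AF = 1/2, not 1/4
        assert m.alt_allele_frequency()[0] == pytest.approx(0.5)

    def test_round_trip_bit_identical(self, tmp_path, small_cohort):
        p1 = tmp_path / "a.vcf"
        p2 = tmp_path / "b.vcf"
        core.write_vcf(small_cohort.matrix, p1, sites=small_cohort.sites)
        m = core.read_vcf(p1)
        assert m.variant_keys == small_cohort.matrix.variant_keys
        assert (m.counts == small_cohort.matrix.counts).all()
        core.write_vcf(m, p2, sites=small_cohort.sites)
        assert p1.read_bytes() == p2.read_bytes()


class TestGenotypeMatrix:
    def test_shape_and_value_validation(self):
        with pytest.raises(ValueError, match="inconsistent"):
            GenotypeMatrix(["a"], ["v1", "v2"], np.zeros((1, 1)))
        with pytest.raises(ValueError, match="allele counts"):
            GenotypeMatrix(["a"], ["v1"], np.array([[3]]))

    def test_af_matches_direct_count(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 3, size=(50, 4)).astype(np.int8)
        m = GenotypeMatrix([f"s{i}" for i in range(50)], list("wxyz"), counts)
        for j in range(4):
            assert m.alt_allele_frequency()[j] == pytest.approx(
                counts[:, j].sum() / 100
            )


class TestCarrierCounts:
    def test_printed_footnote_arithmetic(self):
        # 760 het + 99 hom-alt -> 859 carriers, 958 alternate alleles
        g = np.array([1] * 760 + [2] * 99 + [0] * 100)
        assert carrier_and_allele_counts(g) == (760, 99, 958, 859)

    def test_all_reference(self):
        assert carrier_and_allele_counts(np.zeros(10)) == (0, 0, 0, 0)

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(12)
        g = rng.integers(-1, 3, size=500)
        het, hom, alleles, carriers = carrier_and_allele_counts(g)
        assert het == sum(1 for x in g if x == 1)
        assert hom == sum(1 for x in g if x == 2)
        assert alleles == sum(int(x) for x in g if x > 0)
        assert carriers == sum(1 for x in g if x > 0)


class TestGeneRegistry:
    def test_panel_products_and_diseases(self):
        bsep = core.gene_info("ABCB11")
        assert bsep.product == "BSEP"
        assert bsep.associated_disease == "PFIC-2"
        fic1 = core.gene_info("ATP8B1")
        assert fic1.product == "FIC1"
        assert fic1.associated_disease == "PFIC-1"
        assert len(core.gene_registry()) == 5

    def test_unknown_symbol(self):
        with pytest.raises(KeyError, match="ABCC2"):
            core.gene_info("ABCC2")


class TestAnnotationTable:
    def test_printed_frequencies_parsed(self, nsv_records):
        by_id = {r.variant_id: r for r in nsv_records}
        n510s = by_id["ABCB4:N510S"]
        assert n510s.af_gnomad == pytest.approx(0.00019110)
        assert n510s.af_cohort == pytest.approx(0.00057394)
        assert n510s.literature_known
        # cohort-private row: absent gnomAD cell maps to missing, not zero
        assert by_id["ABCB4:A833T"].af_gnomad is None
        assert by_id["ABCB4:A833T"].af_cohort == pytest.approx(0.00009638)

    def test_af_bound_violation(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene\tprotein_change\taf_cohort\nABCB4\tX1Y\t1.2\n")
        with pytest.raises(AnnotationError, match=r"af_cohort.*\[0, 1\]"):
            core.read_annotation_table(p)

    def test_unknown_phenotype_label_lists_vocabulary(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "gene\tprotein_change\tphenotype_groups\nABCB4\tX1Y\tjaundice\n"
        )
        with pytest.raises(AnnotationError, match="gallstone"):
            core.read_annotation_table(p)

    def test_duplicate_variant_id_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("gene\tprotein_change\nABCB4\tX1Y\nABCB4\tX1Y\n")
        with pytest.raises(AnnotationError, match="duplicate"):
            core.read_annotation_table(p)

    def test_round_trip(self, tmp_path, nsv_records):
        out = tmp_path / "rt.tsv"
        core.write_annotation_table(nsv_records, out)
        back = core.read_annotation_table(out)
        assert [r.variant_id for r in back] == [r.variant_id for r in nsv_records]
        for a, b in zip(back, nsv_records):
            assert a.af_gnomad == b.af_gnomad
            assert a.acmg_codes == b.acmg_codes
            assert a.phenotype_groups == b.phenotype_groups


class TestFixtureIntegrity:
    def test_case_table_one_row_per_volunteer(self, icp_rows):
        ids = [r.volunteer_id for r in icp_rows]
        assert len(ids) == len(set(ids)) == 15

    def test_printed_af_strings_preserved_verbatim(self):
        text = core.fixture_path("phenotype_associated_variants.tsv").read_text()
        for fragment in (
            "0.00019110\t0.00057394",   # N510S
            "0.00026040\t0.00009558",   # V284A
            "0.0005776\t0.0006719",     # T651N (7 printed digits)
            "0.01436000\t0.12647200",   # N591S
        ):
            assert fragment in text
        lof = core.fixture_path("lof_variants.tsv").read_text()
        assert "0.00039970\t0.00336538" in lof

    def test_footnote_zygosity_counts(self, nsv_records):
        by_id = {r.variant_id: r for r in nsv_records}
        n591s = by_id["ABCB11:N591S"]
        assert (n591s.het_count, n591s.hom_count) == (760, 99)
        assert n591s.zygosity_observed == "both"
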