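"""Marker discovery filters, recombination extrapolation, SNP strain calls."""

import pytest

from fawstrain.markers import (
    GeneModel,
    VariantSite,
    call_diagnostic_snp,
    candidate_genes,
    cm_estimate,
    correspondence_table,
    filter_biallelic_maf,
    read_gff3_genes,
    read_vcf,
    split_variants_by_strain,
)
from fawstrain.seqdata import DEFAULT_SEGMENTS


def site(pos, calls, alleles=("A", "G")):
    return VariantSite("Z", pos, tuple(alleles), calls)


class TestSplitVariants:
    def test_c_private_site_polymorphic_only_in_c(self):
        s = site(100, {"c1": (0,), "c2": (1,), "r1": (0,), "r2": (0,)})
        c_sites, r_sites = split_variants_by_strain(
            [s], {"c1": "C", "c2": "C", "r1": "R", "r2": "R"}
        )
        assert not c_sites[0].monomorphic
        assert r_sites[0].monomorphic

    def test_unlabeled_sample_rejected(self):
        s = site(1, {"x": (0,)})
        with pytest.raises(ValueError, match="x"):
            split_variants_by_strain([s], {})

    def test_empty_strain_rejected(self):
        s = site(1, {"x": (0,)})
        with pytest.raises(ValueError, match="strain"):
            split_variants_by_strain([s], {"x": "C"})

    def test_planted_private_snps_recovered(self):
        strain_of = {f"c{i}": "C" for i in range(4)} | {f"r{i}": "R" for i in range(4)}
        private_c = site(10, {f"c{i}": (i % 2,) for i in range(4)} | {f"r{i}": (0,) for i in range(4)})
        private_r = site(20, {f"c{i}": (1,) for i in range(4)} | {f"r{i}": (i % 2,) for i in range(4)})
        shared = site(30, {s: (i % 2,) for i, s in enumerate(strain_of)})
        c_sites, r_sites = split_variants_by_strain([private_c, private_r, shared], strain_of)
        assert [s.pos for s in c_sites if not s.monomorphic] == [10, 30]
        assert [s.pos for s in r_sites if not s.monomorphic] == [20, 30]


class TestBiallelicMaf:
    def test_triallelic_removed(self):
        s = site(1, {"a": (0,), "b": (1,), "c": (2,)}, alleles=("A", "G", "T"))
        assert filter_biallelic_maf([s], 0.0) == []

    def test_maf_half_kept(self):
        s = site(1, {"a": (0,), "b": (1,)})
        assert filter_biallelic_maf([s], 0.05) == [s]

    def test_low_maf_removed_at_threshold(self):
        calls = {f"s{i}": (0,) for i in range(32)} | {"m": (1,)}
        s = site(1, calls)  # MAF = 1/33 = 0.03
        assert filter_biallelic_maf([s], 0.05) == []
        assert filter_biallelic_maf([s], 0.0) == [s]

    def test_monotone_in_threshold(self):
        sites = [
            site(i, {f"s{j}": (1 if j < i else 0,) for j in range(10)})
            for i in range(1, 6)
        ]
        prev = filter_biallelic_maf(sites, 0.0)
        for maf in (0.1, 0.2, 0.3, 0.4, 0.5):
            cur = filter_biallelic_maf(sites, maf)
            assert set(s.pos for s in cur) <= set(s.pos for s in prev)
            prev = cur

    def test_maf_ignores_missing_calls(self):
        s = site(1, {"a": (0,), "b": (1,), "c": (None,)})
        assert s.maf() == pytest.approx(0.5)


class TestCandidateGenes:
    def make_genes(self):
        return [
            GeneModel("short", "Z", 1_000_000, 1_001_499, 3, True),
            GeneModel("good", "Z", 5_000_000, 5_002_499, 3, True),
            GeneModel("long", "Z", 9_000_000, 9_007_999, 2, True),
            GeneModel("fewintrons", "Z", 13_000_000, 13_003_999, 1, True),
        ]

    def test_length_and_intron_filters(self):
        counts = {g.gene_id: (2, 2) for g in self.make_genes()}
        out = candidate_genes(self.make_genes(), counts)
        assert [g.gene_id for g in out] == ["good"]

    def test_spacing_keeps_higher_ranked(self):
        genes = [
            GeneModel("a", "Z", 1_000_000, 1_003_000, 3, True),
            GeneModel("b", "Z", 1_500_000, 1_503_000, 3, True),  # 0.5 Mb away
        ]
        counts = {"a": (3, 3), "b": (1, 1)}
        out = candidate_genes(genes, counts)
        assert [g.gene_id for g in out] == ["a"]

    def test_anchor_spacing_enforced(self):
        genes = [GeneModel("a", "Z", 1_000_000, 1_003_000, 3, True)]
        out = candidate_genes(genes, {"a": (1, 1)}, anchor_positions=(1_500_000,))
        assert out == []

    def test_requires_variability_in_both_strains(self):
        genes = [GeneModel("a", "Z", 1_000_000, 1_003_000, 3, True)]
        assert candidate_genes(genes, {"a": (2, 0)}) == []

    def test_requires_insect_annotation(self):
        genes = [GeneModel("a", "Z", 1_000_000, 1_003_000, 3, False)]
        assert candidate_genes(genes, {"a": (2, 2)}) == []

    def test_empty_input_empty_output(self):
        assert candidate_genes([], {}) == []

    def test_order_independent(self):
        genes = self.make_genes()
        counts = {g.gene_id: (2, 2) for g in genes}
        fwd = candidate_genes(genes, counts)
        rev = candidate_genes(list(reversed(genes)), counts)
        assert [g.gene_id for g in fwd] == [g.gene_id for g in rev]


class TestCmEstimate:
    def test_lower_bound_of_printed_window(self):
        est = cm_estimate(7.4, 5)
        assert est.fraction_pct == pytest.approx(37.0)

    def test_upper_bound_capped_at_unlinked(self):
        est = cm_estimate(7.4, 8)
        assert est.cm == pytest.approx(59.2)
        assert est.fraction_pct == 50.0

    def test_zero_distance(self):
        assert cm_estimate(0, 8).fraction_pct == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cm_estimate(-1, 5)


class TestDiagnosticSnp:
    def test_ubc_cytosine_is_c_strain(self):
        seg = DEFAULT_SEGMENTS["UBCie695"]
        seq = "A" * 198 + "C" + "A" * (695 - 199)
        assert call_diagnostic_snp(seq, seg) == "C"

    def test_nes_thymine_is_c_strain(self):
        seg = DEFAULT_SEGMENTS["nesEI533"]
        seq = "A" * 298 + "T" + "A" * (533 - 299)
        assert call_diagnostic_snp(seq, seg) == "C"

    def test_gap_undetermined(self):
        seg = DEFAULT_SEGMENTS["UBCie695"]
        seq = "A" * 198 + "-" + "A" * (695 - 199)
        assert call_diagnostic_snp(seq, seg) == "UNDETERMINED"

    def test_non_diagnostic_base_never_called(self):
        seg = DEFAULT_SEGMENTS["TpiEI194"]
        for base in "AG-N":
            seq = "A" * 182 + base + "A" * (194 - 183)
            assert call_diagnostic_snp(seq, seg) == "UNDETERMINED"

    def test_position_outside_sequence_rejected(self):
        seg = DEFAULT_SEGMENTS["UBCie695"]
        with pytest.raises(ValueError, match="outside"):
            call_diagnostic_snp("ACGT", seg)


class TestCorrespondence:
    def test_perfect_concordance_diagonal(self):
        calls = {f"s{i}": "C" if i < 5 else "R" for i in range(10)}
        res = correspondence_table(calls, dict(calls))
        assert res.percentages.at["C", "C"] == 100.0
        assert res.percentages.at["R", "R"] == 100.0

    def test_one_discordant_of_ten(self):
        a = {f"s{i}": "C" for i in range(10)}
        b = dict(a)
        b["s9"] = "R"
        res = correspondence_table(a, b)
        assert res.percentages.at["C", "C"] == pytest.approx(90.0)
        assert res.percentages.at["C", "R"] == pytest.approx(10.0)

    def test_undetermined_excluded_and_counted(self):
        a = {"s1": "C", "s2": "UNDETERMINED", "s3": "R"}
        b = {"s1": "C", "s2": "C", "s3": "R"}
        res = correspondence_table(a, b)
        assert res.n_excluded == 1
        assert res.counts.values.sum() == 2

    def test_disjoint_universes_rejected(self):
        with pytest.raises(ValueError, match="share"):
            correspondence_table({"a": "C"}, {"b": "C"})

    def test_simulated_host_vs_snp_agreement_tracks_misassignment(self):
        from conftest import small_config
        from fawstrain.markers import call_alignment_snps
        from fawstrain.seqdata import MarkerAlignment
        from fawstrain.simulate import simulate_cohort

        m = 0.05
        cfg = small_config(seed=8, n=60, male_fraction=0.0, host_misassignment_rate=m)
        co = simulate_cohort(cfg)
        seg = cfg.segment_defs[0]
        recs = [r for r in co.sequences[seg.segment_name] if r.specimen_id != "OUTGROUP"]
        aln = MarkerAlignment(seg, recs, list(range(1, seg.segment_length_nominal + 1)))
        snp = call_alignment_snps(aln)
        host = {s.id: s.host_class.value for s in co.specimens}
        res = correspondence_table(host, snp)
        agree = res.agreement() / 100.0
        n = res.counts.values.sum()
        sd = (m * (1 - m) / n) ** 0.5
        assert abs(agree - (1 - m)) <= 3 * sd


class TestVcfGff3IO:
    def test_vcf_roundtrip_with_cyvcf2(self, tmp_path):
        vcf_text = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=Z,length=1000000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tc1\tc2\tr1\tr2\n"
            "Z\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t./.\n"
            "Z\t200\t.\tC\tT,G\t.\tPASS\t.\tGT\t0/0\t1/2\t0/0\t0/0\n"
        )
        p = tmp_path / "t.vcf"
        p.write_text(vcf_text)
        sites = read_vcf(p)
        assert [s.pos for s in sites] == [100, 200]
        assert sites[0].sample_alleles["r2"] == (None, None)
        assert sites[0].allele_counts == (3, 3)
        assert len(sites[1].alleles) == 3

    def test_gff3_gene_models(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "Z\tsrc\tgene\t1000\t4999\t.\t+\t.\tID=g1;insect_annotated=1\n"
            "Z\tsrc\tmRNA\t1000\t4999\t.\t+\t.\tID=m1;Parent=g1\n"
            "Z\tsrc\texon\t1000\t1500\t.\t+\t.\tParent=m1\n"
            "Z\tsrc\texon\t2000\t2500\t.\t+\t.\tParent=m1\n"
            "Z\tsrc\texon\t4000\t4999\t.\t+\t.\tParent=m1\n"
            "Z\tsrc\tgene\t9000\t9999\t.\t-\t.\tID=g2;introns=4\n"
        )
        p = tmp_path / "t.gff3"
        p.write_text(gff)
        genes = {g.gene_id: g for g in read_gff3_genes(p)}
        assert genes["g1"].n_introns == 2
        assert genes["g1"].insect_annotated
        assert genes["g2"].n_introns == 4
        assert not genes["g2"].insect_annotated
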