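"""Variant filter rules, dinucleotide/indel handling, spike-in, audit."""

import numpy as np
import pandas as pd
import pytest

from clonefate.seq_qc import (
    decisions_to_frame,
    filter_indels,
    filter_snvs,
    harmonize_indels,
    merge_dinucleotides,
    read_strain_snps,
    recurrent_pdx_unique_audit,
    spike_snps_into_reference,
)
from clonefate.simulate import SimulationConfig, simulate_variant_calls
from clonefate.types import SampleMeta, SampleSheet, VariantTable


def vrow(
    sample="S1", patient="P1", pos=100, vaf=0.03, varscan=True, mutect=True,
    p=0.005, depth=35, alt=12, galt=2, gvaf=0.005, vc="SNV", driver=False,
):
    return dict(
        patient_id=patient, sample_id=sample, chrom="1", pos=pos, ref="A", alt="T",
        variant_class=vc, vaf=vaf, depth=depth, alt_reads=alt,
        germline_alt_reads=galt, germline_vaf=gvaf, called_varscan=varscan,
        called_mutect=mutect, somatic_p=p, is_driver=driver,
    )


# every rule boundary of the SNV filter, with hand-derived verdicts
SNV_CASES = [
    # (kwargs, verdict) — baseline passes every gate
    (dict(), "pass"),
    # dual-caller VAF bound is strict: 2% exactly fails, just above passes
    (dict(pos=101, vaf=0.02), "fail"),
    (dict(pos=102, vaf=0.021), "pass"),
    # single-caller needs >= 5%
    (dict(pos=103, mutect=False, vaf=0.03), "fail"),
    (dict(pos=104, mutect=False, vaf=0.05, alt=20, depth=400), "pass"),
    (dict(pos=105, mutect=False, vaf=0.049, alt=20, depth=409), "fail"),
    # mutect-only calls have no VarScan2 p-value support
    (dict(pos=106, varscan=False), "fail"),
    # somatic p bound inclusive at 0.01
    (dict(pos=107, p=0.01), "pass"),
    (dict(pos=108, p=0.011), "fail"),
    # depth bound inclusive at 30
    (dict(pos=109, depth=30, alt=10), "pass"),
    (dict(pos=110, depth=29, alt=10), "fail"),
    # >= 10 supporting reads
    (dict(pos=111, alt=10, depth=330), "pass"),
    (dict(pos=112, alt=9, depth=300), "fail"),
    # germline: < 5 reads and VAF <= 1%
    (dict(pos=113, galt=4, gvaf=0.009), "pass"),
    (dict(pos=114, galt=5, gvaf=0.009), "fail"),
    (dict(pos=115, galt=4, gvaf=0.011), "fail"),
    (dict(pos=116, gvaf=0.01), "pass"),
]


class TestSnvFilter:
    def test_rule_boundaries(self):
        table = VariantTable(pd.DataFrame([vrow(**kw) for kw, _ in SNV_CASES]))
        decisions = {d.pos: d for d in filter_snvs(table)}
        for kw, verdict in SNV_CASES:
            pos = kw.get("pos", 100)
            assert decisions[pos].verdict == verdict, (pos, decisions[pos].reasons)

    def test_fail_has_reasons(self):
        table = VariantTable(pd.DataFrame([vrow(vaf=0.03, mutect=False)]))
        d = filter_snvs(table)[0]
        assert d.verdict == "fail" and d.reasons == ["single-caller VAF < 5%"]

    def test_multi_region_rescue_at_one_percent(self):
        rows = [
            vrow(sample="S1", pos=300, vaf=0.015, alt=12, depth=800),  # fails alone
            vrow(sample="S2", pos=300, vaf=0.10, alt=40, depth=400),  # passes
            vrow(sample="S3", pos=300, vaf=0.005, alt=4, depth=800),  # below rescue VAF
        ]
        decisions = {d.sample_id: d for d in filter_snvs(VariantTable(pd.DataFrame(rows)))}
        assert decisions["S1"].verdict == "rescued"
        assert decisions["S2"].verdict == "pass"
        assert decisions["S3"].verdict == "fail"

    def test_rescue_does_not_cross_patients(self):
        rows = [
            vrow(sample="S1", patient="P1", pos=300, vaf=0.015),
            vrow(sample="S2", patient="P2", pos=300, vaf=0.10, alt=40, depth=400),
        ]
        decisions = {d.sample_id: d for d in filter_snvs(VariantTable(pd.DataFrame(rows)))}
        assert decisions["S1"].verdict == "fail"

    def test_order_invariance(self):
        rows = [vrow(**kw) for kw, _ in SNV_CASES]
        fwd = decisions_to_frame(filter_snvs(VariantTable(pd.DataFrame(rows))))
        rev = decisions_to_frame(filter_snvs(VariantTable(pd.DataFrame(rows[::-1]))))
        key = ["sample_id", "chrom", "pos"]
        pd.testing.assert_frame_equal(
            fwd.sort_values(key).reset_index(drop=True),
            rev.sort_values(key).reset_index(drop=True),
        )


class TestIndelFilter:
    def test_no_min_alt_read_rule(self):
        table = VariantTable(
            pd.DataFrame([vrow(vc="indel", p=0.0005, depth=60, alt=6, vaf=0.1)])
        )
        assert filter_indels(table)[0].verdict == "pass"

    @pytest.mark.parametrize(
        "kw",
        [
            dict(p=0.0011, depth=60, alt=6, vaf=0.1),  # p bound 0.001
            dict(p=0.0005, depth=40, alt=6, vaf=0.1),  # depth bound 50
        ],
    )
    def test_stricter_bounds(self, kw):
        table = VariantTable(pd.DataFrame([vrow(vc="indel", **kw)]))
        assert filter_indels(table)[0].verdict == "fail"

    def test_harmonize_reports_longest(self):
        calls = pd.DataFrame(
            [
                {"sample_id": "S1", "chrom": "1", "pos": 100, "ref": "ATTT", "alt": "A",
                 "depth": 60, "alt_reads": 8, "vaf": 0.13},
                {"sample_id": "S2", "chrom": "1", "pos": 100, "ref": "ATTTTT", "alt": "A",
                 "depth": 80, "alt_reads": 6, "vaf": 0.075},
            ]
        )
        out = harmonize_indels(calls)
        assert len(out) == 1
        rec = out.iloc[0]
        assert rec["ref"] == "ATTTTT"  # 5-bp deletion wins over 3-bp
        assert rec["depth"] == 80 and rec["alt_reads"] == 8
        assert rec["vaf"] == pytest.approx(0.13)

    def test_harmonize_keeps_distinct_loci_apart(self):
        calls = pd.DataFrame(
            [
                {"sample_id": "S1", "chrom": "1", "pos": 100, "ref": "AT", "alt": "A",
                 "depth": 60, "alt_reads": 8, "vaf": 0.13},
                {"sample_id": "S1", "chrom": "1", "pos": 500, "ref": "GC", "alt": "G",
                 "depth": 60, "alt_reads": 8, "vaf": 0.13},
            ]
        )
        assert len(harmonize_indels(calls)) == 2


class TestDinucleotides:
    def snvs(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "alt", "depth", "alt_reads"]
        )

    def test_similar_frequencies_merged(self):
        out = merge_dinucleotides(
            self.snvs([("1", 10, "A", "T", 100, 30), ("1", 11, "C", "G", 100, 28)])
        )
        assert len(out) == 1
        rec = out.iloc[0]
        assert rec["variant_class"] == "dinucleotide"
        assert rec["ref"] == "AC" and rec["alt"] == "TG"
        assert rec["vaf"] == pytest.approx(0.29)

    def test_distinct_frequencies_kept_separate(self):
        out = merge_dinucleotides(
            self.snvs([("1", 10, "A", "T", 100, 30), ("1", 11, "C", "G", 100, 5)])
        )
        assert (out["variant_class"] == "SNV").all() and len(out) == 2

    def test_non_adjacent_never_considered(self):
        out = merge_dinucleotides(
            self.snvs([("1", 10, "A", "T", 100, 30), ("1", 12, "C", "G", 100, 30)])
        )
        assert (out["variant_class"] == "SNV").all()


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=chr1,length=14>\n"
    "##contig=<ID=chr2,length=4>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tMOUSE\n"
)


class TestSpikeIn:
    def write_inputs(self, tmp_path):
        ref = tmp_path / "ref.fa"
        ref.write_text(">chr1 toy\nACGTACGTAC\nGTAC\n>chr2\nTTTT\n")
        vcf = tmp_path / "snp.vcf"
        vcf.write_text(
            VCF_HEADER
            + "chr1\t2\t.\tC\tT\t.\t.\t.\tGT\t1/1\n"  # homozygous: applied
            + "chr1\t5\t.\tA\tG\t.\t.\t.\tGT\t0/1\n"  # ref/alt het: dropped
            + "chr1\t7\t.\tG\tA,T\t.\t.\t.\tGT\t1/2\n"  # non-ref het: first allele
            + "chr2\t1\t.\tT\tG\t.\t.\t.\tGT\t1/1\n"
        )
        return ref, vcf

    def test_exact_substitution_set(self, tmp_path):
        ref, vcf = self.write_inputs(tmp_path)
        snps = read_strain_snps(vcf)
        out = tmp_path / "adapted.fa"
        n = spike_snps_into_reference(ref, snps, out)
        assert n == 3
        text = out.read_text()
        # line wrapping of the input is preserved
        assert text == ">chr1 toy\nATGTACATAC\nGTAC\n>chr2\nGTTT\n"
        # differing positions are exactly the retained SNPs
        orig = "ACGTACGTACGTAC"
        new = "ATGTACATACGTAC"
        diffs = {i + 1 for i, (a, b) in enumerate(zip(orig, new)) if a != b}
        assert diffs == {2, 7}

    def test_reference_mismatch_errors(self, tmp_path):
        ref, vcf = self.write_inputs(tmp_path)
        vcf.write_text(VCF_HEADER + "chr1\t2\t.\tG\tT\t.\t.\t.\tGT\t1/1\n")
        snps = read_strain_snps(vcf)
        with pytest.raises(Exception, match="mismatch"):
            spike_snps_into_reference(ref, snps, tmp_path / "x.fa")

    def test_genotype_classification(self, tmp_path):
        _, vcf = self.write_inputs(tmp_path)
        snps = read_strain_snps(vcf)
        classes = dict(zip(snps.df["pos"], snps.df["genotype_class"]))
        assert classes == {
            2: "homozygous",
            5: "heterozygous",
            7: "non_reference_heterozygous",
            1: "homozygous",
        }
        assert len(snps.retained()) == 3


class TestAudit:
    def meta(self, n_patients=3):
        samples = []
        for i in range(n_patients):
            p = f"P{i + 1}"
            samples.append(SampleMeta(f"{p}_R1", p, f"T{i + 1}", "R1", "primary_region"))
            samples.append(
                SampleMeta(f"{p}_X1", p, f"T{i + 1}", "R1", "pdx", passage=0,
                           region_of_origin=f"{p}_R1")
            )
        return SampleSheet(samples)

    def test_recurrent_pdx_unique_flagged(self):
        rows = [vrow(sample=f"P{i}_X1", patient=f"P{i}", pos=999) for i in (1, 2, 3)]
        out = recurrent_pdx_unique_audit(VariantTable(pd.DataFrame(rows)), self.meta())
        assert len(out) == 1
        assert out.iloc[0]["n_tumors"] == 3 and out.iloc[0]["n_instances"] == 3

    def test_variant_in_matched_primary_excluded(self):
        rows = [
            vrow(sample="P1_X1", patient="P1", pos=999),
            vrow(sample="P1_R1", patient="P1", pos=999),
            vrow(sample="P2_X1", patient="P2", pos=999),
        ]
        out = recurrent_pdx_unique_audit(VariantTable(pd.DataFrame(rows)), self.meta())
        assert out.empty  # only one tumor left PDX-unique

    def test_driver_mutations_excluded(self):
        rows = [
            vrow(sample="P1_X1", patient="P1", pos=999, driver=True),
            vrow(sample="P2_X1", patient="P2", pos=999, driver=True),
        ]
        out = recurrent_pdx_unique_audit(VariantTable(pd.DataFrame(rows)), self.meta())
        assert out.empty

    def test_injected_artifacts_recovered_and_clean_run_empty(self, rng):
        cfg = SimulationConfig(seed=7, artifact_rate=1.0, n_artifact_sites=4,
                               variants_per_patient=10)
        table, truth = simulate_variant_calls(rng, cfg, n_patients=4)
        meta = SampleSheet(
            [
                SampleMeta(f"P{i}_R{r}", f"P{i}", f"T{i}", f"R{r}", "primary_region")
                for i in range(1, 5)
                for r in (1, 2)
            ]
            + [
                SampleMeta(f"P{i}_PDX1", f"P{i}", f"T{i}", "R1", "pdx", passage=0,
                           region_of_origin=f"P{i}_R1")
                for i in range(1, 5)
            ]
        )
        out = recurrent_pdx_unique_audit(table, meta)
        found = set(zip(out["chrom"], out["pos"]))
        injected = set(zip(truth["chrom"], truth["pos"]))
        assert injected <= found
        # with no artifacts, nothing is reported
        clean_cfg = SimulationConfig(seed=7, artifact_rate=0.0, variants_per_patient=10)
        clean, _ = simulate_variant_calls(np.random.default_rng(7), clean_cfg, n_patients=4)
        assert recurrent_pdx_unique_audit(clean, meta).empty
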