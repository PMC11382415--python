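import numpy as np
import pytest

from splicedx.variants import (
    FilterConfig,
    SpliceAIScores,
    VariantCall,
    apply_annotation_filters,
    apply_site_filters,
    filter_variant,
    max_delta,
    parse_annotated_vcf,
    run_filter_cascade,
)

from conftest import vcf_record, write_vcf


def make_call(**kw):
    base = dict(
        chrom="chr1", pos=1000, ref="C", alt="T", qual=200.0, depth=40,
        gq=99, fs=2.0, qd=20.0, gene_symbol="G", gene_type="protein_coding",
        maf=0.0001, spliceai=SpliceAIScores(0.85, 0.02, 0.8, 0.05),
    )
    base.update(kw)
    return VariantCall(**base)


class TestParseVcf:
    def test_single_snv_fields_verbatim(self, tmp_path):
        path = write_vcf(tmp_path / "a.vcf", [vcf_record(pos=1234, qual=87.5,
                                                         fs=3.5, qd=11.0, gq=55, dp=23)])
        calls = parse_annotated_vcf(path)
        assert len(calls) == 1
        v = calls[0]
        assert (v.chrom, v.pos, v.ref, v.alt) == ("chr1", 1234, "C", "T")
        assert v.qual == pytest.approx(87.5)
        assert (v.depth, v.gq) == (23, 55)
        assert v.fs == pytest.approx(3.5) and v.qd == pytest.approx(11.0)
        assert v.gene_symbol == "GENE_A" and v.gene_type == "protein_coding"
        assert v.maf == pytest.approx(0.0001)
        assert max_delta(v.spliceai) == pytest.approx(0.85)

    def test_multiallelic_split(self, tmp_path):
        rec = ("chr1\t500\t.\tG\tA,T\t90\t.\t"
               "FS=1.0;QD=10;GENE=G1;GENE_TYPE=protein_coding;CSQ=x;"
               "MAF=0.001,0.02;DS_AG=0.5,0.1;DS_AL=0,0;DS_DG=0,0;DS_DL=0,0"
               "\tGT:GQ:DP\t1/2:80:50")
        path = write_vcf(tmp_path / "m.vcf", [rec])
        calls = parse_annotated_vcf(path)
        assert [c.alt for c in calls] == ["A", "T"]
        assert calls[0].maf == pytest.approx(0.001)
        assert calls[1].maf == pytest.approx(0.02)
        assert max_delta(calls[0].spliceai) == pytest.approx(0.5)
        assert max_delta(calls[1].spliceai) == pytest.approx(0.1)

    def test_missing_format_fields_left_none(self, tmp_path):
        rec = ("chr1\t500\t.\tG\tA\t90\t.\t"
               "FS=1.0;QD=10;GENE=G1;GENE_TYPE=protein_coding;CSQ=x;MAF=0.001;"
               "DS_AG=0.5;DS_AL=0;DS_DG=0;DS_DL=0\tGT\t0/1")
        path = write_vcf(tmp_path / "x.vcf", [rec])
        v = parse_annotated_vcf(path)[0]
        assert v.gq is None and v.depth is None
        res = apply_site_filters(v)
        assert set(res.failed_criteria) == {"min_depth", "min_gq"}
        assert set(res.missing) == {"min_depth", "min_gq"}

    def test_parsed_table_matches_text_extraction_oracle(self, tmp_path):
        # 30 records; independent regex extraction of pos/qual/GQ/DP
        import re

        rng = np.random.default_rng(17)
        records, expected = [], []
        for i in range(30):
            pos = int(rng.integers(100, 10_000_000))
            qual = float(np.round(rng.uniform(10, 300), 1))
            gq = int(rng.integers(1, 99))
            dp = int(rng.integers(1, 80))
            records.append(vcf_record(pos=pos, qual=qual, gq=gq, dp=dp))
            expected.append((pos, qual, gq, dp))
        path = write_vcf(tmp_path / "many.vcf", records)
        calls = parse_annotated_vcf(path)
        with open(path) as fh:
            text_rows = [
                line for line in fh if not line.startswith("#")
            ]
        assert len(calls) == 30
        for v, (pos, qual, gq, dp), line in zip(calls, expected, text_rows):
            assert v.pos == pos and v.qual == pytest.approx(qual)
            assert v.gq == gq and v.depth == dp
            m = re.match(r"chr1\t(\d+)\t\.\tC\tT\t([\d.]+)\t", line)
            assert int(m.group(1)) == v.pos
            assert float(m.group(2)) == pytest.approx(v.qual)
            gt = line.rstrip().split("\t")[-1]
            assert [int(x) for x in gt.split(":")[1:]] == [v.gq, v.depth]


class TestSiteFilters:
    def test_gq6_fails_only_gq(self):
        res = apply_site_filters(make_call(gq=6))
        assert res.failed_criteria == ["min_gq"]
        assert not res.passed

    def test_boundary_values_pass(self):
        # inclusive thresholds: QUAL 50, DP 8, GQ 16, FS 30, QD 2
        res = apply_site_filters(make_call(qual=50.0, depth=8, gq=16, fs=30.0, qd=2.0))
        assert res.passed

    def test_just_below_boundaries_fail(self):
        assert apply_site_filters(make_call(qual=49.9)).failed_criteria == ["min_qual"]
        assert apply_site_filters(make_call(depth=7)).failed_criteria == ["min_depth"]
        assert apply_site_filters(make_call(gq=15)).failed_criteria == ["min_gq"]
        assert apply_site_filters(make_call(fs=30.1)).failed_criteria == ["max_fs"]
        assert apply_site_filters(make_call(qd=1.9)).failed_criteria == ["min_qd"]

    def test_not_short_circuited(self):
        res = apply_site_filters(make_call(qual=10, depth=2, gq=3, fs=99, qd=0.5))
        assert res.failed_criteria == ["min_qual", "min_depth", "min_gq", "max_fs", "min_qd"]


class TestAnnotationFilters:
    def test_low_spliceai_fails_cutoff(self):
        # acceptor gain 0.11 / donor gain 0.09: max 0.11 < 0.2
        res = apply_annotation_filters(
            make_call(spliceai=SpliceAIScores(0.11, 0.0, 0.09, 0.0))
        )
        assert res.failed_criteria == ["min_delta"]

    def test_high_spliceai_passes(self):
        res = apply_annotation_filters(
            make_call(spliceai=SpliceAIScores(1.00, 0.87, 0.0, 0.0))
        )
        assert res.passed

    def test_indel_fails_snv_only(self):
        res = apply_annotation_filters(make_call(ref="AT", alt="A"))
        assert res.failed_criteria == ["snv_only"]

    def test_maf_boundary_exclusive(self):
        assert apply_annotation_filters(make_call(maf=0.01)).failed_criteria == ["max_maf"]
        assert apply_annotation_filters(make_call(maf=0.009)).passed

    def test_missing_maf_treated_rare(self):
        assert apply_annotation_filters(make_call(maf=None)).passed
        cfg = FilterConfig(missing_maf_passes=False)
        assert apply_annotation_filters(make_call(maf=None), cfg).failed_criteria == ["max_maf"]

    def test_missing_spliceai_fails(self):
        assert apply_annotation_filters(make_call(spliceai=None)).failed_criteria == ["min_delta"]

    def test_non_coding_gene_fails(self):
        res = apply_annotation_filters(make_call(gene_type="lincRNA"))
        assert res.failed_criteria == ["protein_coding"]

    def test_spliceai_boundary_inclusive(self):
        assert apply_annotation_filters(
            make_call(spliceai=SpliceAIScores(0.2, 0, 0, 0))
        ).passed


class TestMaxDelta:
    def test_examples(self):
        assert max_delta(SpliceAIScores(0.11, 0.0, 0.09, 0.0)) == pytest.approx(0.11)
        assert max_delta(SpliceAIScores(0, 0, 0, 0)) == 0.0

    def test_matches_elementwise_max_oracle(self):
        rng = np.random.default_rng(23)
        quads = rng.random((100, 4))
        for q in quads:
            s = SpliceAIScores(*q)
            assert max_delta(s) == pytest.approx(float(np.max(q)))

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            SpliceAIScores(1.2, 0, 0, 0)


class TestCascade:
    def _random_calls(self, n, seed):
        rng = np.random.default_rng(seed)
        calls = []
        for _ in range(n):
            calls.append(
                make_call(
                    qual=float(rng.uniform(0, 120)),
                    depth=int(rng.integers(0, 30)),
                    gq=int(rng.integers(0, 99)),
                    fs=float(rng.uniform(0, 60)),
                    qd=float(rng.uniform(0, 30)),
                    maf=float(rng.uniform(0, 0.05)),
                    spliceai=SpliceAIScores(*rng.random(4) * 0.6),
                    gene_type="protein_coding" if rng.random() < 0.8 else "lincRNA",
                    ref="C" if rng.random() < 0.9 else "CA",
                )
            )
        return calls

    def test_pass_set_equals_conjunction_of_predicates(self):
        calls = self._random_calls(200, seed=31)
        passed, _ = run_filter_cascade(calls)
        expected = [
            v for v in calls
            if v.qual >= 50 and v.depth >= 8 and v.gq >= 16 and v.fs <= 30
            and v.qd >= 2 and v.maf < 0.01 and max_delta(v.spliceai) >= 0.2
            and v.gene_type == "protein_coding" and v.is_snv
        ]
        assert passed == expected

    def test_engineered_single_failure_audit(self):
        spoilers = {
            "min_qual": dict(qual=10.0),
            "min_depth": dict(depth=3),
            "min_gq": dict(gq=6),
            "max_fs": dict(fs=45.0),
            "min_qd": dict(qd=1.0),
            "max_maf": dict(maf=0.05),
            "min_delta": dict(spliceai=SpliceAIScores(0.11, 0, 0.09, 0)),
            "protein_coding": dict(gene_type="lincRNA"),
            "snv_only": dict(ref="AT", alt="A"),
        }
        calls = [make_call()] + [make_call(**kw) for kw in spoilers.values()]
        passed, audit = run_filter_cascade(calls)
        assert len(passed) == 1
        audit_map = dict(zip(audit["criterion"], audit["n_failed"]))
        for crit in spoilers:
            assert audit_map[crit] == 1, crit
        assert audit_map["input"] == 10 and audit_map["passed"] == 1
        # each spoiled call failed exactly its criterion
        for crit, kw in spoilers.items():
            res = filter_variant(make_call(**kw))
            assert res.failed_criteria == [crit]

    def test_empty_input_and_idempotence(self):
        assert run_filter_cascade([])[0] == []
        calls = self._random_calls(50, seed=37)
        once, _ = run_filter_cascade(calls)
        twice, _ = run_filter_cascade(once)
        assert once == twice

    def test_tightening_never_grows_pass_set(self):
        calls = self._random_calls(150, seed=41)
        base, _ = run_filter_cascade(calls, FilterConfig())
        tighter_cfgs = [
            FilterConfig(min_qual=80),
            FilterConfig(min_depth=15),
            FilterConfig(min_gq=40),
            FilterConfig(max_fs=10),
            FilterConfig(min_qd=5),
            FilterConfig(max_maf=0.001),
            FilterConfig(min_delta=0.5),
        ]
        base_set = {id(v) for v in base}
        for cfg in tighter_cfgs:
            tightened, _ = run_filter_cascade(calls, cfg)
            assert {id(v) for v in tightened} <= base_set
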