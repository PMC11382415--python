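import numpy as np
import pytest

from splicedx.annotation import GenomicInterval
from splicedx.junctions import (
    JunctionCountMatrix,
    build_junction_matrix,
    call_novel_junctions,
    flanking_normal_junctions,
    read_star_sj,
)

from conftest import write_sj_file


def make_matrix(junctions, samples, counts, annotated=None):
    if annotated is None:
        annotated = [False] * len(junctions)
    return JunctionCountMatrix(
        junctions=junctions,
        samples=samples,
        counts=np.asarray(counts),
        annotated_flags=np.asarray(annotated),
    )


class TestReadStarSJ:
    def test_parses_unique_and_multi(self, tmp_path):
        p = write_sj_file(
            tmp_path / "a.tab",
            [("chr1", 201, 300, "+", 12), ("chr1", 401, 500, ".", 3)],
        )
        d = read_star_sj(p)
        assert d[("chr1", 201, 300, "+")] == (12, 0)
        assert d[("chr1", 401, 500, ".")] == (3, 0)

    def test_bad_lines_skipped(self, tmp_path):
        p = tmp_path / "bad.tab"
        p.write_text("chr1\tnotanint\t300\t1\t1\t0\t5\t0\t30\nshort\tline\n")
        assert read_star_sj(str(p)) == {}


class TestBuildJunctionMatrix:
    def test_union_with_zero_fill(self, tmp_path, three_exon_ts):
        a = write_sj_file(tmp_path / "a.tab", [
            ("chr1", 201, 300, "+", 10), ("chr1", 700, 800, "+", 4), ("chr1", 900, 950, "+", 2),
        ])
        b = write_sj_file(tmp_path / "b.tab", [
            ("chr1", 1000, 1100, "+", 7), ("chr1", 1200, 1300, "+", 1),
        ])
        m = build_junction_matrix([("s1", a), ("s2", b)], three_exon_ts)
        assert len(m.junctions) == 5
        assert m.count(("chr1", 201, 300, "+"), "s1") == 10
        assert m.count(("chr1", 201, 300, "+"), "s2") == 0
        assert m.count(("chr1", 1000, 1100, "+"), "s1") == 0
        # annotated flag from the transcript set
        flags = dict(zip(m.junctions, m.annotated_flags))
        assert flags[("chr1", 201, 300, "+")]
        assert not flags[("chr1", 700, 800, "+")]

    def test_same_file_both_samples_gives_identical_columns(self, tmp_path, three_exon_ts):
        a = write_sj_file(tmp_path / "a.tab", [("chr1", 201, 300, "+", 10)])
        m = build_junction_matrix([("s1", a), ("s2", a)], three_exon_ts)
        assert (m.sample_column("s1") == m.sample_column("s2")).all()

    def test_matrix_matches_per_file_lookup_oracle(self, tmp_path, three_exon_ts):
        rng = np.random.default_rng(11)
        files = []
        oracles = {}
        for i in range(5):
            juncs = []
            for k in range(int(rng.integers(3, 9))):
                s = int(rng.integers(1000, 5000))
                juncs.append(("chr1", s, s + int(rng.integers(50, 500)), "+",
                              int(rng.integers(1, 40))))
            # dedupe keys within a sample
            seen = {}
            for chrom, s, e, st, n in juncs:
                seen[(chrom, s, e, st)] = n
            path = write_sj_file(tmp_path / f"s{i}.tab",
                                 [(c, s, e, st, n) for (c, s, e, st), n in seen.items()])
            files.append((f"s{i}", path))
            oracles[f"s{i}"] = seen
        m = build_junction_matrix(files, three_exon_ts)
        for j in m.junctions:
            for s, _ in files:
                assert m.count(j, s) == oracles[s].get(j, 0)

    def test_duplicate_sample_fatal(self, tmp_path, three_exon_ts):
        a = write_sj_file(tmp_path / "a.tab", [("chr1", 201, 300, "+", 10)])
        with pytest.raises(ValueError, match="duplicate"):
            build_junction_matrix([("s1", a), ("s1", a)], three_exon_ts)


class TestCallNovelJunctions:
    def test_five_read_rule(self):
        # proband 5 reads, 9 controls all <= 2, unannotated -> called
        counts = np.zeros((1, 10), dtype=int)
        counts[0, 0] = 5
        counts[0, 1:] = 2
        m = make_matrix([("chr1", 10, 20, "+")], [f"s{i}" for i in range(10)], counts)
        calls = call_novel_junctions(m, "s0")
        assert len(calls) == 1
        assert calls[0].proband_count == 5 and calls[0].max_other_count == 2

    def test_below_min_reads_not_called(self):
        counts = np.array([[4, 0, 0]])
        m = make_matrix([("chr1", 10, 20, "+")], ["p", "c1", "c2"], counts)
        assert call_novel_junctions(m, "p") == []

    def test_other_sample_above_max_not_called(self):
        counts = np.array([[8, 3, 0]])
        m = make_matrix([("chr1", 10, 20, "+")], ["p", "c1", "c2"], counts)
        assert call_novel_junctions(m, "p") == []

    def test_annotated_excluded_unless_requested(self):
        counts = np.array([[8, 0, 0]])
        m = make_matrix([("chr1", 10, 20, "+")], ["p", "c1", "c2"], counts, [True])
        assert call_novel_junctions(m, "p") == []
        assert len(call_novel_junctions(m, "p", require_unannotated=False)) == 1

    def test_matches_brute_force_predicate_scan(self):
        rng = np.random.default_rng(42)
        n_j, n_s = 50, 8
        counts = rng.poisson(2.0, size=(n_j, n_s))
        counts[rng.random(size=n_j) < 0.3] += rng.integers(3, 10)
        junctions = [("chr1", 100 * i, 100 * i + 50, "+") for i in range(1, n_j + 1)]
        annotated = rng.random(n_j) < 0.4
        samples = [f"s{i}" for i in range(n_s)]
        m = make_matrix(junctions, samples, counts, annotated)
        calls = call_novel_junctions(m, "s0", min_reads=5, max_other=2)
        got = {c.junction for c in calls}
        expected = set()
        for ji, j in enumerate(junctions):  # exhaustive per-junction predicate
            if (
                counts[ji, 0] >= 5
                and all(counts[ji, si] <= 2 for si in range(1, n_s))
                and not annotated[ji]
            ):
                expected.add(j)
        assert got == expected

    def test_monotonicity_in_thresholds(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(3.0, size=(40, 6))
        junctions = [("chr1", 10 * i, 10 * i + 5, "+") for i in range(1, 41)]
        m = make_matrix(junctions, [f"s{i}" for i in range(6)], counts)
        base = len(call_novel_junctions(m, "s0", min_reads=3, max_other=3))
        assert len(call_novel_junctions(m, "s0", min_reads=5, max_other=3)) <= base
        assert len(call_novel_junctions(m, "s0", min_reads=3, max_other=1)) <= base

    def test_invariant_under_control_permutation(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(3.0, size=(30, 5))
        junctions = [("chr1", 10 * i, 10 * i + 5, "+") for i in range(1, 31)]
        samples = ["p", "c1", "c2", "c3", "c4"]
        m1 = make_matrix(junctions, samples, counts)
        perm = [0, 3, 1, 4, 2]
        m2 = make_matrix(junctions, [samples[i] for i in perm], counts[:, perm])
        c1 = {c.junction for c in call_novel_junctions(m1, "p")}
        c2 = {c.junction for c in call_novel_junctions(m2, "p")}
        assert c1 == c2

    def test_sanity_limit_all_supported_unannotated(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 10, size=(20, 4))
        junctions = [("chr1", 10 * i, 10 * i + 5, "+") for i in range(1, 21)]
        annotated = rng.random(20) < 0.5
        m = make_matrix(junctions, [f"s{i}" for i in range(4)], counts, annotated)
        calls = call_novel_junctions(m, "s0", min_reads=1, max_other=10**9)
        expected = {
            j for ji, j in enumerate(junctions)
            if counts[ji, 0] >= 1 and not annotated[ji]
        }
        assert {c.junction for c in calls} == expected

    def test_unknown_proband_fatal(self):
        m = make_matrix([("chr1", 10, 20, "+")], ["a", "b"], [[1, 1]])
        with pytest.raises(ValueError):
            call_novel_junctions(m, "zz")
        with pytest.raises(ValueError):
            call_novel_junctions(m, "a", min_reads=0)

    def test_batch_restriction(self):
        # control in another batch may exceed max_other without vetoing
        counts = np.array([[8, 0, 9]])
        m = make_matrix([("chr1", 10, 20, "+")], ["p", "c1", "c2"], counts)
        assert call_novel_junctions(m, "p") == []
        batch = {"p": "b1", "c1": "b1", "c2": "b2"}
        assert len(call_novel_junctions(m, "p", batch_map=batch)) == 1


class TestFlankingNormalJunctions:
    def _matrix(self, three_exon_ts, proband_counts):
        junctions = [("chr1", 201, 300, "+"), ("chr1", 401, 500, "+")]
        counts = np.array([[proband_counts[0], 20], [proband_counts[1], 20]])
        return make_matrix(junctions, ["p", "c"], counts, [True, True])

    def test_normal_flanks(self, three_exon_ts):
        m = self._matrix(three_exon_ts, (15, 12))
        assert flanking_normal_junctions(m, three_exon_ts,
                                         GenomicInterval("chr1", 350, 350), "p")

    def test_unsupported_flanks_unassessable(self, three_exon_ts):
        m = self._matrix(three_exon_ts, (0, 0))
        assert not flanking_normal_junctions(m, three_exon_ts,
                                             GenomicInterval("chr1", 350, 350), "p")

    def test_novel_call_in_flanking_intron(self, three_exon_ts):
        junctions = [("chr1", 201, 300, "+"), ("chr1", 401, 500, "+"),
                     ("chr1", 201, 250, "+")]
        counts = np.array([[15, 20], [12, 20], [8, 0]])
        m = make_matrix(junctions, ["p", "c"], counts, [True, True, False])
        assert not flanking_normal_junctions(m, three_exon_ts,
                                             GenomicInterval("chr1", 350, 350), "p")

    def test_locus_outside_genes_is_error(self, three_exon_ts):
        m = self._matrix(three_exon_ts, (15, 12))
        with pytest.raises(ValueError):
            flanking_normal_junctions(m, three_exon_ts,
                                      GenomicInterval("chr1", 90_000, 90_001), "p")
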