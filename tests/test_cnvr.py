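"""Per-base CNV association, region merging, uniqueness, clustering, and
IR-score representative selection."""

import math
import random

import pytest

from varlink.core import CnvRecord, GenomicInterval
from varlink.cnvr import (
    Cnvr,
    cluster_cnvrs,
    cnvr_uniqueness,
    ir_score_select,
    merge_significant_positions,
    per_base_association,
    run_peakcnv,
)
from varlink.simulate import FixtureSpec, simulate_cnvs


def cnv(sample, chrom, start, end, direction="duplication", cohort="case"):
    return CnvRecord(sample, GenomicInterval(chrom, start, end), direction, cohort)


def make_cnvr(chrom, start, end, samples, direction="duplication", min_p=0.01):
    return Cnvr(
        span=GenomicInterval(chrom, start, end),
        direction=direction,
        case_samples=frozenset(samples),
        min_p=min_p,
    )


class TestPerBaseAssociation:
    def test_uncovered_bases_have_p_one(self):
        segs = per_base_association(
            [cnv("A", "chr1", 10, 20)],
            [cnv("X", "chr1", 50, 60, cohort="control")],
            GenomicInterval("chr1", 0, 100),
            "duplication",
            n_case=10,
            n_control=10,
        )
        assert segs[0].a == 0 and segs[0].p == 1.0

    def test_extreme_coverage_table(self):
        case = [cnv(f"A{i}", "chr1", 10, 20) for i in range(10)]
        control = [cnv("X0", "chr1", 50, 60, cohort="control")]
        segs = per_base_association(
            case, control, GenomicInterval("chr1", 0, 100), "duplication",
            n_case=10, n_control=10,
        )
        covered = [s for s in segs if s.a == 10]
        assert covered[0].p == pytest.approx(1 / math.comb(20, 10), abs=1e-15)

    def test_segments_tile_region_and_track_endpoints(self):
        segs = per_base_association(
            [cnv("A", "chr1", 10, 30), cnv("B", "chr1", 20, 40)],
            [cnv("X", "chr1", 0, 5, cohort="control")],
            GenomicInterval("chr1", 0, 50),
            "duplication",
            n_case=5,
            n_control=5,
        )
        assert segs[0].start == 0 and segs[-1].end == 50
        assert all(s1.end == s2.start for s1, s2 in zip(segs, segs[1:]))
        cov = {(s.start, s.end): s.a for s in segs}
        assert cov[(20, 30)] == 2

    def test_sample_with_two_overlapping_cnvs_counts_once(self):
        case = [cnv("A", "chr1", 10, 30), cnv("A", "chr1", 20, 40)]
        control = [cnv("X", "chr1", 90, 95, cohort="control")]
        segs = per_base_association(
            case, control, GenomicInterval("chr1", 0, 100), "duplication",
            n_case=2, n_control=2,
        )
        assert max(s.a for s in segs) == 1


class TestMerging:
    def _segs_from_pattern(self, sig_ranges, region_len=30, threshold=0.05):
        from varlink.cnvr import CoverageSegment

        segs = []
        pos = 0
        points = sorted({0, region_len, *(b for r in sig_ranges for b in r)})
        for start, end in zip(points, points[1:]):
            sig = any(s <= start and end <= e for s, e in sig_ranges)
            segs.append(
                CoverageSegment(start, end, 1, 1, 0, 2, 0.01 if sig else 0.5)
            )
        return segs

    def test_no_significant_bases(self):
        segs = self._segs_from_pattern([])
        assert merge_significant_positions(segs, [], "duplication", "chr1") == []

    def test_runs_become_spans(self):
        segs = self._segs_from_pattern([(5, 15), (20, 23)])
        cnvrs = merge_significant_positions(segs, [cnv("A", "chr1", 0, 30)], "duplication", "chr1")
        assert [(c.span.start, c.span.end) for c in cnvrs] == [(5, 15), (20, 23)]
        assert all(c.case_samples == {"A"} for c in cnvrs)

    def test_whole_region_significant(self):
        segs = self._segs_from_pattern([(0, 30)])
        (c,) = merge_significant_positions(segs, [cnv("A", "chr1", 0, 30)], "duplication", "chr1")
        assert (c.span.start, c.span.end) == (0, 30)

    def test_spans_disjoint_sorted_maximal(self):
        segs = self._segs_from_pattern([(2, 6), (6, 9), (15, 20)])
        cnvrs = merge_significant_positions(segs, [cnv("A", "chr1", 0, 30)], "duplication", "chr1")
        spans = [(c.span.start, c.span.end) for c in cnvrs]
        assert spans == [(2, 9), (15, 20)]  # adjacent runs merged, sorted


class TestUniqueness:
    def test_single_cnvr(self):
        c = make_cnvr("chr1", 0, 10, {"s1", "s2", "s3", "s4", "s5"})
        cnvr_uniqueness([c])
        assert c.uniqueness == 5

    def test_worked_pair(self):
        a = make_cnvr("chr1", 0, 10, {"1", "2", "3", "4", "5"})
        b = make_cnvr("chr1", 20, 30, {"4", "5", "6"})
        cnvr_uniqueness([a, b])
        assert (a.uniqueness, b.uniqueness) == (3, 1)

    def test_identical_sets_zero(self):
        a = make_cnvr("chr1", 0, 10, {"1", "2"})
        b = make_cnvr("chr1", 20, 30, {"1", "2"})
        cnvr_uniqueness([a, b])
        assert (a.uniqueness, b.uniqueness) == (0, 0)

    def test_scoped_per_chrom_and_direction(self):
        a = make_cnvr("chr1", 0, 10, {"1", "2"})
        b = make_cnvr("chr2", 0, 10, {"1", "2"})
        c = make_cnvr("chr1", 0, 10, {"1", "2"}, direction="deletion")
        cnvr_uniqueness([a, b, c])
        assert (a.uniqueness, b.uniqueness, c.uniqueness) == (2, 2, 2)


class TestClustering:
    def test_single_cnvr_one_cluster(self):
        c = make_cnvr("chr1", 0, 10, {"1"})
        cluster_cnvrs([c])
        assert c.cluster_id >= 0

    def test_distant_cnvrs_split(self):
        a = make_cnvr("chr1", 0, 1000, {"1", "2"})
        b = make_cnvr("chr1", 100_000_000, 100_001_000, {"3"})
        cluster_cnvrs([a, b], eps=0.5)
        assert a.cluster_id != b.cluster_id

    def test_tight_group_merges(self):
        cs = [
            make_cnvr("chr1", 0, 500, {"1", "2"}),
            make_cnvr("chr1", 600, 1100, {"1", "3"}),
            make_cnvr("chr1", 1200, 1700, {"2", "3"}),
        ]
        cluster_cnvrs(cs, eps=3.0)
        assert len({c.cluster_id for c in cs}) == 1

    def test_eps_validation(self):
        with pytest.raises(ValueError):
            cluster_cnvrs([make_cnvr("chr1", 0, 10, {"1"})], eps=0.0)


class TestIrScore:
    def test_singleton(self):
        c = make_cnvr("chr1", 0, 10, set("abcdefg"))
        best = ir_score_select([c])
        assert best is c and c.ir_score == 7 and c.is_representative

    def test_worked_pair(self):
        a = make_cnvr("chr1", 0, 10, {"1", "2", "3", "4", "5"})
        b = make_cnvr("chr1", 20, 30, {"4", "5", "6"})
        best = ir_score_select([a, b])
        assert (a.ir_score, b.ir_score) == (3.0, 1.0)
        assert best is a

    def test_tie_breaks_leftmost(self):
        a = make_cnvr("chr1", 50, 60, {"1", "2", "3"})
        b = make_cnvr("chr1", 0, 10, {"1", "2", "3"})
        best = ir_score_select([a, b])
        assert a.ir_score == b.ir_score == 0.0
        assert best is b  # leftmost start


class TestEndToEnd:
    def test_planted_cnvr_recovered_exactly(self, default_spec):
        cnvs, truth = simulate_cnvs(default_spec)
        case = [c for c in cnvs if c.cohort == "case"]
        control = [c for c in cnvs if c.cohort == "control"]
        res = run_peakcnv(case, control, default_spec.chrom_sizes, n_case=30, n_control=30)
        (rep,) = res.representatives
        planted_span, planted_dir, _, _ = default_spec.planted_cnvrs[0]
        assert rep.span == planted_span
        assert rep.direction == planted_dir
        assert rep.case_samples == set(truth["planted_cnvrs"][0]["case_carriers"])
        assert rep.is_representative and rep.min_p < 0.05

    def test_identical_cohorts_give_nothing(self):
        ivs = [("chr1", 100, 200), ("chr1", 150, 300), ("chr2", 0, 50)]
        case = [cnv(f"A{i}", *iv) for i, iv in enumerate(ivs)]
        control = [cnv(f"X{i}", *iv, cohort="control") for i, iv in enumerate(ivs)]
        res = run_peakcnv(case, control, {"chr1": 1000, "chr2": 1000},
                          n_case=3, n_control=3)
        assert res.representatives == []

    def test_two_disjoint_planted_regions(self):
        spec = FixtureSpec(
            seed=3,
            planted_cnvrs=[
                (GenomicInterval("chr1", 100_000, 120_000), "deletion", 20 / 30, 1 / 30),
                (GenomicInterval("chr2", 700_000, 710_000), "duplication", 18 / 30, 0.0),
            ],
        )
        cnvs, _ = simulate_cnvs(spec)
        case = [c for c in cnvs if c.cohort == "case"]
        control = [c for c in cnvs if c.cohort == "control"]
        # controls carry nothing for the duplication; give the control cohort
        # at least one record so both cohorts are represented
        control.append(cnv("CTRL000", "chr1", 900_000, 900_100, "duplication", "control"))
        res = run_peakcnv(case, control, spec.chrom_sizes, n_case=30, n_control=30)
        spans = {(r.span.chrom, r.span.start, r.span.end) for r in res.representatives}
        assert ("chr1", 100_000, 120_000) in spans
        assert ("chr2", 700_000, 710_000) in spans

    def test_invariant_to_record_order_and_relabeling(self, default_spec):
        cnvs, _ = simulate_cnvs(default_spec)
        case = [c for c in cnvs if c.cohort == "case"]
        control = [c for c in cnvs if c.cohort == "control"]
        res1 = run_peakcnv(case, control, default_spec.chrom_sizes, n_case=30, n_control=30)
        shuffled = list(case)
        random.Random(1).shuffle(shuffled)
        relabeled = [
            CnvRecord("Z" + r.sample_id, r.span, r.direction, r.cohort) for r in shuffled
        ]
        res2 = run_peakcnv(relabeled, control, default_spec.chrom_sizes, n_case=30, n_control=30)
        key = lambda res: [(str(c.span), c.direction, len(c.case_samples), c.min_p)
                           for c in res.representatives]
        assert key(res1) == key(res2)

    def test_representatives_unique_per_cluster_and_significant(self, default_spec):
        spec = FixtureSpec(seed=5, cnv_background_per_sample=2.0)
        cnvs, _ = simulate_cnvs(spec)
        case = [c for c in cnvs if c.cohort == "case"]
        control = [c for c in cnvs if c.cohort == "control"]
        res = run_peakcnv(case, control, spec.chrom_sizes, n_case=30, n_control=30)
        clusters = [(c.direction, c.cluster_id) for c in res.representatives]
        assert len(clusters) == len(set(clusters))
        assert all(c.min_p < 0.05 for c in res.representatives)
        per_cluster = {}
        for c in res.candidates:
            per_cluster.setdefault((c.direction, c.cluster_id), []).append(c)
        for members in per_cluster.values():
            assert sum(m.is_representative for m in members) == 1
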