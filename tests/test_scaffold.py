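"""Evidence schedules, link building, greedy joining and the full scaffolder."""

import statistics

import pytest

from bactasm.assemble import Assembly, Contig
from bactasm.mapping import InsertStats
from bactasm.scaffold import (
    LinkEvidence,
    Schedule,
    build_links,
    estimate_gap,
    evidence_schedule,
    run_scaffolder,
    scaffold_iteration,
)
from bactasm.seqio import revcomp


class TestSchedule:
    def test_default_endpoints_and_length(self):
        sched = evidence_schedule()
        assert len(sched.values) == 16
        assert sched.values[0] == 90 and sched.values[-1] == 5

    def test_linear_interpolation_round_half_up(self):
        assert evidence_schedule().values[3] == 73  # 90 - 3*(85/15)

    def test_constant_schedule(self):
        assert evidence_schedule(5, 5, 2).values == (5, 5)

    def test_non_increasing(self):
        values = evidence_schedule(90, 5, 16).values
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            evidence_schedule(90, 5, 1)
        with pytest.raises(ValueError):
            evidence_schedule(5, 90, 16)
        with pytest.raises(ValueError):
            Schedule((5, 90))


class TestEstimateGap:
    def test_median(self):
        link = LinkEvidence("a", "tail", "b", "head", (100, 110, 90))
        assert estimate_gap(link) == statistics.median([100, 110, 90])

    def test_negative_floored_at_one(self):
        assert estimate_gap(LinkEvidence("a", "tail", "b", "head", (-20,))) == 1

    def test_single_estimate(self):
        assert estimate_gap(LinkEvidence("a", "tail", "b", "head", (1,))) == 1


def _links_for(count_ab, count_ac=None):
    links = [LinkEvidence("a", "tail", "b", "head", tuple([10] * count_ab))]
    if count_ac is not None:
        links.append(LinkEvidence("a", "tail", "c", "head", tuple([10] * count_ac)))
    return links


@pytest.fixture
def three_contigs():
    return Assembly(
        [Contig("a", "ACGTAC" * 20), Contig("b", "GGATCC" * 20), Contig("c", "TTGACA" * 20)]
    )


class TestScaffoldIteration:
    def test_join_above_threshold_inserts_n_gap(self, three_contigs):
        merged, joins = scaffold_iteration(three_contigs, _links_for(100), 90)
        assert merged.n_contigs == 2
        assert len(joins) == 1 and joins[0]["count"] == 100
        joined = merged.get("a").seq
        assert "N" in joined
        assert joined.replace("N", "") == three_contigs.get("a").seq + three_contigs.get("b").seq

    def test_below_threshold_unchanged(self, three_contigs):
        merged, joins = scaffold_iteration(three_contigs, _links_for(50), 90)
        assert joins == [] and merged.n_contigs == 3

    def test_ambiguity_guard_blocks_near_equal_competitors(self, three_contigs):
        # counts 95 and 80: ratio 0.84 > 0.7, so the shared end must not join
        # even though only the 95 link passes the threshold
        merged, joins = scaffold_iteration(three_contigs, _links_for(95, 80), 90)
        assert joins == [] and merged.n_contigs == 3

    def test_weak_competitor_does_not_block(self, three_contigs):
        merged, joins = scaffold_iteration(three_contigs, _links_for(95, 20), 90)
        assert len(joins) == 1 and joins[0]["contig_b"] == "b"

    def test_orientation_tail_to_tail_reverse_complements(self, three_contigs):
        links = [LinkEvidence("a", "tail", "b", "tail", tuple([5] * 95))]
        merged, joins = scaffold_iteration(three_contigs, links, 90)
        seq = merged.get("a").seq
        a, b = three_contigs.get("a").seq, three_contigs.get("b").seq
        assert seq.replace("N", "") in (a + revcomp(b), b + revcomp(a))


class TestBuildLinks:
    def test_split_pairs_aggregate_into_one_link(self, cut_genome_case):
        contigs = cut_genome_case["contigs"]
        pairs = cut_genome_case["pairs"]
        stats = InsertStats(median=500, lower=350, upper=650)
        links = build_links(pairs, contigs, stats)
        strong = {
            (l.contig_a, l.end_a, l.contig_b, l.end_b): l.count
            for l in links
            if l.count >= 5
        }
        # the two strong true junctions are present with tail->head geometry
        assert ("c1", "tail", "c2", "head") in strong
        assert ("c3", "tail", "c4", "head") in strong

    def test_no_pairs_no_links(self, three_contigs):
        stats = InsertStats(median=300, lower=250, upper=350)
        assert build_links([], three_contigs, stats) == []


class TestRunScaffolder:
    def test_joins_true_junctions_and_respects_weak_one(self, cut_genome_case):
        scaffolded = cut_genome_case["scaffolded"]
        join_log = cut_genome_case["join_log"]
        # two strong junctions joined, the 3-pair junction never
        assert scaffolded.n_contigs == 2
        joined_pairs = {
            frozenset((j["contig_a"], j["contig_b"])) for j in join_log
        }
        assert joined_pairs == {frozenset(("c1", "c2")), frozenset(("c3", "c4"))}
        assert all(j["count"] >= 5 for j in join_log)

    def test_conserves_non_n_bases_and_contig_count(self, cut_genome_case):
        before = cut_genome_case["contigs"]
        after = cut_genome_case["scaffolded"]
        non_n = lambda asm: sum(
            len(c.seq) - c.seq.count("N") for c in asm.contigs
        )
        assert non_n(after) == non_n(before)
        assert after.n_contigs <= before.n_contigs

    def test_gap_sizes_near_truth(self, cut_genome_case):
        # 60 true bases were removed at each joined junction; the estimated
        # N-gaps should be in the right ballpark (within one insert SD)
        for join in cut_genome_case["join_log"]:
            assert 1 <= join["gap"] <= 200
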