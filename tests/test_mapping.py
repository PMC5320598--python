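"""Seed index, read mapping, insert estimation and pair classification."""

import pysam
import pytest

from bactasm.assemble import Assembly, Contig
from bactasm.mapping import (
    HALF_MAPPED,
    PROPER,
    SAME_CONTIG_IMPROPER,
    SPLIT,
    UNMAPPED,
    Alignment,
    InsertStats,
    SeedIndex,
    classify_pairs,
    estimate_insert,
    map_pairs,
    map_read,
    proper_candidate_distances,
    select_improvement_reads,
    write_sam,
)
from bactasm.seqio import ReadPair, SeqRecord, revcomp
from bactasm.sim import SimSpec, simulate_genome


@pytest.fixture(scope="module")
def toy_index():
    spec = SimSpec(genome_length=2000, seed=3, error_rate=0.0)
    genome = simulate_genome(spec).seq
    contigs = [Contig("c1", genome[:1000]), Contig("c2", genome[1000:])]
    return genome, SeedIndex(contigs, seed_k=15)


class TestSeedIndex:
    def test_seed_count_for_short_contig(self):
        index = SeedIndex([Contig("c1", "ACGTACGTACGTACGTA")], seed_k=15)
        assert len(index.index) == 3  # 17 - 15 + 1

    def test_empty_contig_list_is_error(self):
        with pytest.raises(ValueError):
            SeedIndex([])

    def test_short_contig_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="shorter than seed_k"):
            index = SeedIndex([Contig("tiny", "ACGT"), Contig("ok", "ACGT" * 10)])
        assert "tiny" not in index.contigs

    def test_high_frequency_seeds_masked(self):
        index = SeedIndex([Contig("c1", "A" * 1000)], seed_k=15, max_hits=200)
        assert index.lookup("A" * 15) == []


class TestMapRead:
    def test_prefix_maps_forward(self, toy_index):
        genome, index = toy_index
        aln = map_read(index, SeqRecord("r", genome[:100]))
        assert aln.mapped and (aln.contig_id, aln.start, aln.strand) == ("c1", 0, "+")
        assert aln.mismatches == 0

    def test_reverse_complement_maps_minus(self, toy_index):
        genome, index = toy_index
        aln = map_read(index, SeqRecord("r", revcomp(genome[900:1000])))
        assert aln.mapped and aln.strand == "-" and aln.start == 900

    def test_foreign_read_unmapped(self, toy_index):
        _, index = toy_index
        aln = map_read(index, SeqRecord("r", "AC" * 50))
        assert not aln.mapped and aln.contig_id is None and aln.start is None

    def test_identity_thresholds_differ_by_mode(self, toy_index):
        genome, index = toy_index
        read = list(genome[200:300])
        for pos in (10, 30, 50, 70, 90, 95, 98):  # 7 mismatches: 93 % identity
            read[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[pos]]
        read = "".join(read)
        assert not map_read(index, SeqRecord("r", read), "strict").mapped
        assert map_read(index, SeqRecord("r", read), "lenient").mapped

    def test_deterministic(self, toy_index):
        genome, index = toy_index
        read = SeqRecord("r", genome[500:600])
        assert map_read(index, read) == map_read(index, read)


class TestInsertEstimate:
    def test_zero_spread(self):
        stats = estimate_insert([300] * 60, read_length=100)
        assert (stats.median, stats.lower, stats.upper) == (300, 300, 300)

    def test_median_of_mixture(self):
        distances = [280] * 100 + [300] * 100 + [320] * 100
        stats = estimate_insert(distances, read_length=100)
        assert stats.median == 300
        assert stats.lower >= 200 and stats.upper > 300

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="fall back"):
            estimate_insert([300] * 10, read_length=100)

    def test_lower_clipped_at_twice_read_length(self):
        distances = list(range(260, 420)) * 2  # broad spread
        stats = estimate_insert(distances, read_length=130)
        assert stats.lower >= 260


def _pair(pid):
    seq = "ACGTACGTACGTACGTACGT"
    return ReadPair(
        SeqRecord(f"{pid}/1", seq, None), SeqRecord(f"{pid}/2", seq, None), pid
    )


def _aln(pid, contig, start, end, strand):
    return Alignment(pid, contig, start, end, strand, 0, True)


class TestClassification:
    stats = InsertStats(median=300, lower=250, upper=350)

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (_aln("p/1", "c1", 0, 100, "+"), _aln("p/2", "c1", 200, 300, "-"), PROPER),
            (_aln("p/1", "c1", 0, 100, "+"), _aln("p/2", "c2", 200, 300, "-"), SPLIT),
            (_aln("p/1", "c1", 0, 100, "+"), Alignment.unmapped("p/2"), HALF_MAPPED),
            (Alignment.unmapped("p/1"), Alignment.unmapped("p/2"), UNMAPPED),
            # FF orientation on one contig
            (_aln("p/1", "c1", 0, 100, "+"), _aln("p/2", "c1", 200, 300, "+"),
             SAME_CONTIG_IMPROPER),
            # correct orientation but outer distance outside the window
            (_aln("p/1", "c1", 0, 100, "+"), _aln("p/2", "c1", 400, 500, "-"),
             SAME_CONTIG_IMPROPER),
        ],
    )
    def test_each_category(self, a, b, expected):
        [cls] = classify_pairs([(_pair("p"), a, b)], self.stats)
        assert cls.klass == expected

    def test_improvement_subset_is_complement_of_proper(self):
        pairs = [_pair(f"p{i}") for i in range(3)]
        alns = [
            (pairs[0], _aln("a", "c1", 0, 100, "+"), _aln("a", "c1", 200, 300, "-")),
            (pairs[1], _aln("b", "c1", 0, 100, "+"), _aln("b", "c2", 0, 100, "-")),
            (pairs[2], _aln("c", "c1", 0, 100, "+"), Alignment.unmapped("c")),
        ]
        classes = classify_pairs(alns, self.stats)
        selected = select_improvement_reads(pairs, classes)
        assert selected == [pairs[1], pairs[2]]
        proper = [p for p, c in zip(pairs, classes) if c.klass == PROPER]
        assert sorted(p.pair_id for p in selected + proper) == [
            p.pair_id for p in pairs
        ]  # partition: nothing lost, nothing duplicated


class TestOnSimulatedReads:
    def test_nearly_all_contained_pairs_classify_proper(self, small_sim):
        genome, pairs = small_sim["genome"], small_sim["pairs"]
        index = SeedIndex([Contig("c1", genome.seq)])
        mapped = map_pairs(index, pairs)
        stats = estimate_insert(proper_candidate_distances(mapped), 100)
        classes = classify_pairs(mapped, stats)
        frac = sum(c.klass == PROPER for c in classes) / len(classes)
        assert frac >= 0.99

    def test_sam_export_parses_with_pysam(self, small_sim, tmp_path):
        genome, pairs = small_sim["genome"], small_sim["pairs"]
        index = SeedIndex([Contig("c1", genome.seq)])
        mapped = map_pairs(index, pairs[:50])
        stats = estimate_insert(
            proper_candidate_distances(map_pairs(index, pairs)), 100
        )
        classes = classify_pairs(mapped, stats)
        sam = write_sam(tmp_path / "out.sam", index, mapped, classes)
        with pysam.AlignmentFile(str(sam), "r") as handle:
            records = list(handle)
        assert len(records) == 100  # two per pair
        for rec in records:
            assert rec.is_paired
            if not rec.is_unmapped:
                assert 0 <= rec.reference_start < len(genome.seq)
        n_proper = sum(r.is_proper_pair for r in records)
        assert n_proper >= 90  # flags reflect the classification
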