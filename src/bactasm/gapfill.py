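"""Iterative closure of scaffold N-gaps by local consensus extension.

Each N run left by the scaffolder is targeted for closure: read pairs with
one mate anchored within insert range of a gap flank donate their other mate
as local evidence, and the flanks are extended into the gap one base at a
time by majority consensus, only while the per-base depth stays above the
iteration's threshold.  Like the scaffolder, the depth requirement starts at
90 reads and decreases linearly over the iterations (120 by default), so
well-supported gaps close early and poorly covered ones only close once the
evidence bar has dropped.  Iterations alternate between a strict and a
lenient read-recruitment stringency, because the two dislodge different
stuck gaps.  A gap is declared closed when the two extensions meet on a
sufficiently long exact overlap; otherwise the N run shrinks by however much
was extended.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .assemble import Assembly, Contig
from .mapping import (
    Alignment,
    InsertStats,
    MODE_IDENTITY,
    SeedIndex,
    classify_pairs,
    estimate_insert,
    map_pairs,
    proper_candidate_distances,
    select_improvement_reads,
)
from .scaffold import Schedule, linear_schedule, replace_stage
from .seqio import ReadPair, revcomp

__all__ = [
    "Gap",
    "find_gaps",
    "depth_schedule",
    "fill_gap",
    "run_gapfiller",
    "CLOSED",
    "REDUCED",
    "UNCHANGED",
]

CLOSED = "closed"
REDUCED = "reduced"
UNCHANGED = "unchanged"


@dataclass(frozen=True)
class Gap:
    """A maximal run of Ns: ``seq[start:end]`` is all N, the neighbours are not."""

    contig_id: str
    start: int  # 0-based inclusive offset of the first N
    end: int  # exclusive offset past the last N

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("need 0 <= start < end")

    @property
    def length(self) -> int:
        return self.end - self.start


def find_gaps(assembly: Assembly) -> list[Gap]:
    """All maximal N runs in the assembly, sorted by (contig id, start)."""
    gaps: list[Gap] = []
    for contig in assembly.contigs:
        seq = contig.seq
        i = 0
        n = len(seq)
        while i < n:
            if seq[i] == "N":
                j = i
                while j < n and seq[j] == "N":
                    j += 1
                gaps.append(Gap(contig.id, i, j))
                i = j
            else:
                i += 1
    gaps.sort(key=lambda g: (g.contig_id, g.start))
    return gaps


def depth_schedule(start: int = 90, end: int = 5, n_iterations: int = 120) -> Schedule:
    """The gap filler's descending depth schedule (90 down to 5 over 120).

    Same linear round-half-up contract as the scaffolder's evidence schedule;
    the floor of 5 mirrors the scaffolder's final threshold.
    """
    return linear_schedule(start, end, n_iterations)


def _recruit(
    gap: Gap,
    mapped: Sequence[tuple[ReadPair, Alignment, Alignment]],
    insert_stats: InsertStats,
) -> list[str]:
    """Genome-forward sequences of mates whose anchor points into the gap.

    An anchor on the + strand left of the gap (within the insert window of
    the left flank) implies its mate lies to the right on the - strand, so
    the mate is recruited reverse-complemented; symmetrically for - strand
    anchors right of the gap.
    """
    reach = insert_stats.upper
    recruited: list[str] = []
    for pair, a, b in mapped:
        for anchor, mate in ((a, pair.rev), (b, pair.fwd)):
            if not anchor.mapped or anchor.contig_id != gap.contig_id:
                continue
            if (
                anchor.strand == "+"
                and anchor.end <= gap.start
                and gap.start - anchor.start <= reach
            ):
                recruited.append(revcomp(mate.seq))
            elif (
                anchor.strand == "-"
                and anchor.start >= gap.end
                and anchor.end - gap.end <= reach
            ):
                recruited.append(mate.seq)
    return recruited


def _extend(
    flank: str,
    reads: Sequence[str],
    depth_threshold: int,
    min_identity: float,
    majority: float,
    seed_k: int,
    max_extension: int,
) -> tuple[str, int]:
    """Grow ``flank`` rightward by per-base majority consensus.

    At every step each read is anchored by an exact occurrence of the current
    flank tail seed; reads whose overlap with the flank meets the identity
    threshold vote with their next base.  Extension continues while the vote
    depth is at least ``depth_threshold`` and the winning base carries at
    least the ``majority`` fraction.  Returns (bases added, depth at the
    stall point).
    """
    grown = flank
    added: list[str] = []
    stall_depth = 0
    while len(added) < max_extension:
        if len(grown) < seed_k:
            break
        probe = grown[-seed_k:]
        votes: Counter = Counter()
        for read in reads:
            idx = read.find(probe)
            if idx < 0:
                continue
            overlap = idx + seed_k
            if overlap > len(grown) or overlap >= len(read):
                continue
            a = grown[-overlap:]
            b = read[:overlap]
            if a != b:
                mm = sum(1 for x, y in zip(a, b) if x != y)
                if (overlap - mm) / overlap < min_identity:
                    continue
            votes[read[overlap]] += 1
        depth = sum(votes.values())
        stall_depth = depth
        if depth < depth_threshold:
            break
        base, top = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
        if top / depth < majority:
            break
        grown += base
        added.append(base)
    return "".join(added), stall_depth


def _find_closure(a: str, b: str, min_overlap: int, window: int) -> int:
    """Largest exact overlap (>= min_overlap) between a suffix of a and a prefix of b."""
    if len(a) < min_overlap or len(b) < min_overlap:
        return 0
    probe = b[:min_overlap]
    tail_start = max(0, len(a) - window)
    tail = a[tail_start:]
    best = 0
    idx = tail.find(probe)
    while idx >= 0:
        overlap = len(a) - (tail_start + idx)
        if overlap <= len(b) and a[-overlap:] == b[:overlap]:
            best = max(best, overlap)
        idx = tail.find(probe, idx + 1)
    return best


def fill_gap(
    assembly: Assembly,
    gap: Gap,
    pairs: Sequence[ReadPair],
    insert_stats: InsertStats,
    depth_threshold: int,
    mode: str = "strict",
    seed_k: int = 15,
    majority: float = 0.8,
    read_length: int = 130,
    mapped: Optional[Sequence[tuple[ReadPair, Alignment, Alignment]]] = None,
) -> tuple[Assembly, str]:
    """Attempt one gap at one depth threshold; returns (assembly, status).

    Status is ``closed`` when the two flank extensions meet on an exact
    overlap of at least ``2*seed_k`` bases (which also catches scaffolds
    whose pieces already overlap, i.e. negative true gaps), ``reduced`` when
    sequence was added but the ends did not meet, else ``unchanged``.
    """
    contig = assembly.get(gap.contig_id)
    if set(contig.seq[gap.start : gap.end]) != {"N"}:
        raise ValueError(f"gap coordinates {gap} do not cover an N run")
    if mapped is None:
        index = SeedIndex(assembly, seed_k=seed_k)
        mapped = map_pairs(index, pairs, mode)
    reads_fwd = _recruit(gap, mapped, insert_stats)
    left = contig.seq[: gap.start]
    right = contig.seq[gap.end :]
    min_identity = MODE_IDENTITY[mode]
    max_ext = gap.length + 2 * read_length

    ext_left = ""
    if reads_fwd and left and "N" not in left[-seed_k:]:
        ext_left, _ = _extend(
            left[-(2 * read_length + seed_k):],
            reads_fwd,
            depth_threshold,
            min_identity,
            majority,
            seed_k,
            max_ext,
        )
    ext_right = ""
    if reads_fwd and right and "N" not in right[:seed_k]:
        reads_rc = [revcomp(r) for r in reads_fwd]
        grown, _ = _extend(
            revcomp(right[: 2 * read_length + seed_k]),
            reads_rc,
            depth_threshold,
            min_identity,
            majority,
            seed_k,
            max_ext,
        )
        ext_right = revcomp(grown)

    a_seq = left + ext_left
    b_seq = ext_right + right
    min_overlap = 2 * seed_k
    window = len(ext_left) + len(ext_right) + min_overlap + 2 * read_length
    overlap = _find_closure(a_seq, b_seq, min_overlap, window)
    if overlap:
        new_seq = a_seq + b_seq[overlap:]
        status = CLOSED
    elif ext_left or ext_right:
        remaining = max(gap.length - len(ext_left) - len(ext_right), 1)
        new_seq = a_seq + "N" * remaining + b_seq
        status = REDUCED
    else:
        return assembly, UNCHANGED

    new_contigs = [
        Contig(c.id, new_seq) if c.id == gap.contig_id else c
        for c in assembly.contigs
    ]
    return (
        Assembly(new_contigs, k=assembly.k, stage=assembly.stage, accession=assembly.accession),
        status,
    )


def run_gapfiller(
    assembly: Assembly,
    pairs: Sequence[ReadPair],
    schedule: Optional[Schedule] = None,
    insert_fallback: Optional[InsertStats] = None,
    seed_k: int = 15,
    majority: float = 0.8,
    min_insert_observations: int = 50,
) -> tuple[Assembly, list[dict]]:
    """The full iterative gap-closure loop.

    Even iterations recruit in strict mode, odd in lenient.  The improvement
    subset is selected once against the input scaffolds (proper pairs cannot
    help inside a gap: their fragment is fully accounted for), then re-mapped
    against the current assembly whenever a fill changes it.  Stops early
    when no gaps remain; the total N count never increases.
    """
    if schedule is None:
        schedule = depth_schedule()
    if not assembly.contigs:
        return replace_stage(assembly, "gapfilled"), []
    read_length = max((len(p.fwd.seq) for p in pairs), default=130)
    index = SeedIndex(assembly, seed_k=seed_k)
    mapped_all = map_pairs(index, pairs, "strict")
    try:
        insert_stats = estimate_insert(
            proper_candidate_distances(mapped_all),
            read_length,
            min_observations=min_insert_observations,
        )
    except ValueError:
        if insert_fallback is None:
            raise
        insert_stats = insert_fallback
    classes = classify_pairs(mapped_all, insert_stats)
    # A proper pair whose alignment crosses an N run was not fully used by the
    # assembler: a short gap costs too few mismatches to unmap a read, yet the
    # pair is exactly the evidence needed to fill that gap.  Keep such pairs
    # in the improvement subset alongside the non-proper ones.
    improvement: list[ReadPair] = []
    for (pair, a, b), cls in zip(mapped_all, classes):
        keep = cls.klass != "proper"
        if not keep:
            for aln in (a, b):
                if aln.mapped and "N" in index.contigs[aln.contig_id][aln.start : aln.end]:
                    keep = True
                    break
        if keep:
            improvement.append(pair)

    current = assembly
    log: list[dict] = []
    cache: dict[str, list] = {}  # mode -> improvement-pair alignments
    for iteration, threshold in enumerate(schedule.values):
        gaps = find_gaps(current)
        if not gaps:
            break
        mode = "strict" if iteration % 2 == 0 else "lenient"
        if mode not in cache:
            idx = SeedIndex(current, seed_k=seed_k)
            cache[mode] = map_pairs(idx, improvement, mode)
        mapped = cache[mode]
        changed = False
        # right-to-left within each contig so earlier gap coordinates stay valid
        for gap in sorted(gaps, key=lambda g: (g.contig_id, -g.start)):
            current_after, status = fill_gap(
                current,
                gap,
                improvement,
                insert_stats,
                threshold,
                mode=mode,
                seed_k=seed_k,
                majority=majority,
                read_length=read_length,
                mapped=mapped,
            )
            log.append(
                {
                    "iteration": iteration,
                    "mode": mode,
                    "threshold": threshold,
                    "contig": gap.contig_id,
                    "start": gap.start,
                    "end": gap.end,
                    "status": status,
                }
            )
            if status != UNCHANGED:
                current = current_after
                changed = True
        if changed:
            cache.clear()
    return replace_stage(current, "gapfilled"), log
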