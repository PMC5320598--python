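"""Iterative read-pair scaffolding with a descending evidence schedule.

Split pairs (two ends on two different contigs) are evidence that the
contigs are adjacent in the genome.  Greedy scaffolders joined on weak
evidence make false joins, so joining is done over several iterations with a
decreasing required pair count: on the first iteration a minimum of 90 pairs
must link two contigs, falling linearly to 5 pairs by the 16th.  Contigs
with strong evidence are therefore committed early, and weakly supported
joins only happen once the well-supported neighbourhood is already in place.
Joined contigs are concatenated around a run of Ns whose length is the
median per-pair gap estimate (floored at one N).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .assemble import Assembly, Contig
from .mapping import (
    InsertStats,
    SeedIndex,
    classify_pairs,
    estimate_insert,
    map_pairs,
    proper_candidate_distances,
    select_improvement_reads,
)
from .seqio import ReadPair, revcomp

__all__ = [
    "LinkEvidence",
    "Schedule",
    "evidence_schedule",
    "linear_schedule",
    "build_links",
    "scaffold_iteration",
    "estimate_gap",
    "run_scaffolder",
]

HEAD = "head"
TAIL = "tail"


@dataclass(frozen=True)
class LinkEvidence:
    """Aggregated pairing evidence between two contig ends.

    Stored in canonical orientation: the lexicographically smaller
    (contig, end) first.  ``gap_estimates`` holds one implied gap size per
    supporting pair; negative values mean the contigs appear to overlap.
    """

    contig_a: str
    end_a: str
    contig_b: str
    end_b: str
    gap_estimates: tuple[int, ...]

    def __post_init__(self) -> None:
        if (self.contig_a, self.end_a) == (self.contig_b, self.end_b):
            raise ValueError("a link must connect two distinct contig ends")
        if not self.gap_estimates:
            raise ValueError("a link needs at least one supporting pair")

    @property
    def count(self) -> int:
        return len(self.gap_estimates)

    @property
    def ends(self) -> tuple[tuple[str, str], tuple[str, str]]:
        return (self.contig_a, self.end_a), (self.contig_b, self.end_b)


@dataclass(frozen=True)
class Schedule:
    """A non-increasing sequence of positive integer evidence thresholds."""

    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("schedule must have at least one value")
        if any(v < 1 for v in self.values):
            raise ValueError("thresholds must be positive")
        if any(a < b for a, b in zip(self.values, self.values[1:])):
            raise ValueError("schedule must be non-increasing")


def _round_half_up(x: float) -> int:
    import math

    return math.floor(x + 0.5)


def linear_schedule(start: int, end: int, n_iterations: int) -> Schedule:
    """Linear interpolation from start to end with round-half-up, endpoints pinned."""
    if start < end or end < 1:
        raise ValueError("need start >= end >= 1")
    if n_iterations < 2:
        if n_iterations == 1 and start == end:
            return Schedule((start,))
        raise ValueError("need n_iterations >= 2 when start != end")
    step = (start - end) / (n_iterations - 1)
    values = tuple(_round_half_up(start - i * step) for i in range(n_iterations))
    return Schedule(values)


def evidence_schedule(
    start: int = 90, end: int = 5, n_iterations: int = 16
) -> Schedule:
    """The scaffolder's default descending pair-count schedule (90 to 5 over 16)."""
    return linear_schedule(start, end, n_iterations)


def build_links(
    pairs: Sequence[ReadPair],
    assembly: Assembly,
    insert_stats: InsertStats,
    mode: str = "strict",
    seed_k: int = 15,
    max_hits: int = 200,
    index: Optional[SeedIndex] = None,
) -> list[LinkEvidence]:
    """Aggregate split-pair evidence into contig-end links.

    Each split pair whose two reads sit within the insert window of their
    contig ends (a read on the + strand points off the tail, on the - strand
    off the head) contributes one count and one gap estimate
    ``median_insert - dist_to_end_a - dist_to_end_b``.  Pairs whose reads sit
    too deep inside a contig to plausibly reach across a junction are
    discarded.
    """
    if index is None:
        index = SeedIndex(assembly, seed_k=seed_k, max_hits=max_hits)
    links: dict[tuple, list[int]] = {}
    for pair, a, b in map_pairs(index, pairs, mode):
        if not (a.mapped and b.mapped) or a.contig_id == b.contig_id:
            continue
        sides = []
        reachable = True
        for aln in (a, b):
            contig_len = len(index.contigs[aln.contig_id])
            if aln.strand == "+":
                end, dist = TAIL, contig_len - aln.start
            else:
                end, dist = HEAD, aln.end
            if dist > insert_stats.upper:
                reachable = False
                break
            sides.append((aln.contig_id, end, dist))
        if not reachable:
            continue
        (ca, ea, da), (cb, eb, db) = sides
        gap = int(round(insert_stats.median - da - db))
        if (ca, ea) > (cb, eb):
            (ca, ea), (cb, eb) = (cb, eb), (ca, ea)
        links.setdefault((ca, ea, cb, eb), []).append(gap)
    return [
        LinkEvidence(ca, ea, cb, eb, tuple(gaps))
        for (ca, ea, cb, eb), gaps in sorted(links.items())
    ]


def estimate_gap(link: LinkEvidence) -> int:
    """Median of the per-pair gap estimates, floored at one N.

    Negative medians (apparently overlapping contigs) still produce a single
    N: resolving the overlap is the gap filler's job, not the scaffolder's.
    """
    estimates = sorted(link.gap_estimates)
    n = len(estimates)
    if n % 2 == 1:
        median = float(estimates[n // 2])
    else:
        median = (estimates[n // 2 - 1] + estimates[n // 2]) / 2.0
    return max(1, _round_half_up(median))


def _blocked(
    link: LinkEvidence,
    end: tuple[str, str],
    end_map: dict[tuple[str, str], list[LinkEvidence]],
    ratio: float,
) -> bool:
    # Competing near-equal links at one end indicate a repeat; joining either
    # would be a coin flip, so the end is left alone this iteration.
    for other in end_map.get(end, ()):
        if other is link:
            continue
        if other.count >= ratio * link.count:
            return True
    return False


def scaffold_iteration(
    assembly: Assembly,
    links: Sequence[LinkEvidence],
    threshold: int,
    ambiguity_ratio: float = 0.7,
) -> tuple[Assembly, list[dict]]:
    """One greedy joining pass at a single evidence threshold.

    Links with ``count >= threshold`` are applied in descending count order;
    each contig end joins at most once per iteration, and an end with a
    competing link within ``ambiguity_ratio`` of the best is skipped.  Chains
    of accepted joins are merged into single contigs (reverse-complementing
    as the end labels require) with N-gaps between the pieces; a join that
    would close a circle is skipped.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    end_map: dict[tuple[str, str], list[LinkEvidence]] = {}
    for link in links:
        for end in link.ends:
            end_map.setdefault(end, []).append(link)

    passing = sorted(
        (l for l in links if l.count >= threshold),
        key=lambda l: (-l.count, l.contig_a, l.end_a, l.contig_b, l.end_b),
    )
    used_ends: set[tuple[str, str]] = set()
    parent: dict[str, str] = {c.id: c.id for c in assembly.contigs}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    accepted: list[LinkEvidence] = []
    for link in passing:
        end_a, end_b = link.ends
        if end_a in used_ends or end_b in used_ends:
            continue
        if _blocked(link, end_a, end_map, ambiguity_ratio) or _blocked(
            link, end_b, end_map, ambiguity_ratio
        ):
            continue
        if find(link.contig_a) == find(link.contig_b):
            continue  # would close a circular scaffold
        parent[find(link.contig_a)] = find(link.contig_b)
        used_ends.update((end_a, end_b))
        accepted.append(link)

    if not accepted:
        return assembly, []

    by_end: dict[tuple[str, str], LinkEvidence] = {}
    for link in accepted:
        for end in link.ends:
            by_end[end] = link
    contig_by_id = {c.id: c for c in assembly.contigs}
    joined_ids = {l.contig_a for l in accepted} | {l.contig_b for l in accepted}

    def other_side(link: LinkEvidence, contig: str) -> tuple[str, str]:
        (ca, ea), (cb, eb) = link.ends
        return (cb, eb) if ca == contig else (ca, ea)

    def my_end(link: LinkEvidence, contig: str) -> str:
        (ca, ea), (cb, eb) = link.ends
        return ea if ca == contig else eb

    new_contigs: list[Contig] = []
    visited: set[str] = set()
    joins: list[dict] = []
    for contig in assembly.contigs:
        if contig.id in visited:
            continue
        if contig.id not in joined_ids:
            new_contigs.append(contig)
            visited.add(contig.id)
            continue
        # walk to this chain's far end in the 'head' direction, then emit
        # the chain left-to-right starting there
        start_id = contig.id
        prev_end = HEAD
        seen = {start_id}
        while (start_id, prev_end) in by_end:
            link = by_end[(start_id, prev_end)]
            nxt, nxt_end = other_side(link, start_id)
            if nxt in seen:
                break
            start_id, seen_end = nxt, nxt_end
            prev_end = HEAD if seen_end == TAIL else TAIL
            seen.add(start_id)

        # prev_end is the free (left-facing) end of the chain's first contig
        pieces: list[str] = []
        cur_id = start_id
        incoming_end = prev_end  # the end facing left/outward
        while True:
            visited.add(cur_id)
            seq = contig_by_id[cur_id].seq
            if incoming_end == TAIL:
                seq = revcomp(seq)
            outgoing_end = TAIL if incoming_end == HEAD else HEAD
            pieces.append(seq)
            link = by_end.get((cur_id, outgoing_end))
            if link is None:
                break
            nxt_id, nxt_end = other_side(link, cur_id)
            if nxt_id in visited:
                break
            gap = estimate_gap(link)
            joins.append(
                {
                    "contig_a": cur_id,
                    "end_a": outgoing_end,
                    "contig_b": nxt_id,
                    "end_b": nxt_end,
                    "count": link.count,
                    "gap": gap,
                }
            )
            pieces.append("N" * gap)
            cur_id = nxt_id
            incoming_end = nxt_end
        new_contigs.append(Contig(contig.id, "".join(pieces)))
    merged = Assembly(
        new_contigs, k=assembly.k, stage=assembly.stage, accession=assembly.accession
    )
    return merged, joins


def run_scaffolder(
    assembly: Assembly,
    pairs: Sequence[ReadPair],
    schedule: Optional[Schedule] = None,
    insert_fallback: Optional[InsertStats] = None,
    seed_k: int = 15,
    max_hits: int = 200,
    ambiguity_ratio: float = 0.7,
    min_insert_observations: int = 50,
) -> tuple[Assembly, list[dict]]:
    """The full iterative scaffolding loop.

    Maps all pairs once against the input assembly to estimate the insert
    model and select the improvement subset (everything not proper), then for
    each threshold of the descending schedule rebuilds the link graph against
    the *current* contigs and applies one greedy joining pass.  Returns the
    scaffolded assembly and a join log (iteration, threshold, ends, count,
    gap).  Joins only concatenate, so non-N sequence is conserved and the
    contig count never increases.
    """
    if schedule is None:
        schedule = evidence_schedule()
    if not assembly.contigs:
        return replace_stage(assembly, "scaffolded"), []
    index = SeedIndex(assembly, seed_k=seed_k, max_hits=max_hits)
    mapped = map_pairs(index, pairs, "strict")
    read_length = _median_read_length(pairs)
    try:
        insert_stats = estimate_insert(
            proper_candidate_distances(mapped),
            read_length,
            min_observations=min_insert_observations,
        )
    except ValueError:
        if insert_fallback is None:
            raise
        insert_stats = insert_fallback
    classes = classify_pairs(mapped, insert_stats)
    improvement = select_improvement_reads(list(pairs), classes)

    current = assembly
    log: list[dict] = []
    for iteration, threshold in enumerate(schedule.values):
        if current.n_contigs < 2:
            break
        links = build_links(
            improvement,
            current,
            insert_stats,
            mode="strict",
            seed_k=seed_k,
            max_hits=max_hits,
        )
        current, joins = scaffold_iteration(
            current, links, threshold, ambiguity_ratio=ambiguity_ratio
        )
        for join in joins:
            join["iteration"] = iteration
            join["threshold"] = threshold
            log.append(join)
    return replace_stage(current, "scaffolded"), log


def replace_stage(assembly: Assembly, stage: str) -> Assembly:
    return Assembly(
        list(assembly.contigs), k=assembly.k, stage=stage, accession=assembly.accession
    )


def _median_read_length(pairs: Sequence[ReadPair]) -> int:
    lengths = sorted(len(p.fwd.seq) for p in pairs) or [130]
    return lengths[len(lengths) // 2]
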