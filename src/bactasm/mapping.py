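"""Seed-and-extend read mapping, proper-pair classification and read subsetting.

A proper pair is a pair of reads from one DNA fragment that aligns to a
single contig, in FR (innie) orientation, with an outer distance inside the
empirical insert-size window.  Proper pairs were already used by the
assembler, so the improvement stages work only on the remaining pairs:
unmapped, half-mapped or split across contigs.

The mapper is a deterministic exact-seed, ungapped-extension aligner with two
stringencies: ``strict`` requires 95 % identity over the read, ``lenient``
90 %.  The two modes stand in for the two different aligners the gap-filling
stage alternates between - two recruitment stringencies dislodge different
stuck gaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .assemble import Assembly, Contig
from .seqio import ReadPair, SeqRecord, revcomp

__all__ = [
    "Alignment",
    "InsertStats",
    "PairClass",
    "SeedIndex",
    "index_contigs",
    "map_read",
    "map_pairs",
    "estimate_insert",
    "proper_candidate_distances",
    "classify_pairs",
    "select_improvement_reads",
    "write_sam",
    "MODE_IDENTITY",
    "PROPER",
    "SAME_CONTIG_IMPROPER",
    "SPLIT",
    "HALF_MAPPED",
    "UNMAPPED",
]

MODE_IDENTITY = {"strict": 0.95, "lenient": 0.90}

PROPER = "proper"
SAME_CONTIG_IMPROPER = "same_contig_improper"
SPLIT = "split"
HALF_MAPPED = "half_mapped"
UNMAPPED = "unmapped"


@dataclass(frozen=True)
class Alignment:
    """Where a read landed.  Unmapped alignments carry no coordinates."""

    read_id: str
    contig_id: Optional[str]
    start: Optional[int]  # 0-based inclusive
    end: Optional[int]  # exclusive
    strand: Optional[str]  # '+' or '-'
    mismatches: Optional[int]
    mapped: bool

    @classmethod
    def unmapped(cls, read_id: str) -> "Alignment":
        return cls(read_id, None, None, None, None, None, False)


@dataclass(frozen=True)
class InsertStats:
    """Empirical insert-size model: median with an acceptance window."""

    median: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 < self.lower <= self.median <= self.upper):
            raise ValueError(
                f"need 0 < lower <= median <= upper, got "
                f"({self.lower}, {self.median}, {self.upper})"
            )


@dataclass(frozen=True)
class PairClass:
    pair_id: str
    klass: str


class SeedIndex:
    """Exact-match lookup from seed to (contig, offset) on the forward strand.

    Seeds occurring more than ``max_hits`` times are masked: they sit in
    repeats or low-complexity sequence and would only produce ambiguous,
    expensive candidate lists.
    """

    def __init__(
        self,
        contigs: Union[Assembly, Sequence[Contig]],
        seed_k: int = 15,
        max_hits: int = 200,
    ) -> None:
        if seed_k % 2 == 0:
            raise ValueError("seed_k must be odd")
        contig_list = contigs.contigs if isinstance(contigs, Assembly) else list(contigs)
        if not contig_list:
            raise ValueError("cannot index an empty contig list")
        self.seed_k = seed_k
        self.max_hits = max_hits
        self.contigs: dict[str, str] = {}
        index: dict[str, list[tuple[str, int]]] = {}
        for contig in contig_list:
            if len(contig.seq) < seed_k:
                warnings.warn(
                    f"contig {contig.id!r} shorter than seed_k={seed_k}; skipped "
                    "from the seed index",
                    stacklevel=2,
                )
                continue
            self.contigs[contig.id] = contig.seq
            seq = contig.seq
            for pos in range(len(seq) - seed_k + 1):
                seed = seq[pos : pos + seed_k]
                if "N" in seed:
                    continue
                index.setdefault(seed, []).append((contig.id, pos))
        self.index = {
            seed: hits for seed, hits in index.items() if len(hits) <= max_hits
        }

    def lookup(self, seed: str) -> list[tuple[str, int]]:
        return self.index.get(seed, [])


def index_contigs(
    contigs: Union[Assembly, Sequence[Contig]],
    seed_k: int = 15,
    max_hits: int = 200,
) -> SeedIndex:
    return SeedIndex(contigs, seed_k=seed_k, max_hits=max_hits)


def _mismatches(a: str, b: str) -> int:
    if a == b:
        return 0
    return sum(1 for x, y in zip(a, b) if x != y)


def map_read(
    index: SeedIndex,
    read: Union[SeqRecord, str],
    mode: str = "strict",
) -> Alignment:
    """Best ungapped placement of a read against the indexed contigs.

    Both read orientations are tried; candidate placements come from exact
    seed hits sampled along the read.  The candidate with the fewest
    mismatches wins, ties resolved by lowest (contig id, start, strand), and
    the read is reported mapped only if its full-length identity reaches the
    mode's threshold.  Fully deterministic.
    """
    threshold = MODE_IDENTITY[mode]
    read_id = read.id if isinstance(read, SeqRecord) else "read"
    seq = read.seq if isinstance(read, SeqRecord) else read
    k = index.seed_k
    length = len(seq)
    if length < k:
        return Alignment.unmapped(read_id)
    offsets = list(range(0, length - k + 1, k))
    if offsets[-1] != length - k:
        offsets.append(length - k)

    best: Optional[tuple[int, str, int, str]] = None  # (mm, contig, start, strand)
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        candidates: set[tuple[str, int]] = set()
        for off in offsets:
            for contig_id, pos in index.lookup(oriented[off : off + k]):
                candidates.add((contig_id, pos - off))
        for contig_id, start in candidates:
            contig_seq = index.contigs[contig_id]
            if start < 0 or start + length > len(contig_seq):
                continue
            mm = _mismatches(contig_seq[start : start + length], oriented)
            cand = (mm, contig_id, start, strand)
            if best is None or cand < best:
                best = cand
    if best is None:
        return Alignment.unmapped(read_id)
    mm, contig_id, start, strand = best
    if (length - mm) / length < threshold:
        return Alignment.unmapped(read_id)
    return Alignment(read_id, contig_id, start, start + length, strand, mm, True)


def map_pairs(
    index: SeedIndex, pairs: Iterable[ReadPair], mode: str = "strict"
) -> list[tuple[ReadPair, Alignment, Alignment]]:
    """Map both ends of every pair; convenience wrapper used by all stages."""
    return [
        (pair, map_read(index, pair.fwd, mode), map_read(index, pair.rev, mode))
        for pair in pairs
    ]


def proper_candidate_distances(
    mapped: Iterable[tuple[ReadPair, Alignment, Alignment]]
) -> list[int]:
    """Outer distances of same-contig FR pairs, the input to insert estimation."""
    distances = []
    for _, a, b in mapped:
        if not (a.mapped and b.mapped) or a.contig_id != b.contig_id:
            continue
        if a.strand == b.strand:
            continue
        plus, minus = (a, b) if a.strand == "+" else (b, a)
        if plus.start <= minus.start:
            distances.append(minus.end - plus.start)
    return distances


def estimate_insert(
    distances: Sequence[int], read_length: int, min_observations: int = 50
) -> InsertStats:
    """Robust insert-size model from same-contig FR distances.

    The window is median +/- 3 scaled MADs (MAD * 1.4826 approximates one
    standard deviation for normal data), with the lower bound clipped so a
    "proper" fragment is never shorter than two read lengths.
    """
    if len(distances) < min_observations:
        raise ValueError(
            f"only {len(distances)} same-contig FR pairs (need "
            f">= {min_observations}); fall back to configured insert bounds"
        )
    arr = np.asarray(distances, dtype=float)
    median = float(np.median(arr))
    mad = float(np.median(np.abs(arr - median)))
    spread = 3.0 * 1.4826 * mad
    lower = min(max(median - spread, 2.0 * read_length), median)
    upper = median + spread
    return InsertStats(median=median, lower=lower, upper=upper)


def classify_pairs(
    mapped: Iterable[tuple[ReadPair, Alignment, Alignment]],
    insert_stats: InsertStats,
) -> list[PairClass]:
    """Assign each pair to exactly one of the five pair categories."""
    out: list[PairClass] = []
    for pair, a, b in mapped:
        if not a.mapped and not b.mapped:
            klass = UNMAPPED
        elif a.mapped != b.mapped:
            klass = HALF_MAPPED
        elif a.contig_id != b.contig_id:
            klass = SPLIT
        else:
            klass = SAME_CONTIG_IMPROPER
            if a.strand != b.strand:
                plus, minus = (a, b) if a.strand == "+" else (b, a)
                if plus.start <= minus.start:
                    distance = minus.end - plus.start
                    if insert_stats.lower <= distance <= insert_stats.upper:
                        klass = PROPER
        out.append(PairClass(pair.pair_id, klass))
    return out


def select_improvement_reads(
    pairs: Sequence[ReadPair], classes: Sequence[PairClass]
) -> list[ReadPair]:
    """The pairs fed to scaffolding and gap filling: everything not proper.

    Proper pairs were already used successfully by the assembler, so dropping
    them loses no information and makes the improvement stages fast.
    """
    if len(pairs) != len(classes):
        raise ValueError("classes must cover all pairs")
    return [pair for pair, cls in zip(pairs, classes) if cls.klass != PROPER]


def write_sam(
    path: Union[str, Path],
    index: SeedIndex,
    mapped: Iterable[tuple[ReadPair, Alignment, Alignment]],
    classes: Optional[Sequence[PairClass]] = None,
) -> Path:
    """Export pair alignments as minimal SAM for inspection with samtools.

    Only the columns the debugging use-case needs are filled: FLAG carries
    paired/proper/strand/mate bits, CIGAR is full-length M for mapped reads,
    and NM holds the mismatch count.
    """
    path = Path(path)
    mapped = list(mapped)
    class_by_pair = (
        {c.pair_id: c.klass for c in classes} if classes is not None else {}
    )
    with open(path, "w") as handle:
        handle.write("@HD\tVN:1.6\tSO:unknown\n")
        for contig_id, seq in index.contigs.items():
            handle.write(f"@SQ\tSN:{contig_id}\tLN:{len(seq)}\n")
        for pair, a, b in mapped:
            proper = class_by_pair.get(pair.pair_id) == PROPER
            for read, aln, mate_aln, first in (
                (pair.fwd, a, b, True),
                (pair.rev, b, a, False),
            ):
                flag = 0x1 | (0x40 if first else 0x80)
                if proper:
                    flag |= 0x2
                if not aln.mapped:
                    flag |= 0x4
                if not mate_aln.mapped:
                    flag |= 0x8
                if aln.mapped and aln.strand == "-":
                    flag |= 0x10
                if mate_aln.mapped and mate_aln.strand == "-":
                    flag |= 0x20
                if aln.mapped:
                    rname = aln.contig_id
                    pos = aln.start + 1
                    cigar = f"{len(read.seq)}M"
                    seq_out = (
                        read.seq if aln.strand == "+" else revcomp(read.seq)
                    )
                    tags = f"\tNM:i:{aln.mismatches}"
                else:
                    rname, pos, cigar, seq_out, tags = "*", 0, "*", read.seq, ""
                rnext = (
                    "="
                    if (aln.mapped and mate_aln.mapped and aln.contig_id == mate_aln.contig_id)
                    else (mate_aln.contig_id if mate_aln.mapped else "*")
                )
                pnext = mate_aln.start + 1 if mate_aln.mapped else 0
                qual = read.qual or "*"
                handle.write(
                    f"{pair.pair_id}\t{flag}\t{rname}\t{pos}\t0\t{cigar}\t"
                    f"{rnext}\t{pnext}\t0\t{seq_out}\t{qual}{tags}\n"
                )
    return path
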