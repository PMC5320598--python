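"""De Bruijn unitig assembly, the k-mer sweep and highest-N50 selection.

The assembler builds a graph over canonical k-mers (the lexicographic minimum
of a k-mer and its reverse complement; k is kept odd so no k-mer is its own
reverse complement), drops k-mers below a count threshold as crude error
removal, and compresses every maximal unambiguous path into a unitig.  It has
no repeat resolution, bubble popping or paired-end awareness: pairing is
exploited downstream by the scaffolder, which is where this pipeline invests
its effort.

Multiple assemblies are produced by sweeping k between fixed fractions of the
read length (defaults 66 %-90 %), and the assembly with the highest N50 wins.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .seqio import ReadPair, SeqRecord, revcomp

__all__ = [
    "Contig",
    "Assembly",
    "kmer_sweep",
    "assemble_unitigs",
    "n50",
    "select_best_assembly",
    "run_sweep",
]


@dataclass(frozen=True)
class Contig:
    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Assembly:
    """An ordered set of contigs with provenance.

    ``k`` is the k-mer size the contigs were assembled at (dropped after
    improvement); ``stage`` tracks progress through the pipeline.
    """

    contigs: list[Contig]
    k: Optional[int] = None
    stage: str = "raw"
    accession: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(ids) != len(set(ids)):
            raise ValueError("contig ids must be unique within an assembly")
        if self.k is not None and (self.k % 2 == 0 or self.k < 17):
            raise ValueError("k must be odd and >= 17")

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def lengths(self) -> list[int]:
        return [len(c) for c in self.contigs]

    @property
    def total_length(self) -> int:
        return sum(self.lengths)

    @property
    def n50(self) -> int:
        return n50(self.lengths)

    def get(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(contig_id)


def kmer_sweep(
    read_length: int,
    lo_frac: float = 0.66,
    hi_frac: float = 0.90,
    step: int = 2,
) -> list[int]:
    """Odd k-mer sizes between ``lo_frac`` and ``hi_frac`` of the read length.

    The lower bound is rounded up to the next odd integer and the upper bound
    down, so every returned k satisfies ``lo_frac*L <= k <= hi_frac*L``.
    """
    if not 0 < lo_frac <= hi_frac <= 1:
        raise ValueError("need 0 < lo_frac <= hi_frac <= 1")
    if step < 2 or step % 2 != 0:
        raise ValueError("step must be an even integer >= 2")
    if read_length < 30:
        raise ValueError("read_length must be >= 30")
    lo = lo_frac * read_length
    hi = hi_frac * read_length
    k_first = math.ceil(lo)
    if k_first % 2 == 0:
        k_first += 1
    k_first = max(k_first, 17)
    k_last = math.floor(hi)
    if k_last % 2 == 0:
        k_last -= 1
    if k_first > k_last:
        # degenerate sweep: the interval contains an integer but no odd one
        # (e.g. lo == hi == an even k); take the nearest odd below
        if math.floor(hi) >= math.ceil(lo) and k_last >= 17:
            return [k_last]
        raise ValueError(
            f"no odd k-mer size in [{lo:.1f}, {hi:.1f}]; reads of "
            f"{read_length} bases are too short for this sweep"
        )
    return list(range(k_first, k_last + 1, step))


def _canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _iter_reads(reads: Iterable[Union[ReadPair, SeqRecord, str]]) -> Iterable[str]:
    for item in reads:
        if isinstance(item, ReadPair):
            yield item.fwd.seq
            yield item.rev.seq
        elif isinstance(item, SeqRecord):
            yield item.seq
        else:
            yield item


def count_kmers(reads: Iterable[Union[ReadPair, SeqRecord, str]], k: int) -> Counter:
    """Count canonical k-mers across all reads, skipping k-mers containing N."""
    counts: Counter = Counter()
    for seq in _iter_reads(reads):
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            counts[_canonical(kmer)] += 1
    return counts


def _auto_min_count(counts: Counter, k: int, total_read_bases: int) -> int:
    # Estimate genome size from k-mers seen at least twice (error k-mers are
    # overwhelmingly singletons); at an estimated read coverage >= 20x a
    # k-mer seen once is more likely an error than real sequence.
    solid = sum(1 for c in counts.values() if c >= 2)
    genome_est = solid if solid > 0 else max(len(counts), 1)
    est_coverage = total_read_bases / genome_est
    return 2 if est_coverage >= 20 else 1


def assemble_unitigs(
    reads: Iterable[Union[ReadPair, SeqRecord, str]],
    k: int,
    min_count: Optional[int] = None,
) -> Assembly:
    """Assemble unitigs from reads at a single odd k-mer size.

    Canonical k-mers occurring fewer than ``min_count`` times are discarded
    (``min_count`` defaults to 2 when the estimated read coverage is at least
    20x, else 1).  Maximal unambiguous paths of the remaining graph are
    compressed into unitigs; each unitig is emitted in its canonical
    orientation (lexicographic minimum of the sequence and its reverse
    complement) and contigs are named ``u1..uN`` in order of descending
    length, ties broken by sequence, so output is fully deterministic.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    read_seqs = list(_iter_reads(reads))
    total_bases = sum(len(s) for s in read_seqs)
    counts = count_kmers(read_seqs, k)
    if min_count is None:
        min_count = _auto_min_count(counts, k, total_bases)
    nodes = {km for km, c in counts.items() if c >= min_count}
    if not nodes:
        warnings.warn(
            f"no k-mer passed the count filter (k={k}, min_count={min_count}); "
            "returning an empty assembly",
            stacklevel=2,
        )
        return Assembly([], k=k, stage="raw")

    def succs(kmer: str) -> list[str]:
        suffix = kmer[1:]
        return [suffix + b for b in "ACGT" if _canonical(suffix + b) in nodes]

    def preds(kmer: str) -> list[str]:
        prefix = kmer[:-1]
        return [b + prefix for b in "ACGT" if _canonical(b + prefix) in nodes]

    used: set[str] = set()
    unitigs: list[str] = []
    for seed in sorted(nodes):
        if seed in used:
            continue
        path_canon = {seed}
        right: list[str] = []
        cur = seed
        while True:
            nxts = succs(cur)
            if len(nxts) != 1:
                break
            nxt = nxts[0]
            if len(preds(nxt)) != 1:
                break
            cn = _canonical(nxt)
            if cn in used or cn in path_canon:
                break
            right.append(nxt)
            path_canon.add(cn)
            cur = nxt
        left: list[str] = []
        cur = seed
        while True:
            prvs = preds(cur)
            if len(prvs) != 1:
                break
            prv = prvs[0]
            if len(succs(prv)) != 1:
                break
            cp = _canonical(prv)
            if cp in used or cp in path_canon:
                break
            left.append(prv)
            path_canon.add(cp)
            cur = prv
        chain = left[::-1] + [seed] + right
        seq = chain[0] + "".join(km[-1] for km in chain[1:])
        unitigs.append(min(seq, revcomp(seq)))
        used |= path_canon

    unitigs.sort(key=lambda s: (-len(s), s))
    contigs = [Contig(f"u{i + 1}", s) for i, s in enumerate(unitigs)]
    return Assembly(contigs, k=k, stage="raw")


def n50(lengths: Sequence[int]) -> int:
    """The largest L such that contigs of length >= L hold half the bases.

    This is the classical N50: sort contig lengths in descending order and
    take the length at which the running total first reaches half of the
    assembly size.
    """
    if not lengths:
        raise ValueError("n50 of an empty assembly is undefined")
    if any(x <= 0 for x in lengths):
        raise ValueError("contig lengths must be positive")
    half = sum(lengths) / 2
    running = 0
    for length in sorted(lengths, reverse=True):
        running += length
        if running >= half:
            return length
    raise AssertionError("unreachable")


def select_best_assembly(assemblies: Sequence[Assembly]) -> Assembly:
    """Pick the assembly with the highest N50.

    Ties are broken by larger total length, then fewer contigs, then smallest
    k, so the choice is deterministic.
    """
    if not assemblies:
        raise ValueError("no assemblies to choose from")
    candidates = [a for a in assemblies if a.contigs]
    if not candidates:
        raise ValueError("all candidate assemblies are empty")

    def key(a: Assembly):
        return (a.n50, a.total_length, -a.n_contigs, -(a.k if a.k is not None else 0))

    return max(candidates, key=key)


def run_sweep(
    pairs: Sequence[ReadPair],
    lo_frac: float = 0.66,
    hi_frac: float = 0.90,
    step: int = 2,
    min_count: Optional[int] = None,
) -> tuple[Assembly, list[dict]]:
    """Assemble at every k in the sweep and return (best assembly, report).

    The report holds one row per k with the contig count, total length and
    N50, mirroring what a sweep log would show.
    """
    if not pairs:
        raise ValueError("no read pairs supplied")
    read_length = int(
        sorted(len(p.fwd.seq) for p in pairs)[len(pairs) // 2]
    )
    report: list[dict] = []
    assemblies: list[Assembly] = []
    for k in kmer_sweep(read_length, lo_frac, hi_frac, step):
        asm = assemble_unitigs(pairs, k, min_count=min_count)
        assemblies.append(asm)
        report.append(
            {
                "k": k,
                "contigs": asm.n_contigs,
                "total_len": asm.total_length,
                "n50": asm.n50 if asm.contigs else 0,
            }
        )
    return select_best_assembly(assemblies), report
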