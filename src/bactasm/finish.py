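"""Finishing steps and assembly QC statistics.

After improvement, contigs shorter than the library's target fragment size
are dropped (they are mostly adapter chaff and unresolvable fragments), the
remainder are sorted by size and renamed to carry the sequencing-run
accession, and the reads are mapped once more against the final assembly to
produce the summary statistics: contig count, total length, N50, GC, N
count and the fraction of reads mapping back.  When a reference genome is
available, a k-mer containment genome fraction and a size-versus-reference
check complete the report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from .assemble import Assembly, Contig, n50
from .mapping import SeedIndex, map_read
from .seqio import ReadPair, SeqRecord, revcomp

__all__ = [
    "AsmStats",
    "filter_short_contigs",
    "sort_and_rename",
    "gc_percent",
    "final_qc",
    "genome_fraction",
    "size_vs_reference",
    "write_stats",
]


@dataclass
class AsmStats:
    n_contigs: int
    total_length: int
    n50: int
    gc_percent: float
    n_bases: int
    reads_mapped_percent: float
    genome_fraction_percent: Optional[float] = None
    size_diff_percent: Optional[float] = None


def filter_short_contigs(assembly: Assembly, min_length: int = 300) -> Assembly:
    """Drop contigs shorter than the target fragment size (default 300).

    The boundary is inclusive: a contig of exactly ``min_length`` bases is
    kept.  Removing every contig is legal but prominently warned about.
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    kept = [c for c in assembly.contigs if len(c) >= min_length]
    removed = assembly.n_contigs - len(kept)
    if removed and not kept:
        warnings.warn(
            f"length filter (>= {min_length}) removed all {removed} contigs; "
            "the assembly is now empty",
            stacklevel=2,
        )
    return Assembly(kept, k=assembly.k, stage=assembly.stage, accession=assembly.accession)


def sort_and_rename(assembly: Assembly, accession: str) -> Assembly:
    """Sort contigs by descending length and rename to ``<accession>.<rank>``.

    Ties are broken lexicographically on the sequence so the order (and
    therefore the names) is stable across runs.
    """
    if not accession or any(c.isspace() for c in accession):
        raise ValueError("accession must be non-empty without whitespace")
    ordered = sorted(assembly.contigs, key=lambda c: (-len(c), c.seq))
    renamed = [Contig(f"{accession}.{i + 1}", c.seq) for i, c in enumerate(ordered)]
    return Assembly(renamed, k=None, stage="final", accession=accession)


def gc_percent(seqs: Union[str, Sequence[str]]) -> float:
    """GC percentage over non-N bases; 0.0 when there are none."""
    if isinstance(seqs, str):
        seqs = [seqs]
    gc = acgt = 0
    for seq in seqs:
        gc += seq.count("G") + seq.count("C")
        acgt += len(seq) - seq.count("N")
    return 100.0 * gc / acgt if acgt else 0.0


def final_qc(
    assembly: Assembly,
    pairs: Sequence[ReadPair],
    seed_k: int = 15,
    max_hits: int = 200,
) -> AsmStats:
    """Remap all reads (strict mode) against the final assembly and summarise."""
    if not assembly.contigs:
        raise ValueError("cannot QC an empty assembly")
    seqs = [c.seq for c in assembly.contigs]
    total_reads = 0
    mapped_reads = 0
    if pairs:
        index = SeedIndex(assembly, seed_k=seed_k, max_hits=max_hits)
        for pair in pairs:
            for read in (pair.fwd, pair.rev):
                total_reads += 1
                if map_read(index, read, "strict").mapped:
                    mapped_reads += 1
    return AsmStats(
        n_contigs=assembly.n_contigs,
        total_length=assembly.total_length,
        n50=n50(assembly.lengths),
        gc_percent=gc_percent(seqs),
        n_bases=sum(s.count("N") for s in seqs),
        reads_mapped_percent=(100.0 * mapped_reads / total_reads) if total_reads else 0.0,
    )


def _canonical_kmers(seq: str, k: int) -> set[str]:
    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        rc = revcomp(kmer)
        out.add(kmer if kmer <= rc else rc)
    return out


def genome_fraction(
    assembly: Assembly, reference: Union[SeqRecord, str], k: int = 31
) -> float:
    """Percent of distinct canonical reference k-mers present in the assembly.

    A k-mer containment proxy for the alignment-based genome fraction: it
    converges to the same value on assemblies without misassemblies and is
    insensitive to contig order and strand.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    ref_seq = reference.seq if isinstance(reference, SeqRecord) else reference
    if len(ref_seq) < k:
        raise ValueError(f"reference shorter than k={k}")
    ref_kmers = _canonical_kmers(ref_seq, k)
    if not ref_kmers:
        raise ValueError("reference contains no N-free k-mers")
    asm_kmers: set[str] = set()
    for contig in assembly.contigs:
        asm_kmers |= _canonical_kmers(contig.seq, k)
    return 100.0 * len(ref_kmers & asm_kmers) / len(ref_kmers)


def size_vs_reference(
    assembly_length: int, reference_length: int, tolerance_percent: float = 10.0
) -> tuple[float, bool]:
    """Signed percent size difference and whether it is within tolerance.

    Bacterial assemblies are expected to land within +/-10 % of the size of
    a closely related reference; larger deviations usually mean contamination
    or large-scale loss.
    """
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    percent = 100.0 * (assembly_length - reference_length) / reference_length
    return percent, abs(percent) <= tolerance_percent


def write_stats(stats: AsmStats, tsv_path=None, json_path=None) -> dict:
    """Serialise stats as TSV and/or JSON; returns the plain dict."""
    data = asdict(stats)
    if tsv_path is not None:
        with open(tsv_path, "w") as handle:
            keys = list(data)
            handle.write("\t".join(keys) + "\n")
            handle.write(
                "\t".join("" if data[k] is None else str(data[k]) for k in keys) + "\n"
            )
    if json_path is not None:
        Path(json_path).write_text(json.dumps(data, indent=2) + "\n")
    return data
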