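"""Multi-locus sequence typing (MLST) of assemblies.

Classical MLST assigns a sequence type (ST) from the combination of allele
numbers observed at (typically seven) housekeeping loci.  Schemes are read
from a pubMLST-style directory: one FASTA of numbered alleles per locus
(headers ``locus_number``) and a tab-separated profile table mapping allele
vectors to STs.

An allele counts as found only when a hit reaches at least 95 % of the
allele's length at at least 95 % identity; anything weaker is "partial" and
does not contribute to typing.  Finding two different alleles of the same
locus at distinct places in one assembly is a contamination signal and sets
the contaminated flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .assemble import Assembly, Contig
from .seqio import SeqRecord, read_fasta, revcomp, write_fasta

__all__ = [
    "MlstScheme",
    "LocusCall",
    "MlstResult",
    "load_scheme",
    "find_allele",
    "call_st",
    "type_assembly",
    "make_synthetic_scheme",
    "write_scheme",
    "write_report",
]

MATCH_THRESHOLD = 95.0  # percent, both length and identity

EXACT = "exact"
MATCH = "match"
PARTIAL = "partial"
MISSING = "missing"
MULTIPLE = "multiple"

NOVEL = "novel"


@dataclass(frozen=True)
class MlstScheme:
    loci: tuple[str, ...]
    alleles: dict  # locus -> {allele_number: sequence}
    profiles: dict  # tuple of allele numbers (loci order) -> ST

    def __post_init__(self) -> None:
        for vector in self.profiles:
            if len(vector) != len(self.loci):
                raise ValueError("profile vectors must have one entry per locus")


@dataclass(frozen=True)
class LocusCall:
    locus: str
    allele: Optional[int]
    percent_identity: float
    percent_length: float
    status: str


@dataclass(frozen=True)
class MlstResult:
    calls: tuple[LocusCall, ...]
    st: Union[int, str, None]  # an ST number, "novel", or None
    contaminated: bool


def load_scheme(directory: Union[str, Path]) -> MlstScheme:
    """Load a pubMLST-layout scheme directory.

    Expects a profile TSV (``profiles.tsv`` or the first ``*.tsv``/``*.txt``
    whose header starts with ``ST``) and one allele FASTA per locus named
    after the locus with a ``.fas``/``.fa``/``.fasta``/``.tfa`` extension.
    """
    directory = Path(directory)
    profile_path = None
    for cand in sorted(directory.iterdir()):
        if cand.suffix.lower() in {".tsv", ".txt"}:
            header = cand.read_text().splitlines()
            if header and header[0].split("\t")[0].upper() == "ST":
                profile_path = cand
                break
    if profile_path is None:
        raise FileNotFoundError(f"no profile table (ST\\t...) found in {directory}")
    lines = [l for l in profile_path.read_text().splitlines() if l.strip()]
    loci = tuple(lines[0].split("\t")[1:])
    if not loci:
        raise ValueError(f"profile table {profile_path} lists no loci")

    alleles: dict[str, dict[int, str]] = {}
    for locus in loci:
        for ext in (".fas", ".fa", ".fasta", ".tfa"):
            path = directory / f"{locus}{ext}"
            if path.exists():
                break
        else:
            raise FileNotFoundError(f"no allele FASTA for locus {locus!r} in {directory}")
        locus_alleles: dict[int, str] = {}
        for rec in read_fasta(path):
            stem, _, number = rec.id.rpartition("_")
            if stem != locus or not number.isdigit():
                raise ValueError(
                    f"allele header {rec.id!r} does not follow '{locus}_<number>'"
                )
            locus_alleles[int(number)] = rec.seq
        if not locus_alleles:
            raise ValueError(f"locus {locus!r} has no alleles")
        alleles[locus] = locus_alleles

    profiles: dict[tuple[int, ...], int] = {}
    for line in lines[1:]:
        fields = line.split("\t")
        if len(fields) < 1 + len(loci):
            raise ValueError(f"profile row {fields[0]!r} has too few columns")
        st = int(fields[0])
        vector = tuple(int(x) for x in fields[1 : 1 + len(loci)])
        for locus, num in zip(loci, vector):
            if num not in alleles[locus]:
                raise ValueError(
                    f"profile ST {st} references unknown allele {locus}_{num}"
                )
        profiles[vector] = st
    return MlstScheme(loci=loci, alleles=alleles, profiles=profiles)


def _best_hit(
    contigs: Sequence[Contig], allele_seq: str, seed_k: int
) -> Optional[tuple[float, float, str, int, int]]:
    """Best placement of one allele: (pct_length, pct_identity, contig, start, end).

    Exact substring search first (the overwhelmingly common case for a true
    allele), then seed-and-extend with ungapped scoring, clipping the allele
    at contig boundaries.
    """
    la = len(allele_seq)
    best: Optional[tuple[float, float, str, int, int]] = None
    for contig in contigs:
        for oriented in (allele_seq, revcomp(allele_seq)):
            pos = contig.seq.find(oriented)
            if pos >= 0:
                return (100.0, 100.0, contig.id, pos, pos + la)
    offsets = list(range(0, la - seed_k + 1, seed_k))
    if offsets and offsets[-1] != la - seed_k:
        offsets.append(la - seed_k)
    for contig in contigs:
        cseq = contig.seq
        clen = len(cseq)
        for oriented in (allele_seq, revcomp(allele_seq)):
            starts: set[int] = set()
            for off in offsets:
                seed = oriented[off : off + seed_k]
                idx = cseq.find(seed)
                while idx >= 0:
                    starts.add(idx - off)
                    idx = cseq.find(seed, idx + 1)
            for start in starts:
                span_start = max(start, 0)
                span_end = min(start + la, clen)
                span = span_end - span_start
                if span < seed_k:
                    continue
                a = cseq[span_start:span_end]
                b = oriented[span_start - start : span_end - start]
                matches = sum(1 for x, y in zip(a, b) if x == y)
                pct_len = 100.0 * span / la
                pct_id = 100.0 * matches / span
                cand = (pct_len, pct_id, contig.id, span_start, span_end)
                if best is None or (pct_len, pct_id) > (best[0], best[1]):
                    best = cand
    return best


def find_allele(
    assembly: Assembly,
    locus: str,
    locus_alleles: dict,
    seed_k: int = 15,
) -> LocusCall:
    """Call one locus against an assembly under the 95/95 rule.

    The closest allele is the one with the best (length, identity) pair; ties
    go to higher identity then lower allele number.  If two alleles with
    different sequences both reach 95/95 at non-overlapping assembly
    locations the locus is flagged ``multiple`` (contamination).
    """
    if not locus_alleles:
        raise ValueError(f"locus {locus!r} has no alleles")
    hits: list[tuple[int, tuple[float, float, str, int, int]]] = []
    for number in sorted(locus_alleles):
        hit = _best_hit(assembly.contigs, locus_alleles[number], seed_k)
        if hit is not None:
            hits.append((number, hit))
    if not hits:
        return LocusCall(locus, None, 0.0, 0.0, MISSING)

    qualifying = [
        (num, hit)
        for num, hit in hits
        if hit[0] >= MATCH_THRESHOLD and hit[1] >= MATCH_THRESHOLD
    ]
    # contamination check: two distinct allele sequences at disjoint locations
    distinct: list[tuple[int, tuple]] = []
    for num, hit in qualifying:
        placement = (hit[2], hit[3], hit[4])
        is_new = True
        for num2, hit2 in distinct:
            same_place = hit2[2] == placement[0] and not (
                placement[2] <= hit2[3] or hit2[4] <= placement[1]
            )
            if same_place or locus_alleles[num] == locus_alleles[num2]:
                is_new = False
                break
        if is_new:
            distinct.append((num, hit))
    best_num, best = max(
        hits, key=lambda item: (item[1][0], item[1][1], -item[0])
    )
    if len(distinct) >= 2:
        return LocusCall(locus, best_num, best[1], best[0], MULTIPLE)
    if qualifying:
        best_num, best = max(
            qualifying, key=lambda item: (item[1][0], item[1][1], -item[0])
        )
        status = EXACT if best[0] == 100.0 and best[1] == 100.0 else MATCH
        return LocusCall(locus, best_num, best[1], best[0], status)
    return LocusCall(locus, None, best[1], best[0], PARTIAL)


def call_st(scheme: MlstScheme, calls: Sequence[LocusCall]) -> MlstResult:
    """Combine per-locus calls into an ST.

    An ST is assigned only when every locus is exact or match and the allele
    vector appears in the profile table; a fully called but unknown vector is
    ``novel``; anything else (missing, partial, multiple loci) yields None.
    """
    if len(calls) != len(scheme.loci) or tuple(c.locus for c in calls) != scheme.loci:
        raise ValueError("need exactly one call per scheme locus, in scheme order")
    contaminated = any(c.status == MULTIPLE for c in calls)
    if all(c.status in (EXACT, MATCH) for c in calls):
        vector = tuple(c.allele for c in calls)
        st: Union[int, str, None] = scheme.profiles.get(vector, NOVEL)
    else:
        st = None
    return MlstResult(calls=tuple(calls), st=st, contaminated=contaminated)


def type_assembly(
    assembly: Assembly, scheme: MlstScheme, seed_k: int = 15
) -> MlstResult:
    """Type one assembly: call every locus, then look up the ST."""
    calls = [
        find_allele(assembly, locus, scheme.alleles[locus], seed_k=seed_k)
        for locus in scheme.loci
    ]
    return call_st(scheme, calls)


def write_report(
    result: MlstResult,
    sample: str,
    tsv_path=None,
    json_path=None,
) -> dict:
    data = {
        "sample": sample,
        "st": result.st,
        "contaminated": result.contaminated,
        "loci": [
            {
                "locus": c.locus,
                "allele": c.allele,
                "status": c.status,
                "percent_identity": round(c.percent_identity, 2),
                "percent_length": round(c.percent_length, 2),
            }
            for c in result.calls
        ],
    }
    if tsv_path is not None:
        with open(tsv_path, "w") as handle:
            handle.write("sample\tlocus\tallele\tstatus\tpercent_identity\t"
                         "percent_length\tst\tcontaminated\n")
            for c in result.calls:
                handle.write(
                    f"{sample}\t{c.locus}\t{c.allele if c.allele is not None else '-'}"
                    f"\t{c.status}\t{c.percent_identity:.2f}\t{c.percent_length:.2f}"
                    f"\t{result.st if result.st is not None else '-'}"
                    f"\t{int(result.contaminated)}\n"
                )
    if json_path is not None:
        Path(json_path).write_text(json.dumps(data, indent=2) + "\n")
    return data


def make_synthetic_scheme(
    genome: Union[SeqRecord, str],
    n_loci: int = 7,
    allele_length: int = 450,
    variants_per_locus: int = 3,
    seed: int = 0,
) -> tuple[MlstScheme, dict]:
    """Build a synthetic MLST scheme whose allele 1s are embedded in a genome.

    Intended for tests and simulations: loci are evenly spaced genome
    segments, allele 1 of each locus is the genome's own sequence (so typing
    a faithful assembly of the genome yields ST 1), and higher-numbered
    alleles are variants with a few substitutions.  Returns the scheme and
    the truth locus coordinates.
    """
    seq = genome.seq if isinstance(genome, SeqRecord) else genome
    g = len(seq)
    if g < n_loci * (allele_length + 10):
        raise ValueError("genome too short for the requested synthetic scheme")
    rng = np.random.default_rng([seed % 2**31, 37])
    spacing = g // n_loci
    loci = tuple(f"locus{i + 1}" for i in range(n_loci))
    alleles: dict[str, dict[int, str]] = {}
    positions: dict[str, tuple[int, int]] = {}
    for i, locus in enumerate(loci):
        start = i * spacing + (spacing - allele_length) // 2
        allele1 = seq[start : start + allele_length]
        positions[locus] = (start, start + allele_length)
        variants = {1: allele1}
        for v in range(2, variants_per_locus + 1):
            buf = bytearray(allele1, "ascii")
            n_subs = int(rng.integers(3, 11))
            for pos in rng.choice(allele_length, size=n_subs, replace=False):
                cur = chr(buf[pos])
                options = [b for b in "ACGT" if b != cur]
                buf[pos] = ord(options[int(rng.integers(0, 3))])
            variants[v] = buf.decode("ascii")
        alleles[locus] = variants
    profiles: dict[tuple[int, ...], int] = {tuple([1] * n_loci): 1}
    st = 2
    for v in range(2, variants_per_locus + 1):
        profiles[tuple([v] * n_loci)] = st
        st += 1
    return MlstScheme(loci=loci, alleles=alleles, profiles=profiles), positions


def write_scheme(scheme: MlstScheme, directory: Union[str, Path]) -> Path:
    """Write a scheme as a pubMLST-layout directory (allele FASTAs + profiles.tsv)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for locus in scheme.loci:
        records = [
            SeqRecord(f"{locus}_{num}", seq)
            for num, seq in sorted(scheme.alleles[locus].items())
        ]
        write_fasta(records, directory / f"{locus}.fas")
    with open(directory / "profiles.tsv", "w") as handle:
        handle.write("ST\t" + "\t".join(scheme.loci) + "\n")
        for vector, st in sorted(scheme.profiles.items(), key=lambda kv: kv[1]):
            handle.write(f"{st}\t" + "\t".join(str(v) for v in vector) + "\n")
    return directory
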