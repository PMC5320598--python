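# Methods

This note documents the models and procedures implemented in `bactasm`, the
parameters that matter, and the design decisions taken where the design was
genuinely open.  It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Assembly

Reads are decomposed into canonical k-mers (the lexicographic minimum of a
k-mer and its reverse complement).  k is kept odd so that no k-mer is its own
reverse complement, which would make strand bookkeeping ambiguous.  K-mers
occurring fewer than `min_count` times are dropped; `min_count` defaults to 2
when the estimated read coverage (total read bases over the count of k-mers
seen at least twice) is at least 20×, else 1.  This is a crude error filter:
sequencing errors produce almost exclusively singleton k-mers at these
coverages, and the pipeline's improvement stages repair the occasional true
k-mer lost to it.  Maximal unambiguous graph paths are compressed into
unitigs, emitted in canonical orientation and named `u1..uN` in descending
length order so output is byte-deterministic.

There is no bubble popping, tip clipping or repeat resolution by design:
pairing information is exploited downstream, and the assembler is evaluated
as part of the whole assemble-then-improve loop, not alone.

The sweep assembles at every odd k with 0.66·L ≤ k ≤ 0.90·L (bounds rounded
inward to odd; step 2) and keeps the highest N50, with ties broken by total
length, contig count, then smaller k.  A degenerate sweep whose interval
contains only an even integer uses the nearest odd below it.

## Mapping and pair classification

The internal mapper is exact-seed (15-mer, both strands, seeds with more
than 200 hits masked) followed by ungapped full-length extension; the best
candidate is the one with fewest mismatches, ties resolved by lowest
(contig, start, strand).  `strict` mode requires 95 % identity over the
read, `lenient` 90 %.  There is no gapped alignment or quality-aware
scoring; reads overlapping indel-like artefacts simply fail the identity
threshold, and the evidence thresholds downstream absorb the loss.

The insert model is estimated from same-contig FR pair distances as
median ± 3·1.4826·MAD (the scaling makes one MAD comparable to one standard
deviation under normality), with the lower bound clipped to at least two
read lengths.  A pair is *proper* when both ends map to one contig in FR
orientation with outer distance inside that window.  Improvement works on
the complement: unmapped, half-mapped and split pairs.  Same-contig pairs
with wrong orientation or distance are excluded from improvement; they
indicate structural ambiguity rather than missing joins.

One refinement applies to gap filling only: a proper pair whose alignment
crosses a run of Ns is kept in the improvement subset.  A short gap costs a
read only a few mismatches, so gap-spanning pairs would otherwise classify
proper and be discarded — yet they are precisely the local evidence a gap
needs.

## Scaffolding

Each split pair whose two reads lie within the insert window of their
contig ends (a + strand read points off the tail, a − strand read off the
head) adds one count and one gap estimate, `median_insert − d_a − d_b`, to
the link between those ends.  Per iteration, links with count at least the
iteration's threshold are applied greedily in descending count order; each
end joins at most once per iteration, a join that would close a circle is
skipped, and an end with a competing link within 0.7× of the candidate's
count is left alone (near-equal competitors indicate a repeat, and either
choice would be a guess).  The N-gap between joined contigs is the median
per-pair estimate, floored at one N — apparent overlaps are left to the gap
filler, which can verify them base by base against reads.

The threshold schedule is linear with round-half-up from 90 down to 5 over
16 iterations.  Links are rebuilt from a fresh mapping of the improvement
subset against the current contigs every iteration, so evidence follows the
growing scaffolds.

## Gap filling

120 iterations with a linear 90→5 depth schedule, alternating strict (even
iterations) and lenient (odd) recruitment stringency — two stringencies
dislodge different stuck gaps.  For each gap, pairs with one read anchored
within the insert window of a flank and pointing inward donate their mates,
oriented by the anchor strand.  Each flank is extended one base at a time:
recruited reads are anchored on an exact 15-mer at the flank tip, must meet
the mode's identity over their overlap, and vote with their next base;
extension requires depth ≥ the iteration's threshold and a winning-base
majority ≥ 0.8.  A gap closes when the two extended flanks share an exact
overlap of at least 30 bases (2× the seed size, preventing chimeric meets);
this also resolves scaffolds whose pieces genuinely overlap (negative
gaps).  Otherwise the N run shrinks by the extension lengths, never below
one N, so the genome-wide N count is non-increasing.  The loop exits early
once no gaps remain — with no gaps every iteration is a no-op, so this
changes nothing but run time.

The schedule floor of 5 and the 0.8 majority are this package's choices
(both config-exposed): the floor mirrors the scaffolder's, and 0.8 is a
conservative consensus that tolerates ~0.1–1 % sequencing error without
letting a minority allele rewrite a gap.

## Finishing, QC and MLST

Contigs shorter than 300 bases (the low end of typical 300–500 fragment
sizes; config-exposed) are removed, the rest sorted by descending length
(ties by sequence, for stable names) and renamed `<accession>.<rank>`.  All
reads are re-mapped in strict mode for the summary statistics.  GC is
computed over non-N bases.  Genome fraction is k-mer containment (percent
of distinct canonical reference 31-mers present in the assembly) — an
approximation to the alignment-based metric that agrees with it in the
absence of misassemblies and is strand- and order-invariant.  The size
check reports the signed percent difference from the reference and whether
it is within ±10 %.

MLST schemes use the pubMLST layout: one allele FASTA per locus
(`locus_number` headers) and a profile TSV.  Allele search is exact
substring first, then seed-and-extend with ungapped scoring; percent length
is aligned-span/allele-length and percent identity is computed over the
aligned span, each required to reach 95 % (inclusive) for a match.  Because
extension is ungapped, alleles differing from the assembly by indels may
score partial — a known limitation relative to a gapped aligner.  A locus
is flagged `multiple` (and the assembly contaminated) only when two alleles
with *different sequences* qualify at *non-overlapping* locations, so two
near-identical alleles scoring on the same region do not raise a false
alarm.  An ST is assigned when every locus is exact/match and the vector is
in the profile table; a fully typed but unknown vector is `novel`.

## The simulator

The simulator emulates a bacterial Illumina library at its published
operating point: defaults of 130 bp reads, 30× coverage, insert 300 ± 30,
and a 0.1 % substitution rate representative of quality-trimmed data.
Genomes are i.i.d. sequence with controlled GC, optionally with implanted
exact repeats.  Fragmentation follows a molecule-shearing (renewal) model:
copies of the genome are cut into consecutive fragments with
normal-distributed lengths and a uniformly random phase, size-selected to
mean ± 3 SD, and fragments are sampled with replacement (duplicate pairs
occur, as in real libraries).  Shearing a linear molecule produces terminal
fragments at the same rate as interior ones, so coverage is uniform up to
the chromosome ends; the more common "uniform fragment start" model leaves
linear termini uncovered with high probability and would make exact
whole-genome recovery impossible for any assembler.  Reads are FR-oriented
fragment ends; errors are substitutions only (no indels), a documented
limitation that matches the mapper's ungapped design.  Fragment coordinates
are encoded in read names so tests can audit placements.

What passing on simulated data does *not* show: robustness to indel errors,
quality-score structure, GC-coverage bias, contamination, or the repeat
content of real genomes beyond the implanted exact repeats.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline on 8–30 kb
genomes at 20–30× — large enough that every stage does real work (the raw
sweep assemblies fragment into 5–25 unitigs that the improvement stages
must reassemble) while keeping the whole suite fast.  Every component is
deterministic given the simulator seed: k-mer iteration, candidate
selection, join order and naming all have explicit total orders, and two
pipeline runs on the same input produce byte-identical FASTA and
statistics.  Resumability is file-based (one marker per completed stage),
deliberately avoiding a workflow engine.

## Known limitations

- Ungapped alignment throughout: indel-rich samples will map and type worse
  than with a gapped aligner.
- No misassembly detection or join breaking; a wrong early join persists.
- Single-library support only (one insert-size distribution).
- The assembler holds k-mer counts in memory; it is sized for bacterial
  genomes, not metagenomes.
- Memory-requirement estimation is reduced to logging the predicted k-mer
  table size; scheduler integration is out of scope.
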