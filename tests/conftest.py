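"""Shared fixtures: simulated end-to-end scenarios reused across test modules.

All scenarios are generated programmatically with fixed seeds, so the suite
needs no data files and every expectation can be checked against the known
truth genome.
"""

from __future__ import annotations

import pytest

from bactasm.assemble import Assembly, Contig, run_sweep
from bactasm.finish import filter_short_contigs, final_qc, sort_and_rename
from bactasm.gapfill import run_gapfiller
from bactasm.scaffold import run_scaffolder
from bactasm.sim import SimSpec, simulate_genome, simulate_reads


@pytest.fixture(scope="session")
def recovery_case():
    """Full pipeline on an error-free repeat-free 20 kb genome at 30x.

    Insert 300 +/- 30, 130 bp reads: the operating point every stage is
    designed for.  Returns every stage output plus the truth genome.
    """
    spec = SimSpec(
        genome_length=20000, seed=11, gc=0.50, coverage=30.0,
        read_length=130, insert_mean=300, insert_sd=30, error_rate=0.0,
    )
    genome = simulate_genome(spec)
    pairs = simulate_reads(genome, spec)
    best, sweep_report = run_sweep(pairs)
    scaffolded, join_log = run_scaffolder(best, pairs)
    gapfilled, fill_log = run_gapfiller(scaffolded, pairs)
    final = sort_and_rename(filter_short_contigs(gapfilled, 300), "ERR000001")
    stats = final_qc(final, pairs)
    return {
        "spec": spec,
        "genome": genome,
        "pairs": pairs,
        "raw": best,
        "sweep_report": sweep_report,
        "scaffolded": scaffolded,
        "join_log": join_log,
        "gapfilled": gapfilled,
        "fill_log": fill_log,
        "final": final,
        "stats": stats,
    }


CUT_POINTS = (6000, 12000, 18000)
CUT_GAP = 60  # true bases removed at each junction
WEAK_JUNCTION = 1  # index into CUT_POINTS: bridging pairs withheld here


@pytest.fixture(scope="session")
def cut_genome_case():
    """Improvement-only scenario: truth genome cut into four contigs.

    60 true bases are removed at each of three junctions.  All read pairs
    (simulated from the intact truth with a 500 bp insert so fragments span
    the junctions) go to the improvement stages, except across the middle
    junction where only three bridging pairs are kept - below the
    scaffolder's final threshold of five, so that junction must never join.
    """
    spec = SimSpec(
        genome_length=24000, seed=19, gc=0.50, coverage=30.0,
        read_length=130, insert_mean=500, insert_sd=50, error_rate=0.0,
    )
    genome = simulate_genome(spec)
    pairs = simulate_reads(genome, spec)

    seq = genome.seq
    bounds = [0]
    for cut in CUT_POINTS:
        bounds.extend([cut, cut + CUT_GAP])
    bounds.append(len(seq))
    pieces = [seq[bounds[i] : bounds[i + 1]] for i in range(0, len(bounds), 2)]
    contigs = Assembly([Contig(f"c{i + 1}", s) for i, s in enumerate(pieces)])

    weak_lo = CUT_POINTS[WEAK_JUNCTION] - 140
    weak_hi = CUT_POINTS[WEAK_JUNCTION] + CUT_GAP + 140

    def fragment(pair):
        _, _, start, end = pair.pair_id.split("_")
        return int(start), int(end)

    kept, withheld_bridging = [], []
    for pair in pairs:
        start, end = fragment(pair)
        if start < weak_hi and end > weak_lo:
            # crosses the weak junction region; keep only true bridging pairs
            # (both reads clear of the removed bases) and only three of them
            bridges = (
                start + spec.read_length <= CUT_POINTS[WEAK_JUNCTION]
                and end - spec.read_length >= CUT_POINTS[WEAK_JUNCTION] + CUT_GAP
            )
            if bridges and len(withheld_bridging) < 3:
                withheld_bridging.append(pair)
                kept.append(pair)
        else:
            kept.append(pair)

    scaffolded, join_log = run_scaffolder(contigs, kept)
    gapfilled, fill_log = run_gapfiller(scaffolded, kept)
    return {
        "cut_points": CUT_POINTS,
        "cut_gap": CUT_GAP,
        "weak_junction": WEAK_JUNCTION,
        "spec": spec,
        "genome": genome,
        "contigs": contigs,
        "pairs": kept,
        "weak_bridge_count": len(withheld_bridging),
        "scaffolded": scaffolded,
        "join_log": join_log,
        "gapfilled": gapfilled,
        "fill_log": fill_log,
    }


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated genome + reads for mapper/scaffolder unit tests."""
    spec = SimSpec(
        genome_length=6000, seed=4, gc=0.5, coverage=30.0,
        read_length=100, insert_mean=300, insert_sd=30, error_rate=0.0,
    )
    genome = simulate_genome(spec)
    return {"spec": spec, "genome": genome, "pairs": simulate_reads(genome, spec)}
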