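"""End-to-end orchestration: sweep-assemble, improve, finish, QC, type.

The pipeline runs the stages in a fixed order, writing one FASTA and a
marker file per completed stage so an interrupted run resumes from the last
finished stage instead of starting over.  Everything is deterministic for a
given input and configuration, so two runs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional, Union

import yaml

from . import assemble as asm_mod
from . import finish as finish_mod
from . import gapfill as gapfill_mod
from . import mlst as mlst_mod
from . import scaffold as scaffold_mod
from .assemble import Assembly, Contig
from .mapping import InsertStats
from .seqio import ReadPair, SeqRecord, read_fasta, read_fastq_pairs, write_fasta

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "STAGES"]

STAGES = ("assemble", "scaffold", "gapfill", "finish", "mlst")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All pipeline knobs with their default values.

    The defaults encode the published operating point of the method: k-mer
    sweep over 66-90 % of the read length, scaffolding evidence from 90 down
    to 5 pairs over 16 iterations, gap-fill depth from 90 over 120
    iterations, and a 300-base minimum contig length.
    """

    kmer_lo_frac: float = 0.66
    kmer_hi_frac: float = 0.90
    kmer_step: int = 2
    scaffold_start: int = 90
    scaffold_end: int = 5
    scaffold_iterations: int = 16
    gapfill_start: int = 90
    gapfill_end: int = 5
    gapfill_iterations: int = 120
    min_contig_length: int = 300
    insert_fallback_median: float = 300.0
    insert_fallback_lower: float = 150.0
    insert_fallback_upper: float = 700.0
    min_insert_observations: int = 50
    seed_k: int = 15
    max_hits: int = 200
    ambiguity_ratio: float = 0.7
    consensus_majority: float = 0.8
    accession: str = "sample"
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def insert_fallback(self) -> InsertStats:
        return InsertStats(
            median=self.insert_fallback_median,
            lower=self.insert_fallback_lower,
            upper=self.insert_fallback_upper,
        )


def _log(handle, stage: str, event: str, **metrics) -> None:
    parts = " ".join(f"{k}={v}" for k, v in metrics.items())
    line = f"[{time.strftime('%Y-%m-%dT%H:%M:%S')}] stage={stage} event={event} {parts}"
    handle.write(line.rstrip() + "\n")
    handle.flush()


def _marker(out_dir: Path, stage: str) -> Path:
    return out_dir / f".{stage}.done"


def _write_tsv(path: Path, rows: list[dict], columns: list[str]) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(columns) + "\n")
        for row in rows:
            handle.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")


def run_pipeline(
    fastq_fwd: Union[str, Path],
    fastq_rev: Union[str, Path],
    out_dir: Union[str, Path],
    config: Optional[PipelineConfig] = None,
    mlst_scheme_dir: Optional[Union[str, Path]] = None,
    reference_path: Optional[Union[str, Path]] = None,
) -> dict:
    """Run the whole pipeline; returns a summary dict (also written as JSON).

    Stage outputs (FASTA per stage, join/fill logs, stats TSV/JSON) land in
    ``out_dir``; a stage whose marker file and output already exist is
    skipped on re-run, which is what makes an interrupted run resumable.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_handle = open(out_dir / "run.log", "a")
    _log(log_handle, "setup", "config", **asdict(config))

    pairs = read_fastq_pairs(fastq_fwd, fastq_rev)
    if not pairs:
        raise PipelineError("no read pairs in input FASTQ; nothing to assemble")
    read_length = sorted(len(p.fwd.seq) for p in pairs)[len(pairs) // 2]
    # crude memory prediction for the k-mer table, logged for scheduling
    k_lo = int(config.kmer_lo_frac * read_length)
    est_kmers = sum(len(p.fwd.seq) + len(p.rev.seq) for p in pairs)
    _log(
        log_handle, "setup", "input",
        pairs=len(pairs), read_length=read_length,
        predicted_kmer_table_entries=est_kmers, min_k=k_lo,
    )

    best: Optional[Assembly]

    # --- stage: assemble (k-mer sweep + N50 selection) ---
    best_path = out_dir / "assembly_raw.fa"
    if _marker(out_dir, "assemble").exists() and best_path.exists():
        best = Assembly(
            [Contig(r.id, r.seq) for r in read_fasta(best_path)], stage="raw"
        )
        _log(log_handle, "assemble", "resumed", contigs=best.n_contigs)
    else:
        best, report = asm_mod.run_sweep(
            pairs, config.kmer_lo_frac, config.kmer_hi_frac, config.kmer_step
        )
        _write_tsv(
            out_dir / "sweep_report.tsv", report, ["k", "contigs", "total_len", "n50"]
        )
        write_fasta(
            [SeqRecord(c.id, c.seq) for c in best.contigs], best_path
        )
        _marker(out_dir, "assemble").touch()
        _log(
            log_handle, "assemble", "done",
            k=best.k, contigs=best.n_contigs, n50=best.n50, total=best.total_length,
        )
    if not best.contigs:
        raise PipelineError("assembly is empty: no k-mer passed the count filter")

    # --- stage: scaffold ---
    scaffolds_path = out_dir / "assembly_scaffolded.fa"
    if _marker(out_dir, "scaffold").exists() and scaffolds_path.exists():
        scaffolded = Assembly(
            [Contig(r.id, r.seq) for r in read_fasta(scaffolds_path)],
            stage="scaffolded",
        )
        _log(log_handle, "scaffold", "resumed", contigs=scaffolded.n_contigs)
    else:
        schedule = scaffold_mod.linear_schedule(
            config.scaffold_start, config.scaffold_end, config.scaffold_iterations
        )
        scaffolded, join_log = scaffold_mod.run_scaffolder(
            best,
            pairs,
            schedule=schedule,
            insert_fallback=config.insert_fallback(),
            seed_k=config.seed_k,
            max_hits=config.max_hits,
            ambiguity_ratio=config.ambiguity_ratio,
            min_insert_observations=config.min_insert_observations,
        )
        _write_tsv(
            out_dir / "join_log.tsv",
            join_log,
            ["iteration", "threshold", "contig_a", "end_a", "contig_b", "end_b",
             "count", "gap"],
        )
        write_fasta(
            [SeqRecord(c.id, c.seq) for c in scaffolded.contigs],
            scaffolds_path,
        )
        _marker(out_dir, "scaffold").touch()
        _log(
            log_handle, "scaffold", "done",
            contigs=scaffolded.n_contigs, joins=len(join_log),
        )

    # --- stage: gapfill ---
    gapfilled_path = out_dir / "assembly_gapfilled.fa"
    if _marker(out_dir, "gapfill").exists() and gapfilled_path.exists():
        gapfilled = Assembly(
            [Contig(r.id, r.seq) for r in read_fasta(gapfilled_path)],
            stage="gapfilled",
        )
        _log(log_handle, "gapfill", "resumed", contigs=gapfilled.n_contigs)
    else:
        schedule = gapfill_mod.depth_schedule(
            config.gapfill_start, config.gapfill_end, config.gapfill_iterations
        )
        gapfilled, fill_log = gapfill_mod.run_gapfiller(
            scaffolded,
            pairs,
            schedule=schedule,
            insert_fallback=config.insert_fallback(),
            seed_k=config.seed_k,
            majority=config.consensus_majority,
            min_insert_observations=config.min_insert_observations,
        )
        _write_tsv(
            out_dir / "fill_log.tsv",
            fill_log,
            ["iteration", "mode", "threshold", "contig", "start", "end", "status"],
        )
        write_fasta(
            [SeqRecord(c.id, c.seq) for c in gapfilled.contigs],
            gapfilled_path,
        )
        _marker(out_dir, "gapfill").touch()
        n_left = sum(c.seq.count("N") for c in gapfilled.contigs)
        _log(log_handle, "gapfill", "done", contigs=gapfilled.n_contigs, n_bases=n_left)

    # --- stage: finish (filter, sort, rename, QC) ---
    final_path = out_dir / "assembly_final.fa"
    stats_json = out_dir / "stats.json"
    if _marker(out_dir, "finish").exists() and final_path.exists() and stats_json.exists():
        final = Assembly(
            [Contig(r.id, r.seq) for r in read_fasta(final_path)],
            stage="final", accession=config.accession,
        )
        stats_dict = json.loads(stats_json.read_text())
        _log(log_handle, "finish", "resumed", contigs=final.n_contigs)
    else:
        filtered = finish_mod.filter_short_contigs(gapfilled, config.min_contig_length)
        if not filtered.contigs:
            raise PipelineError(
                f"all contigs shorter than {config.min_contig_length} bases"
            )
        final = finish_mod.sort_and_rename(filtered, config.accession)
        stats = finish_mod.final_qc(
            final, pairs, seed_k=config.seed_k, max_hits=config.max_hits
        )
        if reference_path is not None:
            reference = read_fasta(reference_path)
            ref_seq = "".join(r.seq for r in reference)
            stats.genome_fraction_percent = finish_mod.genome_fraction(
                final, ref_seq
            )
            stats.size_diff_percent, _within = finish_mod.size_vs_reference(
                final.total_length, len(ref_seq)
            )
        write_fasta(
            [SeqRecord(c.id, c.seq) for c in final.contigs], final_path
        )
        stats_dict = finish_mod.write_stats(
            stats, tsv_path=out_dir / "stats.tsv", json_path=stats_json
        )
        _marker(out_dir, "finish").touch()
        _log(log_handle, "finish", "done", **stats_dict)

    summary = {"stats": stats_dict, "final_fasta": str(final_path)}

    # --- stage: mlst (optional) ---
    if mlst_scheme_dir is not None:
        report_json = out_dir / "mlst.json"
        if _marker(out_dir, "mlst").exists() and report_json.exists():
            summary["mlst"] = json.loads(report_json.read_text())
            _log(log_handle, "mlst", "resumed")
        else:
            scheme = mlst_mod.load_scheme(mlst_scheme_dir)
            result = mlst_mod.type_assembly(final, scheme, seed_k=config.seed_k)
            summary["mlst"] = mlst_mod.write_report(
                result,
                config.accession,
                tsv_path=out_dir / "mlst.tsv",
                json_path=report_json,
            )
            _marker(out_dir, "mlst").touch()
            _log(log_handle, "mlst", "done", st=result.st,
                 contaminated=result.contaminated)

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    log_handle.close()
    return summary
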