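"""End-to-end orchestration: tile → design → ePCR ×2 → screen → report.

Every stage materializes a flat tab-delimited artifact and every stage
re-reads its inputs from those artifacts, so running the subcommands one at
a time produces byte-identical output to a single ``run`` — users can enter
or exit the pipeline at any stage.  All stages are deterministic functions
of their inputs and the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .core_io import ContigSet, PipelineConfig, read_fasta
from .tiling import Window, tile_contigs, write_windows_bed, read_windows_bed
from .primer_engine import PrimerPair, design_all
from .insilico_pcr import AmpliconHit, Site, build_index, amplify
from .marker_calling import (MarkerTable, call_markers, annotate_reference,
                             write_marker_table, read_marker_frame,
                             SIZE_CLASSES)

log = logging.getLogger("ampindel")

PRIMERS_HEADER = ("pair_id\tcontig\twindow_start\twindow_end\tfwd_start\trev_end\t"
                  "fwd_seq\trev_seq\tfwd_tm\trev_tm\tfwd_gc\trev_gc\tproduct\tpenalty")
HITS_HEADER = ("pair_id\tcontig\tstart\tend\tproduct\tfwd_pos\tfwd_strand\tfwd_mm\t"
               "rev_pos\trev_strand\trev_mm\ttotal_mm")


# ---------------------------------------------------------------------------
# Flat-file serialization of intermediate artifacts
# ---------------------------------------------------------------------------

def write_primers_tsv(pairs: Sequence[PrimerPair], path: "str | Path") -> None:
    with open(path, "w") as fh:
        fh.write(PRIMERS_HEADER + "\n")
        for p in pairs:
            fh.write(f"{p.pair_id}\t{p.contig_id}\t{p.window_start}\t{p.window_end}\t"
                     f"{p.fwd_start}\t{p.rev_end}\t{p.fwd_seq}\t{p.rev_seq}\t"
                     f"{p.fwd_tm:.3f}\t{p.rev_tm:.3f}\t{p.fwd_gc:.4f}\t{p.rev_gc:.4f}\t"
                     f"{p.designed_product}\t{p.penalty:.4f}\n")


def read_primers_tsv(path: "str | Path") -> list[PrimerPair]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != PRIMERS_HEADER:
        raise ValueError(f"{path}: not a primer-pool table")
    pairs = []
    for line in lines[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        pairs.append(PrimerPair(
            pair_id=f[0], contig_id=f[1], window_start=int(f[2]),
            window_end=int(f[3]), fwd_start=int(f[4]), rev_end=int(f[5]),
            fwd_seq=f[6], rev_seq=f[7], fwd_tm=float(f[8]), rev_tm=float(f[9]),
            fwd_gc=float(f[10]), rev_gc=float(f[11]),
            designed_product=int(f[12]), penalty=float(f[13])))
    return pairs


def write_hits_tsv(hits_per_pair: "dict[str, list[AmpliconHit]]",
                   path: "str | Path") -> None:
    with open(path, "w") as fh:
        fh.write(HITS_HEADER + "\n")
        for pair_id, hits in hits_per_pair.items():
            for h in hits:
                fh.write(f"{pair_id}\t{h.contig_id}\t{h.start}\t{h.end}\t{h.product}\t"
                         f"{h.fwd_site.pos}\t{h.fwd_site.strand}\t{h.fwd_site.mismatches}\t"
                         f"{h.rev_site.pos}\t{h.rev_site.strand}\t{h.rev_site.mismatches}\t"
                         f"{h.total_mismatches}\n")


def read_hits_tsv(path: "str | Path") -> "dict[str, list[AmpliconHit]]":
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != HITS_HEADER:
        raise ValueError(f"{path}: not an amplicon-hit table")
    hits: dict[str, list[AmpliconHit]] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        fwd = Site(f[1], int(f[5]), f[6], int(f[7]))
        rev = Site(f[1], int(f[8]), f[9], int(f[10]))
        hits.setdefault(f[0], []).append(
            AmpliconHit(f[1], int(f[2]), int(f[3]), int(f[4]), fwd, rev, int(f[11])))
    return hits


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_tile(source: ContigSet, config: PipelineConfig,
               out_bed: "str | Path") -> list[Window]:
    windows = tile_contigs(source, config.window_size, config.step)
    write_windows_bed(windows, out_bed)
    return windows


def stage_design(source: ContigSet, windows_bed: "str | Path",
                 config: PipelineConfig, out_tsv: "str | Path") -> list[PrimerPair]:
    windows = read_windows_bed(windows_bed, source)
    pairs = design_all(windows, config.primer_params)
    write_primers_tsv(pairs, out_tsv)
    return read_primers_tsv(out_tsv)


def stage_epcr(primers_tsv: "str | Path", genome: ContigSet,
               config: PipelineConfig, out_tsv: "str | Path"
               ) -> "dict[str, list[AmpliconHit]]":
    pairs = read_primers_tsv(primers_tsv)
    index = build_index(genome, config.seed_k)
    hits = {p.pair_id: amplify(p, genome, index, config) for p in pairs}
    n = sum(len(v) for v in hits.values())
    log.info("ePCR: %d hits for %d pairs on %d contigs", n, len(pairs), len(genome))
    write_hits_tsv(hits, out_tsv)
    return read_hits_tsv(out_tsv)


def stage_screen(primers_tsv: "str | Path", source_hits_tsv: "str | Path",
                 target_hits_tsv: "str | Path", config: PipelineConfig,
                 out_tsv: "str | Path",
                 reference: Optional[ContigSet] = None) -> MarkerTable:
    pairs = read_primers_tsv(primers_tsv)
    shits = read_hits_tsv(source_hits_tsv)
    thits = read_hits_tsv(target_hits_tsv)
    table = call_markers(pairs,
                         [shits.get(p.pair_id, []) for p in pairs],
                         [thits.get(p.pair_id, []) for p in pairs],
                         config)
    table = annotate_reference(table, reference, config)
    write_marker_table(table, out_tsv, summary=False)
    return table


def stage_report(markers_tsv: "str | Path", summary_path: "str | Path",
                 bed_path: "Optional[str | Path]" = None) -> None:
    df = read_marker_frame(markers_tsv)
    with open(summary_path, "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"total_indels\t{len(df)}\n")
        fh.write(f"optimum_markers\t{int(df['optimum'].sum()) if len(df) else 0}\n")
        mean = df["indel_size"].mean() if len(df) else 0.0
        fh.write(f"mean_size_bp\t{mean:.1f}\n")
        for cls in SIZE_CLASSES:
            n = int((df["size_class"] == cls).sum()) if len(df) else 0
            fh.write(f"class_{cls}\t{n}\n")
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for _, r in df.iterrows():
                start = int(r["source_start"]) - 1
                fh.write(f"{r['source_contig']}\t{start}\t"
                         f"{start + int(r['source_product'])}\t{r['marker_id']}\t"
                         f"{r['score']:.3f}\n")


# ---------------------------------------------------------------------------
# Single-command run
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Auditable record of one pipeline run: config, inputs, attrition, timing."""

    config: dict
    inputs: dict
    counts: dict = field(default_factory=dict)
    seconds: dict = field(default_factory=dict)

    def write(self, path: "str | Path") -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def _digest(path: "str | Path") -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(source_fasta: "str | Path", target_fasta: "str | Path",
                 config: PipelineConfig, out_dir: "str | Path",
                 reference_fasta: "Optional[str | Path]" = None
                 ) -> tuple[MarkerTable, RunManifest]:
    """Run every stage, writing all intermediate and final artifacts.

    Writes ``windows.bed``, ``primers.tsv``, ``hits_source.tsv``,
    ``hits_target.tsv``, ``markers.tsv``, ``markers.summary.tsv``,
    ``markers.bed`` and ``manifest.json`` into ``out_dir``.  Fully
    deterministic given inputs and config (manifest timing aside).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_flat_dict(),
        inputs={"source": _digest(source_fasta), "target": _digest(target_fasta),
                **({"reference": _digest(reference_fasta)} if reference_fasta else {})},
    )

    def timed(name, fn):
        t0 = time.perf_counter()
        result = fn()
        manifest.seconds[name] = round(time.perf_counter() - t0, 3)
        return result

    source = read_fasta(source_fasta)
    target = read_fasta(target_fasta)
    reference = read_fasta(reference_fasta) if reference_fasta else None
    manifest.counts["source_contigs"] = len(source)
    manifest.counts["target_contigs"] = len(target)

    windows = timed("tile", lambda: stage_tile(source, config, out / "windows.bed"))
    manifest.counts["windows"] = len(windows)

    pairs = timed("design", lambda: stage_design(
        source, out / "windows.bed", config, out / "primers.tsv"))
    manifest.counts["primer_pairs"] = len(pairs)

    shits = timed("epcr_source", lambda: stage_epcr(
        out / "primers.tsv", source, config, out / "hits_source.tsv"))
    thits = timed("epcr_target", lambda: stage_epcr(
        out / "primers.tsv", target, config, out / "hits_target.tsv"))
    manifest.counts["source_hits"] = sum(len(v) for v in shits.values())
    manifest.counts["target_hits"] = sum(len(v) for v in thits.values())

    table = timed("screen", lambda: stage_screen(
        out / "primers.tsv", out / "hits_source.tsv", out / "hits_target.tsv",
        config, out / "markers.tsv", reference=reference))
    manifest.counts["markers"] = len(table)
    manifest.counts["optimum_markers"] = sum(m.optimum for m in table)

    timed("report", lambda: stage_report(
        out / "markers.tsv", out / "markers.summary.tsv", out / "markers.bed"))

    manifest.write(out / "manifest.json")
    log.info("run complete: %s", json.dumps(manifest.counts))
    return table, manifest
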