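"""InDel marker calling, screening, ranking and reporting.

A primer pair becomes a marker when it amplifies in both genotypes with
different product sizes; the absolute size difference is the accrued InDel —
the net sum of all insertions and deletions between the primer sites.  A
marker is *optimum* when the amplicon is single-copy in both genotypes and
its accrued size exceeds ``min_indel`` (default 20 bp, i.e. >=21 bp), making
it unambiguous and easily resolvable on agarose gels.  Multi-copy markers
are reported but flagged, never optimum.

InDel sizes are binned 1–10 / 11–20 / 21–100 / >100 bp, and markers are
ranked by a value score rewarding large InDels (capped at 200 bp), locus
uniqueness, and primer quality:

    score = min(size, 200)/200 * 50 + (30 if optimum else 0) + max(0, 20 - penalty)

Overlapping windows rediscover the same polymorphism; duplicates are
collapsed (keeping the higher score) when two markers' source amplicons
overlap by more than half of the shorter, or overlap at all while measuring
the same signed product difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .core_io import ContigSet, PipelineConfig
from .insilico_pcr import AmpliconHit, build_index, amplify
from .primer_engine import PrimerPair

log = logging.getLogger("ampindel")

SIZE_CLASSES = ("1~10", "11~20", "21~100", ">100")

SCORE_SIZE_CAP = 200
SCORE_SIZE_WEIGHT = 50.0
SCORE_OPTIMUM_BONUS = 30.0
SCORE_QUALITY_WEIGHT = 20.0

DEDUP_OVERLAP_FRACTION = 0.5


def classify_indel_size(indel_size: int) -> str:
    """Bin an InDel size into 1~10 / 11~20 / 21~100 / >100 bp."""
    if indel_size < 1:
        raise ValueError("indel_size must be >= 1")
    if indel_size <= 10:
        return "1~10"
    if indel_size <= 20:
        return "11~20"
    if indel_size <= 100:
        return "21~100"
    return ">100"


@dataclass
class InDelMarker:
    """A primer pair with paired product sizes and the accrued InDel call."""

    marker_id: str
    pair: PrimerPair
    source_hit: AmpliconHit
    target_hit: AmpliconHit
    source_product: int
    target_product: int
    signed_diff: int          # target - source; >0 net insertion in target
    indel_size: int
    size_class: str
    source_copies: int
    target_copies: int
    optimum: bool
    score: float = 0.0
    ref_location: Optional[str] = None   # "contig:start" (1-based)
    ref_copies: Optional[int] = None


def score_marker(marker: InDelMarker) -> float:
    """Value score; higher is better, bounded by 100 at default weights."""
    size_term = min(marker.indel_size, SCORE_SIZE_CAP) / SCORE_SIZE_CAP * SCORE_SIZE_WEIGHT
    bonus = SCORE_OPTIMUM_BONUS if marker.optimum else 0.0
    quality = max(0.0, SCORE_QUALITY_WEIGHT - marker.pair.penalty)
    return size_term + bonus + quality


@dataclass
class MarkerTable:
    """Markers ordered by descending score, with a per-class summary."""

    markers: list[InDelMarker] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def summary(self) -> dict[str, object]:
        counts = {c: 0 for c in SIZE_CLASSES}
        for m in self.markers:
            counts[m.size_class] += 1
        total = len(self.markers)
        mean = (sum(m.indel_size for m in self.markers) / total) if total else 0.0
        return {
            "total": total,
            "optimum": sum(m.optimum for m in self.markers),
            "counts": counts,
            "mean_indel_size": mean,
        }


def _best_hit_pair(shits: Sequence[AmpliconHit], thits: Sequence[AmpliconHit]
                   ) -> tuple[AmpliconHit, AmpliconHit]:
    """Lowest-mismatch, then smallest |size difference| hit combination."""
    return min(
        ((s, t) for s in shits for t in thits),
        key=lambda st: (st[0].total_mismatches + st[1].total_mismatches,
                        abs(st[1].product - st[0].product),
                        st[0].start, st[1].start),
    )


def _overlap(a: AmpliconHit, b: AmpliconHit) -> int:
    if a.contig_id != b.contig_id:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _duplicates(a: InDelMarker, b: InDelMarker) -> bool:
    ov = _overlap(a.source_hit, b.source_hit)
    if ov == 0:
        return False
    shorter = min(a.source_hit.product, b.source_hit.product)
    if ov > DEDUP_OVERLAP_FRACTION * shorter:
        return True
    # same signed size change at overlapping loci: the same polymorphism
    # rediscovered from an adjacent overlapping window
    return a.signed_diff == b.signed_diff


def call_markers(pairs: Sequence[PrimerPair],
                 source_hits: Sequence[Sequence[AmpliconHit]],
                 target_hits: Sequence[Sequence[AmpliconHit]],
                 config: PipelineConfig) -> MarkerTable:
    """Mine InDel markers from paired per-primer-pair amplicon hits.

    ``source_hits[i]`` and ``target_hits[i]`` must belong to ``pairs[i]``.
    A pair contributes a marker iff it amplifies at least once in each
    genotype and the compared products differ.  Single-copy pairs compare
    their unique hits; multi-copy pairs compare their best hits but can never
    be optimum.
    """
    if not (len(pairs) == len(source_hits) == len(target_hits)):
        raise ValueError("pairs and hit sequences must align one-to-one")
    raw: list[InDelMarker] = []
    for pair, shits, thits in zip(pairs, source_hits, target_hits):
        if not shits or not thits:
            continue
        if len(shits) == 1 and len(thits) == 1:
            s, t = shits[0], thits[0]
        else:
            s, t = _best_hit_pair(shits, thits)
        diff = t.product - s.product
        if diff == 0:
            continue
        size = abs(diff)
        optimum = (len(shits) == 1 and len(thits) == 1
                   and size > config.min_indel)
        m = InDelMarker(
            marker_id="",
            pair=pair,
            source_hit=s,
            target_hit=t,
            source_product=s.product,
            target_product=t.product,
            signed_diff=diff,
            indel_size=size,
            size_class=classify_indel_size(size),
            source_copies=len(shits),
            target_copies=len(thits),
            optimum=optimum,
        )
        m.score = score_marker(m)
        raw.append(m)

    deduped = _dedup(raw)
    table = MarkerTable(_rank(deduped))
    s = table.summary()
    log.info("called %d markers (%d optimum) from %d pairs; mean InDel %.1f bp",
             s["total"], s["optimum"], len(pairs), s["mean_indel_size"])
    return table


def _sort_key(m: InDelMarker):
    return (-m.score, m.pair.contig_id, m.source_hit.start)


def _dedup(markers: list[InDelMarker]) -> list[InDelMarker]:
    kept: list[InDelMarker] = []
    for m in sorted(markers, key=_sort_key):
        if any(_duplicates(m, k) for k in kept):
            continue
        kept.append(m)
    return kept


def _rank(markers: list[InDelMarker]) -> list[InDelMarker]:
    ranked = sorted(markers, key=_sort_key)
    for i, m in enumerate(ranked):
        m.marker_id = f"M{i + 1:06d}"
    return ranked


def annotate_reference(table: MarkerTable, reference: Optional[ContigSet],
                       config: PipelineConfig) -> MarkerTable:
    """Map each marker's pair onto a reference genome for specificity screening.

    A unique reference hit records its location (1-based start); multiple
    hits demote the marker from optimum (the locus is not specific).  With no
    reference the table is returned unchanged.
    """
    if reference is None:
        return table
    index = build_index(reference, config.seed_k)
    demoted = 0
    for m in table.markers:
        hits = amplify(m.pair, reference, index, config)
        m.ref_copies = len(hits)
        if len(hits) == 1:
            m.ref_location = f"{hits[0].contig_id}:{hits[0].start + 1}"
        if len(hits) > 1 and m.optimum:
            m.optimum = False
            demoted += 1
        m.score = score_marker(m)
    if demoted:
        log.info("reference screening demoted %d markers from optimum", demoted)
    return MarkerTable(_rank(table.markers))


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

TABLE_COLUMNS = [
    "marker_id", "source_contig", "source_start", "fwd_primer", "rev_primer",
    "fwd_tm", "rev_tm", "source_product", "target_product", "indel_size",
    "size_class", "source_copies", "target_copies", "optimum", "score",
    "ref_location", "ref_copies",
]


def markers_to_frame(table: MarkerTable) -> pd.DataFrame:
    rows = []
    for m in table:
        rows.append({
            "marker_id": m.marker_id,
            "source_contig": m.source_hit.contig_id,
            "source_start": m.source_hit.start + 1,  # 1-based at the boundary
            "fwd_primer": m.pair.fwd_seq,
            "rev_primer": m.pair.rev_seq,
            "fwd_tm": round(m.pair.fwd_tm, 2),
            "rev_tm": round(m.pair.rev_tm, 2),
            "source_product": m.source_product,
            "target_product": m.target_product,
            "indel_size": m.indel_size,
            "size_class": m.size_class,
            "source_copies": m.source_copies,
            "target_copies": m.target_copies,
            "optimum": int(m.optimum),
            "score": round(m.score, 3),
            "ref_location": m.ref_location or "",
            "ref_copies": "" if m.ref_copies is None else m.ref_copies,
        })
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_marker_table(table: MarkerTable, path: "str | Path",
                       summary: bool = True) -> None:
    """Write the ranked marker table as tab-delimited text (with header).

    With ``summary=True`` a companion ``<path stem>.summary.tsv`` holds the
    per-size-class counts and mean InDel size.
    """
    path = Path(path)
    markers_to_frame(table).to_csv(path, sep="\t", index=False)
    if summary:
        write_summary(table, path.with_suffix(".summary.tsv"))


def write_summary(table: MarkerTable, path: "str | Path") -> None:
    s = table.summary()
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"total_indels\t{s['total']}\n")
        fh.write(f"optimum_markers\t{s['optimum']}\n")
        fh.write(f"mean_size_bp\t{s['mean_indel_size']:.1f}\n")
        for cls in SIZE_CLASSES:
            fh.write(f"class_{cls}\t{s['counts'][cls]}\n")


def read_marker_frame(path: "str | Path") -> pd.DataFrame:
    """Parse a written marker table back into a DataFrame (round-trip aid)."""
    return pd.read_csv(path, sep="\t", dtype={"ref_location": "string"},
                       keep_default_na=False, na_values=[])


def write_marker_bed(table: MarkerTable, path: "str | Path") -> None:
    """BED of marker source amplicon intervals (0-based, half-open)."""
    with open(path, "w") as fh:
        for m in table:
            fh.write(f"{m.source_hit.contig_id}\t{m.source_hit.start}\t"
                     f"{m.source_hit.end}\t{m.marker_id}\t{m.score:.3f}\n")
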