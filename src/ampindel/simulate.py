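"""Synthetic contig pairs with planted, truth-tracked InDels.

The generator emulates the real input of the pipeline — two de novo
assemblies of the same genome differing by insertions/deletions — at the
contig level (read simulation and assembly are outside the method's scope).
Sources are random i.i.d. nucleotide sequences at a target GC content,
optionally salted with duplicated segments to exercise the single-copy
screen; targets are the sources with a known edit list applied.

Placement physics (why edits are planted in window cores): a deletion is
detectable only when it lies strictly between the two primer binding sites,
and with forward/reverse candidates confined to the outer thirds of a window
the *guaranteed* straddled interior is the middle third (~window_size/3 bp).
The samplers therefore place edits inside the middle third of a tiled
window, and plant edits longer than that interior as insertions (which only
need their insertion point inside the interior).  Sampled lengths are
distinct within a run so every planted polymorphism has a unique signed
size signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core_io import Contig, ContigSet

log = logging.getLogger("ampindel")

BASES = np.array(list("ACGT"))

#: InDel size bins used throughout reporting, as (low, high) inclusive.
SIZE_BINS = ((1, 10), (11, 20), (21, 100), (101, 300))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def generate_contigs(n: int, mean_length: int, gc: float = 0.5,
                     repeat_fraction: float = 0.0, rng_seed: int = 0) -> ContigSet:
    """Random source contigs, reproducible from the seed.

    Contig lengths vary uniformly within ±20 % of ``mean_length``.  When
    ``repeat_fraction`` > 0, that fraction of total length is overwritten
    with copies of 500 bp segments sampled from the contigs themselves,
    creating exact duplications.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must be in (0, 1)")
    if not (0.0 <= repeat_fraction < 1.0):
        raise ValueError("repeat_fraction must be in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    seqs = []
    for i in range(n):
        length = int(round(mean_length * rng.uniform(0.8, 1.2))) if n > 1 else mean_length
        seqs.append(list(_random_seq(rng, length, gc)))
    total = sum(len(s) for s in seqs)
    if repeat_fraction > 0:
        seg_len = min(500, max(50, total // 20))
        n_copies = max(1, int(total * repeat_fraction / seg_len))
        for _ in range(n_copies):
            si = int(rng.integers(n))
            di = int(rng.integers(n))
            if len(seqs[si]) <= seg_len or len(seqs[di]) <= seg_len:
                continue
            spos = int(rng.integers(len(seqs[si]) - seg_len))
            dpos = int(rng.integers(len(seqs[di]) - seg_len))
            seqs[di][dpos:dpos + seg_len] = seqs[si][spos:spos + seg_len]
    contigs = ContigSet(
        [Contig(f"contig{i + 1}", "".join(s)) for i, s in enumerate(seqs)]
    )
    log.info("generated %d contigs, %d bp total (gc=%.2f, repeats=%.2f, seed=%d)",
             n, contigs.total_length, gc, repeat_fraction, rng_seed)
    return contigs


@dataclass(frozen=True)
class EditSpec:
    """One planted edit, positioned on the source (0-based)."""

    contig_id: str
    position: int
    kind: str                  # "insertion" or "deletion"
    length: int
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("edit length must be >= 1")
        if self.kind == "insertion" and len(self.inserted_seq) != self.length:
            raise ValueError("inserted_seq length must equal edit length")

    @property
    def source_span(self) -> tuple[int, int]:
        """Source interval occupied by the edit (a point for insertions)."""
        if self.kind == "deletion":
            return (self.position, self.position + self.length)
        return (self.position, self.position)

    @property
    def signed_size(self) -> int:
        """Product-size change in the target: + for insertion, - for deletion."""
        return self.length if self.kind == "insertion" else -self.length


@dataclass
class TruthTable:
    """Edit list plus, per edit, the source windows expected to span it."""

    edits: list[EditSpec]
    spanning: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    def attach_spans(self, window_size: int, step: int,
                     contig_lengths: dict[str, int]) -> None:
        """Record, per edit, the tiled windows whose guaranteed amplicon
        interior (the middle third of the window) contains the edit."""
        third = window_size // 3
        self.spanning = {}
        for i, e in enumerate(self.edits):
            L = contig_lengths[e.contig_id]
            spans = []
            lo, hi = e.source_span
            if lo == hi:
                hi = lo + 1  # insertion point must be interior
            start = 0
            while start + window_size <= L:
                core0, core1 = start + third, start + 2 * third
                if core0 <= lo and hi <= core1:
                    spans.append((start, start + window_size))
                start += step
            self.spanning[i] = spans


def _validated(edits: Sequence[EditSpec], contigs: ContigSet) -> list[EditSpec]:
    ordered = sorted(edits, key=lambda e: (contigs.index_of(e.contig_id), e.position))
    prev_end: dict[str, int] = {}
    for e in ordered:
        if e.contig_id not in contigs:
            raise ValueError(f"edit on unknown contig {e.contig_id!r}")
        L = len(contigs[e.contig_id])
        lo, hi = e.source_span
        if not (0 <= lo <= hi <= L):
            raise ValueError(f"edit out of range on {e.contig_id}: {lo}-{hi} vs {L}")
        if lo < prev_end.get(e.contig_id, -1):
            raise ValueError(f"overlapping edits on {e.contig_id} near {lo}")
        prev_end[e.contig_id] = max(hi, lo + 1)
    return ordered


def plant_edits(source: ContigSet, edits: Sequence[EditSpec]
                ) -> tuple[ContigSet, TruthTable]:
    """Apply edits to a copy of the source, right-to-left per contig.

    Right-to-left application means stated positions never need shifting.
    The returned target has total length
    ``len(source) + sum(insertions) - sum(deletions)``.
    """
    ordered = _validated(edits, source)
    per_contig: dict[str, list[EditSpec]] = {}
    for e in ordered:
        per_contig.setdefault(e.contig_id, []).append(e)
    out = []
    for contig in source:
        seq = contig.seq
        for e in reversed(per_contig.get(contig.id, [])):
            if e.kind == "deletion":
                seq = seq[:e.position] + seq[e.position + e.length:]
            else:
                seq = seq[:e.position] + e.inserted_seq + seq[e.position:]
        out.append(Contig(contig.id, seq, contig.description))
    target = ContigSet(out)
    log.info("planted %d edits; target %+d bp vs source",
             len(ordered), target.total_length - source.total_length)
    return target, TruthTable(edits=ordered)


def invert_edits(source: ContigSet, edits: Sequence[EditSpec]) -> list[EditSpec]:
    """Edits that undo ``edits`` when applied to the planted target."""
    ordered = _validated(edits, source)
    inverse: list[EditSpec] = []
    delta: dict[str, int] = {}
    for e in ordered:
        p = e.position + delta.get(e.contig_id, 0)
        if e.kind == "insertion":
            inverse.append(EditSpec(e.contig_id, p, "deletion", e.length))
            delta[e.contig_id] = delta.get(e.contig_id, 0) + e.length
        else:
            removed = source[e.contig_id].seq[e.position:e.position + e.length]
            inverse.append(EditSpec(e.contig_id, p, "insertion", e.length, removed))
            delta[e.contig_id] = delta.get(e.contig_id, 0) - e.length
    return inverse


def sample_edits(source: ContigSet, bin_counts: Sequence[int], rng_seed: int,
                 window_size: int = 300, step: int = 150,
                 window_gap: int = 3, gc: float = 0.5) -> list[EditSpec]:
    """Sample isolated edits spanning the size bins, aligned to window cores.

    ``bin_counts`` gives the number of edits per size bin
    (1–10, 11–20, 21–100, >100 bp).  Each edit is placed inside the middle
    third of a distinct tiled window, with chosen windows at least
    ``window_gap`` window indices apart so edits stay isolated (one per
    amplicon).  Deletions are only drawn where they fit the middle third;
    larger sizes are planted as insertions.  All sampled lengths are
    distinct.
    """
    if len(bin_counts) != len(SIZE_BINS):
        raise ValueError(f"bin_counts must have {len(SIZE_BINS)} entries")
    # spawn-keyed stream: decorrelated from generate_contigs even when the
    # caller reuses one seed for both (otherwise inserted sequences can
    # replay stretches of the source stream and duplicate primer sites)
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed, spawn_key=(1,)))
    third = window_size // 3
    del_max = third - 2

    lengths: list[int] = []
    for (lo, hi), count in zip(SIZE_BINS, bin_counts):
        if count > hi - lo + 1:
            raise ValueError(f"cannot draw {count} distinct lengths from bin {lo}-{hi}")
        lengths.extend(int(x) for x in
                       rng.choice(np.arange(lo, hi + 1), size=count, replace=False))

    # candidate windows: stepped windows, skipping the first and last of each
    # contig so edits sit clear of contig ends
    slots: list[tuple[str, int]] = []
    for contig in source:
        L = len(contig)
        idx = 0
        starts = []
        while idx * step + window_size <= L:
            starts.append(idx * step)
            idx += 1
        slots.extend((contig.id, s) for s in starts[1:-1])
    # thin to every window_gap-th slot so neighbouring edits never share an
    # amplicon, then sample
    spaced = slots[::window_gap]
    if len(spaced) < len(lengths):
        raise ValueError(
            f"source too small: {len(spaced)} isolated window slots for "
            f"{len(lengths)} edits")
    chosen = [spaced[i] for i in
              sorted(rng.choice(len(spaced), size=len(lengths), replace=False))]
    order = rng.permutation(len(lengths))

    edits: list[EditSpec] = []
    for (cid, wstart), li in zip(chosen, order):
        length = lengths[li]
        core0, core1 = wstart + third, wstart + 2 * third
        can_delete = length <= del_max
        kind = "deletion" if (can_delete and rng.random() < 0.5) else "insertion"
        if kind == "deletion":
            pos = int(rng.integers(core0 + 1, core1 - length))
            edits.append(EditSpec(cid, pos, "deletion", length))
        else:
            pos = int(rng.integers(core0 + 2, core1 - 2))
            edits.append(EditSpec(cid, pos, "insertion", length,
                                  _random_seq(rng, length, gc)))
    return sorted(edits, key=lambda e: (source.index_of(e.contig_id), e.position))


def write_truth_table(truth: TruthTable, path: "str | Path") -> None:
    """Tab-delimited truth dump: contig, 1-based position, kind, length."""
    with open(path, "w") as fh:
        fh.write("contig\tposition\tkind\tlength\n")
        for e in truth.edits:
            fh.write(f"{e.contig_id}\t{e.position + 1}\t{e.kind}\t{e.length}\n")
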