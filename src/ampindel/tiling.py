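"""Overlapping window generation along source contigs.

Primer pairs are designed per window, so overlapping windows give every locus
several chances at an amplicon and protect InDels near window edges.  Windows
start at multiples of ``step``; if the last stepped window does not reach the
contig end a final right-anchored window is appended so the union of windows
covers every base.  Contigs shorter than the window yield a single window
spanning the whole contig.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .core_io import ContigSet

log = logging.getLogger("ampindel")


@dataclass(frozen=True)
class Window:
    """A coordinate-addressed fragment of a source contig (0-based, half-open)."""

    contig_id: str
    start: int
    end: int
    seq: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")
        if len(self.seq) != self.end - self.start:
            raise ValueError("seq length must equal end - start")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_fraction(self) -> float:
        return self.seq.count("N") / len(self.seq)

    @property
    def high_n(self) -> bool:
        """Windows that are mostly N; emitted but unlikely to yield primers."""
        return self.n_fraction > 0.5


def tile_contigs(contigs: ContigSet, window_size: int, step: int) -> list[Window]:
    """Tile every contig with overlapping fixed-size windows.

    For a contig of length L >= window_size, windows start at
    0, step, 2*step, ... while ``start + window_size <= L``; a right-anchored
    terminal window ``[L - window_size, L)`` is appended when the stepped
    progression leaves a tail uncovered.  For L < window_size exactly one
    window ``[0, L)`` is emitted.  Output order is (input contig order,
    ascending start) and the result is a pure function of the inputs.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if not (1 <= step <= window_size):
        raise ValueError("step must be in [1, window_size]")
    windows: list[Window] = []
    for contig in contigs:
        L = len(contig)
        if L < window_size:
            windows.append(Window(contig.id, 0, L, contig.seq))
            continue
        starts = list(range(0, L - window_size + 1, step))
        if starts[-1] + window_size < L:
            starts.append(L - window_size)
        for s in starts:
            windows.append(Window(contig.id, s, s + window_size, contig.seq[s:s + window_size]))
    log.info("tiled %d contigs into %d windows (window=%d, step=%d)",
             len(contigs), len(windows), window_size, step)
    return windows


def write_windows_bed(windows: list[Window], path: "str | Path") -> None:
    """Dump windows as 3-column BED (contig, start, end) for inspection/chaining."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.contig_id}\t{w.start}\t{w.end}\n")


def read_windows_bed(path: "str | Path", contigs: ContigSet) -> list[Window]:
    """Rehydrate windows from a BED dump using the source contig sequences."""
    windows: list[Window] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 BED columns")
        cid, start, end = fields[0], int(fields[1]), int(fields[2])
        if cid not in contigs:
            raise ValueError(f"{path}:{lineno}: unknown contig {cid!r}")
        seq = contigs[cid].seq[start:end]
        windows.append(Window(cid, start, end, seq))
    return windows
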