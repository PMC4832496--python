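"""Mismatch-tolerant primer site search and in-silico amplification.

Primer binding sites are located by pigeonhole seeding over a k-mer index:
the primer is split into ``max_mismatch + 1`` contiguous segments; any
ungapped alignment within the mismatch budget leaves at least one segment
exact, and since every segment is at least ``k`` long its leading k-mer is an
exact, indexed seed.  Every seed hit is then verified by a full Hamming
comparison.  This makes the search provably equivalent to a brute-force scan
over every offset on both strands, provided
``len(primer) >= (max_mismatch + 1) * k``.

An N in the target counts as a mismatch.  The primer's 3'-terminal
``anchor3`` bases must match the template exactly (a 3' mismatch blocks
polymerase extension); ``anchor3 = 0`` restores pure Hamming matching.

Amplicons are convergent site pairs (one primer on each strand, 3' ends
facing) whose product — measured 5' end to 5' end — does not exceed the
product-size cap.  Both template orientations are enumerated, so results are
invariant under reverse-complementing the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core_io import ContigSet, PipelineConfig, reverse_complement
from .primer_engine import PrimerPair

log = logging.getLogger("ampindel")


class SeedIndex:
    """Exact k-mer index over the forward strand of a target ContigSet.

    Maps every N-free k-mer to the ascending list of ``(contig_index, pos)``
    occurrences.
    """

    def __init__(self, targets: ContigSet, k: int):
        if not (4 <= k <= 16):
            raise ValueError("seed length k must be in [4, 16]")
        self.k = k
        self.targets = targets
        self._seqs = [c.seq for c in targets]
        index: dict[str, list[tuple[int, int]]] = {}
        for ci, contig in enumerate(targets):
            seq = contig.seq
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos:pos + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((ci, pos))
        self.index = index

    def lookup(self, kmer: str) -> list[tuple[int, int]]:
        return self.index.get(kmer, [])


def build_index(targets: ContigSet, k: int = 6) -> SeedIndex:
    """Build a complete seed index of all N-free k-mers of the targets."""
    idx = SeedIndex(targets, k)
    log.info("indexed %d distinct %d-mers over %d contigs",
             len(idx.index), k, len(targets))
    return idx


@dataclass(frozen=True)
class Site:
    """One primer binding site.

    ``pos`` is the 0-based offset of the 5'-most base of the matched region
    on the forward strand; on the minus strand the primer's 3' end therefore
    maps to ``pos``.
    """

    contig_id: str
    pos: int
    strand: str  # '+' or '-'
    mismatches: int


def _hamming_within(a: str, target: str, pos: int, budget: int) -> int:
    """Mismatches of ``a`` vs ``target[pos:pos+len(a)]``; -1 if over budget.

    N in the target never matches.
    """
    mm = 0
    for i, c in enumerate(a):
        t = target[pos + i]
        if t != c or t == "N":
            mm += 1
            if mm > budget:
                return -1
    return mm


def _segment_starts(length: int, segments: int, k: int) -> list[int]:
    """Start offsets of ``segments`` contiguous, >=k-long primer segments."""
    bounds = [round(i * length / segments) for i in range(segments + 1)]
    starts = bounds[:-1]
    if any(b - a < k for a, b in zip(bounds, bounds[1:])):
        raise ValueError(
            f"primer of length {length} too short for {segments} segments of >= {k} bases"
        )
    return starts


def _scan_oriented(query: str, targets: ContigSet, index: SeedIndex,
                   max_mismatch: int, exact_prefix: int, exact_suffix: int
                   ) -> dict[int, dict[int, int]]:
    """Positions where ``query`` matches the forward strand within budget.

    ``exact_prefix``/``exact_suffix`` bases at the query ends must match
    exactly (used to express the 3' anchor for either orientation).  Returns
    {contig_index: {pos: mismatches}}.
    """
    k = index.k
    n = len(query)
    starts = _segment_starts(n, max_mismatch + 1, k)
    found: dict[int, dict[int, int]] = {}
    seen: set[tuple[int, int]] = set()
    for segstart in starts:
        seed = query[segstart:segstart + k]
        if "N" in seed:
            continue
        for ci, pos in index.lookup(seed):
            cand = pos - segstart
            if cand < 0 or (ci, cand) in seen:
                continue
            seen.add((ci, cand))
            seq = index._seqs[ci]
            if cand + n > len(seq):
                continue
            mm = _hamming_within(query, seq, cand, max_mismatch)
            if mm < 0:
                continue
            if exact_suffix and _hamming_within(query[-exact_suffix:], seq,
                                                cand + n - exact_suffix, 0) < 0:
                continue
            if exact_prefix and _hamming_within(query[:exact_prefix], seq, cand, 0) < 0:
                continue
            found.setdefault(ci, {})[cand] = mm
    return found


def find_sites(primer: str, targets: ContigSet, index: SeedIndex,
               max_mismatch: int, anchor3: int) -> list[Site]:
    """All binding sites of a primer on either strand of the targets.

    A site is an ungapped alignment with at most ``max_mismatch`` Hamming
    mismatches (N in the target counting as a mismatch) whose 3'-terminal
    ``anchor3`` bases match exactly.  Results are sorted by
    (contig input order, position, strand).
    """
    if "N" in primer:
        raise ValueError("primer contains N")
    need = (max_mismatch + 1) * index.k
    if len(primer) < need:
        raise ValueError(
            f"primer length {len(primer)} < (max_mismatch+1)*k = {need}; "
            "shorten the seed k or the mismatch budget"
        )
    if anchor3 > len(primer):
        raise ValueError("anchor3 longer than primer")
    ids = targets.ids
    sites: list[tuple[int, int, str, int]] = []
    plus = _scan_oriented(primer, targets, index, max_mismatch,
                          exact_prefix=0, exact_suffix=anchor3)
    for ci, posmap in plus.items():
        for pos, mm in posmap.items():
            sites.append((ci, pos, "+", mm))
    # Minus strand: the primer binds the reverse complement, i.e. rc(primer)
    # matches the forward strand; the primer's 3' end maps to the slice start.
    minus = _scan_oriented(reverse_complement(primer), targets, index,
                           max_mismatch, exact_prefix=anchor3, exact_suffix=0)
    for ci, posmap in minus.items():
        for pos, mm in posmap.items():
            sites.append((ci, pos, "-", mm))
    sites.sort(key=lambda s: (s[0], s[1], s[2]))
    return [Site(ids[ci], pos, strand, mm) for ci, pos, strand, mm in sites]


@dataclass(frozen=True)
class AmpliconHit:
    """One in-silico amplification event on a target contig.

    ``[start, end)`` is the product interval on the forward strand; the
    product size is measured from one primer's 5' end to the other's
    (``end - start``).
    """

    contig_id: str
    start: int
    end: int
    product: int
    fwd_site: Site
    rev_site: Site
    total_mismatches: int

    def __post_init__(self) -> None:
        if self.product != self.end - self.start:
            raise ValueError("product must equal end - start")


def amplify(pair: PrimerPair, targets: ContigSet, index: SeedIndex,
            config: PipelineConfig) -> list[AmpliconHit]:
    """Enumerate every amplicon a primer pair produces on the targets.

    Both convergent configurations are considered: forward primer on '+' with
    reverse on '-', and (template flipped) reverse primer on '+' with forward
    on '-'.  Products longer than ``config.max_product`` or shorter than the
    summed oligo lengths are discarded.  Hits are sorted by (contig input
    order, start).  An empty result is a valid outcome.
    """
    lf, lr = len(pair.fwd_seq), len(pair.rev_seq)
    fsites = find_sites(pair.fwd_seq, targets, index,
                        config.max_mismatch_per_primer, config.anchor3)
    rsites = find_sites(pair.rev_seq, targets, index,
                        config.max_mismatch_per_primer, config.anchor3)
    by_contig: dict[str, dict[str, list[Site]]] = {}
    for s in fsites:
        by_contig.setdefault(s.contig_id, {"f+": [], "f-": [], "r+": [], "r-": []})[
            "f+" if s.strand == "+" else "f-"].append(s)
    for s in rsites:
        by_contig.setdefault(s.contig_id, {"f+": [], "f-": [], "r+": [], "r-": []})[
            "r+" if s.strand == "+" else "r-"].append(s)

    hits: list[AmpliconHit] = []
    min_product = lf + lr
    for cid, groups in by_contig.items():
        # forward primer upstream on '+', reverse primer downstream on '-'
        for f in groups["f+"]:
            for r in groups["r-"]:
                start, end = f.pos, r.pos + lr
                product = end - start
                if min_product <= product <= config.max_product:
                    hits.append(AmpliconHit(cid, start, end, product, f, r,
                                            f.mismatches + r.mismatches))
        # template flipped: reverse primer upstream on '+', forward on '-'
        for r in groups["r+"]:
            for f in groups["f-"]:
                start, end = r.pos, f.pos + lf
                product = end - start
                if min_product <= product <= config.max_product:
                    hits.append(AmpliconHit(cid, start, end, product, f, r,
                                            f.mismatches + r.mismatches))
    hits.sort(key=lambda h: (targets.index_of(h.contig_id), h.start, h.end))
    return hits
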