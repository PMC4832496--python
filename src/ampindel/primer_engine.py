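"""Primer pair design and scoring within tiled windows.

Each window yields (at most) ``pairs_per_window`` primer pairs.  Forward
candidates are restricted to the first third of the window and reverse
candidates to the last third, so every admissible amplicon straddles the
middle third of the window — the core where InDels are measured.

Thermodynamics: duplex melting temperature from the unified nearest-neighbour
parameter set (ΔH/ΔS per dinucleotide stack plus terminal initiation terms),

    Tm = ΔH / (ΔS + ΔS_salt + R·ln(C/4)) − 273.15,

with the entropic monovalent-salt correction
ΔS_salt = 0.368·(N−1)·ln([Na+]) and total oligo concentration C.  Divalent
and dNTP corrections are deliberately omitted (documented limitation).

Candidate pairs are ranked by a penalty

    penalty = Σ_oligo |len − opt_len| + Σ_oligo |Tm − opt_Tm| + 10·GC-range excess

(lower is better), with ties broken by smaller product then leftmost forward
start.  Selection is exactly equivalent to exhaustive enumeration over every
legal (forward, reverse) candidate pair; a penalty-ordered search with an
early-exit bound just avoids evaluating dominated pairs.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from typing import Optional

from .core_io import PrimerParams, reverse_complement
from .tiling import Window

log = logging.getLogger("ampindel")

R_GAS = 1.987  # cal / (K * mol)

# Unified nearest-neighbour parameters: ΔH in kcal/mol, ΔS in cal/(mol*K),
# keyed by the 5'->3' dinucleotide on one strand (the complementary stack is
# identical by duplex symmetry).
NN_DH = {
    "AA": -7.9, "TT": -7.9,
    "AT": -7.2,
    "TA": -7.2,
    "CA": -8.5, "TG": -8.5,
    "GT": -8.4, "AC": -8.4,
    "CT": -7.8, "AG": -7.8,
    "GA": -8.2, "TC": -8.2,
    "CG": -10.6,
    "GC": -9.8,
    "GG": -8.0, "CC": -8.0,
}
NN_DS = {
    "AA": -22.2, "TT": -22.2,
    "AT": -20.4,
    "TA": -21.3,
    "CA": -22.7, "TG": -22.7,
    "GT": -22.4, "AC": -22.4,
    "CT": -21.0, "AG": -21.0,
    "GA": -22.2, "TC": -22.2,
    "CG": -27.2,
    "GC": -24.4,
    "GG": -19.9, "CC": -19.9,
}
# Terminal initiation terms, per duplex end.
INIT_DH = {"A": 2.3, "T": 2.3, "G": 0.1, "C": 0.1}
INIT_DS = {"A": 4.1, "T": 4.1, "G": -2.8, "C": -2.8}

MAX_TM_DIFF = 3.0   # °C allowed between forward and reverse Tm
W_LEN, W_TM, W_GC = 1.0, 1.0, 10.0  # penalty weights

MIN_TM_OLIGO_LEN = 8


def gc_fraction(seq: str) -> float:
    """G+C count divided by length; rejects empty or N-containing input."""
    if not seq:
        raise ValueError("empty oligo")
    if "N" in seq:
        raise ValueError("oligo contains N")
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(seq: str, monovalent_mM: float = 50.0,
                        oligo_nM: float = 250.0) -> float:
    """Nearest-neighbour duplex Tm in °C at the given reaction conditions."""
    if len(seq) < MIN_TM_OLIGO_LEN:
        raise ValueError(f"oligo shorter than {MIN_TM_OLIGO_LEN} nt")
    if "N" in seq:
        raise ValueError("oligo contains N")
    dh = INIT_DH[seq[0]] + INIT_DH[seq[-1]]
    ds = INIT_DS[seq[0]] + INIT_DS[seq[-1]]
    for i in range(len(seq) - 1):
        step = seq[i:i + 2]
        dh += NN_DH[step]
        ds += NN_DS[step]
    ds_salt = 0.368 * (len(seq) - 1) * math.log(monovalent_mM / 1000.0)
    ct = oligo_nM * 1e-9
    return (dh * 1000.0) / (ds + ds_salt + R_GAS * math.log(ct / 4.0)) - 273.15


def self_complementarity(seq: str) -> tuple[int, int]:
    """Self-annealing guard: longest ungapped self-complementary stretch.

    Returns ``(max_comp, max_3p_comp)``: the length of the longest contiguous
    run of matches between the oligo and its own reverse complement over all
    alignment offsets, and the same restricted to runs that include the
    oligo's 3'-terminal base.
    """
    if not seq:
        raise ValueError("empty oligo")
    rc = reverse_complement(seq)
    n = len(seq)
    best = best3 = 0
    for off in range(-(n - 1), n):
        run = 0
        for i in range(n):
            j = i + off
            if 0 <= j < n and seq[i] == rc[j]:
                run += 1
                if run > best:
                    best = run
                if i == n - 1 and run > best3:
                    best3 = run
            else:
                run = 0
    return best, best3


@dataclass(frozen=True)
class PrimerPair:
    """A designed forward/reverse oligo pair with its source product size.

    ``rev_seq`` is given 5'->3' on the minus strand, i.e. the reverse
    complement of the source slice ``[rev_end - len, rev_end)``.  Coordinates
    are 0-based offsets on the source contig.
    """

    pair_id: str
    contig_id: str
    window_start: int
    window_end: int
    fwd_seq: str
    rev_seq: str
    fwd_start: int
    rev_end: int
    designed_product: int
    fwd_tm: float
    rev_tm: float
    fwd_gc: float
    rev_gc: float
    penalty: float


class _Candidate:
    """One oligo candidate within a window (window-local coordinates)."""

    __slots__ = ("start", "end", "tm", "gc", "pen", "valid")

    def __init__(self, start: int, end: int, tm: float, gc: float, pen: float):
        self.start = start
        self.end = end
        self.tm = tm
        self.gc = gc
        self.pen = pen
        self.valid: Optional[bool] = None  # self-complementarity, checked lazily


def _oligo_penalty(length: int, tm: float, gc: float, p: PrimerParams) -> float:
    gc_excess = max(0.0, p.min_gc - gc) + max(0.0, gc - p.max_gc)
    # quantized so float summation order can never flip a genuine tie of the
    # (penalty, product, position) ranking
    return round(W_LEN * abs(length - p.opt_len)
                 + W_TM * abs(tm - p.opt_tm)
                 + W_GC * gc_excess, 6)


def _enumerate_candidates(seq: str, lo: int, hi: int, params: PrimerParams):
    """All oligo placements with both ends inside [lo, hi) passing hard bounds.

    Prefix sums over the window make Tm and GC O(1) per candidate.
    """
    n = len(seq)
    has_n = [False] * (n + 1)          # prefix count of N
    gc_pre = [0] * (n + 1)
    dh_pre = [0.0] * n                 # prefix sum of stack terms up to step i
    ds_pre = [0.0] * n
    nprev = gprev = 0
    for i, c in enumerate(seq):
        nprev += c == "N"
        gprev += c in "GC"
        has_n[i + 1] = nprev
        gc_pre[i + 1] = gprev
    for i in range(n - 1):
        step = seq[i:i + 2]
        if "N" in step:
            dh_pre[i + 1] = dh_pre[i]
            ds_pre[i + 1] = ds_pre[i]
        else:
            dh_pre[i + 1] = dh_pre[i] + NN_DH[step]
            ds_pre[i + 1] = ds_pre[i] + NN_DS[step]

    ds_salt_per = 0.368 * math.log(params.monovalent_mM / 1000.0)
    ln_ct = R_GAS * math.log(params.oligo_nM * 1e-9 / 4.0)
    out: list[_Candidate] = []
    for a in range(lo, hi - params.min_len + 1):
        max_b = min(hi, a + params.max_len)
        for b in range(a + params.min_len, max_b + 1):
            if has_n[b] - has_n[a]:
                continue
            length = b - a
            gc = (gc_pre[b] - gc_pre[a]) / length
            if not (params.min_gc <= gc <= params.max_gc):
                continue
            dh = INIT_DH[seq[a]] + INIT_DH[seq[b - 1]] + dh_pre[b - 1] - dh_pre[a]
            ds = INIT_DS[seq[a]] + INIT_DS[seq[b - 1]] + ds_pre[b - 1] - ds_pre[a]
            tm = (dh * 1000.0) / (ds + ds_salt_per * (length - 1) + ln_ct) - 273.15
            if not (params.min_tm <= tm <= params.max_tm):
                continue
            out.append(_Candidate(a, b, tm, gc,
                                  _oligo_penalty(length, tm, gc, params)))
    return out


def _self_comp_ok(oligo: str, params: PrimerParams) -> bool:
    comp, comp3 = self_complementarity(oligo)
    return comp <= params.max_self_comp and comp3 <= params.max_3p_self_comp


def design_primer_pairs(window: Window, params: PrimerParams,
                        pair_id_prefix: str = "P") -> list[PrimerPair]:
    """Design the best primer pairs for one window.

    Returns up to ``params.pairs_per_window`` pairs ranked by penalty with
    ties broken by (smaller product, leftmost forward start).  An empty
    result means the window admits no legal pair (e.g. N-rich or extreme
    composition) and is a valid outcome.
    """
    seq = window.seq
    L = len(seq)
    third = L // 3
    if third < params.min_len:
        return []
    fwd = _enumerate_candidates(seq, 0, third, params)
    rev = _enumerate_candidates(seq, L - third, L, params)
    if not fwd or not rev:
        return []
    fwd.sort(key=lambda c: (c.pen, c.start, c.end))
    rev.sort(key=lambda c: (c.pen, c.end, c.start))
    min_rev_pen = rev[0].pen

    keep_n = params.pairs_per_window
    kept: list[tuple[tuple[float, int, int, int], _Candidate, _Candidate]] = []

    def worst_pen() -> float:
        return kept[-1][0][0]

    for f in fwd:
        if len(kept) == keep_n and f.pen + min_rev_pen > worst_pen():
            break
        if f.valid is None:
            f.valid = _self_comp_ok(seq[f.start:f.end], params)
        if not f.valid:
            continue
        for r in rev:
            pen = f.pen + r.pen
            if len(kept) == keep_n and pen > worst_pen():
                break
            product = r.end - f.start
            if product < params.min_product or product > L:
                continue
            if abs(f.tm - r.tm) > MAX_TM_DIFF:
                continue
            if r.valid is None:
                r.valid = _self_comp_ok(reverse_complement(seq[r.start:r.end]), params)
            if not r.valid:
                continue
            key = (pen, product, f.start, r.end)
            entry = (key, f, r)
            if len(kept) < keep_n:
                kept.append(entry)
                kept.sort(key=lambda e: e[0])
            elif key < kept[-1][0]:
                kept[-1] = entry
                kept.sort(key=lambda e: e[0])

    pairs: list[PrimerPair] = []
    for rank, (key, f, r) in enumerate(kept):
        pairs.append(PrimerPair(
            pair_id=f"{pair_id_prefix}{rank}" if keep_n > 1 else pair_id_prefix,
            contig_id=window.contig_id,
            window_start=window.start,
            window_end=window.end,
            fwd_seq=seq[f.start:f.end],
            rev_seq=reverse_complement(seq[r.start:r.end]),
            fwd_start=window.start + f.start,
            rev_end=window.start + r.end,
            designed_product=key[1],
            fwd_tm=f.tm,
            rev_tm=r.tm,
            fwd_gc=f.gc,
            rev_gc=r.gc,
            penalty=key[0],
        ))
    return pairs


def design_all(windows: list[Window], params: PrimerParams,
               id_prefix: str = "P") -> list[PrimerPair]:
    """Design primers across all windows with sequential pair identifiers."""
    pairs: list[PrimerPair] = []
    for w in windows:
        for p in design_primer_pairs(w, params, pair_id_prefix="x"):
            pairs.append(dataclasses.replace(p, pair_id=f"{id_prefix}{len(pairs) + 1:06d}"))
    log.info("designed %d primer pairs from %d windows", len(pairs), len(windows))
    return pairs
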