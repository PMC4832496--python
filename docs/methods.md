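# Methods

## Overview

`ampindel` measures insertion/deletion polymorphism between two genotypes as
the difference in in-silico PCR product size at homologous loci. The method
never aligns the two assemblies base-by-base: it designs primer pairs on one
assembly (the *source*), locates their binding sites on the other (the
*target*) with limited mismatch tolerance, and compares product lengths.
Everything between the two primer sites is a black box, which is exactly
what makes the measurement robust on fragmented, reference-free assemblies
and what lets many small, linked InDels accrue into one large product-size
difference that is easy to score on an agarose gel.

Assumptions: the two inputs are assemblies of closely related genotypes of
the same genome, with primer flanks conserved up to a couple of mismatches;
structural differences other than InDels (inversions, translocations) are
not modelled — a locus rearranged between the genotypes simply fails to
amplify convergently and drops out.

## Pipeline stages and the parameters that matter

### Window tiling

Each source contig is tiled with windows of `window_size` (default 300 bp)
at stride `step` (default `window_size/2` = 150 bp), plus a right-anchored
terminal window so every base is covered. Half-window stride makes every
point interior to at least one window, protecting InDels near window edges.
Contigs shorter than one window become a single whole-contig window.
Windows that are mostly N are still emitted (tiling stays a pure geometry
stage); primer design rejects them naturally because oligos may not
contain N.

### Primer design

Within each window, forward oligo candidates are confined to the first
third and reverse candidates to the last third. This guarantees that every
admissible amplicon straddles the middle third of the window — the *core*
where size differences are measured. Candidates must satisfy, with defaults:

| parameter | default | meaning |
|---|---|---|
| length | 18–27 nt, optimum 20 | oligo length bounds |
| Tm | 57–63 °C, optimum 60 | nearest-neighbour duplex melting temperature |
| GC | 0.30–0.70 | composition bounds |
| self-complementarity | ≤ 8 nt (≤ 3 at the 3' end) | longest contiguous self-complementary stretch |
| product | ≥ 100 bp, ≤ window | designed amplicon bounds |
| ΔTm | ≤ 3 °C | forward/reverse compatibility |

These mirror widely used primer-design defaults so markers stay compatible
with a standard PCR protocol annealing near 58–60 °C.

Tm uses the unified nearest-neighbour ΔH/ΔS parameter set with terminal
initiation terms, the entropic monovalent-salt correction
0.368·(N−1)·ln[Na⁺], and total-strand concentration term R·ln(C_T/4)
(defaults 50 mM Na⁺, 250 nM oligo). Divalent-cation and dNTP corrections
are omitted; absolute Tm is therefore approximate, but the engine only uses
Tm comparatively and the implementation is verified to 10⁻⁶ °C against an
independent implementation of the same model.

Pairs are ranked by `penalty = Σ|len−20| + Σ|Tm−60| + 10·(GC-range excess)`
with ties broken by smaller product, then leftmost forward start. Oligo
penalties are quantized to 10⁻⁶ so floating-point summation order can never
flip a genuine tie. Selection is exactly equivalent to exhaustive
enumeration of all legal candidate pairs (property-tested); a
penalty-ordered search with an early-exit bound and lazily evaluated
self-complementarity merely skips dominated candidates. One pair per window
is kept by default: overlapping windows already provide locus redundancy.

### In-silico PCR

Binding sites are ungapped alignments with at most `max_mismatch` (default
2, i.e. "fewer than 3") Hamming mismatches per primer, N in the target
counting as a mismatch. The primer's 3'-terminal `anchor3` bases (default
3) must match exactly, because a 3' mismatch abolishes polymerase
extension; `anchor3 = 0` restores pure Hamming matching. The mismatch
budget is per primer; the summed per-pair mismatch count is also reported
for downstream screening.

Search is pigeonhole-seeded over an exact k-mer index of the target
(default k = 6): the primer is split into `max_mismatch + 1` contiguous
segments, each ≥ k long; any alignment within budget contains one exact
segment whose leading k-mer is an indexed seed, so seeding followed by full
verification is provably equivalent to a brute-force scan of every offset
on both strands. This requires `(max_mismatch+1)·k ≤ primer length`; k = 6
covers the default 18–27-mers at 2 mismatches with full sensitivity, which
a larger seed could not. Gapped primer binding is not modelled (18–27-mers;
bulged primers rarely prime well).

Amplicons are convergent site pairs — one primer on each strand, 3' ends
facing — with product measured 5' end to 5' end, capped at `max_product`
(default 1000 bp, single-pass PCR amplification ability; raise it to detect
longer insertions). Both template orientations are enumerated, so hit sets
are invariant under reverse-complementing a target contig.

### Marker calling and screening

A pair yields a marker iff it amplifies at least once in each genotype and
the compared products differ. Single-copy pairs compare their unique hits;
multi-copy pairs compare their best hits (fewest mismatches, then smallest
size difference) but can never be *optimum*. A marker is optimum iff it is
single-copy in source and target (and reference, when given) and its size
exceeds `min_indel` (default 20 bp — strictly greater, matching the
boundary between the 11–20 and 21–100 bins). The bins 1–10 / 11–20 /
21–100 / >100 bp partition all sizes; small and multi-copy markers are
reported and flagged rather than dropped, so totals and screens are both
available.

The rank score is a bounded combination of the three properties the optimum
screen cares about:

    score = min(size, 200)/200 × 50 + (30 if optimum) + max(0, 20 − penalty)

Large (gel-resolvable) InDels, locus uniqueness, primer quality; 100 is the
best possible. The cap at 200 bp reflects that beyond ~200 bp every gel
resolves the polymorphism equally well.

Overlapping windows rediscover the same polymorphism. Duplicates are
collapsed, keeping the higher score, when two markers' source amplicons
overlap by more than half of the shorter — or overlap at all while
measuring the same signed product difference. The second clause is needed
because adjacent-window amplicons straddling one edit can overlap by less
than half their length; the signed size signature identifies them as the
same polymorphism, while markers measuring different accrued sums at
overlapping loci are kept separate.

With a reference genome, each marker's pair is amplified against it: a
unique hit records the 1-based location; multiple hits demote the marker
from optimum (specificity screening). Scores and ranks are recomputed after
demotion.

## Synthetic data: what it emulates and what it does not

The generator produces random i.i.d. contigs at a target GC (default 0.5),
optionally salted with duplicated 500 bp segments to exercise the
single-copy screen, and plants a truth-tracked edit list (applied
right-to-left so positions never shift). It emulates the *contig-level*
input contract — two assemblies differing by isolated or clustered InDels —
not reads, sequencing error, assembly fragmentation/misassembly, or the
repeat structure of real plant genomes. Passing tests therefore demonstrate
correctness of tiling, design, site search, amplification and calling, not
end-to-end performance on large repeat-rich crop genomes, where assembly
quality and repeat content dominate.

Edit placement encodes the method's detection physics deliberately:

- A deletion is detectable only if it lies strictly between the primer
  sites, and the interior guaranteed for *every* admissible pair is the
  window's middle third (~100 bp at defaults). The sampler therefore places
  edits inside the middle third of a tiled window, making exact recovery a
  decidable property of the pipeline rather than of primer-placement luck.
- Detectable deletion size is bounded by that interior, while an insertion
  only needs its insertion *point* inside it (bounded instead by
  `max_product` minus the designed product). Edits over 100 bp are planted
  as insertions for this reason. Detecting deletions beyond ~window/3
  requires a larger `window_size` — a real limitation of the method, not of
  the fixture.
- Sampled lengths are all distinct, so the signed-difference deduplication
  clause cannot merge markers of different edits; chosen windows are spaced
  ≥ 3 window indices apart so each amplicon contains at most one edit
  (a separate clustered fixture exercises accrual).
- The sampler draws from a spawn-keyed RNG stream so that reusing one seed
  for both genome and edits cannot replay source sequence into inserted
  sequence (which would silently duplicate primer sites).

Validation scales (chosen as the package's own test design): exact recovery
uses a 100 kb repeat-free genome with 40 isolated edits, 10 per size bin;
site-search equivalence uses 500 20-mers against a 5 kb target; accrual
uses a +30 bp insertion and −80 bp deletion in one amplicon (net 50 bp).

## Numerical and degenerate-case choices

- All internal coordinates are 0-based half-open; tables report 1-based
  starts. Conversion happens only at the reporting boundary.
- Sort orders are total and deterministic everywhere (input contig order,
  position, strand; score descending with (contig, start) tie-break), so
  repeated runs and chained subcommands are byte-identical.
- An empty design result, an empty hit list and an empty marker table are
  valid outcomes, propagated as header-only files and zero-count summaries.
- IUPAC ambiguity codes other than N are rejected on input rather than
  converted: the supported assemblers emit only ACGTN, and silent
  conversion would corrupt primer thermodynamics.
- `find_sites` refuses primers shorter than `(max_mismatch+1)·k` instead of
  silently losing sensitivity.

## Known limitations

- Ungapped primer-site matching only; no secondary-structure ΔG, mispriming
  libraries or internal probes (not full Primer3 parity).
- Net-sum semantics: equal-sized linked insertion and deletion inside one
  amplicon cancel to zero and are invisible, and breakpoint positions are
  not resolved — the method measures size difference per amplicon.
- Tm omits divalent/dNTP corrections.
- Marker totals depend on assembly quality and repeat content of real
  inputs; the synthetic fixtures do not model either.
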