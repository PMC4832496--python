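"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import numpy as np
import pytest

from ampindel import Contig, ContigSet, reverse_complement


def random_dna(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


def brute_force_sites(primer: str, contigs: ContigSet, max_mismatch: int,
                      anchor3: int) -> set[tuple[str, int, str, int]]:
    """Quadratic-scan oracle for primer binding sites.

    Vectorized full Hamming scan over every offset and both strands, with N
    in the target counting as a mismatch and the primer's 3'-terminal
    ``anchor3`` bases required to match exactly.  Independent of the seeded
    search it checks.
    """
    out: set[tuple[str, int, str, int]] = set()
    for contig in contigs:
        t = np.frombuffer(contig.seq.encode(), dtype=np.uint8)
        n_mask = t == ord("N")
        for strand, query in (("+", primer), ("-", reverse_complement(primer))):
            q = np.frombuffer(query.encode(), dtype=np.uint8)
            n_off = len(t) - len(q) + 1
            if n_off <= 0:
                continue
            # on '+' the primer 3' end is the query suffix; on '-' the query
            # is rc(primer), whose prefix is the primer 3' end
            anchor = (set(range(len(q) - anchor3, len(q))) if strand == "+"
                      else set(range(anchor3)))
            mm = np.zeros(n_off, dtype=np.int32)
            amm = np.zeros(n_off, dtype=np.int32)
            for i in range(len(q)):
                bad = (t[i:i + n_off] != q[i]) | n_mask[i:i + n_off]
                mm += bad
                if i in anchor:
                    amm += bad
            hits = np.nonzero((mm <= max_mismatch) & (amm == 0))[0]
            for pos in hits:
                out.add((contig.id, int(pos), strand, int(mm[pos])))
    return out


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20260923)


@pytest.fixture
def small_contigs(rng) -> ContigSet:
    return ContigSet([
        Contig("c1", random_dna(rng, 2000)),
        Contig("c2", random_dna(rng, 900)),
    ])
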