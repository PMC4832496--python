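"""Sequence containers, FASTA I/O and run configuration.

Inputs are de novo assembled contigs (one FASTA per genotype).  Assemblers in
common use emit only the alphabet {A, C, G, T, N}; IUPAC ambiguity codes other
than N are rejected on load rather than silently converted, because a silent
conversion would corrupt primer thermodynamics downstream.

Coordinate convention: every coordinate held in memory is 0-based, half-open.
Conversion to 1-based inclusive happens only where tables are written.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("ampindel")

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class SequenceError(ValueError):
    """Raised for malformed sequence input (bad alphabet, duplicates, empty)."""


@dataclass(frozen=True)
class Contig:
    """One named nucleotide sequence (uppercase, alphabet {A,C,G,T,N})."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


class ContigSet:
    """Ordered collection of contigs with unique identifiers.

    The unit of genotype input: one ContigSet per assembled genotype (and,
    optionally, one for the reference genome used in specificity screening).
    """

    def __init__(self, records: "list[Contig] | tuple[Contig, ...]" = ()):
        self._records: list[Contig] = []
        self._by_id: dict[str, int] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: Contig) -> None:
        if record.id in self._by_id:
            raise SequenceError(f"duplicate identifier {record.id!r}")
        if not record.seq:
            raise SequenceError(f"record {record.id!r}: empty sequence")
        seq = record.seq.upper()
        bad = next((i for i, c in enumerate(seq) if c not in VALID_BASES), None)
        if bad is not None:
            raise SequenceError(
                f"record {record.id!r}: illegal character {seq[bad]!r} "
                f"at position {bad + 1}"
            )
        if seq is not record.seq:
            record = dataclasses.replace(record, seq=seq)
        self._by_id[record.id] = len(self._records)
        self._records.append(record)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[Contig]:
        return iter(self._records)

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._by_id

    def __getitem__(self, contig_id: str) -> Contig:
        return self._records[self._by_id[contig_id]]

    def index_of(self, contig_id: str) -> int:
        """Position of a contig in input order (used for stable sorting)."""
        return self._by_id[contig_id]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self._records]

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self._records)


def read_fasta(path: "str | Path") -> ContigSet:
    """Read a FASTA file into a ContigSet.

    Sequences are uppercased; header text after the first whitespace is kept
    as the record description but is unused downstream.  Duplicate
    identifiers, empty sequences and characters outside {A,C,G,T,N} raise
    :class:`SequenceError` naming the record and offending position.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    contigs = ContigSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        contigs.add(Contig(id=rec.id, seq=str(rec.seq), description=rec.description))
    log.info("read %d contigs (%d bp) from %s", len(contigs), contigs.total_length, path)
    return contigs


def write_fasta(contigs: ContigSet, path: "str | Path") -> None:
    """Write a ContigSet as FASTA with 60-column line wrapping.

    Round-trip contract: ``read_fasta`` on the written file reproduces every
    identifier and sequence exactly.
    """
    records = [
        SeqRecord(Seq(c.seq), id=c.id, description=c.description)
        for c in contigs
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class PrimerParams:
    """Primer design constraints and reaction conditions.

    Defaults mirror the widely used primer-design conventions so that emitted
    markers stay wet-lab plausible (length 18–27 nt around an optimum of 20,
    Tm 57–63 °C around 60 °C, GC 30–70 %).  ``monovalent_mM`` and ``oligo_nM``
    parameterize the nearest-neighbour melting-temperature model.
    """

    min_len: int = 18
    opt_len: int = 20
    max_len: int = 27
    min_tm: float = 57.0
    opt_tm: float = 60.0
    max_tm: float = 63.0
    min_gc: float = 0.30
    max_gc: float = 0.70
    max_self_comp: int = 8
    max_3p_self_comp: int = 3
    min_product: int = 100
    monovalent_mM: float = 50.0
    oligo_nM: float = 250.0
    pairs_per_window: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.opt_len <= self.max_len):
            raise ValueError("require 0 < min_len <= opt_len <= max_len")
        if not (self.min_tm <= self.opt_tm <= self.max_tm):
            raise ValueError("require min_tm <= opt_tm <= max_tm")
        if not (0.0 <= self.min_gc <= self.max_gc <= 1.0):
            raise ValueError("require 0 <= min_gc <= max_gc <= 1")
        if self.min_product < 1:
            raise ValueError("min_product must be >= 1")
        if self.pairs_per_window < 1:
            raise ValueError("pairs_per_window must be >= 1")
        if self.monovalent_mM <= 0 or self.oligo_nM <= 0:
            raise ValueError("reaction-condition concentrations must be positive")


@dataclass
class PipelineConfig:
    """Configuration for a full marker-discovery run.

    window_size
        Sliding-window (in-silico amplicon design) width in bp.
    step
        Window stride; defaults to ``window_size // 2`` so that every point of
        a contig is interior to at least one window.
    max_product
        Cap on in-silico product size in bp; bounded by single-pass PCR
        amplification ability, so insertions can grow a product only up to
        this length.
    max_mismatch_per_primer
        Hamming mismatches tolerated per primer when locating binding sites.
    anchor3
        Number of 3'-terminal primer bases required to match the template
        exactly (a 3' mismatch abolishes extension in real PCR).  0 restores
        pure Hamming matching.
    min_indel
        Markers with accrued InDel size strictly greater than this are
        eligible for "optimum" status (gel-resolvable polymorphisms).
    seed_k
        Seed length of the k-mer index used for mismatch-tolerant site
        search.  Full sensitivity requires
        ``(max_mismatch_per_primer + 1) * seed_k <= primer length``.
    """

    window_size: int = 300
    step: "int | None" = None
    max_product: int = 1000
    max_mismatch_per_primer: int = 2
    anchor3: int = 3
    min_indel: int = 20
    seed_k: int = 6
    primer_params: PrimerParams = field(default_factory=PrimerParams)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.step is None:
            self.step = max(1, self.window_size // 2)
        if self.window_size < self.primer_params.max_len * 2 + 1:
            raise ValueError(
                "window_size must be >= 2*max primer length + 1 "
                f"({self.primer_params.max_len * 2 + 1})"
            )
        if not (1 <= self.step <= self.window_size):
            raise ValueError("step must be in [1, window_size]")
        if self.max_product < self.window_size:
            raise ValueError("max_product must be >= window_size")
        if self.max_mismatch_per_primer < 0:
            raise ValueError("max_mismatch_per_primer must be >= 0")
        if self.anchor3 < 0:
            raise ValueError("anchor3 must be >= 0")
        if self.min_indel < 0:
            raise ValueError("min_indel must be >= 0")
        if not (4 <= self.seed_k <= 16):
            raise ValueError("seed_k must be in [4, 16]")
        if self.primer_params.min_product > self.window_size:
            raise ValueError("primer min_product must be <= window_size")

    # -- flat key=value config files -------------------------------------

    _INT_KEYS = {
        "window_size", "step", "max_product", "max_mismatch_per_primer",
        "anchor3", "min_indel", "seed_k", "rng_seed",
    }
    _PRIMER_INT_KEYS = {
        "min_len", "opt_len", "max_len", "max_self_comp", "max_3p_self_comp",
        "min_product", "pairs_per_window",
    }
    _PRIMER_FLOAT_KEYS = {
        "min_tm", "opt_tm", "max_tm", "min_gc", "max_gc",
        "monovalent_mM", "oligo_nM",
    }

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "PipelineConfig":
        """Build a config from flat string key=value pairs (e.g. a config file)."""
        top: dict[str, object] = {}
        primer: dict[str, object] = {}
        for key, raw in mapping.items():
            if key in cls._INT_KEYS:
                top[key] = int(raw)
            elif key in cls._PRIMER_INT_KEYS:
                primer[key] = int(raw)
            elif key in cls._PRIMER_FLOAT_KEYS:
                primer[key] = float(raw)
            else:
                raise ValueError(f"unknown configuration key {key!r}")
        return cls(primer_params=PrimerParams(**primer), **top)

    def to_flat_dict(self) -> dict[str, object]:
        d = {k: getattr(self, k) for k in sorted(self._INT_KEYS)}
        d.update({k: getattr(self.primer_params, k)
                  for k in sorted(self._PRIMER_INT_KEYS | self._PRIMER_FLOAT_KEYS)})
        return d


def load_config_file(path: "str | Path") -> dict[str, str]:
    """Parse a flat ``key=value`` config file; '#' starts a comment."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        mapping[key] = value
    return mapping
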