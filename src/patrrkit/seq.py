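"""Sequence and region primitives.

Coordinates are 1-based inclusive everywhere in the public API, matching the
convention used for genomic spans such as "positions 911-1964"; BED output
converts to 0-based half-open.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence, Union

from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input; carries the offending line number."""


class CoordinateError(ValueError):
    """Raised when a region falls outside its sequence."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An uppercase DNA sequence over {A,C,G,T,N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-ACGTN residues: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    @classmethod
    def from_raw(cls, id: str, raw: str) -> "NucleotideSequence":
        """Normalize arbitrary nucleotide text: uppercase, U->T, other IUPAC -> N."""
        s = raw.upper().replace("U", "T")
        if set(s) - ALPHABET:
            n_mapped = sum(1 for c in s if c not in ALPHABET)
            logger.warning(
                "sequence %r: %d ambiguous/IUPAC residues mapped to N", id, n_mapped
            )
            s = "".join(c if c in ALPHABET else "N" for c in s)
        return cls(id=id, residues=s)


@dataclass(frozen=True)
class GenomicRegion:
    """1-based inclusive coordinate span with strand."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise CoordinateError(
                f"invalid region {self.seq_id}:{self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start + 1

    def to_bed_fields(self, score: Union[int, float] = 0) -> tuple:
        """BED6 fields (0-based half-open)."""
        return (self.seq_id, self.start - 1, self.end, ".", score, self.strand)


@dataclass(frozen=True)
class CompositionProfile:
    counts: dict
    length: int

    @property
    def at_fraction(self) -> float:
        return (self.counts.get("A", 0) + self.counts.get("T", 0)) / self.length

    @property
    def gc_fraction(self) -> float:
        return (self.counts.get("G", 0) + self.counts.get("C", 0)) / self.length

    @property
    def n_fraction(self) -> float:
        return self.counts.get("N", 0) / self.length


def read_fasta(path: Union[str, Path]) -> List[NucleotideSequence]:
    """Read a FASTA file into normalized :class:`NucleotideSequence` records.

    Residues are uppercased, U mapped to T, and any other IUPAC ambiguity
    codes mapped to N with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if not text.strip():
        raise FastaFormatError(f"{path}: empty file (line 1)")
    first = next(i for i, ln in enumerate(text.splitlines(), 1) if ln.strip())
    if not text.splitlines()[first - 1].startswith(">"):
        raise FastaFormatError(f"{path}: expected '>' header at line {first}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(NucleotideSequence.from_raw(rec.id, str(rec.seq)))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found (line 1)")
    return records


def write_fasta(path: Union[str, Path], seqs: Iterable[NucleotideSequence],
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i:i + width] + "\n")


def reverse_complement(seq: Union[str, NucleotideSequence]) -> Union[str, NucleotideSequence]:
    """Reverse complement; N maps to N. Returns the same type it is given."""
    if isinstance(seq, NucleotideSequence):
        return NucleotideSequence(seq.id + "_rc",
                                  seq.residues.translate(_COMPLEMENT)[::-1])
    return seq.translate(_COMPLEMENT)[::-1]


def extract_region(seq: NucleotideSequence, region: GenomicRegion) -> NucleotideSequence:
    """Extract a 1-based inclusive span; minus strand returns the reverse complement."""
    if region.start < 1 or region.end > seq.length:
        raise CoordinateError(
            f"region {region.start}-{region.end} outside sequence "
            f"{seq.id!r} of length {seq.length}"
        )
    sub = seq.residues[region.start - 1:region.end]
    if region.strand == "-":
        sub = sub.translate(_COMPLEMENT)[::-1]
    return NucleotideSequence(
        f"{seq.id}:{region.start}-{region.end}({region.strand})", sub)


def composition(seq: Union[str, NucleotideSequence]) -> CompositionProfile:
    s = seq.residues if isinstance(seq, NucleotideSequence) else seq
    if not s:
        raise ValueError("composition of empty sequence is undefined")
    return CompositionProfile(counts=dict(Counter(s)), length=len(s))


def find_at_rich_segments(seq: NucleotideSequence, window: int = 100,
                          at_threshold: float = 0.85,
                          min_len: int = 300) -> List[GenomicRegion]:
    """Locate maximal A+T-rich segments by merging qualifying sliding windows.

    Every window of the given width whose A+T fraction is at or above the
    threshold is marked; overlapping/adjacent marked windows are merged, and
    merged spans shorter than ``min_len`` are dropped. Regions are disjoint
    and sorted by start. A threshold of 0 returns the whole sequence.
    """
    if window < 9:
        raise ValueError("window must be >= 9")
    if not (0 <= at_threshold <= 1):
        raise ValueError("at_threshold must be in [0,1]")
    n = seq.length
    if at_threshold == 0:
        return [GenomicRegion(seq.id, 1, n)]
    if n < window:
        return []
    s = seq.residues
    is_at = [1 if c in "AT" else 0 for c in s]
    # prefix sums for O(1) window AT counts
    pref = [0]
    for v in is_at:
        pref.append(pref[-1] + v)
    need = at_threshold * window
    spans = []
    for i in range(n - window + 1):
        if pref[i + window] - pref[i] >= need - 1e-12:
            start, end = i + 1, i + window  # 1-based inclusive
            if spans and start <= spans[-1][1] + 1:
                spans[-1][1] = end
            else:
                spans.append([start, end])
    return [GenomicRegion(seq.id, a, b) for a, b in spans if b - a + 1 >= min_len]


def write_bed(path: Union[str, Path], seq: NucleotideSequence,
              regions: Sequence[GenomicRegion]) -> None:
    """Write regions as BED6; score column is A+T percent x 10, rounded."""
    with open(path, "w") as fh:
        for r in regions:
            at = composition(extract_region(seq, GenomicRegion(
                r.seq_id, r.start, r.end))).at_fraction
            fields = r.to_bed_fields(score=round(at * 1000))
            fh.write("\t".join(str(x) for x in fields) + "\n")
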