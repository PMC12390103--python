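"""Sequence and annotation I/O, coordinates, translation.

Every stage of the screen speaks in :class:`GenomicInterval` — a 1-based,
inclusive, strand-aware span on a genome.  Internally coordinates are always
stored as ``low <= high`` plus a strand; the report layer converts to the
5'-start convention (Start > End on the minus strand) used by the tabular
outputs, and to GFF3.

Translation uses the bacterial/archaeal genetic code (NCBI table 11) with
start codons ATG/GTG/TTG; the initiator codon is rendered as M regardless of
the underlying codon and the terminal stop is excluded from the product.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.Data.CodonTable import TranslationError

__all__ = [
    "FormatError",
    "GenomicInterval",
    "GenomeRecord",
    "GeneAnnotation",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "reverse_complement",
    "translate_orf",
    "extract",
    "START_CODONS",
    "STOP_CODONS",
]

VALID_BASES = frozenset("ACGTN")
START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = frozenset(("TAA", "TAG", "TGA"))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised on malformed input files (FASTA, GFF3, tabular hits)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, inclusive, strand-aware span.

    ``low <= high`` always; ``strand`` is +1 or -1.  The 5' end of the span
    is ``low`` on the plus strand and ``high`` on the minus strand.
    """

    low: int
    high: int
    strand: int = 1

    def __post_init__(self) -> None:
        if self.low < 1:
            raise ValueError(f"low must be >= 1, got {self.low}")
        if self.high < self.low:
            raise ValueError(f"high ({self.high}) < low ({self.low})")
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand}")

    @property
    def length(self) -> int:
        return self.high - self.low + 1

    @property
    def five_prime(self) -> int:
        """Position of the 5'-most base on this interval's strand."""
        return self.low if self.strand == 1 else self.high

    @property
    def three_prime(self) -> int:
        """Position of the 3'-most base on this interval's strand."""
        return self.high if self.strand == 1 else self.low

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two spans share at least one position (any strand)."""
        return self.low <= other.high and other.low <= self.high

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap in nucleotides between two spans; 0 when they touch or overlap."""
        if self.overlaps(other):
            return 0
        if other.low > self.high:
            return other.low - self.high - 1
        return self.low - other.high - 1

    def as_start_end(self) -> tuple[int, int]:
        """(Start, End) in the 5'-first reporting convention."""
        return (self.five_prime, self.three_prime)

    @classmethod
    def from_start_end(cls, start: int, end: int, strand: int | None = None) -> "GenomicInterval":
        """Build from 5'-first (Start, End) coordinates.

        When ``strand`` is omitted it is inferred from the coordinate order
        (Start > End implies minus strand, as in the tabular reports).
        """
        if strand is None:
            strand = 1 if start <= end else -1
        return cls(min(start, end), max(start, end), strand)


@dataclass(frozen=True)
class GenomeRecord:
    """A named nucleotide sequence over {A,C,G,T,N}, linear or circular."""

    identifier: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.identifier!r}")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear or circular, got {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneAnnotation:
    """A located feature from an annotation file (for the operon check)."""

    interval: GenomicInterval
    feature_kind: str
    identifier: str


def _clean_sequence(raw: str, name: str, invalid: str) -> str:
    seq = raw.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        if invalid == "to_n":
            table = str.maketrans({c: "N" for c in bad})
            seq = seq.translate(table)
        else:
            raise FormatError(
                f"record {name!r} contains non-nucleotide characters "
                f"{sorted(bad)}; expected only A,C,G,T,N"
            )
    return seq


def read_fasta(path: str | Path, invalid: str = "error", topology: str = "linear") -> list[GenomeRecord]:
    """Read a nucleotide FASTA file into :class:`GenomeRecord` objects.

    Parameters
    ----------
    path:
        FASTA file; one record per header.  Sequences are uppercased.
    invalid:
        ``"error"`` rejects characters outside {A,C,G,T,N}; ``"to_n"`` maps
        them to N.
    topology:
        Applied to every record (``linear`` or ``circular``).
    """
    if invalid not in ("error", "to_n"):
        raise ValueError("invalid must be 'error' or 'to_n'")
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _clean_sequence(str(rec.seq), rec.id, invalid)
        if not seq:
            raise FormatError(f"record {rec.id!r} in {path} has an empty sequence")
        records.append(GenomeRecord(rec.id, seq, topology))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[GenomeRecord], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.identifier}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_annotations(path: str | Path, feature_kinds: tuple[str, ...] = ("gene", "CDS")) -> list[GeneAnnotation]:
    """Read gene annotations from a GFF3 file (for the operon-proximity check)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out: list[GeneAnnotation] = []
    for kind in feature_kinds:
        for feat in db.features_of_type(kind):
            strand = 1 if feat.strand != "-" else -1
            ident = feat.id or f"{kind}:{feat.start}-{feat.end}"
            out.append(GeneAnnotation(GenomicInterval(feat.start, feat.end, strand), kind, ident))
    out.sort(key=lambda a: (a.interval.low, a.interval.high))
    return out


def reverse_complement(sequence: str) -> str:
    """Watson–Crick reverse complement; N maps to N.  An involution."""
    bad = set(sequence.upper()) - VALID_BASES
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def translate_orf(orf_nucleotides: str) -> str:
    """Translate a complete ORF under the bacterial code (table 11).

    The input must start with a permitted start codon, end with a stop codon,
    and contain no internal stop.  The initiator is rendered M and the
    terminal stop is excluded, so the product has ``len/3 - 1`` residues.
    """
    seq = orf_nucleotides.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"ORF length {len(seq)} is not divisible by 3")
    try:
        return str(Seq(seq).translate(table=11, cds=True))
    except TranslationError as exc:
        raise ValueError(f"invalid ORF: {exc}") from exc


def extract(genome: GenomeRecord, interval: GenomicInterval) -> str:
    """Sequence of ``interval`` read 5'→3' on its strand.

    On circular genomes an interval may wrap the origin, represented with
    ``high`` exceeding the genome length (positions taken modulo length);
    on linear genomes that is an error.
    """
    L = len(genome)
    if interval.low > L:
        raise ValueError(f"interval {interval} outside genome of length {L}")
    if interval.high > L:
        if genome.topology != "circular":
            raise ValueError(
                f"interval {interval} exceeds linear genome of length {L}"
            )
        if interval.length > L:
            raise ValueError("wrapped interval longer than the genome")
        doubled = genome.sequence + genome.sequence
        sub = doubled[interval.low - 1 : interval.high]
    else:
        sub = genome.sequence[interval.low - 1 : interval.high]
    return sub if interval.strand == 1 else reverse_complement(sub)
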