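"""Core domain types shared across the package.

Internally every interval is 0-based half-open on a named chromosome and
strand.  GTF and GFF3 use 1-based inclusive coordinates and are converted
at the I/O boundary; BED12 already matches the internal convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "AltEventsError",
    "ParseError",
    "ValidationError",
    "ConfigurationError",
    "GenomicInterval",
    "TranscriptModel",
    "CassetteEvent",
]


class AltEventsError(Exception):
    """Base class for all package errors."""


class ParseError(AltEventsError):
    """A malformed input record (names the offending line where possible)."""


class ValidationError(AltEventsError):
    """Structurally valid input that violates a domain invariant."""


class ConfigurationError(AltEventsError):
    """An infeasible or self-contradictory configuration."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (isinstance(self.start, int) and isinstance(self.end, int)):
            raise ValidationError("interval coordinates must be integers")
        if self.start >= self.end:
            raise ValidationError(
                f"interval start must precede end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def to_1based(self) -> tuple[int, int]:
        """Coordinates as 1-based inclusive (GTF/GFF3/browser style)."""
        return self.start + 1, self.end


def _merge_abutting(
    pairs: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Sort exon (start, end) pairs and merge abutting or overlapping blocks.

    Zero-length introns occasionally appear in assembler output; the
    segmentation downstream assumes every intron has positive length, so
    abutting blocks are collapsed at read time.
    """
    merged: list[tuple[int, int]] = []
    for start, end in sorted(pairs):
        if merged and start <= merged[-1][1]:
            prev_start, prev_end = merged[-1]
            merged[-1] = (prev_start, max(prev_end, end))
        else:
            merged.append((start, end))
    return merged


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript isoform: an ordered chain of exons on one strand.

    Invariants: exons are sorted by start, strictly non-overlapping, all on
    the transcript's chromosome and strand, and separated by at least one
    intronic base.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValidationError("transcript_id must be non-empty")
        if not self.exons:
            raise ValidationError(
                f"transcript {self.transcript_id!r} has no exons"
            )
        for exon in self.exons:
            if exon.chrom != self.chrom or exon.strand != self.strand:
                raise ValidationError(
                    f"transcript {self.transcript_id!r}: exon {exon} not on "
                    f"{self.chrom}({self.strand})"
                )
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start <= prev.end:
                raise ValidationError(
                    f"transcript {self.transcript_id!r}: exons "
                    f"[{prev.start},{prev.end}) and [{cur.start},{cur.end}) "
                    "overlap or abut"
                )

    @classmethod
    def from_exon_pairs(
        cls,
        transcript_id: str,
        gene_id: str,
        chrom: str,
        strand: str,
        pairs: Iterable[tuple[int, int]],
    ) -> "TranscriptModel":
        """Build a model from raw (start, end) pairs, sorting and merging
        abutting blocks."""
        merged = _merge_abutting(list(pairs))
        exons = tuple(
            GenomicInterval(chrom, s, e, strand) for s, e in merged
        )
        return cls(transcript_id, gene_id, chrom, strand, exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def exon_chain(self) -> tuple[tuple[int, int], ...]:
        """The exon structure as bare coordinate pairs (identity of the
        isoform's shape, ignoring ids)."""
        return tuple((e.start, e.end) for e in self.exons)

    def total_exon_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass(frozen=True)
class CassetteEvent:
    """A cassette (skipped) exon event.

    ``flank5`` and ``flank3`` are the 5' and 3' constitutive exons in
    transcription order: on the minus strand the 5' flank is the trio
    member with the *larger* genomic coordinates.  ``including_isoforms``
    are the transcripts whose exon chain contains the trio consecutively;
    ``skipping_isoforms`` join the two flanks with a direct junction.
    """

    chrom: str
    strand: str
    flank5: GenomicInterval
    cassette: GenomicInterval
    flank3: GenomicInterval
    including_isoforms: frozenset[str] = field(default_factory=frozenset)
    skipping_isoforms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "including_isoforms", frozenset(self.including_isoforms)
        )
        object.__setattr__(
            self, "skipping_isoforms", frozenset(self.skipping_isoforms)
        )
        trio = (self.flank5, self.cassette, self.flank3)
        for iv in trio:
            if iv.chrom != self.chrom or iv.strand != self.strand:
                raise ValidationError(
                    f"event exon {iv} not on {self.chrom}({self.strand})"
                )
        if self.strand == "+":
            ordered = self.flank5.end <= self.cassette.start <= self.cassette.end <= self.flank3.start
        else:
            ordered = self.flank3.end <= self.cassette.start <= self.cassette.end <= self.flank5.start
        if not ordered:
            raise ValidationError(
                f"event trio not contiguous in genome order on strand "
                f"{self.strand}: {self.flank5}, {self.cassette}, {self.flank3}"
            )
        if not self.including_isoforms or not self.skipping_isoforms:
            raise ValidationError(
                "event requires at least one including and one skipping isoform"
            )
        if self.including_isoforms & self.skipping_isoforms:
            raise ValidationError(
                "an isoform cannot both include and skip the same cassette"
            )

    @property
    def event_id(self) -> str:
        """Unique, human-readable id built from the trio loci in
        transcription order, 1-based inclusive coordinates."""
        f5 = self.flank5.to_1based()
        cx = self.cassette.to_1based()
        f3 = self.flank3.to_1based()
        return (
            f"{self.chrom}:{f5[0]}-{f5[1]}@{cx[0]}-{cx[1]}@{f3[0]}-{f3[1]}"
            f":{self.strand}"
        )

    @property
    def genomic_trio(self) -> tuple[GenomicInterval, GenomicInterval, GenomicInterval]:
        """The three exons sorted by genome coordinate (left, middle, right)."""
        if self.strand == "+":
            return (self.flank5, self.cassette, self.flank3)
        return (self.flank3, self.cassette, self.flank5)

    @property
    def span(self) -> GenomicInterval:
        left, _, right = self.genomic_trio
        return GenomicInterval(self.chrom, left.start, right.end, self.strand)

    def trio_key(self) -> tuple:
        """Identity used for exact matching: chromosome, strand and the
        full coordinates of all three exons."""
        return (
            self.chrom,
            self.strand,
            self.flank5.start,
            self.flank5.end,
            self.cassette.start,
            self.cassette.end,
            self.flank3.start,
            self.flank3.end,
        )

    def sort_key(self) -> tuple:
        return (self.chrom, self.span.start, self.event_id)
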