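"""Gene grouping, exon-union segmentation and cassette-exon detection.

The central idea: within a gene, the union of all isoforms' exons is
partitioned into *minimum non-overlapping exon units* — maximal intervals
over which the set of covering isoforms is constant.  Projecting each
isoform onto these units yields a per-unit isoform count; the ordered list
of counts (with 0 for intronic gaps) is the gene's *count string*.  For a
two-isoform gene the substring [2, 0, 1, 0, 2] signals a cassette exon:
both isoforms share the flanks, one of them carries the middle unit and
the other skips it across a direct junction.

For genes with more than two isoforms, counts alone cannot tell whether
any isoform actually joins the two flanks directly, so detection is based
on exon-chain evidence: a trio (F5, X, F3) is a cassette event when at
least one isoform contains the three exons consecutively and at least one
other contains the two flanks consecutively.  At two isoforms this
reduces exactly to the count-string pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .model import (
    CassetteEvent,
    GenomicInterval,
    TranscriptModel,
    ValidationError,
)

__all__ = [
    "GeneGroup",
    "Segment",
    "SegmentProfile",
    "group_transcripts",
    "flatten_units",
    "detect_cassette_events",
    "find_events",
]


@dataclass(frozen=True)
class GeneGroup:
    """The set of isoforms treated as one gene for event finding."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"gene group {self.gene_id!r} is empty")
        for t in self.transcripts:
            if t.chrom != self.chrom or t.strand != self.strand:
                raise ValidationError(
                    f"gene group {self.gene_id!r}: transcript "
                    f"{t.transcript_id!r} on {t.chrom}({t.strand}), "
                    f"expected {self.chrom}({self.strand})"
                )
        ids = [t.transcript_id for t in self.transcripts]
        if len(ids) != len(set(ids)):
            raise ValidationError(
                f"gene group {self.gene_id!r}: duplicate transcript ids"
            )

    @property
    def span(self) -> GenomicInterval:
        start = min(t.exons[0].start for t in self.transcripts)
        end = max(t.exons[-1].end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)


@dataclass(frozen=True)
class Segment:
    """One minimum non-overlapping exon unit (count > 0) or intronic gap
    (count 0) within a gene span."""

    interval: GenomicInterval
    covering: frozenset[str]

    @property
    def count(self) -> int:
        return len(self.covering)

    @property
    def kind(self) -> str:
        return "unit" if self.covering else "gap"


@dataclass(frozen=True)
class SegmentProfile:
    """The ordered partition of a gene span into units and gaps, with the
    derived count string."""

    gene: GeneGroup
    segments: tuple[Segment, ...]

    @property
    def counts(self) -> list[int]:
        return [s.count for s in self.segments]


def _cluster_by_exon_overlap(
    transcripts: list[TranscriptModel],
) -> list[list[TranscriptModel]]:
    """Single-linkage clusters over the pairwise exon-overlap graph.

    Sweep over all exons in coordinate order, keeping the active set of
    exons whose end exceeds the current start; overlapping exons union
    their transcripts.
    """
    parent = list(range(len(transcripts)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    exons = sorted(
        (exon.start, exon.end, idx)
        for idx, t in enumerate(transcripts)
        for exon in t.exons
    )
    active: list[tuple[int, int]] = []  # (end, transcript index)
    for start, end, idx in exons:
        active = [(e, i) for e, i in active if e > start]
        for _, other in active:
            union(idx, other)
        active.append((end, idx))

    clusters: dict[int, list[TranscriptModel]] = {}
    for idx, t in enumerate(transcripts):
        clusters.setdefault(find(idx), []).append(t)
    return list(clusters.values())


def group_transcripts(
    transcripts: Sequence[TranscriptModel],
) -> list[GeneGroup]:
    """Partition transcripts into gene groups.

    Transcripts carrying a gene_id (GTF input) are grouped by
    (gene_id, chrom, strand).  Transcripts without one (BED12 input) are
    clustered per chromosome and strand by single-linkage exonic overlap,
    each cluster receiving a synthesized id ``GRP_<chrom>_<strand>_<k>``.
    Groups are returned sorted by span, so output does not depend on
    input order.
    """
    named: dict[tuple[str, str, str], list[TranscriptModel]] = {}
    anonymous: dict[tuple[str, str], list[TranscriptModel]] = {}
    for t in transcripts:
        if t.gene_id:
            named.setdefault((t.gene_id, t.chrom, t.strand), []).append(t)
        else:
            anonymous.setdefault((t.chrom, t.strand), []).append(t)

    groups: list[GeneGroup] = []
    for (gene_id, chrom, strand), members in named.items():
        members = sorted(members, key=lambda t: (t.span.start, t.transcript_id))
        groups.append(GeneGroup(gene_id, chrom, strand, tuple(members)))

    for (chrom, strand), members in anonymous.items():
        clusters = _cluster_by_exon_overlap(members)
        clusters.sort(key=lambda c: min(t.span.start for t in c))
        for k, cluster in enumerate(clusters, 1):
            cluster = sorted(
                cluster, key=lambda t: (t.span.start, t.transcript_id)
            )
            groups.append(
                GeneGroup(
                    f"GRP_{chrom}_{strand}_{k}", chrom, strand, tuple(cluster)
                )
            )

    groups.sort(
        key=lambda g: (g.chrom, g.span.start, g.span.end, g.gene_id)
    )
    return groups


def flatten_units(gene: GeneGroup) -> SegmentProfile:
    """Split the gene's exon union into minimum non-overlapping units.

    Segment boundaries are the sorted distinct exon start/end coordinates
    of the group; each segment's covering set lists the isoforms with an
    exon fully containing it.  Because every exon endpoint is a boundary,
    no exon ever partially overlaps a segment.
    """
    bounds = sorted(
        {c for t in gene.transcripts for e in t.exons for c in (e.start, e.end)}
    )
    segments: list[Segment] = []
    for lo, hi in zip(bounds, bounds[1:]):
        covering = frozenset(
            t.transcript_id
            for t in gene.transcripts
            if any(e.start <= lo and hi <= e.end for e in t.exons)
        )
        # exact-cover check: any overlapping exon must contain the segment
        for t in gene.transcripts:
            for e in t.exons:
                if e.start < hi and lo < e.end:
                    assert e.start <= lo and hi <= e.end, (
                        f"exon {e} partially overlaps segment [{lo},{hi})"
                    )
        segments.append(
            Segment(GenomicInterval(gene.chrom, lo, hi, gene.strand), covering)
        )
    # first/last segments are exon-covered by construction (bounds come
    # from exon endpoints), so the span is already trimmed to the union
    return SegmentProfile(gene, tuple(segments))


def detect_cassette_events(gene: GeneGroup) -> list[CassetteEvent]:
    """Find cassette-exon events within one gene group.

    A trio (F5, X, F3) is emitted when at least one isoform's exon chain
    contains the three exons consecutively (inclusion evidence) and at
    least one other isoform's chain contains the two flanks consecutively
    (a direct skipping junction).  Flank coordinates must match exactly on
    both sides; trios differing in a flank boundary are distinct events.
    Terminal exons may serve as flanks but never as the cassette.
    """
    trio_isoforms: dict[tuple, set[str]] = {}
    pair_isoforms: dict[tuple, set[str]] = {}
    for t in gene.transcripts:
        chain = t.exon_chain
        for i in range(len(chain) - 1):
            pair_isoforms.setdefault(
                (chain[i], chain[i + 1]), set()
            ).add(t.transcript_id)
        for i in range(1, len(chain) - 1):
            trio_isoforms.setdefault(
                (chain[i - 1], chain[i], chain[i + 1]), set()
            ).add(t.transcript_id)

    events: list[CassetteEvent] = []
    for (left, middle, right), including in trio_isoforms.items():
        skipping = pair_isoforms.get((left, right), set()) - including
        if not skipping:
            continue
        ivals = [
            GenomicInterval(gene.chrom, s, e, gene.strand)
            for s, e in (left, middle, right)
        ]
        if gene.strand == "+":
            flank5, cassette, flank3 = ivals
        else:
            flank3, cassette, flank5 = ivals
        events.append(
            CassetteEvent(
                chrom=gene.chrom,
                strand=gene.strand,
                flank5=flank5,
                cassette=cassette,
                flank3=flank3,
                including_isoforms=frozenset(including),
                skipping_isoforms=frozenset(skipping),
            )
        )
    events.sort(key=lambda e: e.sort_key())
    return events


def find_events(
    transcripts: Sequence[TranscriptModel],
) -> list[CassetteEvent]:
    """Group transcripts into genes and detect cassette events, with
    global deduplication by event id and deterministic ordering."""
    by_id: dict[str, CassetteEvent] = {}
    for gene in group_transcripts(transcripts):
        for event in detect_cassette_events(gene):
            prev = by_id.get(event.event_id)
            if prev is None:
                by_id[event.event_id] = event
            else:
                # same trio found in overlapping groups: merge evidence
                by_id[event.event_id] = CassetteEvent(
                    chrom=event.chrom,
                    strand=event.strand,
                    flank5=event.flank5,
                    cassette=event.cassette,
                    flank3=event.flank3,
                    including_isoforms=prev.including_isoforms
                    | event.including_isoforms,
                    skipping_isoforms=prev.skipping_isoforms
                    | event.skipping_isoforms,
                )
    return sorted(by_id.values(), key=lambda e: e.sort_key())
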