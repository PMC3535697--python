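"""Benchmarking data-derived events against a known event library.

Matching is deliberately conservative: a data-driven event counts as known
only if chromosome, strand and the exact coordinates of the cassette exon
and of both constitutive flanks are identical.  Two summary fractions are
reported: the rate of known events (RKE — matched events over data-driven
events) and recall (matched events over known-library events).  A
read-support filter reproduces the adjusted-recall protocol, keeping only
events with enough junction reads supporting both the inclusion and the
exclusion form.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .model import CassetteEvent, ParseError, ValidationError
from .annotation_io import atomic_write

__all__ = [
    "EventMatch",
    "EvaluationMetrics",
    "ReadSupport",
    "match_events",
    "compute_metrics",
    "filter_by_read_support",
    "read_support_table",
    "write_metrics_tsv",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_INCLUSION = 10
DEFAULT_MIN_EXCLUSION = 1


@dataclass(frozen=True)
class EventMatch:
    """A data-driven event paired with the coordinate-identical known
    event."""

    data_event: CassetteEvent
    known_event: CassetteEvent

    def __post_init__(self) -> None:
        if self.data_event.trio_key() != self.known_event.trio_key():
            raise ValidationError(
                "matched events differ in loci or strand: "
                f"{self.data_event.event_id} vs {self.known_event.event_id}"
            )


@dataclass(frozen=True)
class EvaluationMetrics:
    """Overlap counts plus RKE and recall.

    ``rke`` is n_overlap / n_data and ``recall`` is n_overlap / n_known;
    either is ``None`` (undefined, never 0) when its denominator is
    empty.
    """

    n_data: int
    n_known: int
    n_overlap: int
    rke: Optional[float]
    recall: Optional[float]

    def summary(self) -> str:
        fmt = lambda v: "undefined" if v is None else f"{v:.4f}"
        return (
            f"data-driven events : {self.n_data}\n"
            f"known events       : {self.n_known}\n"
            f"overlapping events : {self.n_overlap}\n"
            f"rate of known (RKE): {fmt(self.rke)}\n"
            f"recall             : {fmt(self.recall)}"
        )


@dataclass(frozen=True)
class ReadSupport:
    """Junction-read counts for one event: reads supporting the
    cassette-containing (inclusion) form and the flank-joining
    (exclusion) form."""

    event_id: str
    inclusion_reads: int
    exclusion_reads: int

    def __post_init__(self) -> None:
        if self.inclusion_reads < 0 or self.exclusion_reads < 0:
            raise ValidationError(
                f"read counts must be non-negative for {self.event_id!r}"
            )


def _dedupe(events: Sequence[CassetteEvent]) -> dict[tuple, CassetteEvent]:
    unique: dict[tuple, CassetteEvent] = {}
    for event in events:
        unique.setdefault(event.trio_key(), event)
    return unique


def match_events(
    data: Sequence[CassetteEvent], known: Sequence[CassetteEvent]
) -> list[EventMatch]:
    """One-to-one exact-trio matches between data and known events.

    Both inputs are deduplicated by trio identity first; there is no
    partial or overlap-based matching.
    """
    data_unique = _dedupe(data)
    known_unique = _dedupe(known)
    return [
        EventMatch(event, known_unique[key])
        for key, event in sorted(data_unique.items())
        if key in known_unique
    ]


def compute_metrics(
    data: Sequence[CassetteEvent], known: Sequence[CassetteEvent]
) -> EvaluationMetrics:
    """RKE and recall from exact-trio matching, after deduplication."""
    n_data = len(_dedupe(data))
    n_known = len(_dedupe(known))
    n_overlap = len(match_events(data, known))
    rke = n_overlap / n_data if n_data else None
    recall = n_overlap / n_known if n_known else None
    if rke is None:
        logger.warning("RKE undefined: no data-driven events")
    if recall is None:
        logger.warning("recall undefined: no known events")
    return EvaluationMetrics(n_data, n_known, n_overlap, rke, recall)


def filter_by_read_support(
    events: Sequence[CassetteEvent],
    support: Sequence[ReadSupport],
    min_inclusion: int = DEFAULT_MIN_INCLUSION,
    min_exclusion: int = DEFAULT_MIN_EXCLUSION,
) -> list[CassetteEvent]:
    """Keep events with at least ``min_inclusion`` reads supporting the
    inclusion form AND ``min_exclusion`` reads supporting the exclusion
    form.  Events absent from the support table count as 0/0."""
    table: dict[str, ReadSupport] = {}
    for record in support:
        if record.event_id in table:
            raise ValidationError(
                f"duplicate event_id in support table: {record.event_id!r}"
            )
        table[record.event_id] = record
    kept = []
    for event in events:
        rec = table.get(event.event_id)
        inc = rec.inclusion_reads if rec else 0
        exc = rec.exclusion_reads if rec else 0
        if inc >= min_inclusion and exc >= min_exclusion:
            kept.append(event)
    return kept


def read_support_table(path: str | os.PathLike) -> list[ReadSupport]:
    """Read a headered TSV with columns event_id, inclusion_reads,
    exclusion_reads."""
    frame = pd.read_csv(path, sep="\t", dtype={"event_id": str})
    required = {"event_id", "inclusion_reads", "exclusion_reads"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(
            f"{path}: support table missing columns {sorted(missing)}"
        )
    return [
        ReadSupport(
            row.event_id, int(row.inclusion_reads), int(row.exclusion_reads)
        )
        for row in frame.itertuples(index=False)
    ]


def write_metrics_tsv(
    metrics: EvaluationMetrics, path: str | os.PathLike
) -> None:
    """Write the metrics as a one-row headered TSV (empty cells for
    undefined fractions)."""
    fmt = lambda v: "" if v is None else f"{v:.6f}"
    with atomic_write(path) as handle:
        handle.write("n_data\tn_known\tn_overlap\trke\trecall\n")
        handle.write(
            f"{metrics.n_data}\t{metrics.n_known}\t{metrics.n_overlap}"
            f"\t{fmt(metrics.rke)}\t{fmt(metrics.recall)}\n"
        )
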