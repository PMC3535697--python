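"""Reading transcript models (GTF, BED12) and reading/writing cassette-event
annotations as GFF3.

The GFF3 event dialect uses a three-level gene/mRNA/exon hierarchy per event
with exactly two mRNAs — the canonical inclusion form (three exons) and the
canonical exclusion form (two exons) — matching the two-isoform event model
expected by downstream PSI quantifiers such as MISO.  The transcript ids of
every source isoform supporting each form are carried in an ``isoforms=``
attribute on the mRNA record.
"""

from __future__ import annotations

import logging
import os
import re
import tempfile
from contextlib import contextmanager
from typing import Iterator, Sequence

import gffutils

from .model import (
    CassetteEvent,
    GenomicInterval,
    ParseError,
    TranscriptModel,
    ValidationError,
)

__all__ = [
    "read_gtf",
    "read_bed12",
    "write_gtf",
    "write_bed12",
    "write_gff3_events",
    "read_gff3_events",
]

logger = logging.getLogger(__name__)

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@contextmanager
def atomic_write(path: str | os.PathLike) -> Iterator:
    """Write to a temporary file in the target directory and rename on
    success, so failures never leave partial output behind."""
    path = os.fspath(path)
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".tmp.", suffix="~")
    try:
        with os.fdopen(fd, "w") as handle:
            yield handle
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def _build_models(
    raw: dict[str, list[tuple[str, str, int, int]]],
    gene_ids: dict[str, str],
    order: list[str],
) -> list[TranscriptModel]:
    models = []
    for tid in order:
        records = raw[tid]
        chroms = {chrom for chrom, _, _, _ in records}
        strands = {strand for _, strand, _, _ in records}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"transcript {tid!r} has exons on multiple chromosomes or "
                f"strands ({sorted(chroms)}, {sorted(strands)})"
            )
        chrom, strand = records[0][0], records[0][1]
        models.append(
            TranscriptModel.from_exon_pairs(
                tid,
                gene_ids.get(tid, ""),
                chrom,
                strand,
                [(start, end) for _, _, start, end in records],
            )
        )
    return models


def read_gtf(path: str | os.PathLike) -> list[TranscriptModel]:
    """Read transcript models from a GTF file (Cufflinks-style).

    Only ``exon`` features are consumed; they are grouped by their
    ``transcript_id`` attribute with ``gene_id`` carried through.
    Coordinates are converted from 1-based inclusive to the internal
    0-based half-open convention.  Comment lines are skipped.

    Raises :class:`ParseError` naming the line for malformed records and
    :class:`ValidationError` for transcripts spanning multiple
    chromosomes or strands.
    """
    raw: dict[str, list[tuple[str, str, int, int]]] = {}
    gene_ids: dict[str, str] = {}
    order: list[str] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            if fields[2] != "exon":
                continue
            try:
                start_1 = int(fields[3])
                end_1 = int(fields[4])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"{fields[3]!r}, {fields[4]!r}"
                ) from None
            attrs = dict(_GTF_ATTR_RE.findall(fields[8]))
            tid = attrs.get("transcript_id")
            if not tid:
                raise ParseError(
                    f"{path}: line {lineno}: missing transcript_id attribute"
                )
            if tid not in raw:
                raw[tid] = []
                order.append(tid)
                gene_ids[tid] = attrs.get("gene_id", "")
            raw[tid].append((fields[0], fields[6], start_1 - 1, end_1))
    return _build_models(raw, gene_ids, order)


def read_bed12(path: str | os.PathLike) -> list[TranscriptModel]:
    """Read transcript models from a 12-column BED file (Scripture-style).

    Each line becomes one transcript; exons are reconstructed from the
    blockSizes/blockStarts columns (already 0-based half-open, no shift).
    The ``name`` column becomes ``transcript_id``; ``gene_id`` is left
    empty for later overlap-based grouping.  Strandless records are
    rejected because 5'/3' flank labelling is undefined without strand.
    """
    models: list[TranscriptModel] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected 12 BED columns, "
                    f"got {len(fields)}"
                )
            chrom, name, strand = fields[0], fields[3], fields[5]
            if strand not in ("+", "-"):
                raise ValidationError(
                    f"{path}: line {lineno}: transcript {name!r} has "
                    f"strand {strand!r}; stranded records are required"
                )
            try:
                chrom_start = int(fields[1])
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer block fields"
                ) from None
            if len(sizes) != block_count or len(starts) != block_count:
                raise ParseError(
                    f"{path}: line {lineno}: blockCount {block_count} does "
                    f"not match blockSizes/blockStarts lengths "
                    f"({len(sizes)}/{len(starts)})"
                )
            pairs = [
                (chrom_start + off, chrom_start + off + size)
                for off, size in zip(starts, sizes)
            ]
            models.append(
                TranscriptModel.from_exon_pairs(name, "", chrom, strand, pairs)
            )
    return models


def write_gtf(
    models: Sequence[TranscriptModel], path: str | os.PathLike
) -> None:
    """Serialize transcript models as GTF ``exon`` records (1-based
    inclusive)."""
    with atomic_write(path) as handle:
        for model in models:
            for exon in model.exons:
                start_1, end_1 = exon.to_1based()
                attrs = (
                    f'gene_id "{model.gene_id}"; '
                    f'transcript_id "{model.transcript_id}";'
                )
                handle.write(
                    f"{model.chrom}\taltevents\texon\t{start_1}\t{end_1}\t."
                    f"\t{model.strand}\t.\t{attrs}\n"
                )


def write_bed12(
    models: Sequence[TranscriptModel], path: str | os.PathLike
) -> None:
    """Serialize transcript models as BED12 (one transcript per line)."""
    with atomic_write(path) as handle:
        for model in models:
            span = model.span
            sizes = ",".join(str(len(e)) for e in model.exons)
            offsets = ",".join(
                str(e.start - span.start) for e in model.exons
            )
            handle.write(
                f"{model.chrom}\t{span.start}\t{span.end}"
                f"\t{model.transcript_id}\t0\t{model.strand}"
                f"\t{span.start}\t{span.end}\t0\t{len(model.exons)}"
                f"\t{sizes}\t{offsets}\n"
            )


def _gff3_line(
    chrom: str,
    feature: str,
    interval_start: int,
    interval_end: int,
    strand: str,
    attrs: str,
) -> str:
    # interval_* are internal 0-based half-open; emit 1-based inclusive
    return (
        f"{chrom}\taltevents\t{feature}\t{interval_start + 1}"
        f"\t{interval_end}\t.\t{strand}\t.\t{attrs}\n"
    )


def write_gff3_events(
    events: Sequence[CassetteEvent], path: str | os.PathLike
) -> None:
    """Write cassette events as GFF3 with a gene/mRNA/exon hierarchy.

    Per event: one ``gene`` record spanning the trio, an inclusion
    ``mRNA`` with the three exons and an exclusion ``mRNA`` with the two
    flanks.  Events are ordered by chromosome, trio start, then event id,
    so output is deterministic.
    """
    ordered = sorted(events, key=lambda e: e.sort_key())
    with atomic_write(path) as handle:
        handle.write("##gff-version 3\n")
        for event in ordered:
            eid = event.event_id
            span = event.span
            iso_in = ",".join(sorted(event.including_isoforms))
            iso_ex = ",".join(sorted(event.skipping_isoforms))
            handle.write(
                _gff3_line(
                    event.chrom, "gene", span.start, span.end, event.strand,
                    f"ID={eid};Name={eid}",
                )
            )
            mrna_a = f"{eid}.A"
            mrna_b = f"{eid}.B"
            handle.write(
                _gff3_line(
                    event.chrom, "mRNA", span.start, span.end, event.strand,
                    f"ID={mrna_a};Parent={eid};isoforms={iso_in}",
                )
            )
            handle.write(
                _gff3_line(
                    event.chrom, "mRNA", span.start, span.end, event.strand,
                    f"ID={mrna_b};Parent={eid};isoforms={iso_ex}",
                )
            )
            left, middle, right = event.genomic_trio
            for k, exon in enumerate((left, middle, right)):
                handle.write(
                    _gff3_line(
                        event.chrom, "exon", exon.start, exon.end,
                        event.strand,
                        f"ID={mrna_a}.ex{k};Parent={mrna_a}",
                    )
                )
            for k, exon in enumerate((left, right)):
                handle.write(
                    _gff3_line(
                        event.chrom, "exon", exon.start, exon.end,
                        event.strand,
                        f"ID={mrna_b}.ex{k};Parent={mrna_b}",
                    )
                )


def read_gff3_events(
    path: str | os.PathLike, with_skip_count: bool = False
) -> list[CassetteEvent] | tuple[list[CassetteEvent], int]:
    """Read cassette events from GFF3 in the gene/mRNA/exon dialect.

    The trio is reconstructed from the three-exon mRNA: the middle exon
    is the cassette and the flanks are assigned 5'/3' by strand.  Genes
    whose mRNAs do not carry exactly three and two exons are skipped
    with a warning (tolerating foreign records in third-party event
    libraries); pass ``with_skip_count=True`` to also get the number of
    skipped genes.
    """
    try:
        db = gffutils.create_db(
            os.fspath(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return ([], 0) if with_skip_count else []

    events: list[CassetteEvent] = []
    skipped = 0
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        exon_sets = {}
        for mrna in mrnas:
            exons = sorted(
                db.children(mrna, featuretype="exon"), key=lambda f: f.start
            )
            exon_sets[mrna.id] = (mrna, exons)
        counts = sorted(len(ex) for _, ex in exon_sets.values())
        if counts != [2, 3]:
            skipped += 1
            logger.warning(
                "skipping gene %s: mRNA exon counts %s (expected one "
                "3-exon and one 2-exon mRNA)", gene.id, counts,
            )
            continue
        inclusion = next(v for v in exon_sets.values() if len(v[1]) == 3)
        exclusion = next(v for v in exon_sets.values() if len(v[1]) == 2)
        strand = gene.strand
        if strand not in ("+", "-"):
            skipped += 1
            logger.warning("skipping gene %s: missing strand", gene.id)
            continue
        trio = [
            GenomicInterval(gene.seqid, f.start - 1, f.end, strand)
            for f in inclusion[1]
        ]
        left, middle, right = trio
        flank5, flank3 = (left, right) if strand == "+" else (right, left)

        def _iso_ids(mrna) -> frozenset[str]:
            raw = mrna.attributes.get("isoforms", [])
            ids = {tok for item in raw for tok in item.split(",") if tok}
            return frozenset(ids) if ids else frozenset({mrna.id})

        try:
            events.append(
                CassetteEvent(
                    chrom=gene.seqid,
                    strand=strand,
                    flank5=flank5,
                    cassette=middle,
                    flank3=flank3,
                    including_isoforms=_iso_ids(inclusion[0]),
                    skipping_isoforms=_iso_ids(exclusion[0]),
                )
            )
        except ValidationError as exc:
            skipped += 1
            logger.warning("skipping gene %s: %s", gene.id, exc)
    events.sort(key=lambda e: e.sort_key())
    return (events, skipped) if with_skip_count else events
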