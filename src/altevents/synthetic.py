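"""Ground-truthed synthetic transcript annotations.

Generates multi-isoform gene models on artificial chromosomes
(``synth1..synthK``) with planted cassette-exon events and decoy
structures, so detection, I/O and evaluation can all be exercised without
external data.  Coordinates are laid out left to right with a fixed
intergenic gap; no two genes overlap, and generation is fully
deterministic for a given configuration and seed.

Decoy gene classes deliberately exercise the detector's negative rules:

* ``single``      — one isoform (no alternative structure at all),
* ``identical``   — several isoforms with byte-identical exon chains,
* ``alt_first``   — isoforms differing only in the first exon boundary
                    (alternative transcription start, not a cassette),
* ``alt_last``    — likewise for the last exon,
* ``flank_shift`` — a skipped internal exon whose skipping isoform uses a
                    shifted flank boundary, which must NOT match the
                    exact-flank cassette definition.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation_io import write_bed12, write_gff3_events, write_gtf
from .model import (
    CassetteEvent,
    ConfigurationError,
    GenomicInterval,
    TranscriptModel,
)

__all__ = ["SimulationConfig", "TruthSet", "generate_annotation", "write_fixture_pair"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic annotation generator.

    Ranges are inclusive ``(low, high)`` tuples in base pairs or counts.
    Defaults emulate compact mammalian-like gene models at desk scale:
    exons around the genome-wide median of ~150 bp, introns scaled down
    to hundreds of bases so whole chromosomes stay small, and a mix of
    cassette-carrying genes and structurally negative decoys.
    """

    n_genes: int = 25
    cassette_fraction: float = 0.4
    isoforms_per_gene: tuple[int, int] = (2, 3)
    exons_per_isoform: tuple[int, int] = (3, 8)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (200, 2000)
    strand_probability: float = 0.5
    intergenic_gap: int = 5000
    genes_per_chromosome: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be non-negative")
        for name in ("cassette_fraction", "strand_probability"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
        for name in (
            "isoforms_per_gene",
            "exons_per_isoform",
            "exon_length",
            "intron_length",
        ):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ConfigurationError(
                    f"{name} must be a non-empty positive range, got ({lo}, {hi})"
                )
        if self.intergenic_gap < 1 or self.genes_per_chromosome < 1:
            raise ConfigurationError(
                "intergenic_gap and genes_per_chromosome must be positive"
            )
        if self.cassette_fraction > 0 and self.exons_per_isoform[1] < 3:
            raise ConfigurationError(
                "planting cassette events requires isoforms of at least 3 "
                f"exons; exons_per_isoform={self.exons_per_isoform}"
            )
        if self.intron_length[0] < 2:
            # flank-shift decoys move a flank boundary into the intron
            raise ConfigurationError(
                "intron_length lower bound must be at least 2"
            )

    def as_flat_dict(self) -> dict[str, str]:
        return {
            "n_genes": str(self.n_genes),
            "cassette_fraction": str(self.cassette_fraction),
            "isoforms_per_gene": f"{self.isoforms_per_gene[0]},{self.isoforms_per_gene[1]}",
            "exons_per_isoform": f"{self.exons_per_isoform[0]},{self.exons_per_isoform[1]}",
            "exon_length": f"{self.exon_length[0]},{self.exon_length[1]}",
            "intron_length": f"{self.intron_length[0]},{self.intron_length[1]}",
            "strand_probability": str(self.strand_probability),
            "intergenic_gap": str(self.intergenic_gap),
            "genes_per_chromosome": str(self.genes_per_chromosome),
            "seed": str(self.seed),
        }


@dataclass(frozen=True)
class TruthSet:
    """The planted ground truth: every cassette event constructed into the
    transcripts, plus the gene_ids carrying no event at all."""

    events: tuple[CassetteEvent, ...] = field(default_factory=tuple)
    decoys: tuple[str, ...] = field(default_factory=tuple)


def _rand_in(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


def _backbone(
    rng: np.random.Generator, config: SimulationConfig, start: int, n_exons: int
) -> tuple[list[tuple[int, int]], list[int]]:
    """A chain of exon (start, end) pairs separated by drawn introns."""
    exons: list[tuple[int, int]] = []
    introns: list[int] = []
    cursor = start
    for i in range(n_exons):
        length = _rand_in(rng, config.exon_length)
        exons.append((cursor, cursor + length))
        cursor += length
        if i < n_exons - 1:
            gap = _rand_in(rng, config.intron_length)
            introns.append(gap)
            cursor += gap
    return exons, introns


def generate_annotation(
    config: SimulationConfig,
) -> tuple[list[TranscriptModel], TruthSet]:
    """Generate transcripts with planted cassettes and decoys.

    Returns the transcript list (deterministic order) and the truth set.
    Every truth event is detectable by construction: its including chain
    and its flank-joining skipping chain are both emitted verbatim.
    """
    rng = np.random.default_rng(config.seed)
    transcripts: list[TranscriptModel] = []
    truth_events: list[CassetteEvent] = []
    decoys: list[str] = []

    decoy_classes = ("single", "identical", "alt_first", "alt_last", "flank_shift")
    cursors: dict[str, int] = {}

    for g in range(config.n_genes):
        chrom = f"synth{g // config.genes_per_chromosome + 1}"
        start = cursors.get(chrom, 1000)
        strand = "+" if rng.random() < config.strand_probability else "-"
        gene_id = f"G{g + 1:04d}"
        is_cassette = rng.random() < config.cassette_fraction
        n_iso = _rand_in(rng, config.isoforms_per_gene)
        n_exons = _rand_in(rng, config.exons_per_isoform)

        if is_cassette:
            n_iso = max(n_iso, 2)
            n_exons = max(n_exons, 3)
        exons, introns = _backbone(rng, config, start, n_exons)

        chains: list[list[tuple[int, int]]]
        if is_cassette:
            x = int(rng.integers(1, n_exons - 1))
            inclusion = exons
            skipping = exons[:x] + exons[x + 1:]
            chains = [inclusion, skipping]
            # extra isoforms duplicate one of the two forms
            for k in range(n_iso - 2):
                chains.append(inclusion if k % 2 == 0 else skipping)
            tids = [f"{gene_id}.{i + 1}" for i in range(len(chains))]
            including = frozenset(
                tid for tid, c in zip(tids, chains) if c == inclusion
            )
            skipping_ids = frozenset(
                tid for tid, c in zip(tids, chains) if c == skipping
            )
            ivals = [
                GenomicInterval(chrom, s, e, strand)
                for s, e in (exons[x - 1], exons[x], exons[x + 1])
            ]
            if strand == "+":
                flank5, cassette, flank3 = ivals
            else:
                flank3, cassette, flank5 = ivals
            truth_events.append(
                CassetteEvent(
                    chrom=chrom,
                    strand=strand,
                    flank5=flank5,
                    cassette=cassette,
                    flank3=flank3,
                    including_isoforms=including,
                    skipping_isoforms=skipping_ids,
                )
            )
        else:
            decoy = (
                "single"
                if n_iso == 1
                else decoy_classes[int(rng.integers(1, len(decoy_classes)))]
            )
            if decoy == "flank_shift" and n_exons < 3:
                decoy = "identical"
            base = exons
            chains = [base]
            if decoy == "identical":
                chains += [list(base) for _ in range(n_iso - 1)]
            elif decoy == "alt_first":
                s0, e0 = base[0]
                delta = int(rng.integers(1, max(2, (e0 - s0)))) if e0 - s0 > 1 else 0
                alt = [(s0 + delta, e0)] + base[1:] if delta else list(base)
                chains.append(alt)
                chains += [list(base) for _ in range(n_iso - 2)]
            elif decoy == "alt_last":
                sn, en = base[-1]
                delta = int(rng.integers(1, max(2, (en - sn)))) if en - sn > 1 else 0
                alt = base[:-1] + [(sn, en - delta)] if delta else list(base)
                chains.append(alt)
                chains += [list(base) for _ in range(n_iso - 2)]
            elif decoy == "flank_shift":
                x = int(rng.integers(1, n_exons - 1))
                delta = int(rng.integers(1, introns[x - 1]))
                shifted_flank = (base[x - 1][0], base[x - 1][1] + delta)
                alt = base[: x - 1] + [shifted_flank] + base[x + 1:]
                chains.append(alt)
                chains += [list(base) for _ in range(n_iso - 2)]
            else:  # single
                pass
            tids = [f"{gene_id}.{i + 1}" for i in range(len(chains))]
            decoys.append(gene_id)

        for tid, chain in zip(tids, chains):
            transcripts.append(
                TranscriptModel.from_exon_pairs(tid, gene_id, chrom, strand, chain)
            )
        gene_end = max(e for _, e in exons)
        cursors[chrom] = gene_end + config.intergenic_gap

    return transcripts, TruthSet(tuple(truth_events), tuple(decoys))


def write_fixture_pair(
    transcripts: list[TranscriptModel],
    truth: TruthSet,
    outdir: str | os.PathLike,
) -> tuple[Path, Path, Path]:
    """Serialize the same models as GTF and BED12 plus the truth events as
    GFF3; returns the three paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gtf = outdir / "annotation.gtf"
    bed = outdir / "annotation.bed"
    gff3 = outdir / "truth_events.gff3"
    write_gtf(transcripts, gtf)
    write_bed12(transcripts, bed)
    write_gff3_events(list(truth.events), gff3)
    return gtf, bed, gff3
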