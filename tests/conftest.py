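"""Shared helpers: transcript builders, random gene-group generation and
independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import random

import pytest

from altevents import GeneGroup, TranscriptModel


def make_transcript(tid, pairs, gene_id="", chrom="chrT", strand="+"):
    return TranscriptModel.from_exon_pairs(tid, gene_id, chrom, strand, pairs)


def random_chain(rng: random.Random, max_exons: int = 8) -> list[tuple[int, int]]:
    """A random exon chain with small coordinates so chains from one gene
    frequently share boundaries (the interesting regime for detection)."""
    n = rng.randint(1, max_exons)
    # draw exon boundaries from a small grid to force shared coordinates
    grid = sorted(rng.sample(range(0, 400, 5), 2 * n))
    pairs = []
    for i in range(n):
        lo, hi = grid[2 * i], grid[2 * i + 1]
        if hi - lo < 1:
            hi = lo + 1
        pairs.append((lo, hi))
    # enforce >=1 base introns
    fixed = [pairs[0]]
    for lo, hi in pairs[1:]:
        if lo <= fixed[-1][1]:
            lo = fixed[-1][1] + 2
            hi = max(hi, lo + 1)
        fixed.append((lo, hi))
    return fixed


def random_gene_group(
    rng: random.Random,
    gene_id: str = "G",
    max_isoforms: int = 6,
    max_exons: int = 8,
    strand: str | None = None,
) -> GeneGroup:
    """A random multi-isoform gene built from perturbations of a shared
    backbone chain, so cassette-like structures arise often."""
    strand = strand or rng.choice("+-")
    backbone = random_chain(rng, max_exons)
    n_iso = rng.randint(1, max_isoforms)
    transcripts = []
    for i in range(n_iso):
        chain = list(backbone)
        op = rng.random()
        if op < 0.5 and len(chain) >= 3:
            # drop a random internal exon (candidate skipping isoform)
            del chain[rng.randint(1, len(chain) - 2)]
        elif op < 0.65 and len(chain) >= 2:
            # shift a boundary into the intron (alt donor/acceptor decoy)
            j = rng.randint(0, len(chain) - 2)
            gap = chain[j + 1][0] - chain[j][1]
            if gap > 1:
                chain[j] = (chain[j][0], chain[j][1] + rng.randint(1, gap - 1))
        elif op < 0.8 and len(chain) >= 3:
            # truncate terminal exons (alternative first/last structures)
            chain = chain[rng.randint(0, 1): len(chain) - rng.randint(0, 1) or None]
        transcripts.append(
            make_transcript(f"{gene_id}.t{i}", chain, gene_id, "chrT", strand)
        )
    return GeneGroup(gene_id, "chrT", strand, tuple(transcripts))


# ---------------------------------------------------------------- oracles

def per_base_coverage(group: GeneGroup) -> dict[int, frozenset[str]]:
    """Direct per-base membership: base -> set of isoforms covering it."""
    cover: dict[int, set[str]] = {}
    for t in group.transcripts:
        for exon in t.exons:
            for base in range(exon.start, exon.end):
                cover.setdefault(base, set()).add(t.transcript_id)
    return {b: frozenset(s) for b, s in cover.items()}


def brute_force_cassettes(group: GeneGroup) -> set[tuple]:
    """Independent oracle: double loop over all isoform pairs and all exon
    trios; returns the set of (left, middle, right) coordinate trios in
    genome order."""
    found = set()
    for a in group.transcripts:
        ca = a.exon_chain
        for i in range(1, len(ca) - 1):
            trio = (ca[i - 1], ca[i], ca[i + 1])
            for b in group.transcripts:
                if b.transcript_id == a.transcript_id:
                    continue
                cb = b.exon_chain
                for j in range(len(cb) - 1):
                    if (cb[j], cb[j + 1]) == (trio[0], trio[2]):
                        found.add(trio)
    return found


@pytest.fixture
def two_isoform_gene():
    """The canonical two-isoform cassette gene: three shared-boundary
    exons in one isoform, the middle one skipped in the other."""
    inc = make_transcript("iso_inc", [(0, 100), (200, 300), (400, 500)], "G1")
    skp = make_transcript("iso_skip", [(0, 100), (400, 500)], "G1")
    return GeneGroup("G1", "chrT", "+", (inc, skp))
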