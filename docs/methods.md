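# Methods

## The problem

RNA-seq transcriptome reconstruction tools (Cufflinks, Scripture) emit
transcript isoform models, not splicing *events*. Downstream quantifiers of
exon inclusion (PSI estimators such as MISO) consume event annotations: a
cassette exon together with its 5' and 3' constitutive flanking exons, in
GFF3. `altevents` bridges the two: it derives cassette-exon events de novo
from isoform models, so events can be quantified even when they are absent
from curated event libraries, and it scores a derived event set against such
a library.

## Segmentation and count strings

All coordinates are held internally as 0-based half-open intervals on a
named chromosome and strand; GTF and GFF3 (1-based inclusive) are converted
at the I/O boundary, BED12 needs no shift. Using one internal convention
removes an entire class of off-by-one defects.

Isoforms are first grouped into genes — by the assembler's `gene_id` when
present (GTF), otherwise by single-linkage clustering over exonic overlap on
the same chromosome and strand (BED12, which carries no gene ids). Span
overlap is deliberately insufficient: a transcript nested inside another's
intron shares no exonic bases and stays a separate gene.

Within a gene, the union of all isoforms' exons is partitioned into
**minimum non-overlapping exon units**: the segment boundaries are exactly
the distinct exon start/end coordinates of the group, so every exon of every
isoform is a concatenation of whole segments and no exon ever partially
overlaps a segment (asserted during projection). Each segment carries the
set of isoforms whose exons contain it; the ordered list of set sizes, with
0 for uncovered gaps, is the gene's **count string**. Two invariants pin the
construction down:

* tiling — segments are consecutive, non-overlapping, and cover the exon
  union exactly, with adjacent segments differing in their covering sets;
* conservation — Σ(count × length) over segments equals the summed exon
  length over isoforms.

For a two-isoform gene, the substring `[2, 0, 1, 0, 2]` diagnoses a cassette
exon: both isoforms share the flanks, one covers the middle unit, the other
skips it.

## Cassette detection beyond two isoforms

Counts alone are ambiguous once a gene has three or more isoforms: a unit
covered by k of N isoforms does not reveal whether any isoform joins the two
flanks with a *direct junction*, which is what exon skipping means.
Detection therefore works on exon-chain evidence. A trio (F5, X, F3) is
emitted as a cassette event when

1. at least one isoform's chain contains the three exons consecutively
   (inclusion evidence), and
2. at least one other isoform's chain contains the two flanks consecutively
   (a direct skipping junction).

At N = 2 this reduces exactly to the count-string pattern (property-tested).
Flank identity is exact on both coordinates of both flanks: trios differing
in a flank boundary (an alternative donor/acceptor on a flank) are distinct
events, which keeps derived events comparable to libraries matched under the
same exact-loci rule. Terminal exons may serve as flanks but never as the
cassette (a cassette needs both a 5' and a 3' junction). 5'/3' flank roles
follow the strand: on the minus strand the 5' flank is the trio member with
the larger genomic coordinates. Byte-identical duplicate isoforms add no
events (detection is set-valued over chains); identical trios discovered in
different gene groups are merged by event id with their isoform-evidence
sets unioned. Detection is purely structural — no expression weighting —
since quantification belongs downstream.

The implementation hashes consecutive exon pairs and triples per gene, so it
is linear in total exon count; an exhaustive O(isoforms² × exons) scan
serves as the independent oracle in the test suite, never as the
implementation.

## Event I/O

Events are serialized as GFF3 with a gene/mRNA/exon hierarchy: one `gene`
record spanning the trio, one 3-exon inclusion `mRNA` and one 2-exon
exclusion `mRNA` — exactly two mRNAs regardless of how many source isoforms
support each form, matching the two-isoform event model of downstream PSI
tools; the supporting transcript ids ride in an `isoforms=` attribute. The
event id encodes the trio in transcription order with 1-based inclusive
coordinates (`chrom:f5s-f5e@cs-ce@f3s-f3e:strand`), unique per trio and
readable in a genome browser. The reader tolerates foreign gene records
(mRNA exon counts other than {3, 2}) by skipping them with a warning and an
optional returned count, so third-party event libraries with extra record
types can still be loaded. Output ordering is deterministic (chromosome,
trio start, event id) and all writes are atomic (temp file + rename), so a
failed run never leaves partial output.

## Evaluation

Matching against a known library is the most conservative possible: a match
requires identical chromosome, strand, and all three exon intervals. Both
sides are deduplicated by full trio before counting, making matching
one-to-one. Two fractions are reported: **RKE** (rate of known events,
matched / data-driven) and **recall** (matched / known). Empty denominators
yield *undefined* (absent in reports, `None` in code), never 0 — a 0 would
silently misreport vacuous comparisons. Strand participates in identity even
though loci alone might seem sufficient: the same coordinates on opposite
strands describe different transcription-order events.

The read-support filter retains events with ≥ `min_inclusion` reads
supporting the inclusion form **and** ≥ `min_exclusion` reads supporting the
exclusion form (defaults 10 and 1, both thresholds inclusive — "no less
than"). Counts arrive as a side table (headered TSV: `event_id`,
`inclusion_reads`, `exclusion_reads`) rather than from alignments, keeping
the module desk-testable; producing such counts is a quantifier's job. The
filter is monotone in both thresholds and idempotent (both property-tested).
Applied to the known library before computing recall, it reproduces the
adjusted-recall protocol in which poorly supported library events are
excluded from the denominator.

## Synthetic annotations

The generator lays genes left to right on artificial chromosomes
(`synth1..synthK`, ten genes per chromosome, 5 kb intergenic gaps — no
reference genome is needed because detection is purely interval-based). A
cassette gene gets an inclusion isoform (F5–X–F3 consecutive) and a skipping
isoform (F5–F3 direct junction), optionally plus duplicates of either form;
the planted event is recorded in a truth set. Decoy genes exercise the
detector's negative rules: single-isoform genes, multi-isoform genes with
identical chains, alternative first/last exons, and flank-boundary shifts —
all of which must yield no events.

Defaults (chosen once as desk-scale, mammalian-flavoured models): 25 genes,
cassette fraction 0.4, 2–3 isoforms per gene, 3–8 exons of 80–300 bp (the
genome-wide median exon is ~150 bp), introns 200–2000 bp (real mammalian
introns are often far longer; they are scaled down so whole fixtures stay
small), strand probability 0.5. Generation is fully deterministic for a
given config and seed, down to byte-identical files.

What the generator does *not* emulate: reads and coverage, assembler noise
(truncated or chimeric isoforms, missed junctions), overlapping genes,
expression levels, and real intron-length distributions. Passing the
recovery tests therefore demonstrates the detector's structural correctness
on clean isoform models, not robustness to reconstruction errors — on real
assemblies, missed junctions make inclusion isoforms undetectable upstream
of this tool, which no event finder can repair.

## Numerical and degenerate-input choices

There is no floating-point numerics in the core — everything is integer
interval arithmetic, so results are exact. Degenerate inputs are defined
explicitly: empty annotation → empty event set; single-isoform gene → no
events; empty GFF3 → header-only file that reads back as an empty list;
abutting exon blocks (zero-length introns) are merged at read time because
the segmentation assumes real introns; raw overlapping exon blocks within
one transcript are also merged leniently at the boundary, while the
in-memory transcript type itself rejects overlap. Strandless BED12 records
are rejected rather than guessed, since 5'/3' flank labelling is undefined
without strand.

## Problem sizes

The test suite and the acceptance script use 500 random gene groups (≤ 6
isoforms, ≤ 8 exons) for the brute-force oracle comparison, 50 seeds of the
default-size simulation plus a 200-gene run for planted-truth recovery, 100
genes for the conservation check and 1000 events for the filter recount —
sizes at which the exhaustive oracles remain fast while covering the
combinatorial space densely.

## Known limitations

Only cassette exons are detected; retained introns, alternative donors/
acceptors and mutually exclusive exons would need their own chain patterns.
Whether a skipping junction must be explicit in some isoform chain (our
rule) or could be inferred from count strings alone at N > 2 is a design
choice of this package; both reduce to the same behaviour at N = 2. Events
are detected per gene group and merged afterwards; groups are otherwise
treated independently. The GFF3 reader is a best-effort compatibility layer
for third-party event libraries, not a full GFF3 validator.
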