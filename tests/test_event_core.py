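"""Segmentation, count strings and cassette detection, cross-checked
against brute-force oracles."""

import random

import pytest

from altevents import (
    GeneGroup,
    GenomicInterval,
    TranscriptModel,
    detect_cassette_events,
    find_events,
    flatten_units,
    group_transcripts,
)
from conftest import (
    brute_force_cassettes,
    make_transcript,
    per_base_coverage,
    random_gene_group,
)


class TestFlattenUnits:
    def test_two_isoform_cassette_count_string(self, two_isoform_gene):
        """The canonical skipped-exon gene yields the count string
        [2, 0, 1, 0, 2]."""
        profile = flatten_units(two_isoform_gene)
        assert profile.counts == [2, 0, 1, 0, 2]
        kinds = [s.kind for s in profile.segments]
        assert kinds == ["unit", "gap", "unit", "gap", "unit"]

    def test_single_isoform_projection(self):
        t = make_transcript("t1", [(0, 10), (20, 30), (40, 50)], "G")
        profile = flatten_units(GeneGroup("G", "chrT", "+", (t,)))
        assert profile.counts == [1, 0, 1, 0, 1]
        assert all(
            s.covering == frozenset({"t1"})
            for s in profile.segments
            if s.count
        )

    def test_segments_tile_the_span(self, two_isoform_gene):
        profile = flatten_units(two_isoform_gene)
        span = two_isoform_gene.span
        assert profile.segments[0].interval.start == span.start
        assert profile.segments[-1].interval.end == span.end
        for prev, cur in zip(profile.segments, profile.segments[1:]):
            assert prev.interval.end == cur.interval.start
            assert prev.covering != cur.covering  # maximality

    def test_first_and_last_segments_are_units(self, two_isoform_gene):
        profile = flatten_units(two_isoform_gene)
        assert profile.segments[0].count > 0
        assert profile.segments[-1].count > 0

    @pytest.mark.parametrize("seed", range(40))
    def test_per_base_oracle(self, seed):
        """Every base's covering-isoform set (computed by direct per-base
        membership) matches the covering set of its segment."""
        rng = random.Random(seed)
        group = random_gene_group(rng)
        profile = flatten_units(group)
        truth = per_base_coverage(group)
        for segment in profile.segments:
            for base in range(segment.interval.start, segment.interval.end):
                assert truth.get(base, frozenset()) == segment.covering

    @pytest.mark.parametrize("seed", range(40))
    def test_conservation_invariant(self, seed):
        """Sum of count x length over segments equals the summed exon
        length over isoforms."""
        group = random_gene_group(random.Random(seed + 1000))
        profile = flatten_units(group)
        lhs = sum(s.count * len(s.interval) for s in profile.segments)
        rhs = sum(t.total_exon_length() for t in group.transcripts)
        assert lhs == rhs


class TestDetectCassetteEvents:
    def test_canonical_two_isoform_event(self, two_isoform_gene):
        events = detect_cassette_events(two_isoform_gene)
        assert len(events) == 1
        event = events[0]
        assert (event.cassette.start, event.cassette.end) == (200, 300)
        assert (event.flank5.start, event.flank5.end) == (0, 100)
        assert (event.flank3.start, event.flank3.end) == (400, 500)
        assert event.including_isoforms == {"iso_inc"}
        assert event.skipping_isoforms == {"iso_skip"}

    def test_minus_strand_flank_labels(self):
        """On the reverse strand the 5' flank is the higher-coordinate
        exon of the trio."""
        inc = make_transcript(
            "inc", [(0, 100), (200, 300), (400, 500)], "G", strand="-"
        )
        skp = make_transcript("skp", [(0, 100), (400, 500)], "G", strand="-")
        events = detect_cassette_events(GeneGroup("G", "chrT", "-", (inc, skp)))
        assert len(events) == 1
        assert events[0].flank5.start == 400
        assert events[0].flank3.start == 0

    def test_single_isoform_yields_nothing(self):
        t = make_transcript("t", [(0, 10), (20, 30), (40, 50)], "G")
        assert detect_cassette_events(GeneGroup("G", "chrT", "+", (t,))) == []

    def test_flank_mismatch_is_not_an_event(self):
        """A skipping chain whose flank boundary is shifted does not
        support the trio: flank identity must be exact on both sides."""
        inc = make_transcript("inc", [(0, 100), (200, 300), (400, 500)], "G")
        shifted = make_transcript("skp", [(0, 110), (400, 500)], "G")
        events = detect_cassette_events(
            GeneGroup("G", "chrT", "+", (inc, shifted))
        )
        assert events == []

    def test_terminal_exon_cannot_be_cassette(self):
        """Dropping a terminal exon (alternative end) is not skipping."""
        long = make_transcript("long", [(0, 100), (200, 300)], "G")
        short = make_transcript("short", [(0, 100)], "G")
        assert detect_cassette_events(
            GeneGroup("G", "chrT", "+", (long, short))
        ) == []

    def test_duplicate_isoforms_add_no_events(self, two_isoform_gene):
        inc, skp = two_isoform_gene.transcripts
        dup = make_transcript("iso_inc2", [(0, 100), (200, 300), (400, 500)], "G1")
        bigger = GeneGroup("G1", "chrT", "+", (inc, skp, dup))
        events = detect_cassette_events(bigger)
        assert len(events) == 1
        assert events[0].including_isoforms == {"iso_inc", "iso_inc2"}

    @pytest.mark.parametrize("seed", range(100))
    def test_brute_force_oracle(self, seed):
        """Detection equals an exhaustive scan over all isoform pairs and
        exon trios."""
        group = random_gene_group(random.Random(seed))
        events = detect_cassette_events(group)
        got = {
            tuple((iv.start, iv.end) for iv in e.genomic_trio) for e in events
        }
        assert got == brute_force_cassettes(group)

    @pytest.mark.parametrize("seed", range(30))
    def test_strand_mirror_symmetry(self, seed):
        """Reflecting all coordinates and flipping strand maps the event
        set to its mirror image, with 5'/3' flank roles swapped in genome
        order but preserved in transcription order."""
        C = 10_000
        group = random_gene_group(random.Random(seed), strand="+")
        flipped = "-"
        mirrored = GeneGroup(
            group.gene_id,
            group.chrom,
            flipped,
            tuple(
                TranscriptModel.from_exon_pairs(
                    t.transcript_id,
                    t.gene_id,
                    t.chrom,
                    flipped,
                    [(C - e.end, C - e.start) for e in t.exons],
                )
                for t in group.transcripts
            ),
        )
        fwd = detect_cassette_events(group)
        rev = detect_cassette_events(mirrored)
        fwd_keys = {
            (
                (C - e.flank5.end, C - e.flank5.start),
                (C - e.cassette.end, C - e.cassette.start),
                (C - e.flank3.end, C - e.flank3.start),
                frozenset(e.including_isoforms),
            )
            for e in fwd
        }
        rev_keys = {
            (
                (e.flank5.start, e.flank5.end),
                (e.cassette.start, e.cassette.end),
                (e.flank3.start, e.flank3.end),
                frozenset(e.including_isoforms),
            )
            for e in rev
        }
        assert fwd_keys == rev_keys

    @pytest.mark.parametrize("seed", range(30))
    def test_monotonicity_adding_isoforms(self, seed):
        """Adding an isoform to a group never removes an event."""
        rng = random.Random(seed)
        group = random_gene_group(rng, max_isoforms=5)
        extra_chain = random_gene_group(
            rng, max_isoforms=1, strand=group.strand
        ).transcripts[0]
        extra = TranscriptModel.from_exon_pairs(
            "extra_iso", group.gene_id, group.chrom, group.strand,
            extra_chain.exon_chain,
        )
        before = {
            tuple((iv.start, iv.end) for iv in e.genomic_trio)
            for e in detect_cassette_events(group)
        }
        after_group = GeneGroup(
            group.gene_id, group.chrom, group.strand,
            group.transcripts + (extra,),
        )
        after = {
            tuple((iv.start, iv.end) for iv in e.genomic_trio)
            for e in detect_cassette_events(after_group)
        }
        assert before <= after

    @pytest.mark.parametrize("seed", range(30))
    def test_two_isoform_reduction_to_count_string(self, seed):
        """In a two-isoform gene, every event corresponds to a
        [2, 0, 1, 0, 2] count substring over the window of its trio."""
        rng = random.Random(seed + 500)
        group = random_gene_group(rng, max_isoforms=2)
        if len(group.transcripts) != 2:
            return
        profile = flatten_units(group)
        for event in detect_cassette_events(group):
            left, middle, right = event.genomic_trio
            window = [
                s.count
                for s in profile.segments
                if left.end <= s.interval.start and s.interval.end <= right.start
            ]
            assert window == [0, 1, 0]
            flank_counts = [
                s.count
                for s in profile.segments
                if (s.interval.end == left.end) or (s.interval.start == right.start)
            ]
            assert all(c == 2 for c in flank_counts)


class TestGroupTranscripts:
    def test_shared_gene_id_groups_together(self):
        a = make_transcript("a", [(0, 10)], "G1")
        b = make_transcript("b", [(100, 110)], "G1")
        groups = group_transcripts([a, b])
        assert len(groups) == 1
        assert groups[0].gene_id == "G1"

    def test_overlap_clustering_without_gene_ids(self):
        a = make_transcript("a", [(0, 100)])
        b = make_transcript("b", [(50, 150)])
        c = make_transcript("c", [(1000, 1100)])
        groups = group_transcripts([a, b, c])
        sizes = sorted(len(g.transcripts) for g in groups)
        assert sizes == [1, 2]
        assert all(g.gene_id.startswith("GRP_chrT_+_") for g in groups)

    def test_opposite_strands_never_cluster(self):
        a = make_transcript("a", [(0, 100)], strand="+")
        b = make_transcript("b", [(0, 100)], strand="-")
        assert len(group_transcripts([a, b])) == 2

    def test_span_overlap_without_exon_overlap_stays_separate(self):
        """A transcript nested inside another's intron shares no exonic
        bases and must form its own gene."""
        outer = make_transcript("outer", [(0, 100), (900, 1000)])
        inner = make_transcript("inner", [(400, 500)])
        assert len(group_transcripts([outer, inner])) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_connected_components_oracle(self, seed):
        """Synthesized grouping equals connected components of the
        pairwise exon-overlap graph, computed by direct O(n^2) search."""
        rng = random.Random(seed)
        transcripts = []
        for i in range(200):
            start = rng.randrange(0, 5000, 10)
            n = rng.randint(1, 3)
            pairs, cursor = [], start
            for _ in range(n):
                length = rng.randint(10, 80)
                pairs.append((cursor, cursor + length))
                cursor += length + rng.randint(2, 60)
            transcripts.append(make_transcript(f"t{i}", pairs))
        # oracle: union-find over all overlapping transcript pairs
        parent = list(range(len(transcripts)))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i, a in enumerate(transcripts):
            for j, b in enumerate(transcripts[:i]):
                if any(ea.overlaps(eb) for ea in a.exons for eb in b.exons):
                    parent[find(i)] = find(j)
        expected = {}
        for i, t in enumerate(transcripts):
            expected.setdefault(find(i), set()).add(t.transcript_id)
        got = {
            frozenset(t.transcript_id for t in g.transcripts)
            for g in group_transcripts(transcripts)
        }
        assert got == {frozenset(v) for v in expected.values()}

    def test_grouping_is_input_order_independent(self):
        rng = random.Random(3)
        transcripts = [
            make_transcript(f"t{i}", [(i * 7 % 300, i * 7 % 300 + 50)])
            for i in range(30)
        ]
        groups_fwd = group_transcripts(transcripts)
        shuffled = list(transcripts)
        rng.shuffle(shuffled)
        groups_shuf = group_transcripts(shuffled)
        key = lambda gs: [
            (g.gene_id, tuple(t.transcript_id for t in g.transcripts))
            for g in gs
        ]
        assert key(groups_fwd) == key(groups_shuf)


class TestFindEvents:
    def test_empty_input(self):
        assert find_events([]) == []

    def test_planted_events_recovered(self):
        from altevents import SimulationConfig, generate_annotation

        transcripts, truth = generate_annotation(
            SimulationConfig(n_genes=25, cassette_fraction=0.4, seed=11)
        )
        events = find_events(transcripts)
        assert {e.event_id for e in events} == {
            e.event_id for e in truth.events
        }

    def test_output_sorted_and_unique(self):
        from altevents import SimulationConfig, generate_annotation

        transcripts, _ = generate_annotation(
            SimulationConfig(n_genes=30, cassette_fraction=1.0, seed=5)
        )
        events = find_events(transcripts)
        ids = [e.event_id for e in events]
        assert len(ids) == len(set(ids))
        keys = [e.sort_key() for e in events]
        assert keys == sorted(keys)
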