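"""Novelty classification of transcripts and junctions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicepept.annotation_events import (
    AnnotationSet,
    Junction,
    TranscriptModel,
    build_novel_event_set,
    classify_junctions,
    classify_transcripts,
    extract_junctions,
    merge_assembled,
)


def _ann(*transcripts):
    return AnnotationSet(transcripts=list(transcripts))


@pytest.fixture
def official():
    return _ann(
        TranscriptModel("ref1", "chr1", "+", [(100, 200), (300, 400), (500, 600)], "g1"),
        TranscriptModel("ref2", "chr1", "-", [(1000, 1200)], "g2"),
        TranscriptModel("ref3", "chr2", "+", [(50, 150), (250, 350)], "g3"),
    )


class TestExtractJunctions:
    def test_two_exons(self):
        t = TranscriptModel("t", "chr1", "+", [(100, 200), (300, 400)])
        assert [(j.start, j.end) for j in extract_junctions(t)] == [(200, 300)]

    def test_mono_exonic_empty(self):
        t = TranscriptModel("t", "chr1", "+", [(0, 10)])
        assert extract_junctions(t) == []

    def test_three_exons_two_introns(self):
        t = TranscriptModel("t", "chr1", "+", [(0, 10), (20, 30), (40, 50)])
        assert len(extract_junctions(t)) == 2


class TestClassifyJunctions:
    def test_exact_match_known(self, official):
        known, novel = classify_junctions([Junction("chr1", 200, 300, "+")], official)
        assert len(known) == 1 and not novel

    def test_off_by_one_novel(self, official):
        known, novel = classify_junctions([Junction("chr1", 201, 300, "+")], official)
        assert len(novel) == 1 and not known

    def test_duplicates_counted_once(self, official):
        obs = [Junction("chr1", 200, 300, "+")] * 3 + [Junction("chr1", 7, 70, "+")] * 2
        known, novel = classify_junctions(obs, official)
        assert len(known) == 1 and len(novel) == 1

    def test_unstranded_matches_either_strand(self, official):
        known, _ = classify_junctions([Junction("chr1", 200, 300, ".")], official)
        assert len(known) == 1

    def test_partition_exhaustive_disjoint(self, official):
        obs = [
            Junction("chr1", 200, 300, "+"),
            Junction("chr1", 400, 500, "+"),
            Junction("chr2", 1, 9, "-"),
        ]
        known, novel = classify_junctions(obs, official)
        assert len(known) + len(novel) == 3
        assert not {j.key() for j in known} & {j.key() for j in novel}


class TestClassifyTranscripts:
    def test_chain_identity_with_end_jitter_is_known(self, official):
        t = TranscriptModel("a", "chr1", "+", [(90, 200), (300, 400), (500, 777)])
        known, novel = classify_transcripts([t], official)
        assert [x.id for x in known] == ["a"] and not novel

    def test_skipped_exon_is_novel(self, official):
        t = TranscriptModel("a", "chr1", "+", [(100, 200), (500, 600)])
        _, novel = classify_transcripts([t], official)
        assert [x.id for x in novel] == ["a"]

    def test_mono_exonic_containment_same_strand(self, official):
        inside = TranscriptModel("in", "chr1", "-", [(1050, 1150)])
        opposite = TranscriptModel("op", "chr1", "+", [(1050, 1150)])
        outside = TranscriptModel("out", "chr1", "-", [(5000, 5100)])
        known, novel = classify_transcripts([inside, opposite, outside], official)
        assert [x.id for x in known] == ["in"]
        assert sorted(x.id for x in novel) == ["op", "out"]

    def test_mono_exonic_against_brute_force_overlap_oracle(self, official):
        rng = np.random.default_rng(0)
        exon_list = [
            (t.chrom, t.strand, s, e)
            for t in official.transcripts
            for s, e in t.exons
        ]
        for i in range(200):
            chrom = "chr1" if rng.random() < 0.7 else "chr2"
            strand = "+" if rng.random() < 0.5 else "-"
            s = int(rng.integers(0, 1300))
            e = s + int(rng.integers(1, 300))
            t = TranscriptModel(f"m{i}", chrom, strand, [(s, e)])
            oracle = any(
                c == chrom and st_ == strand and os_ <= s and e <= oe
                for c, st_, os_, oe in exon_list
            )
            known, _ = classify_transcripts([t], official)
            assert bool(known) == oracle


class TestMergeAssembled:
    def test_identical_across_runs_deduplicated(self):
        t = TranscriptModel("a", "chr1", "+", [(0, 10), (20, 30)])
        u = TranscriptModel("b", "chr1", "+", [(0, 10), (20, 30)])
        assert len(merge_assembled([[t], [u]])) == 1

    def test_same_chain_widest_span(self):
        t = TranscriptModel("a", "chr1", "+", [(5, 10), (20, 30)])
        u = TranscriptModel("b", "chr1", "+", [(0, 10), (20, 44)])
        merged = merge_assembled([[t], [u]])
        assert merged[0].exons == [(0, 10), (20, 44)]

    def test_disjoint_kept(self):
        t = TranscriptModel("a", "chr1", "+", [(0, 10), (20, 30)])
        u = TranscriptModel("b", "chr1", "+", [(100, 110), (120, 130)])
        assert len(merge_assembled([[t], [u]])) == 2

    def test_mono_exonic_containment_keeps_widest(self):
        t = TranscriptModel("a", "chr1", "+", [(0, 100)])
        u = TranscriptModel("b", "chr1", "+", [(10, 50)])
        merged = merge_assembled([[t, u]])
        assert [m.exons for m in merged] == [[(0, 100)]]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 80)), max_size=12))
    def test_idempotent(self, spans):
        ts = [
            TranscriptModel(f"t{i}", "chr1", "+", [(s, s + w)])
            for i, (s, w) in enumerate(spans)
        ]
        once = merge_assembled([ts])
        twice = merge_assembled([once])
        assert [t.exons for t in twice] == [t.exons for t in once]


class TestNovelEventSet:
    def test_nj_inside_nt_chain_subsumed(self):
        nts = [
            TranscriptModel("a", "chr1", "+", [(0, 10), (20, 30)]),
            TranscriptModel("b", "chr1", "+", [(100, 110), (120, 130), (140, 150)]),
        ]
        njs = [
            Junction("chr1", 10, 20, "+"),  # inside NT a
            Junction("chr1", 500, 600, "+"),
            Junction("chr2", 1, 9, "-"),
        ]
        events = build_novel_event_set(nts, njs)
        assert len(events) == 4
        assert sum(1 for e in events if e.kind == "NT") == 2

    def test_empty_inputs(self):
        assert build_novel_event_set([], []) == []

    def test_duplicate_nj_single_event(self):
        njs = [Junction("chr1", 10, 20, "+")] * 2
        assert len(build_novel_event_set([], njs)) == 1

    def test_ids_deterministic(self):
        nts = [TranscriptModel("a", "chr1", "+", [(0, 10), (20, 30)])]
        e1 = build_novel_event_set(nts, [])[0]
        e2 = build_novel_event_set(nts, [])[0]
        assert e1.id == e2.id and e1.id.startswith("NT:chr1:0-30:+")
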