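import numpy as np
import pysam
import pytest

from indelsplice.annotation import DONOR, ACCEPTOR, PersonalizedAnnotation
from indelsplice.junctions import (
    CANDIDATE_NOVEL,
    CANONICAL,
    EXOTIC,
    UNANNOTATED,
    JunctionRead,
    call_events,
    classify_junction,
    extract_junctions,
)

from test_annotation import make_transcript


def aligned(pos, cigar, chrom="chr1", flag=0):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": 100000}]}
    )
    a = pysam.AlignedSegment(header)
    a.query_name = "r"
    a.flag = flag
    a.reference_id = 0
    a.reference_start = pos
    a.cigarstring = cigar
    a.query_sequence = "A" * a.infer_query_length()
    a.mapping_quality = 60
    return a


class TestExtractJunctions:
    def test_simple_gap(self):
        reads = [aligned(1000, "30M100N30M")]
        (j,) = extract_junctions(reads, "s1")
        assert (j.left_block_end, j.right_block_start) == (1030, 1130)
        assert (j.left_anchor_len, j.right_anchor_len) == (30, 30)

    def test_no_gap_no_junction(self):
        assert extract_junctions([aligned(1000, "60M")], "s1") == []

    def test_short_right_anchor_reported(self):
        (j,) = extract_junctions([aligned(500, "10M50N4M")], "s1")
        assert j.right_anchor_len == 4

    def test_multi_gap_read_yields_two(self):
        js = extract_junctions([aligned(0, "20M100N20M200N35M")], "s1")
        assert [(j.left_block_end, j.right_block_start) for j in js] == [
            (20, 120),
            (140, 340),
        ]
        assert [(j.left_anchor_len, j.right_anchor_len) for j in js] == [(20, 20), (20, 35)]

    def test_indels_in_blocks_handled(self):
        # 10M2D5M consumes 17 reference bases before the gap; anchor = 15 aligned
        (j,) = extract_junctions([aligned(100, "10M2D5M50N20M")], "s1")
        assert j.left_block_end == 117
        assert j.left_anchor_len == 15

    def test_secondary_and_unmapped_skipped(self):
        reads = [aligned(0, "20M100N20M", flag=256), aligned(0, "20M100N20M", flag=4)]
        assert extract_junctions(reads, "s1") == []

    def test_unknown_reference_raises(self):
        with pytest.raises(ValueError, match="absent"):
            extract_junctions([aligned(0, "20M100N20M")], "s1", valid_references={"chr9"})


@pytest.fixture()
def annotation():
    # two-transcript annotation sharing gene boundaries
    t1 = make_transcript(exon_spans=((100, 200), (300, 400), (500, 600)))
    return PersonalizedAnnotation.from_transcripts("s1", [t1])


def jr(left, right, la=20, ra=20, sample="s1"):
    return JunctionRead(sample, "chr1", left, right, la, ra)


class TestClassify:
    def test_canonical(self, annotation):
        assert classify_junction(jr(200, 300), annotation)[0] == CANONICAL

    def test_candidate_novel_extension_site(self, annotation):
        cls, hits = classify_junction(jr(235, 300), annotation)
        assert cls == CANDIDATE_NOVEL and hits

    def test_unannotated(self, annotation):
        assert classify_junction(jr(250, 270), annotation)[0] == UNANNOTATED

    def test_exotic_skipping(self, annotation):
        # exon1 end to exon3 start: both annotated, never an annotated pair
        assert classify_junction(jr(200, 500), annotation)[0] == EXOTIC


class TestCallEvents:
    def test_donor_extension_called(self, annotation):
        junctions = [jr(235, 300) for _ in range(6)]
        (e,) = call_events(junctions, annotation)
        assert (e.side, e.event_class, e.delta_bp) == (DONOR, "extension", 35)
        assert e.authentic_pos == 200 and e.novel_pos == 235

    def test_below_min_reads_not_called(self, annotation):
        assert call_events([jr(235, 300)], annotation) == []

    def test_anchor_rule_any_read_suffices(self, annotation):
        weak = [jr(235, 300, la=3) for _ in range(3)]
        assert call_events(weak, annotation) == []
        assert len(call_events(weak + [jr(235, 300, la=9)], annotation)) == 1

    def test_acceptor_shrinkage(self, annotation):
        # novel boundary 10 bp inside exon 2 (right side novel, left consistent)
        junctions = [jr(200, 310) for _ in range(4)]
        (e,) = call_events(junctions, annotation)
        assert (e.side, e.event_class, e.delta_bp) == (ACCEPTOR, "shrinkage", -10)

    def test_novel_pos_never_annotated(self, annotation, rng):
        junctions = [
            jr(200, int(rng.integers(301, 500))) for _ in range(40)
        ] + [jr(int(rng.integers(201, 299)), 300) for _ in range(40)]
        for e in call_events(junctions, annotation):
            assert not annotation.matches_left(e.chrom, e.novel_pos)
            assert not annotation.matches_right(e.chrom, e.novel_pos)

    def test_strand_symmetry(self):
        """Mirroring the geometry onto the minus strand flips donor/acceptor
        but preserves the extension call and delta."""
        plus = make_transcript(exon_spans=((100, 200), (300, 400)))
        minus = make_transcript(strand="-", exon_spans=((100, 200), (300, 400)))
        ann_p = PersonalizedAnnotation.from_transcripts("s", [plus])
        ann_m = PersonalizedAnnotation.from_transcripts("s", [minus])
        junctions = [jr(235, 300) for _ in range(4)]
        (ep,) = call_events(junctions, ann_p)
        (em,) = call_events(junctions, ann_m)
        assert ep.side == DONOR and em.side == ACCEPTOR
        assert ep.event_class == em.event_class == "extension"
        assert ep.delta_bp == em.delta_bp == 35

    def test_matches_bruteforce_filter_oracle(self, annotation, rng):
        """Random junction pools: the call set equals an exhaustive
        enumeration that applies both thresholds group by group."""
        boundaries_left = {200, 400}
        boundaries_right = {300, 500}
        for rep in range(30):
            pool = []
            for _ in range(25):
                if rng.random() < 0.5:
                    left = int(rng.choice(list(boundaries_left)))
                    right = int(rng.integers(left + 50, left + 95))
                else:
                    right = int(rng.choice(list(boundaries_right)))
                    left = int(rng.integers(right - 95, right - 50))
                pool.append(
                    jr(left, right, la=int(rng.integers(1, 30)), ra=int(rng.integers(1, 30)))
                )
            min_reads = int(rng.integers(1, 4))
            min_anchor = int(rng.integers(1, 12))
            got = {
                (e.junction.consistent_pos, e.novel_pos, e.transcript_id)
                for e in call_events(pool, annotation, min_reads, min_anchor)
            }
            expect = set()
            groups = {}
            for j in pool:
                lm = bool(annotation.matches_left("chr1", j.left_block_end))
                rm = bool(annotation.matches_right("chr1", j.right_block_start))
                if lm == rm:
                    continue
                cons, nov = (
                    (j.left_block_end, j.right_block_start)
                    if lm
                    else (j.right_block_start, j.left_block_end)
                )
                anchor = j.right_anchor_len if lm else j.left_anchor_len
                groups.setdefault((cons, nov, lm), []).append(anchor)
            for (cons, nov, lm), anchors in groups.items():
                if len(anchors) >= min_reads and max(anchors) >= min_anchor:
                    hits = (
                        annotation.matches_left("chr1", cons)
                        if lm
                        else annotation.matches_right("chr1", cons)
                    )
                    for t, k in hits:
                        introns = list(t.introns())
                        auth = introns[k][1] if lm else introns[k][0]
                        if nov != auth:
                            expect.add((cons, nov, t.transcript_id))
            assert got == expect

    def test_monotonic_in_thresholds(self, annotation, rng):
        pool = [
            jr(
                200,
                int(rng.integers(301, 360)),
                la=int(rng.integers(1, 30)),
                ra=int(rng.integers(1, 30)),
            )
            for _ in range(60)
        ]
        def key_set(mr, ma):
            return {
                (e.junction.consistent_pos, e.novel_pos)
                for e in call_events(pool, annotation, mr, ma)
            }
        base = key_set(2, 5)
        assert key_set(5, 5) <= base
        assert key_set(2, 10) <= base
        assert key_set(5, 10) <= base
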