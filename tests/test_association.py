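import itertools

import pytest

from indelsplice.annotation import ACCEPTOR, DONOR, PersonalizedAnnotation
from indelsplice.association import (
    CohortDecision,
    allele_frequency,
    associate,
    cohort_filter,
    event_reference_key,
    personalized_affected_span,
    window_for,
)
from indelsplice.genome import apply_indels
from indelsplice.junctions import JunctionRead, call_events
from indelsplice.variants import Indel, Zygosity

from test_annotation import make_transcript


class TestWindow:
    def test_plus_donor(self):
        w = window_for(1000, DONOR, "+")
        assert (w.start, w.end) == (997, 1006)

    def test_minus_donor_mirrors(self):
        w = window_for(1000, DONOR, "-")
        assert (w.start, w.end) == (994, 1003)

    def test_acceptor_extents(self):
        wp = window_for(1000, ACCEPTOR, "+")
        wm = window_for(1000, ACCEPTOR, "-")
        assert (wp.start, wp.end) == (982, 1003)
        assert (wm.start, wm.end) == (997, 1018)

    @pytest.mark.parametrize("side,width", [(DONOR, 9), (ACCEPTOR, 21)])
    @pytest.mark.parametrize("strand", "+-")
    def test_widths(self, side, width, strand):
        assert window_for(12345, side, strand).width == width


def _event_for(seq, indel, exon_spans, novel, consistent, strand="+"):
    """Build a one-sample SpliceEvent by running the caller on a fixture."""
    pers, cmap = apply_indels(seq, [indel] if indel else [], chrom="chr1")
    t = make_transcript(strand=strand, exon_spans=exon_spans, cds=None)
    from indelsplice.annotation import lift_transcript

    lifted = lift_transcript(t, cmap)
    ann = PersonalizedAnnotation.from_transcripts("s1", [lifted])
    left, right = min(novel, consistent), max(novel, consistent)
    junctions = [JunctionRead("s1", "chr1", left, right, 20, 20) for _ in range(3)]
    (event,) = call_events(junctions, ann)
    return event, cmap


class TestAssociate:
    def test_insertion_spanning_novel_donor_is_candidate(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        # 35-bp insertion 8 bp into the intron after exon1 (ends at 200)
        ins = Indel("chr1", 208, seq[207], seq[207] + "G" * 35)
        # novel donor 35 bp downstream of the authentic one, personalized
        event, cmap = _event_for(seq, ins, ((100, 200), (300, 400)), 235, 335)
        assert event.delta_bp == 35
        cands = associate(event, [ins], cmap)
        assert [c.indel for c in cands] == [ins]

    def test_deletion_near_novel_boundary_counted_from_novel_not_authentic(self, rng):
        # deletion at +8 of the authentic donor, novel boundary 4 bp
        # downstream: the deletion sits at +4 of the novel boundary, inside
        # the -3/+6 donor window even though it is outside it relative to
        # the authentic site
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        dele = Indel("chr1", 208, seq[207:209], seq[207])
        event, cmap = _event_for(seq, dele, ((100, 200), (300, 400)), 204, 299)
        assert event.delta_bp == 4
        assert associate(event, [dele], cmap)

    def test_distant_indel_not_associated(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        far = Indel("chr1", 601, seq[600], seq[600] + "AT")
        event, cmap = _event_for(seq, None, ((100, 200), (300, 400)), 235, 300)
        assert associate(event, [far], cmap) == []

    def test_strand_mirrored_association(self, rng):
        """The same geometry mirrored to the minus strand yields the same
        candidate set."""
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        ins = Indel("chr1", 208, seq[207], seq[207] + "G" * 9)
        event_p, cmap_p = _event_for(seq, ins, ((100, 200), (300, 400)), 209, 309, "+")
        event_m, cmap_m = _event_for(seq, ins, ((100, 200), (300, 400)), 209, 309, "-")
        assert event_p.side == DONOR and event_m.side == ACCEPTOR
        assert bool(associate(event_p, [ins], cmap_p)) == bool(
            associate(event_m, [ins], cmap_m)
        )

    def test_affected_span_of_deletion_covers_seam(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=100))
        dele = Indel("chr1", 11, seq[10:14], seq[10])
        pers, cmap = apply_indels(seq, [dele], chrom="chr1")
        assert personalized_affected_span(dele, cmap) == (10, 12)


class TestCohortFilter:
    def test_retained_case(self):
        d = CohortDecision.decide(7, 3, 0)
        assert d.retained

    def test_any_noncarrier_event_rejects(self):
        assert not CohortDecision.decide(10, 0, 1).retained

    def test_tie_rejected(self):
        assert not CohortDecision.decide(2, 2, 0).retained

    def test_truth_table_oracle(self):
        """Exhaustive check against the rule 'no non-carrier shows the
        event AND strictly more carriers show it than not'."""
        for cw, cwo, nw in itertools.product(range(11), repeat=3):
            got = CohortDecision.decide(cw, cwo, nw).retained
            assert got == (nw == 0 and cw > cwo)

    def test_counts_from_sample_sets(self):
        carriers = ["a", "b", "c"]
        noncarriers = ["d", "e"]
        d = cohort_filter(carriers, noncarriers, {"a", "b"})
        assert (d.carriers_with_event, d.carriers_without_event) == (2, 1)
        assert d.retained
        d = cohort_filter(carriers, noncarriers, {"a", "b", "d"})
        assert not d.retained


def test_event_reference_key_consistent_across_samples(rng):
    """Two carriers with different upstream indels must map the same event
    to the same reference-projected key."""
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    shared = Indel("chr1", 1008, seq[1007], seq[1007] + "G" * 5)
    upstream = Indel("chr1", 51, seq[50], seq[50] + "TTTT")
    spans = ((900, 1000), (1100, 1200))
    ev1, cm1 = _event_for(seq, shared, spans, 1005, 1100 + 5)
    # second sample also carries a 4-bp insertion far upstream: all
    # personalized coordinates shift by +4
    pers, cm2 = apply_indels(seq, [upstream, shared], chrom="chr1")
    from indelsplice.annotation import lift_transcript

    t = lift_transcript(make_transcript(exon_spans=spans, cds=None), cm2)
    ann = PersonalizedAnnotation.from_transcripts("s2", [t])
    junctions = [JunctionRead("s2", "chr1", 1009, 1109, 20, 20) for _ in range(3)]
    (ev2,) = call_events(junctions, ann)
    assert event_reference_key(ev1, cm1) == event_reference_key(ev2, cm2)


def test_allele_frequency_counts():
    indel = Indel(
        "chr1", 10, "A", "AT",
        genotype_by_sample={"a": Zygosity.HETEROZYGOUS, "b": Zygosity.HOMOZYGOUS},
    )
    af, n_het, n_hom = allele_frequency(indel, ["a", "b", "c", "d"])
    assert (n_het, n_hom) == (1, 1)
    assert af == pytest.approx(3 / 8)
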