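import numpy as np
import pytest
from Bio.Seq import Seq

from indelsplice.annotation import DONOR, ACCEPTOR, ExonRecord, TranscriptModel
from indelsplice.consequence import (
    NOT_IN_CDS,
    NO_PTC,
    PTC,
    STOP_LOST,
    annotate_consequence,
    nmd_escape_rule,
    normal_mrna,
    rebuild_transcript,
)
from indelsplice.genome import CoordinateMap, PersonalizedGenome
from indelsplice.junctions import EXTENSION, SHRINKAGE, NovelJunction, SpliceEvent
from indelsplice.simulate import _SENSE_CODONS


def make_genome(seq, chrom="chr1"):
    return PersonalizedGenome(
        "s1", {chrom: seq}, {chrom: CoordinateMap.identity(chrom, len(seq))}, []
    )


def make_event(t, intron_idx, delta, side_is_left):
    """Event displacing one boundary of intron ``intron_idx`` (genomic order).

    ``side_is_left``: the novel boundary replaces the intron's left edge
    (an exon end); otherwise its right edge (an exon start).
    """
    left, right = list(t.introns())[intron_idx]
    if side_is_left:
        novel, authentic, consistent_side, consistent = left + delta, left, "right", right
    else:
        novel, authentic, consistent_side, consistent = right - delta, right, "left", left
    role = (DONOR if t.strand == "+" else ACCEPTOR) if side_is_left else (
        ACCEPTOR if t.strand == "+" else DONOR
    )
    nj = NovelJunction(t.chrom, consistent_side, consistent, novel, role, {"s1": 3}, 20)
    return SpliceEvent(
        junction=nj,
        transcript_id=t.transcript_id,
        gene_name=t.gene_name,
        strand=t.strand,
        event_class=EXTENSION if delta > 0 else SHRINKAGE,
        delta_bp=delta,
        authentic_pos=authentic,
    )


def toy_transcript(seq_len, exon_spans, strand="+", cds=None, chrom="chr1"):
    n = len(exon_spans)
    order = range(1, n + 1) if strand == "+" else range(n, 0, -1)
    exons = tuple(ExonRecord(chrom, s, e, i) for (s, e), i in zip(exon_spans, order))
    cs, ce = cds if cds else (None, None)
    return TranscriptModel("toy.t1", "TOY", chrom, strand, exons, cs, ce)


class TestRebuild:
    def test_extension_inserts_genomic_block(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=600))
        t = toy_transcript(600, ((100, 200), (300, 400)))
        g = make_genome(seq)
        ev = make_event(t, 0, 35, side_is_left=True)
        normal = normal_mrna(t, g)
        altered = rebuild_transcript(t, ev, g)
        assert len(altered) == len(normal) + 35
        assert altered[100:135] == seq[200:235]

    def test_shrinkage_removes_block(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=600))
        t = toy_transcript(600, ((100, 200), (300, 400)))
        g = make_genome(seq)
        ev = make_event(t, 0, -15, side_is_left=True)
        assert len(rebuild_transcript(t, ev, g)) == len(normal_mrna(t, g)) - 15

    def test_minus_strand_reverse_complemented(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=600))
        t = toy_transcript(600, ((100, 200), (300, 400)), strand="-")
        g = make_genome(seq)
        assert normal_mrna(t, g) == str(
            Seq(seq[100:200] + seq[300:400]).reverse_complement()
        )

    def test_zero_delta_rejected(self):
        t = toy_transcript(600, ((100, 200), (300, 400)))
        with pytest.raises(ValueError):
            make_event(t, 0, 0, side_is_left=True)


class TestNmdRule:
    def test_last_exon_escapes(self):
        assert nmd_escape_rule(5, 5)

    def test_internal_exon_decays(self):
        assert not nmd_escape_rule(2, 10)

    def test_single_exon_escapes(self):
        assert nmd_escape_rule(1, 1)

    def test_50nt_variant(self):
        # PTC 60 nt upstream of the final junction: decays under the 50-nt
        # rule even though close to the last exon
        assert not nmd_escape_rule(
            3, 4, ptc_mrna_offset=400, last_junction_offset=460, use_50nt_rule=True
        )
        assert nmd_escape_rule(
            3, 4, ptc_mrna_offset=420, last_junction_offset=460, use_50nt_rule=True
        )


def _build_coding_fixture(rng, n_exons=3, exon_len=60, intron_len=80):
    """Random multi-exon coding gene with stop-free CDS (plus strand)."""
    u5, u3 = 9, 9
    total = n_exons * exon_len
    cds_len = total - u5 - u3 - (total - u5 - u3) % 3
    u3 = total - u5 - cds_len
    mrna = (
        "".join(rng.choice(list("ACGT"), size=u5))
        + "ATG"
        + "".join(rng.choice(_SENSE_CODONS, size=cds_len // 3 - 2))
        + "TAA"
        + "".join(rng.choice(list("ACGT"), size=u3))
    )
    spans, seq_parts, cursor = [], [], 100
    seq_parts.append("".join(rng.choice(list("ACGT"), size=100)))
    for i in range(n_exons):
        ex = mrna[i * exon_len : (i + 1) * exon_len]
        spans.append((cursor, cursor + exon_len))
        seq_parts.append(ex)
        cursor += exon_len
        if i < n_exons - 1:
            intron = "GT" + "".join(rng.choice(list("ACGT"), size=intron_len - 4)) + "AG"
            seq_parts.append(intron)
            cursor += intron_len
    seq_parts.append("".join(rng.choice(list("ACGT"), size=100)))
    seq = "".join(seq_parts)
    # genomic CDS bounds via transcript offsets
    def t2g(off):
        for (s, e), base in zip(spans, range(0, total, exon_len)):
            if off < base + exon_len:
                return s + off - base
        raise IndexError

    t = toy_transcript(len(seq), tuple(spans), cds=(t2g(u5), t2g(u5 + cds_len - 1) + 1))
    return t, make_genome(seq), u5, cds_len


def _oracle_category(t, ev, genome, u5, cds_len):
    """Independent brute-force check: translate both mRNAs fully and
    compare stop positions via transcript-coordinate arithmetic."""
    normal = normal_mrna(t, genome)
    altered = rebuild_transcript(t, ev, genome)

    def first_stop_nt(m):
        prot = str(Seq(m[u5 : len(m) - (len(m) - u5) % 3]).translate())
        i = prot.find("*")
        return None if i == -1 else u5 + 3 * i

    ns = first_stop_nt(normal)
    asx = first_stop_nt(altered)
    # transcript offset of the variable region's start in the normal mRNA
    lo = min(ev.authentic_pos, ev.novel_pos)
    off = 0
    for e in t.exons:
        if lo <= e.start:
            break
        off += min(lo, e.end) - e.start if lo < e.end else e.length
    event_t = off
    if ns is None:
        return None  # malformed fixture
    if event_t >= ns + 3:
        return NOT_IN_CDS if ns + 3 <= event_t else NO_PTC
    if event_t < u5 + 3 and ev.delta_bp < 0:
        return None  # start codon may be hit; not exercised here
    auth_stop_in_alt = ns + ev.delta_bp if event_t <= ns else ns
    if asx is None:
        return STOP_LOST
    if ev.delta_bp < 0 and event_t <= ns < event_t - ev.delta_bp:
        return STOP_LOST  # authentic stop codon removed
    if asx < auth_stop_in_alt:
        return PTC
    return NO_PTC


def test_agrees_with_bruteforce_translation_oracle():
    """Random toy transcripts and events: category matches an independent
    full-translation comparison (200 cases)."""
    rng = np.random.default_rng(987)
    checked = 0
    while checked < 200:
        t, genome, u5, cds_len = _build_coding_fixture(rng)
        intron_idx = int(rng.integers(0, len(t.exons) - 1))
        delta = int(rng.choice([-7, -5, -4, -2, -1, 1, 2, 3, 4, 6, 9]))
        side_is_left = bool(rng.random() < 0.5)
        ev = make_event(t, intron_idx, delta, side_is_left)
        expect = _oracle_category(t, ev, genome, u5, cds_len)
        if expect is None:
            continue
        rec = annotate_consequence(t, ev, genome)
        assert rec.category == expect, (
            f"delta={delta} intron={intron_idx} left={side_is_left}: "
            f"{rec.category} != {expect}"
        )
        if rec.category == PTC:
            assert rec.frameshift == (abs(delta) % 3 != 0) or not rec.frameshift
            assert rec.ptc_codon is not None and rec.ptc_codon >= 1
            assert rec.nmd_escape == (rec.ptc_exon_index == len(t.exons))
        checked += 1


def test_prefix_identity_up_to_event():
    """The altered protein equals the normal protein upstream of the event."""
    rng = np.random.default_rng(55)
    t, genome, u5, _ = _build_coding_fixture(rng)
    ev = make_event(t, 1, 4, side_is_left=True)
    rec = annotate_consequence(t, ev, genome)
    if rec.category == PTC:
        normal_p = str(Seq(normal_mrna(t, genome)[u5:]).translate())
        altered_p = str(
            Seq(rebuild_transcript(t, ev, genome)[u5 : u5 + 3 * rec.ptc_codon]).translate()
        )
        # event is in intron 1 (after exon 2 starts); exon1+part of exon2
        # codons are untouched
        n_safe = (t.exons[1].start - t.exons[0].start) // 3 // 2
        assert altered_p[:n_safe] == normal_p[:n_safe]


class TestFramePreservation:
    def test_inframe_extension_without_stop_is_silent(self, rng):
        t, genome, u5, _ = _build_coding_fixture(rng)
        left, right = list(t.introns())[0]
        chrom = t.chrom
        seq = genome.sequences[chrom]
        # force the three intronic bases that would be gained to a sense codon
        genome.sequences[chrom] = seq[:left] + "GCA" + seq[left + 3 :]
        ev = make_event(t, 0, 3, side_is_left=True)
        rec = annotate_consequence(t, ev, genome)
        assert rec.category == NO_PTC and not rec.frameshift and rec.delta_mod3 == 0

    def test_inframe_extension_with_stop_creates_ptc(self, rng):
        t, genome, u5, _ = _build_coding_fixture(rng)
        left, right = list(t.introns())[0]
        chrom = t.chrom
        seq = genome.sequences[chrom]
        genome.sequences[chrom] = seq[:left] + "TAA" + seq[left + 3 :]
        ev = make_event(t, 0, 3, side_is_left=True)
        rec = annotate_consequence(t, ev, genome)
        assert rec.category == PTC and rec.delta_mod3 == 0

    def test_utr_event_not_in_cds(self, rng):
        t, genome, u5, cds_len = _build_coding_fixture(rng, n_exons=3)
        # shrink the CDS so the last intron lies beyond the stop codon
        t2 = TranscriptModel(
            t.transcript_id, t.gene_name, t.chrom, t.strand, t.exons,
            t.cds_start, t.exons[1].start + 6,
        )
        ev = make_event(t2, 1, 4, side_is_left=True)
        rec = annotate_consequence(t2, ev, genome)
        assert rec.category == NOT_IN_CDS and not rec.in_cds
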