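"""Transcript consequences of extension/shrinkage events: frameshift,
premature termination codons (PTC) and NMD escape.

The altered transcript is rebuilt by substituting the event's novel
boundary for the authentic one and re-splicing the exon chain off the
personalized genome.  Translation starts from the annotated start codon;
a stop reached strictly upstream of where the authentic stop codon sits
in the altered mRNA is a PTC.  NMD escape uses the simple last-exon
rule — a PTC in the final exon of the altered transcript is assumed to
evade decay — with the canonical 50-nt-before-last-junction variant
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio.Seq import Seq

from .annotation import TranscriptModel
from .genome import PersonalizedGenome
from .junctions import SpliceEvent

NOT_IN_CDS = "Not in CDS"
PTC = "PTC"
NO_PTC = "No PTC"
START_LOST = "start_lost"
STOP_LOST = "stop_lost"


@dataclass(frozen=True)
class ConsequenceRecord:
    """Coding-level outcome of one event on one transcript."""

    event: SpliceEvent
    transcript_id: str
    category: str  # PTC / No PTC / Not in CDS / start_lost / stop_lost
    in_cds: bool
    delta_mod3: int
    frameshift: bool
    ptc_codon: int | None = None  # 1-based codon index of the premature stop
    ptc_exon_index: int | None = None  # 1-based, transcription order, altered transcript
    nmd_escape: bool | None = None
    normal_protein_len: int | None = None  # codons before the authentic stop
    altered_protein_prefix_len: int | None = None  # codons before the PTC
    ambiguous_base: bool = False  # translation hit an N-containing codon


class EventOutsideTranscriptError(ValueError):
    pass


def altered_exons(t: TranscriptModel, event: SpliceEvent) -> tuple:
    """Exon chain with the event's novel boundary substituted in.

    The displaced authentic boundary is either an exon end (intron start)
    or an exon start (intron end) of ``t``; the matching exon edge is
    moved to the novel position.
    """
    lo, hi = t.span
    if not (lo <= event.novel_pos <= hi) and not (lo <= event.authentic_pos <= hi):
        raise EventOutsideTranscriptError(
            f"event boundary {event.novel_pos} outside transcript "
            f"{t.transcript_id} span {lo}-{hi}"
        )
    out = []
    hit = False
    for e in t.exons:
        if event.junction.consistent_side == "right" and e.end == event.authentic_pos:
            out.append(replace(e, end=event.novel_pos))
            hit = True
        elif event.junction.consistent_side == "left" and e.start == event.authentic_pos:
            out.append(replace(e, start=event.novel_pos))
            hit = True
        else:
            out.append(e)
    if not hit:
        raise EventOutsideTranscriptError(
            f"authentic boundary {event.authentic_pos} is not an exon edge of "
            f"{t.transcript_id}"
        )
    for a, b in zip(out, out[1:]):
        if a.end > b.start:
            raise EventOutsideTranscriptError(
                f"novel boundary {event.novel_pos} inverts the exon chain of "
                f"{t.transcript_id}"
            )
    return tuple(out)


def _splice(exons, chrom_seq: str, strand: str) -> str:
    s = "".join(chrom_seq[e.start : e.end] for e in exons)
    return str(Seq(s).reverse_complement()) if strand == "-" else s


def rebuild_transcript(
    t: TranscriptModel, event: SpliceEvent, genome: PersonalizedGenome
) -> str:
    """mRNA of the event-modified transcript (5'->3')."""
    chrom_seq = genome.sequences[t.chrom]
    return _splice(altered_exons(t, event), chrom_seq, t.strand)


def normal_mrna(t: TranscriptModel, genome: PersonalizedGenome) -> str:
    """mRNA of the annotated (unmodified) transcript (5'->3')."""
    return _splice(t.exons, genome.sequences[t.chrom], t.strand)


def _genomic_to_mrna(exons, strand: str, gpos: int) -> int | None:
    """Map a genomic position to its mRNA offset, or None if intronic."""
    off = 0
    ordered = exons if strand == "+" else tuple(reversed(exons))
    for e in ordered:
        if e.start <= gpos < e.end:
            within = gpos - e.start if strand == "+" else e.end - 1 - gpos
            return off + within
        off += e.length
    return None


def _mrna_to_exon_index(exons, strand: str, offset: int) -> int | None:
    """Exon ordinal (1-based, transcription order) holding an mRNA offset."""
    ordered = exons if strand == "+" else tuple(reversed(exons))
    off = 0
    for k, e in enumerate(ordered, start=1):
        if offset < off + e.length:
            return k
        off += e.length
    return None


def _cds_start_offset(t: TranscriptModel, exons) -> int | None:
    """mRNA offset of the first base of the start codon."""
    if not t.is_coding:
        return None
    gpos = t.cds_start if t.strand == "+" else t.cds_end - 1
    return _genomic_to_mrna(exons, t.strand, gpos)


def _translate(seq: str) -> str:
    return str(Seq(seq[: len(seq) // 3 * 3]).translate())


def _first_stop(protein: str) -> tuple[int | None, bool]:
    """(0-based codon index of first stop, ambiguous-base flag)."""
    stop = protein.find("*")
    amb = protein.find("X")
    if amb != -1 and (stop == -1 or amb < stop):
        return None, True
    return (stop if stop != -1 else None), False


def nmd_escape_rule(
    ptc_exon_index: int,
    n_exons: int,
    ptc_mrna_offset: int | None = None,
    last_junction_offset: int | None = None,
    use_50nt_rule: bool = False,
) -> bool:
    """Decide whether a PTC-bearing transcript escapes NMD.

    Default: escape iff the PTC lies in the last exon.  With
    ``use_50nt_rule`` the canonical refinement is applied instead: escape
    iff the PTC starts fewer than 50 nt upstream of the final exon-exon
    junction (which includes all last-exon PTCs).
    """
    if use_50nt_rule:
        if ptc_mrna_offset is None or last_junction_offset is None:
            raise ValueError("50-nt rule needs mRNA offsets")
        return ptc_mrna_offset >= last_junction_offset - 50
    return ptc_exon_index == n_exons


def annotate_consequence(
    t: TranscriptModel,
    event: SpliceEvent,
    genome: PersonalizedGenome,
    use_50nt_rule: bool = False,
) -> ConsequenceRecord:
    """Full coding-consequence annotation of one event on one transcript.

    Non-coding transcripts, events whose variable region lies entirely in
    UTR, and frame-preserving changes without a new in-frame stop are
    reported in the Table-1 vocabulary (``Not in CDS`` / ``No PTC``);
    events removing the start codon report ``start_lost``, events
    removing the authentic stop ``stop_lost``.
    """
    delta_mod3 = abs(event.delta_bp) % 3
    lo, hi = sorted((event.authentic_pos, event.novel_pos))

    def base(category, in_cds, frameshift=False, **kw):
        return ConsequenceRecord(
            event=event,
            transcript_id=t.transcript_id,
            category=category,
            in_cds=in_cds,
            delta_mod3=delta_mod3,
            frameshift=frameshift,
            **kw,
        )

    if not t.is_coding:
        return base(NOT_IN_CDS, in_cds=False)
    # the variable region is [lo, hi) on the genome; outside the CDS span
    # the protein cannot change
    if hi <= t.cds_start or lo >= t.cds_end:
        return base(NOT_IN_CDS, in_cds=False)

    exons_alt = altered_exons(t, event)
    chrom_seq = genome.sequences[t.chrom]
    mrna_n = _splice(t.exons, chrom_seq, t.strand)
    mrna_a = _splice(exons_alt, chrom_seq, t.strand)

    start_g = t.cds_start if t.strand == "+" else t.cds_end - 1
    start_n = _genomic_to_mrna(t.exons, t.strand, start_g)
    start_a = _genomic_to_mrna(exons_alt, t.strand, start_g)
    if start_n is None or start_a is None:
        return base(START_LOST, in_cds=True, frameshift=delta_mod3 != 0)

    prot_n = _translate(mrna_n[start_n:])
    prot_a = _translate(mrna_a[start_a:])
    stop_n, amb_n = _first_stop(prot_n)
    stop_a, amb_a = _first_stop(prot_a)
    if amb_n or amb_a:
        return base(NO_PTC, in_cds=True, frameshift=delta_mod3 != 0, ambiguous_base=True)
    normal_len = stop_n  # codons before the authentic stop

    # locate the authentic stop codon in the altered mRNA
    if stop_n is not None:
        stop_codon_mrna_n = start_n + 3 * stop_n
        # genomic position of the stop codon's first base
        stop_codon_g = _mrna_offset_to_genomic(t.exons, t.strand, stop_codon_mrna_n)
        auth_stop_in_alt = _genomic_to_mrna(exons_alt, t.strand, stop_codon_g)
    else:
        auth_stop_in_alt = None

    frameshift = delta_mod3 != 0
    if stop_a is None:
        return base(
            STOP_LOST,
            in_cds=True,
            frameshift=frameshift,
            normal_protein_len=normal_len,
        )
    stop_a_mrna = start_a + 3 * stop_a
    if auth_stop_in_alt is None:
        # the event removed the authentic stop codon itself
        return base(
            STOP_LOST,
            in_cds=True,
            frameshift=frameshift,
            normal_protein_len=normal_len,
        )
    if stop_a_mrna < auth_stop_in_alt:
        ptc_exon = _mrna_to_exon_index(exons_alt, t.strand, stop_a_mrna)
        last_junction = len(mrna_a) - (
            exons_alt[-1].length if t.strand == "+" else exons_alt[0].length
        )
        escape = nmd_escape_rule(
            ptc_exon,
            len(exons_alt),
            ptc_mrna_offset=stop_a_mrna,
            last_junction_offset=last_junction,
            use_50nt_rule=use_50nt_rule,
        )
        return base(
            PTC,
            in_cds=True,
            frameshift=frameshift,
            ptc_codon=stop_a + 1,
            ptc_exon_index=ptc_exon,
            nmd_escape=escape,
            normal_protein_len=normal_len,
            altered_protein_prefix_len=stop_a,
        )
    return base(
        NO_PTC,
        in_cds=True,
        frameshift=frameshift,
        normal_protein_len=normal_len,
        altered_protein_prefix_len=stop_a,
    )


def _mrna_offset_to_genomic(exons, strand: str, offset: int) -> int:
    ordered = exons if strand == "+" else tuple(reversed(exons))
    off = 0
    for e in ordered:
        if offset < off + e.length:
            within = offset - off
            return e.start + within if strand == "+" else e.end - 1 - within
        off += e.length
    raise IndexError(f"mRNA offset {offset} beyond transcript")
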