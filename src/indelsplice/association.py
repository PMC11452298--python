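"""Candidate-indel association windows and cohort carrier filters.

An event is attributed to an indel when the indel's affected span
intersects a short window anchored at the *novel* exon-intron boundary:
3 exonic + 6 intronic bases at a donor (the 9-base donor motif), 18
intronic + 3 exonic bases at an acceptor (polypyrimidine tract + AG +
exon start).  Distance from the authentic boundary is recorded but never
filtered on.

Cohort filtering is deterministic: an association survives only if no
non-carrier shows the event and, among carriers, strictly more
individuals show the event than do not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .annotation import ACCEPTOR, DONOR
from .genome import INSERTED, CoordinateMap
from .junctions import SpliceEvent
from .variants import Indel, Zygosity

DONOR_EXONIC, DONOR_INTRONIC = 3, 6
ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC = 18, 3


@dataclass(frozen=True)
class AssociationWindow:
    """Genomic search window anchored at a novel boundary."""

    side: str
    start: int  # 0-based half-open genomic interval
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start


def window_for(
    novel_boundary: int,
    side: str,
    strand: str,
    donor_extents: tuple[int, int] = (DONOR_EXONIC, DONOR_INTRONIC),
    acceptor_extents: tuple[int, int] = (ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC),
) -> AssociationWindow:
    """Build the candidate-indel window at a novel boundary.

    ``novel_boundary`` is a half-open boundary coordinate (the first base
    on its right belongs to the downstream feature).  Extents are counted
    in transcript orientation: a donor window covers
    ``donor_extents[0]`` exonic + ``donor_extents[1]`` intronic bases, an
    acceptor window ``acceptor_extents[0]`` intronic +
    ``acceptor_extents[1]`` exonic bases; the genomic interval mirrors on
    the minus strand.
    """
    if side == DONOR:
        exonic, intronic = donor_extents
    elif side == ACCEPTOR:
        intronic, exonic = acceptor_extents
    else:
        raise ValueError(f"unknown side {side!r}")
    b = novel_boundary
    if side == DONOR:
        # plus strand: exon ends at b, intron starts at b
        if strand == "+":
            start, end = b - exonic, b + intronic
        else:  # exon starts at b, intron is left of b
            start, end = b - intronic, b + exonic
    else:
        # plus strand acceptor: intron ends at b, exon starts at b
        if strand == "+":
            start, end = b - intronic, b + exonic
        else:
            start, end = b - exonic, b + intronic
    return AssociationWindow(side, start, end)


@dataclass(frozen=True)
class CandidateAssociation:
    """One indel intersecting one event's novel-boundary window."""

    event: SpliceEvent
    indel: Indel
    indel_in_window: bool
    distance_to_authentic: int  # bp from indel start to authentic boundary


def personalized_affected_span(indel: Indel, cmap: CoordinateMap) -> tuple[int, int]:
    """The indel's footprint in personalized coordinates.

    The ALT allele occupies ``len(ALT)`` bases starting at the lifted
    anchor; for net deletions one extra base on the right is included so
    the span covers both flanks of the deletion seam.
    """
    start0 = indel.pos - 1
    status, pers = cmap.lift(start0)
    # the anchor base itself is never deleted (alleles share first base)
    span_len = len(indel.alt_allele) + (1 if indel.net_length < 0 else 0)
    return pers, min(pers + span_len, cmap.pers_length)


def associate(
    event: SpliceEvent,
    indels: Sequence[Indel],
    cmap: CoordinateMap,
    donor_extents: tuple[int, int] = (DONOR_EXONIC, DONOR_INTRONIC),
    acceptor_extents: tuple[int, int] = (ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC),
) -> list[CandidateAssociation]:
    """Find candidate indels for one event in one sample.

    ``indels`` are in reference coordinates and are lifted through the
    sample's map; candidates are those whose personalized affected span
    intersects the window anchored at the event's novel boundary,
    regardless of distance from the authentic boundary.
    """
    win = window_for(
        event.novel_pos, event.side, event.strand, donor_extents, acceptor_extents
    )
    out = []
    for indel in indels:
        if indel.chrom != event.chrom:
            continue
        s, e = personalized_affected_span(indel, cmap)
        if s < win.end and e > win.start:
            out.append(
                CandidateAssociation(
                    event=event,
                    indel=indel,
                    indel_in_window=True,
                    distance_to_authentic=s - event.authentic_pos,
                )
            )
    return out


@dataclass(frozen=True)
class CohortDecision:
    """Outcome of the carrier/non-carrier filters for one association."""

    carriers_with_event: int
    carriers_without_event: int
    noncarriers_with_event: int
    retained: bool

    @classmethod
    def decide(
        cls, carriers_with: int, carriers_without: int, noncarriers_with: int
    ) -> "CohortDecision":
        retained = noncarriers_with == 0 and carriers_with > carriers_without
        return cls(carriers_with, carriers_without, noncarriers_with, retained)


def cohort_filter(
    carrier_samples: Iterable[str],
    noncarrier_samples: Iterable[str],
    samples_with_event: set[str],
) -> CohortDecision:
    """Apply the two cohort criteria to one (event, indel) pair.

    ``samples_with_event`` holds the samples whose own junction data
    produced this event (reference-projected identity).  The association
    is retained iff no non-carrier shows the event and strictly more
    carriers show it than do not.
    """
    carriers = list(carrier_samples)
    cw = sum(1 for s in carriers if s in samples_with_event)
    nw = sum(1 for s in noncarrier_samples if s in samples_with_event)
    return CohortDecision.decide(cw, len(carriers) - cw, nw)


def event_reference_key(event: SpliceEvent, cmap: CoordinateMap) -> tuple:
    """Project an event to a sample-independent identity key.

    Personalized coordinates differ between individuals, so events are
    compared via (chrom, gene, side, reference position of the authentic
    boundary, delta_bp).  The authentic boundary always has a reference
    image (or a flagged left anchor when indel-disrupted); using delta
    rather than the novel boundary keeps the key total even when the
    novel site lies inside inserted sequence with no reference preimage.
    """
    ref_authentic, _ = cmap.lift_back_boundary(event.authentic_pos)
    return (event.chrom, event.gene_name, event.side, ref_authentic, event.delta_bp)


def allele_frequency(indel: Indel, samples: Sequence[str]) -> tuple[float, int, int]:
    """Cohort allele frequency and het/hom counts for a variant."""
    n_het = sum(1 for s in samples if indel.zygosity(s) is Zygosity.HETEROZYGOUS)
    n_hom = sum(1 for s in samples if indel.zygosity(s) is Zygosity.HOMOZYGOUS)
    af = (n_het + 2 * n_hom) / (2 * len(samples)) if samples else 0.0
    return af, n_het, n_hom
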