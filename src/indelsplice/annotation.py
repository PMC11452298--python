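"""Transcript models, GTF input/output and annotation liftover.

The personalized genome shifts the genomic coordinates of every exon
downstream of an applied indel, so each individual needs their own copy
of the annotation before junction reads can be compared with authentic
splice-site positions.  Exon boundaries are stored as 0-based half-open
intervals; a junction's gap ``[left_end, right_start)`` matches an intron
exactly when ``left_end`` equals an exon end and ``right_start`` the next
exon's start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import gffutils

logger = logging.getLogger(__name__)

DONOR = "donor"
ACCEPTOR = "acceptor"


@dataclass(frozen=True)
class ExonRecord:
    """One exon: 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    index: int  # ordinal in transcription order, 1-based

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty exon {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    """Ordered exon chain with an optional CDS span.

    ``exons`` are kept in genomic order (ascending start) regardless of
    strand; ``index`` on each exon records transcription order.  CDS
    bounds are genomic (0-based half-open) and must lie inside the exon
    union.
    """

    transcript_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: tuple[ExonRecord, ...]
    cds_start: int | None = None
    cds_end: int | None = None
    disrupted_boundaries: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or out of order "
                    f"({a.start}-{a.end} vs {b.start}-{b.end})"
                )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.transcript_id}: half-specified CDS")

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end

    def exons_transcription_order(self) -> tuple[ExonRecord, ...]:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def introns(self) -> Iterator[tuple[int, int]]:
        """Genomic intron intervals [end_of_exon, start_of_next)."""
        for a, b in zip(self.exons, self.exons[1:]):
            yield a.end, b.start


def authentic_splice_sites(t: TranscriptModel) -> list[tuple[int, str]]:
    """Enumerate (boundary position, donor/acceptor) for one transcript.

    Boundaries are half-open coordinates: a donor on the plus strand sits
    at the *end* of a non-terminal exon, an acceptor at the *start* of a
    non-initial exon; roles swap on the minus strand.  Single-exon
    transcripts have no splice sites.
    """
    sites: list[tuple[int, str]] = []
    for left, right in t.introns():
        if t.strand == "+":
            sites.append((left, DONOR))
            sites.append((right, ACCEPTOR))
        else:
            sites.append((left, ACCEPTOR))
            sites.append((right, DONOR))
    return sites


def boundary_role(side: str, strand: str) -> str:
    """Role of a junction boundary given which side of the gap it is on.

    ``side`` is "left" (exon ends here, gap begins) or "right" (gap ends,
    exon begins).  On the plus strand a left boundary is a donor; on the
    minus strand the roles are mirrored.
    """
    if side == "left":
        return DONOR if strand == "+" else ACCEPTOR
    return ACCEPTOR if strand == "+" else DONOR


@dataclass
class PersonalizedAnnotation:
    """Transcript set in one individual's coordinates, with boundary indexes.

    ``left_index[(chrom, pos)]`` lists ``(transcript, intron_idx)`` pairs
    whose intron begins at ``pos``; ``right_index`` the analogue for
    intron ends.  ``intron_pairs`` holds every annotated
    ``(chrom, left, right)`` junction for canonical-junction lookup.
    """

    sample_id: str
    transcripts: list[TranscriptModel]
    left_index: dict[tuple[str, int], list[tuple[TranscriptModel, int]]] = field(
        default_factory=dict
    )
    right_index: dict[tuple[str, int], list[tuple[TranscriptModel, int]]] = field(
        default_factory=dict
    )
    intron_pairs: set[tuple[str, int, int]] = field(default_factory=set)

    @classmethod
    def from_transcripts(
        cls, sample_id: str, transcripts: Iterable[TranscriptModel]
    ) -> "PersonalizedAnnotation":
        ann = cls(sample_id, [])
        for t in transcripts:
            ann.add(t)
        return ann

    def add(self, t: TranscriptModel) -> None:
        self.transcripts.append(t)
        for k, (left, right) in enumerate(t.introns()):
            self.left_index.setdefault((t.chrom, left), []).append((t, k))
            self.right_index.setdefault((t.chrom, right), []).append((t, k))
            self.intron_pairs.add((t.chrom, left, right))

    def matches_left(self, chrom: str, pos: int) -> list[tuple[TranscriptModel, int]]:
        return self.left_index.get((chrom, pos), [])

    def matches_right(self, chrom: str, pos: int) -> list[tuple[TranscriptModel, int]]:
        return self.right_index.get((chrom, pos), [])


def lift_transcript(t: TranscriptModel, cmap) -> TranscriptModel | None:
    """Map one transcript through a coordinate map.

    Boundaries inside deleted spans are anchored to the deletion's left
    edge and recorded in ``disrupted_boundaries`` (indel-disrupted
    authentic sites are the causal class of interest, so they are kept,
    not dropped).  A transcript whose exons land out of order — possible
    when a deletion swallows a whole exon — is excluded with a logged
    reason, mirroring how unliftable annotation is dropped by chain-based
    liftover.
    """
    new_exons = []
    disrupted = set()
    for e in t.exons:
        s, s_bad = cmap.lift_boundary(e.start)
        en, e_bad = cmap.lift_boundary(e.end)
        if s_bad:
            disrupted.add(s)
        if e_bad:
            disrupted.add(en)
        if s >= en:
            logger.warning(
                "transcript %s: exon %d collapsed by deletion; transcript excluded",
                t.transcript_id,
                e.index,
            )
            return None
        new_exons.append(ExonRecord(e.chrom, s, en, e.index))
    for a, b in zip(new_exons, new_exons[1:]):
        if a.end > b.start:
            logger.warning(
                "transcript %s: exons out of order after lifting; excluded",
                t.transcript_id,
            )
            return None
    cds_start = cds_end = None
    if t.is_coding:
        cds_start, cs_bad = cmap.lift_boundary(t.cds_start)
        cds_end, ce_bad = cmap.lift_boundary(t.cds_end)
        if cs_bad:
            disrupted.add(cds_start)
        if ce_bad:
            disrupted.add(cds_end)
        if cds_start >= cds_end:
            cds_start = cds_end = None
    return replace(
        t,
        exons=tuple(new_exons),
        cds_start=cds_start,
        cds_end=cds_end,
        disrupted_boundaries=frozenset(disrupted),
    )


def lift_annotation(
    transcripts: Iterable[TranscriptModel],
    maps: dict[str, "object"],
    sample_id: str = "",
) -> PersonalizedAnnotation:
    """Lift a full annotation through per-chromosome coordinate maps."""
    lifted = []
    for t in transcripts:
        cmap = maps.get(t.chrom)
        if cmap is None:
            logger.warning("transcript %s: no map for %s; excluded", t.transcript_id, t.chrom)
            continue
        lt = lift_transcript(t, cmap)
        if lt is not None:
            lifted.append(lt)
    return PersonalizedAnnotation.from_transcripts(sample_id, lifted)


# ---------------------------------------------------------------------------
# GTF I/O


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse exon and CDS rows of a GTF into transcript models.

    Both UCSC and Ensembl attribute dialects are accepted (whatever
    gffutils can group by ``transcript_id``); features other than exon
    and CDS are ignored.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes.get("transcript_id", [""])[0]
        if not tid:
            continue
        gene = (
            feat.attributes.get("gene_name", [None])[0]
            or feat.attributes.get("gene_id", [""])[0]
        )
        meta.setdefault(tid, (feat.seqid, feat.strand, gene))
        target = exons if feat.featuretype == "exon" else cds
        target.setdefault(tid, []).append((feat.start - 1, feat.end))
    out = []
    for tid, spans in exons.items():
        chrom, strand, gene = meta[tid]
        spans.sort()
        order = range(1, len(spans) + 1) if strand == "+" else range(len(spans), 0, -1)
        ex = tuple(
            ExonRecord(chrom, s, e, idx) for (s, e), idx in zip(spans, order)
        )
        cspans = cds.get(tid)
        cds_start = min(s for s, _ in cspans) if cspans else None
        cds_end = max(e for _, e in cspans) if cspans else None
        out.append(
            TranscriptModel(tid, gene, chrom, strand, ex, cds_start, cds_end)
        )
    out.sort(key=lambda t: (t.chrom, t.span, t.transcript_id))
    return out


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write exon/CDS rows (1-based inclusive, per GTF convention)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_name}"; transcript_id "{t.transcript_id}";'
            for e in t.exons:
                fh.write(
                    f"{t.chrom}\tindelsplice\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )
                if t.is_coding:
                    cs = max(e.start, t.cds_start)
                    ce = min(e.end, t.cds_end)
                    if cs < ce:
                        fh.write(
                            f"{t.chrom}\tindelsplice\tCDS\t{cs + 1}\t{ce}\t.\t"
                            f"{t.strand}\t.\t{attrs}\n"
                        )


def write_splice_site_table(
    ann: PersonalizedAnnotation, path: str | Path
) -> None:
    """TSV of authentic splice sites (chrom, pos, side, transcript, disrupted)."""
    rows = []
    for t in ann.transcripts:
        for pos, side in authentic_splice_sites(t):
            rows.append(
                (t.chrom, pos, side, t.transcript_id, int(pos in t.disrupted_boundaries))
            )
    rows.sort()
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tside\ttranscript_id\tdisrupted\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
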