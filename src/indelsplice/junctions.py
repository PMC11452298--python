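"""Junction-read extraction and exon extension/shrinkage event calling.

A spliced read whose CIGAR contains a skipped region (N) witnesses one
splice junction per gap.  Candidate novel events are junctions where
exactly one side coincides with an annotated exon boundary — the
one-side-consistent rule — the other side then being a putative novel
splice site.  Groups of such reads become events once they clear the
read-coverage filter (>= min_reads supporting reads) and the novel-side
anchor filter (at least one read whose block on the inconsistent side
spans >= min_novel_anchor aligned bases).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .annotation import PersonalizedAnnotation, TranscriptModel, boundary_role

CANONICAL = "canonical"
CANDIDATE_NOVEL = "candidate_novel"
UNANNOTATED = "unannotated"
EXOTIC = "exotic"

EXTENSION = "extension"
SHRINKAGE = "shrinkage"

DEFAULT_MIN_READS = 2
DEFAULT_MIN_NOVEL_ANCHOR = 5


@dataclass(frozen=True)
class JunctionRead:
    """One skipped-region gap from one read.

    ``left_block_end`` / ``right_block_start`` delimit the gap as a
    0-based half-open genomic interval; the anchors are the aligned block
    lengths immediately flanking the gap.
    """

    sample_id: str
    chrom: str
    left_block_end: int
    right_block_start: int
    left_anchor_len: int
    right_anchor_len: int

    def __post_init__(self) -> None:
        if self.left_block_end >= self.right_block_start:
            raise ValueError("junction gap is empty or inverted")
        if self.left_anchor_len < 1 or self.right_anchor_len < 1:
            raise ValueError("anchors must be >= 1 bp")


@dataclass
class NovelJunction:
    """A one-side-consistent junction aggregated over its supporting reads."""

    chrom: str
    consistent_side: str  # "left" or "right"
    consistent_pos: int
    novel_pos: int
    side: str  # donor/acceptor role of the NOVEL boundary
    support: dict[str, int] = field(default_factory=dict)
    max_novel_anchor: int = 0

    @property
    def total_support(self) -> int:
        return sum(self.support.values())


@dataclass(frozen=True)
class SpliceEvent:
    """One novel boundary displacing one authentic boundary of a transcript.

    ``delta_bp`` is the signed change in exon length: positive for an
    extension (novel boundary intronic of the authentic one), negative
    for a shrinkage.
    """

    junction: NovelJunction
    transcript_id: str
    gene_name: str
    strand: str
    event_class: str
    delta_bp: int
    authentic_pos: int

    def __post_init__(self) -> None:
        if self.delta_bp == 0:
            raise ValueError("a splice event must displace the boundary")
        expect = EXTENSION if self.delta_bp > 0 else SHRINKAGE
        if self.event_class != expect:
            raise ValueError(
                f"event_class {self.event_class} inconsistent with delta {self.delta_bp}"
            )

    @property
    def chrom(self) -> str:
        return self.junction.chrom

    @property
    def novel_pos(self) -> int:
        return self.junction.novel_pos

    @property
    def side(self) -> str:
        return self.junction.side


def _junction_gaps(read: pysam.AlignedSegment) -> list[tuple[int, int, int, int]]:
    """All N gaps of one alignment with flanking anchor lengths.

    Anchor lengths count read-aligned bases (M/=/X) in the blocks
    adjoining the gap; deletions extend a block on the reference but add
    no anchor, insertions and clips consume no reference at all.
    """
    out = []
    ref = read.reference_start
    blocks: list[tuple[int, int]] = []  # (aligned_len, ref_end) per block
    gaps: list[tuple[int, int, int]] = []  # (left_end, right_start, left_block_idx)
    aligned = 0
    for op, length in read.cigartuples:
        if op == 3:
            blocks.append((aligned, ref))
            gaps.append((ref, ref + length, len(blocks) - 1))
            ref += length
            aligned = 0
        elif op in (0, 7, 8):
            ref += length
            aligned += length
        elif op == 2:
            ref += length
    blocks.append((aligned, ref))
    for left_end, right_start, i in gaps:
        left_anchor = blocks[i][0]
        right_anchor = blocks[i + 1][0]
        out.append((left_end, right_start, left_anchor, right_anchor))
    return out


def extract_junctions(
    alignments: "pysam.AlignmentFile | Iterable[pysam.AlignedSegment]",
    sample_id: str,
    valid_references: set[str] | None = None,
) -> list[JunctionRead]:
    """Collect one :class:`JunctionRead` per skipped-region gap per read.

    Unmapped, secondary, supplementary and duplicate records are skipped.
    Multi-gap reads contribute each gap independently.
    """
    out: list[JunctionRead] = []
    for read in alignments:
        if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
            continue
        if read.cigartuples is None:
            continue
        chrom = read.reference_name
        if valid_references is not None and chrom not in valid_references:
            raise ValueError(
                f"alignment reference {chrom!r} absent from the personalized genome"
            )
        for left_end, right_start, la, ra in _junction_gaps(read):
            if la < 1 or ra < 1:
                continue  # gap at the very edge of the alignment
            out.append(
                JunctionRead(sample_id, chrom, left_end, right_start, la, ra)
            )
    return out


def extract_junctions_from_file(
    path: str | Path, sample_id: str, valid_references: set[str] | None = None
) -> list[JunctionRead]:
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        return extract_junctions(af, sample_id, valid_references)


def classify_junction(
    j: JunctionRead, ann: PersonalizedAnnotation
) -> tuple[str, list[tuple[TranscriptModel, int]]]:
    """One-side-consistent classification of a junction read.

    Returns the class and, for ``candidate_novel``, the transcripts (with
    intron index) matched on the consistent side.

    - ``canonical``: both sides are the two ends of an annotated intron;
    - ``candidate_novel``: exactly one side matches any annotated boundary;
    - ``unannotated``: neither side matches;
    - ``exotic``: both sides match boundaries but never as an annotated
      intron pair (e.g. exon skipping); excluded from event calling.
    """
    left_hits = ann.matches_left(j.chrom, j.left_block_end)
    right_hits = ann.matches_right(j.chrom, j.right_block_start)
    if left_hits and right_hits:
        if (j.chrom, j.left_block_end, j.right_block_start) in ann.intron_pairs:
            return CANONICAL, []
        return EXOTIC, []
    if left_hits:
        return CANDIDATE_NOVEL, left_hits
    if right_hits:
        return CANDIDATE_NOVEL, right_hits
    return UNANNOTATED, []


def call_events(
    junctions: Iterable[JunctionRead],
    ann: PersonalizedAnnotation,
    min_reads: int = DEFAULT_MIN_READS,
    min_novel_anchor: int = DEFAULT_MIN_NOVEL_ANCHOR,
) -> list[SpliceEvent]:
    """Call exon extension/shrinkage events from one sample's junctions.

    Candidate-novel junction reads are grouped by
    (consistent boundary, novel boundary); a group becomes an event when
    it has ``min_reads`` or more supporting reads and at least one read
    whose anchor on the novel (inconsistent) side spans
    ``min_novel_anchor`` aligned bases.  One event is emitted per matched
    transcript, deduplicated per gene.
    """
    groups: dict[tuple, NovelJunction] = {}
    matches: dict[tuple, list[tuple[TranscriptModel, int]]] = {}
    for j in junctions:
        cls, hits = classify_junction(j, ann)
        if cls != CANDIDATE_NOVEL:
            continue
        consistent_side = "left" if ann.matches_left(j.chrom, j.left_block_end) else "right"
        if consistent_side == "left":
            consistent_pos, novel_pos = j.left_block_end, j.right_block_start
            novel_anchor = j.right_anchor_len
            novel_side_of_gap = "right"
        else:
            consistent_pos, novel_pos = j.right_block_start, j.left_block_end
            novel_anchor = j.left_anchor_len
            novel_side_of_gap = "left"
        key = (j.chrom, consistent_side, consistent_pos, novel_pos)
        strand = hits[0][0].strand
        if key not in groups:
            groups[key] = NovelJunction(
                chrom=j.chrom,
                consistent_side=consistent_side,
                consistent_pos=consistent_pos,
                novel_pos=novel_pos,
                side=boundary_role(novel_side_of_gap, strand),
            )
            matches[key] = hits
        nj = groups[key]
        nj.support[j.sample_id] = nj.support.get(j.sample_id, 0) + 1
        nj.max_novel_anchor = max(nj.max_novel_anchor, novel_anchor)

    events: list[SpliceEvent] = []
    seen_gene: set[tuple] = set()
    for key in sorted(groups, key=lambda k: (k[0], k[2], k[3], k[1])):
        nj = groups[key]
        if nj.total_support < min_reads or nj.max_novel_anchor < min_novel_anchor:
            continue
        for t, intron_idx in matches[key]:
            left, right = list(t.introns())[intron_idx]
            if nj.consistent_side == "right":
                # consistent boundary = intron end; displaced authentic
                # boundary = intron start (exon end on its left)
                authentic = left
                delta = nj.novel_pos - authentic
            else:
                authentic = right
                delta = authentic - nj.novel_pos
            if delta == 0:
                continue  # novel side coincides with the partner boundary
            event_class = EXTENSION if delta > 0 else SHRINKAGE
            gene_key = (t.gene_name, nj.chrom, authentic, nj.novel_pos)
            if gene_key in seen_gene:
                continue
            seen_gene.add(gene_key)
            events.append(
                SpliceEvent(
                    junction=nj,
                    transcript_id=t.transcript_id,
                    gene_name=t.gene_name,
                    strand=t.strand,
                    event_class=event_class,
                    delta_bp=delta,
                    authentic_pos=authentic,
                )
            )
    return events


def write_junction_table(junctions: Sequence[JunctionRead], path: str | Path) -> None:
    """Per-sample TSV of junction gaps with support and anchor maxima."""
    agg: dict[tuple, list[int, int, int]] = defaultdict(lambda: [0, 0, 0])
    for j in junctions:
        row = agg[(j.chrom, j.left_block_end, j.right_block_start)]
        row[0] += 1
        row[1] = max(row[1], j.left_anchor_len)
        row[2] = max(row[2], j.right_anchor_len)
    with open(path, "w") as fh:
        fh.write("chrom\tleft_end\tright_start\tsupport\tmax_left_anchor\tmax_right_anchor\n")
        for key in sorted(agg):
            fh.write("\t".join(map(str, key + tuple(agg[key]))) + "\n")
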