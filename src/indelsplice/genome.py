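"""Personalized-genome construction and invertible coordinate mapping.

Rewriting a reference chromosome with an individual's indels shifts every
downstream coordinate.  The :class:`CoordinateMap` records that shift as a
piecewise-constant offset over reference intervals, plus the intervals
that exist on only one side (deleted reference spans, inserted
personalized spans), so positions and annotation can be lifted in both
directions exactly.

All arithmetic here is 0-based half-open; 1-based conversions happen at
the VCF/GTF boundaries only.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .variants import Indel

MAPPED = "mapped"
DELETED = "deleted"
INSERTED = "inserted"


class ReferenceMismatchError(ValueError):
    """An indel's REF allele disagrees with the reference sequence."""


@dataclass(frozen=True)
class _Segment:
    ref_start: int
    ref_end: int
    offset: int  # personalized = reference + offset within this segment

    @property
    def pers_start(self) -> int:
        return self.ref_start + self.offset

    @property
    def pers_end(self) -> int:
        return self.ref_end + self.offset


@dataclass
class CoordinateMap:
    """Invertible piecewise-offset map for one chromosome.

    ``segments`` cover every reference position outside ``deleted_spans``;
    ``inserted_spans`` are personalized intervals with no reference
    preimage.  ``lift`` and ``lift_back`` return a ``(status, position)``
    pair: positions inside a one-sided span get status ``"deleted"`` /
    ``"inserted"`` together with the coordinate of the span's left anchor
    on the other side.
    """

    chrom: str
    ref_length: int
    segments: list[_Segment] = field(default_factory=list)
    # (ref_start, ref_end, personalized position of left anchor base)
    deleted_spans: list[tuple[int, int, int]] = field(default_factory=list)
    # (pers_start, pers_end, reference position of left anchor base)
    inserted_spans: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._seg_ref_starts = [s.ref_start for s in self.segments]
        self._seg_pers_starts = [s.pers_start for s in self.segments]
        self._del_starts = [d[0] for d in self.deleted_spans]
        self._ins_starts = [i[0] for i in self.inserted_spans]

    @property
    def pers_length(self) -> int:
        if not self.segments:
            return self.ref_length
        return self.segments[-1].pers_end

    def lift(self, ref_pos: int) -> tuple[str, int]:
        """Reference position -> (status, personalized position)."""
        if not 0 <= ref_pos < self.ref_length:
            raise IndexError(
                f"{self.chrom}: reference position {ref_pos} outside [0, {self.ref_length})"
            )
        i = bisect.bisect_right(self._seg_ref_starts, ref_pos) - 1
        if i >= 0:
            seg = self.segments[i]
            if ref_pos < seg.ref_end:
                return MAPPED, ref_pos + seg.offset
        j = bisect.bisect_right(self._del_starts, ref_pos) - 1
        d = self.deleted_spans[j]
        assert d[0] <= ref_pos < d[1]
        return DELETED, d[2]

    def lift_back(self, pers_pos: int) -> tuple[str, int]:
        """Personalized position -> (status, reference position)."""
        if not 0 <= pers_pos < self.pers_length:
            raise IndexError(
                f"{self.chrom}: personalized position {pers_pos} outside "
                f"[0, {self.pers_length})"
            )
        i = bisect.bisect_right(self._seg_pers_starts, pers_pos) - 1
        if i >= 0:
            seg = self.segments[i]
            if pers_pos < seg.pers_end:
                return MAPPED, pers_pos - seg.offset
        j = bisect.bisect_right(self._ins_starts, pers_pos) - 1
        ins = self.inserted_spans[j]
        assert ins[0] <= pers_pos < ins[1]
        return INSERTED, ins[2]

    def lift_boundary(self, ref_boundary: int) -> tuple[int, bool]:
        """Lift a half-open boundary coordinate (between-base position).

        Returns ``(personalized boundary, disrupted)``.  A boundary whose
        right-adjacent base was deleted is anchored to the left edge of
        the deletion's image and flagged disrupted.  Insertions exactly at
        the boundary land *after* the boundary by convention (the boundary
        maps with the base to its right).
        """
        if not 0 <= ref_boundary <= self.ref_length:
            raise IndexError(
                f"{self.chrom}: boundary {ref_boundary} outside [0, {self.ref_length}]"
            )
        if ref_boundary == self.ref_length:
            return self.pers_length, False
        status, pos = self.lift(ref_boundary)
        if status == MAPPED:
            return pos, False
        return pos + 1, True  # left edge of the deletion seam

    def lift_back_boundary(self, pers_boundary: int) -> tuple[int, bool]:
        """Inverse of :meth:`lift_boundary`; flag is True inside insertions."""
        if not 0 <= pers_boundary <= self.pers_length:
            raise IndexError(
                f"{self.chrom}: boundary {pers_boundary} outside [0, {self.pers_length}]"
            )
        if pers_boundary == self.pers_length:
            return self.ref_length, False
        status, pos = self.lift_back(pers_boundary)
        if status == MAPPED:
            return pos, False
        return pos + 1, True

    @classmethod
    def identity(cls, chrom: str, length: int) -> "CoordinateMap":
        return cls(chrom, length, [_Segment(0, length, 0)] if length else [])

    def write_chain(self, handle, chain_id: int = 1) -> None:
        """Write the map as a UCSC chain (reference = target side)."""
        t_size, q_size = self.ref_length, self.pers_length
        print(
            f"chain 1000 {self.chrom} {t_size} + 0 {t_size} "
            f"{self.chrom} {q_size} + 0 {q_size} {chain_id}",
            file=handle,
        )
        for k, seg in enumerate(self.segments):
            size = seg.ref_end - seg.ref_start
            if k == len(self.segments) - 1:
                print(size, file=handle)
            else:
                nxt = self.segments[k + 1]
                dt = nxt.ref_start - seg.ref_end  # deleted from reference
                dq = nxt.pers_start - seg.pers_end  # inserted in personalized
                print(f"{size}\t{dt}\t{dq}", file=handle)
        print(file=handle)


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def apply_indels(
    reference_seq: str, indels: Sequence[Indel], chrom: str = ""
) -> tuple[str, CoordinateMap]:
    """Rewrite one chromosome with a disjoint, sorted set of indels.

    Each indel's REF span is replaced by its ALT string.  REF must match
    the reference exactly at its position, otherwise
    :class:`ReferenceMismatchError` is raised naming both strings.

    Returns the personalized sequence and the :class:`CoordinateMap`
    linking the two coordinate systems.
    """
    ref_len = len(reference_seq)
    segments: list[_Segment] = []
    deleted: list[tuple[int, int, int]] = []
    inserted: list[tuple[int, int, int]] = []
    pieces: list[str] = []

    cur_ref = 0
    offset = 0
    last = None
    for indel in indels:
        if chrom and indel.chrom != chrom:
            raise ValueError(f"indel {indel.chrom}:{indel.pos} on wrong chromosome {chrom!r}")
        start, end = indel.ref_span
        if last is not None and start < last:
            raise ValueError(
                f"indels out of order or overlapping at {indel.chrom}:{indel.pos}; "
                "run select_nonoverlapping_indels first"
            )
        if end > ref_len:
            raise IndexError(f"indel at {indel.chrom}:{indel.pos} runs past the chromosome end")
        observed = reference_seq[start:end].upper()
        if observed != indel.ref_allele:
            raise ReferenceMismatchError(
                f"{indel.chrom or chrom}:{indel.pos}: REF allele "
                f"{indel.ref_allele!r} does not match reference {observed!r}"
            )
        c = _common_prefix_len(indel.ref_allele, indel.alt_allele)
        # matched prefix stays 1:1; the REF remainder is deleted, the ALT
        # remainder is inserted, both at the same seam.
        seg_end = start + c
        if seg_end > cur_ref:
            segments.append(_Segment(cur_ref, seg_end, offset))
            pieces.append(reference_seq[cur_ref:seg_end])
        del_len = len(indel.ref_allele) - c
        ins_len = len(indel.alt_allele) - c
        seam_pers = seg_end + offset
        if del_len:
            deleted.append((seg_end, seg_end + del_len, seam_pers - 1))
        if ins_len:
            inserted.append((seam_pers, seam_pers + ins_len, seg_end - 1))
            pieces.append(indel.alt_allele[c:])
        offset += ins_len - del_len
        cur_ref = end
        last = end
    if cur_ref < ref_len:
        segments.append(_Segment(cur_ref, ref_len, offset))
        pieces.append(reference_seq[cur_ref:])

    pers = "".join(pieces)
    cmap = CoordinateMap(chrom, ref_len, segments, deleted, inserted)
    assert len(pers) == cmap.pers_length == ref_len + sum(i.net_length for i in indels)
    return pers, cmap


def lift_position(cmap: CoordinateMap, ref_pos: int) -> tuple[str, int]:
    """Functional alias for :meth:`CoordinateMap.lift` (0-based)."""
    return cmap.lift(ref_pos)


def lift_position_back(cmap: CoordinateMap, pers_pos: int) -> tuple[str, int]:
    """Functional alias for :meth:`CoordinateMap.lift_back` (0-based)."""
    return cmap.lift_back(pers_pos)


@dataclass
class PersonalizedGenome:
    """One individual's rewritten genome plus its coordinate maps."""

    sample_id: str
    sequences: dict[str, str]
    maps: dict[str, CoordinateMap]
    applied_indels: list[Indel]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]

    @classmethod
    def build(
        cls,
        sample_id: str,
        reference: dict[str, str] | "object",
        indels_by_chrom: dict[str, Sequence[Indel]],
        chroms: Iterable[str] | None = None,
    ) -> "PersonalizedGenome":
        """Apply per-chromosome indel sets to a reference.

        ``reference`` may be a plain dict of sequences or any mapping-like
        object (e.g. a :class:`pyfaidx.Fasta`) whose values stringify to
        sequence.
        """
        if chroms is None:
            chroms = list(reference.keys())
        sequences: dict[str, str] = {}
        maps: dict[str, CoordinateMap] = {}
        applied: list[Indel] = []
        for chrom in chroms:
            ref_seq = str(reference[chrom]).upper()
            ind = list(indels_by_chrom.get(chrom, []))
            pers, cmap = apply_indels(ref_seq, ind, chrom=chrom)
            sequences[chrom] = pers
            maps[chrom] = cmap
            applied.extend(ind)
        return cls(sample_id, sequences, maps, applied)

    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        write_fasta(self.sequences, path, width=width)

    def write_chains(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for k, chrom in enumerate(sorted(self.maps), start=1):
                self.maps[chrom].write_chain(fh, chain_id=k)


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (small) FASTA into memory, uppercased."""
    import pyfaidx

    with pyfaidx.Fasta(str(path), rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}
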