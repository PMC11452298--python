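"""Indel representation, VCF input and per-individual indel selection.

An individual-specific genome is built from the short insertions and
deletions an individual carries.  Only indels are consumed: pure
substitutions never shift coordinates and are ignored by genome
personalization.  When two carried indels overlap on the reference, the
one earlier in ascending positional order wins and the later one is
dropped, so the retained set always has pairwise-disjoint reference
spans.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

_VALID_BASES = frozenset("ACGTN")


class Zygosity(enum.Enum):
    """Carrier status of one sample for one variant."""

    ABSENT = 0
    HETEROZYGOUS = 1
    HOMOZYGOUS = 2

    @property
    def is_carrier(self) -> bool:
        return self is not Zygosity.ABSENT


class MalformedVariantError(ValueError):
    """A variant record violates the indel invariants (bad alleles etc.)."""


@dataclass(frozen=True)
class Indel:
    """One normalized, biallelic VCF-style indel.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    pos : int
        1-based reference position of the first REF base (VCF POS).
    ref_allele, alt_allele : str
        Uppercase DNA strings; lengths must differ (a pure substitution
        is not an indel).
    variant_id : str
        dbSNP-style identifier, or ``""``.
    genotype_by_sample : mapping
        sample id -> :class:`Zygosity`.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_id: str = ""
    genotype_by_sample: Mapping[str, Zygosity] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, allele in (("REF", self.ref_allele), ("ALT", self.alt_allele)):
            if not allele or set(allele) - _VALID_BASES:
                raise MalformedVariantError(
                    f"{self.chrom}:{self.pos} ({self.variant_id or 'no id'}): "
                    f"{name} allele {allele!r} is not a non-empty ACGTN string"
                )
        if len(self.ref_allele) == len(self.alt_allele):
            raise MalformedVariantError(
                f"{self.chrom}:{self.pos}: REF/ALT have equal length "
                f"({self.ref_allele!r} -> {self.alt_allele!r}); not an indel"
            )
        if self.ref_allele[0] != self.alt_allele[0]:
            raise MalformedVariantError(
                f"{self.chrom}:{self.pos}: REF and ALT do not share their "
                f"first base ({self.ref_allele!r} -> {self.alt_allele!r}); "
                "left-normalize the record first"
            )

    @property
    def net_length(self) -> int:
        """len(ALT) - len(REF); positive for insertions."""
        return len(self.alt_allele) - len(self.ref_allele)

    @property
    def is_insertion(self) -> bool:
        return self.net_length > 0

    @property
    def ref_span(self) -> tuple[int, int]:
        """0-based half-open reference interval occupied by REF."""
        start = self.pos - 1
        return start, start + len(self.ref_allele)

    def zygosity(self, sample: str) -> Zygosity:
        return self.genotype_by_sample.get(sample, Zygosity.ABSENT)


def select_nonoverlapping_indels(
    variants: Iterable[Indel],
    sample: str | None = None,
    min_len: int = 1,
    max_len: int | None = None,
) -> list[Indel]:
    """Pick the indels applied to one personalized genome.

    Variants are restricted to those carried by ``sample`` (het or hom;
    ``sample=None`` keeps all), length-filtered on ``|net_length|``, and
    sorted by ascending position.  Whenever two reference-affected spans
    ``[pos, pos+len(REF))`` intersect, only the earlier variant is kept,
    so the result has pairwise-disjoint spans.

    Ties at the same position are broken by input order, matching the
    "first in ascending positional order" rule.
    """
    pool = []
    for order, v in enumerate(variants):
        if sample is not None and not v.zygosity(sample).is_carrier:
            continue
        size = abs(v.net_length)
        if size < min_len or (max_len is not None and size > max_len):
            continue
        pool.append((v.pos, order, v))
    pool.sort(key=lambda t: (t[0], t[1]))

    kept: list[Indel] = []
    occupied_end = -1  # exclusive 0-based end of last kept span
    for _, _, v in pool:
        start, end = v.ref_span
        if start < occupied_end:
            continue  # overlaps an earlier (already kept) indel
        kept.append(v)
        occupied_end = end
    return kept


def _zygosity_from_gt(gt: tuple | None, alt_index: int) -> Zygosity:
    if gt is None:
        return Zygosity.ABSENT
    n_alt = sum(1 for a in gt if a == alt_index)
    n_called = sum(1 for a in gt if a is not None)
    if n_alt == 0:
        return Zygosity.ABSENT
    if n_called and n_alt == n_called:
        return Zygosity.HOMOZYGOUS
    return Zygosity.HETEROZYGOUS


def read_indels_vcf(
    path: str | Path,
    samples: Sequence[str] | None = None,
) -> list[Indel]:
    """Read indels from a VCF 4.x file (plain or bgzipped).

    Multi-allelic records are split into biallelic ones; each split
    record's genotypes reflect carriage of that specific ALT.  SNV
    (equal-length) alleles, symbolic alleles and alleles with
    non-ACGTN characters are skipped.  Records whose REF/ALT do not
    share a first base (not left-anchored) are skipped as well rather
    than guessed at.
    """
    indels: list[Indel] = []
    with pysam.VariantFile(str(path)) as vcf:
        want = list(samples) if samples is not None else list(vcf.header.samples)
        for rec in vcf:
            if not rec.alts:
                continue
            for alt_index, alt in enumerate(rec.alts, start=1):
                if alt is None or alt.startswith("<") or "*" in alt:
                    continue
                ref = rec.ref.upper()
                alt = alt.upper()
                if set(ref) - _VALID_BASES or set(alt) - _VALID_BASES:
                    continue
                if len(ref) == len(alt) or ref[0] != alt[0]:
                    continue
                genotypes = {}
                for s in want:
                    gt = rec.samples[s].get("GT") if s in rec.samples else None
                    z = _zygosity_from_gt(gt, alt_index)
                    if z.is_carrier:
                        genotypes[s] = z
                indels.append(
                    Indel(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=ref,
                        alt_allele=alt,
                        variant_id=rec.id or "",
                        genotype_by_sample=genotypes,
                    )
                )
    return indels
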