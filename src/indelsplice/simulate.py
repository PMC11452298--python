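"""Self-contained synthetic cohorts with planted splice-altering indels.

The generator stands in for a population variant panel plus cohort
RNA-seq: it emits a reference genome (FASTA), gene annotation (GTF),
per-individual indel calls (VCF) and per-individual spliced alignments
(SAM) written directly against each individual's personalized genome,
together with a truth table describing every planted event and the
outcome the pipeline should reach.

Planted event kinds mirror the mechanisms seen in real data:

- ``duplicated_donor_insertion`` — an intronic insertion whose 3' end
  duplicates the 21 bases spanning the authentic donor, recreating the
  donor motif downstream and extending the exon by exactly the net
  inserted length;
- ``gc_ag_activation_deletion`` — a small intronic deletion that
  activates a non-canonical GC-AG donor 4 bp into the intron;
- ``splice_site_deletion`` — a deletion removing the authentic donor GT,
  shifting splicing to a cryptic exonic donor (exon shrinkage);
- ``acceptor_region_insertion`` — a 2-bp insertion near the intron 3'
  end that creates a new AG, extending the exon at the acceptor;
- ``neutral_indel`` — a deep-intronic indel with no splicing effect;
- ``coincidental_indel`` — indel plus event, but the event also appears
  in one non-carrier, so the cohort filter must reject it.

Coding sequences are built from stop-free sense codons; every internal
exon carries a short motif that is a stop codon in both shifted frames
(and silent in frame zero), so any frameshifting planted event
deterministically yields a premature termination codon downstream.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import ACCEPTOR, DONOR, ExonRecord, TranscriptModel, write_gtf
from .genome import PersonalizedGenome, write_fasta
from .junctions import EXTENSION, SHRINKAGE
from .variants import Indel, Zygosity

_SENSE_CODONS = sorted(
    {
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
    }
    - {"TAA", "TAG", "TGA"}
)

# ATA ATT AAT AAC: no stop in frame 0, TAA in frame 1, AAT-TAA in frame 2.
_FRAMESHIFT_STOP_MOTIF = "ATAATTAATAAC"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@dataclass
class PlantedEvent:
    """Specification of one planted indel and its expected outcome."""

    kind: str
    gene_index: int
    intron_index: int | None = None  # transcription order, 1-based
    insert_length: int = 35  # duplicated_donor_insertion only

    # filled in by build_cohort:
    indel: Indel | None = None
    side: str | None = None
    event_class: str | None = None
    delta_bp: int | None = None
    gene_name: str | None = None

    @property
    def expects_event(self) -> bool:
        return self.kind not in ("neutral_indel",)

    @property
    def expects_retained(self) -> bool:
        return self.expects_event and self.kind != "coincidental_indel"

    @property
    def disrupts_authentic(self) -> bool:
        return self.kind == "splice_site_deletion"


def default_planted_events() -> list[PlantedEvent]:
    return [
        PlantedEvent("duplicated_donor_insertion", 0, insert_length=35),
        PlantedEvent("gc_ag_activation_deletion", 1),
        PlantedEvent("splice_site_deletion", 2),
        PlantedEvent("acceptor_region_insertion", 3),
        PlantedEvent("neutral_indel", 4),
        PlantedEvent("coincidental_indel", 5),
    ]


@dataclass
class SimulationConfig:
    """Cohort-simulation parameters.

    Defaults emulate the study conditions at desk scale: a cohort of 20
    diploid individuals, ~30% carriers per planted indel, mean junction
    coverage 10 reads, no expression dropout, and a low rate of spurious
    junctions.  The same seed always reproduces byte-identical output.
    """

    seed: int
    n_samples: int = 20
    n_genes: int = 8
    exons_per_gene: tuple[int, int] = (4, 6)
    exon_len_range: tuple[int, int] = (90, 150)
    intron_len_range: tuple[int, int] = (150, 300)
    utr5_len: int = 30
    flank_len: int = 200
    coverage: float = 10.0
    carrier_fraction: float = 0.3
    hom_fraction: float = 0.3
    expression_dropout_prob: float = 0.0
    noise_junction_rate: float = 0.05
    read_length: int = 75
    planted_events: list[PlantedEvent] = field(default_factory=default_planted_events)

    def __post_init__(self) -> None:
        for p, name in (
            (self.carrier_fraction, "carrier_fraction"),
            (self.hom_fraction, "hom_fraction"),
            (self.expression_dropout_prob, "expression_dropout_prob"),
            (self.noise_junction_rate, "noise_junction_rate"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if any(ev.gene_index >= self.n_genes for ev in self.planted_events):
            raise ValueError("planted event references a gene beyond n_genes")


@dataclass
class _Gene:
    name: str
    chrom: str
    strand: str
    exon_seqs: list[str]  # transcription order
    intron_seqs: list[str]
    cds_t: tuple[int, int]  # transcript-space CDS span (includes stop codon)
    locus_start: int = 0  # genomic start of the locus on its chromosome

    @property
    def n_exons(self) -> int:
        return len(self.exon_seqs)

    def locus_seq(self) -> str:
        """Genomic-strand locus sequence."""
        parts = []
        for i, ex in enumerate(self.exon_seqs):
            parts.append(ex)
            if i < len(self.intron_seqs):
                parts.append(self.intron_seqs[i])
        t = "".join(parts)
        return t if self.strand == "+" else _revcomp(t)

    def t_exon_spans(self) -> list[tuple[int, int]]:
        """Transcript-space (locus) exon intervals, transcription order."""
        spans, off = [], 0
        for i, ex in enumerate(self.exon_seqs):
            spans.append((off, off + len(ex)))
            off += len(ex)
            if i < len(self.intron_seqs):
                off += len(self.intron_seqs[i])
        return spans

    def locus_len(self) -> int:
        return sum(map(len, self.exon_seqs)) + sum(map(len, self.intron_seqs))

    def transcript_model(self) -> TranscriptModel:
        L = self.locus_len()
        spans = self.t_exon_spans()
        exons = []
        for idx, (s, e) in enumerate(spans, start=1):
            if self.strand == "+":
                gs, ge = self.locus_start + s, self.locus_start + e
            else:
                gs, ge = self.locus_start + L - e, self.locus_start + L - s
            exons.append((gs, ge, idx))
        exons.sort()
        ex = tuple(ExonRecord(self.chrom, s, e, idx) for s, e, idx in exons)
        # CDS transcript-space -> genomic: map through the exon chain
        cs_t, ce_t = self.cds_t
        g_positions = []
        for t_off in (cs_t, ce_t - 1):
            g_positions.append(self._t_to_genomic(t_off))
        cds_start, cds_end = min(g_positions), max(g_positions) + 1
        return TranscriptModel(
            transcript_id=f"{self.name}.t1",
            gene_name=self.name,
            chrom=self.chrom,
            strand=self.strand,
            exons=ex,
            cds_start=cds_start,
            cds_end=cds_end,
        )

    def _t_to_genomic(self, mrna_off: int) -> int:
        """Map an mRNA offset (transcription order) to a genomic position."""
        L = self.locus_len()
        spans = self.t_exon_spans()
        acc = 0
        for s, e in spans:
            if mrna_off < acc + (e - s):
                t_pos = s + (mrna_off - acc)
                if self.strand == "+":
                    return self.locus_start + t_pos
                return self.locus_start + L - 1 - t_pos
            acc += e - s
        raise IndexError(mrna_off)

    def donor_boundary(self, intron_index: int) -> int:
        """Genomic boundary coordinate of the donor of intron k (1-based)."""
        t = self.transcript_model()
        ordered = t.exons_transcription_order()
        exon = ordered[intron_index - 1]
        return exon.end if self.strand == "+" else exon.start

    def acceptor_boundary(self, intron_index: int) -> int:
        t = self.transcript_model()
        ordered = t.exons_transcription_order()
        exon = ordered[intron_index]
        return exon.start if self.strand == "+" else exon.end


def _build_gene(
    rng: np.random.Generator, cfg: SimulationConfig, name: str, chrom: str, strand: str
) -> _Gene:
    n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    exon_lens = [
        int(rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1))
        for _ in range(n_ex)
    ]
    intron_lens = [
        int(rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1] + 1))
        for _ in range(n_ex - 1)
    ]
    total = sum(exon_lens)
    u5 = cfg.utr5_len
    # choose a 3'UTR so the CDS length is a positive multiple of 3
    u3 = 30 + (total - u5 - 30) % 3
    cds_len = total - u5 - u3
    assert cds_len % 3 == 0 and cds_len >= 60, "exons too short for a CDS"
    n_codons = cds_len // 3 - 2  # minus start and stop
    cds = "ATG" + "".join(rng.choice(_SENSE_CODONS, size=n_codons)) + "TAA"
    mrna = list(_random_seq(rng, u5) + cds + _random_seq(rng, u3))

    # plant the frameshift-stop motif at the first codon boundary of every
    # internal/terminal exon's CDS portion, so frameshifts hit a stop
    exon_starts_t = np.cumsum([0] + exon_lens[:-1])
    for s in exon_starts_t[1:]:
        p = u5 + -(-(max(s, u5) - u5) // 3) * 3  # ceil to codon boundary
        if p + len(_FRAMESHIFT_STOP_MOTIF) <= u5 + cds_len - 3:
            mrna[p : p + len(_FRAMESHIFT_STOP_MOTIF)] = _FRAMESHIFT_STOP_MOTIF

    mrna = "".join(mrna)
    exon_seqs, off = [], 0
    for ln in exon_lens:
        exon_seqs.append(mrna[off : off + ln])
        off += ln
    intron_seqs = [
        "GT" + _random_seq(rng, ln - 4) + "AG" for ln in intron_lens
    ]
    return _Gene(name, chrom, strand, exon_seqs, intron_seqs, (u5, u5 + cds_len))


# ---------------------------------------------------------------------------
# planting


def _engineer_intron(gene: _Gene, intron_index: int, prefix: str) -> None:
    """Overwrite the transcript-sense 5' bases of one intron."""
    old = gene.intron_seqs[intron_index - 1]
    if len(prefix) >= len(old) - 2:
        raise ValueError("intron too short for engineered prefix")
    gene.intron_seqs[intron_index - 1] = prefix + old[len(prefix) :]


def _plant(
    ev: PlantedEvent,
    gene: _Gene,
    reference: dict[str, str],
    rng: np.random.Generator,
) -> None:
    """Derive the VCF-style indel and the expected event for one plan.

    Called after genome assembly so REF alleles can be read off the
    final reference sequence.
    """
    ref = reference[gene.chrom]
    if ev.intron_index is None:
        ev.intron_index = max(1, (gene.n_exons - 1) // 2)
    k = ev.intron_index
    ev.gene_name = gene.name
    strand = gene.strand

    def intron_base(boundary: int, j: int, side: str) -> int:
        """Genomic 0-based position of transcript-sense intron base.

        ``j`` > 0 counts into the intron from a donor boundary; ``j`` < 0
        counts back from an acceptor boundary (-1 = last intron base).
        """
        if side == DONOR:
            return boundary + j - 1 if strand == "+" else boundary - j
        return boundary + j if strand == "+" else boundary - j - 1

    if ev.kind == "duplicated_donor_insertion":
        b = gene.donor_boundary(k)
        L = ev.insert_length
        if L <= 21:
            raise ValueError("duplicated-donor insertions must exceed 21 bp")
        # transcript-sense duplicate of the 21 bases spanning the donor,
        # ending at the insertion anchor (intron base +8)
        if strand == "+":
            dup_t = ref[b - 13 : b + 8]
            anchor = b + 7
        else:
            dup_t = _revcomp(ref[b - 8 : b + 13])
            anchor = b - 9
        insert_t = _random_seq(rng, L - 21) + dup_t
        insert_g = insert_t if strand == "+" else _revcomp(insert_t)
        ev.indel = Indel(gene.chrom, anchor + 1, ref[anchor], ref[anchor] + insert_g)
        ev.side, ev.event_class, ev.delta_bp = DONOR, EXTENSION, L
    elif ev.kind in ("gc_ag_activation_deletion", "coincidental_indel"):
        b = gene.donor_boundary(k)
        # intron prefix engineered to GTAAGCTGT at build time:
        # deleting +9 leaves a GC donor active at +4
        if strand == "+":
            anchor = b + 7
            refa = ref[anchor : anchor + 2]
        else:
            anchor = b - 10
            refa = ref[anchor : anchor + 2]
        ev.indel = Indel(gene.chrom, anchor + 1, refa, refa[0])
        ev.side, ev.event_class, ev.delta_bp = DONOR, EXTENSION, 4
    elif ev.kind == "splice_site_deletion":
        b = gene.donor_boundary(k)
        # remove the donor GT (intron +1..+2); splicing falls back to a
        # cryptic exonic donor 4 bp upstream -> shrinkage by 4
        if strand == "+":
            anchor = b - 1
            refa = ref[anchor : anchor + 3]
        else:
            anchor = b - 3
            refa = ref[anchor : anchor + 3]
        ev.indel = Indel(gene.chrom, anchor + 1, refa, refa[0])
        ev.side, ev.event_class, ev.delta_bp = DONOR, SHRINKAGE, -4
    elif ev.kind == "acceptor_region_insertion":
        b = gene.acceptor_boundary(k)
        # GC inserted between intron -2 and -1 creates a new AG two bases
        # upstream of the authentic acceptor -> extension by 2
        anchor = intron_base(b, -2, ACCEPTOR)
        ev.indel = Indel(gene.chrom, anchor + 1, ref[anchor], ref[anchor] + "GC")
        ev.side, ev.event_class, ev.delta_bp = ACCEPTOR, EXTENSION, 2
    elif ev.kind == "neutral_indel":
        # 3-bp deletion deep inside the intron: shifts coordinates but
        # leaves splicing untouched
        b = gene.donor_boundary(k)
        anchor = intron_base(b, 60, DONOR)
        if strand == "-":
            anchor -= 3
        ev.indel = Indel(gene.chrom, anchor + 1, ref[anchor : anchor + 4], ref[anchor])
        ev.side = ev.event_class = None
        ev.delta_bp = None
    else:
        raise ValueError(f"unknown planted-event kind {ev.kind!r}")


def _novel_boundary(ev: PlantedEvent, authentic_pers: int, strand: str) -> int:
    """Personalized novel-boundary position implied by a planted event."""
    sign = 1 if (ev.side == DONOR) == (strand == "+") else -1
    return authentic_pers + sign * ev.delta_bp


# ---------------------------------------------------------------------------
# read generation and file output


@dataclass
class _Read:
    chrom: str
    pos0: int  # leftmost aligned position
    left_len: int
    gap: int
    right_len: int
    seq: str


def _make_junction_reads(
    rng: np.random.Generator,
    genome_seq: str,
    chrom: str,
    left_end: int,
    right_start: int,
    n: int,
    read_len: int,
) -> list[_Read]:
    """Plant n spliced reads across the junction [left_end, right_start)."""
    reads = []
    for _ in range(n):
        o = int(rng.integers(1, read_len))  # left anchor length, >= 1 both sides
        o = min(o, left_end)  # stay on the chromosome
        o = max(o, read_len - (len(genome_seq) - right_start))
        o = max(1, min(o, read_len - 1))
        left = genome_seq[left_end - o : left_end]
        right = genome_seq[right_start : right_start + read_len - o]
        reads.append(
            _Read(chrom, left_end - o, o, right_start - left_end, len(right), left + right)
        )
    return reads


def _write_sam(path: Path, reads: list[_Read], chrom_lengths: dict[str, int]) -> None:
    reads = sorted(reads, key=lambda r: (r.chrom, r.pos0))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom in sorted(chrom_lengths):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{chrom_lengths[chrom]}\n")
        for i, r in enumerate(reads):
            cigar = f"{r.left_len}M{r.gap}N{r.right_len}M"
            fh.write(
                f"r{i:06d}\t0\t{r.chrom}\t{r.pos0 + 1}\t60\t{cigar}\t*\t0\t0\t"
                f"{r.seq}\t{'I' * len(r.seq)}\n"
            )


def _write_vcf(
    path: Path,
    sample: str,
    indels: list[tuple[Indel, Zygosity]],
    contig_lengths: dict[str, int],
) -> None:
    rows = sorted(indels, key=lambda t: (t[0].chrom, t[0].pos, t[0].alt_allele))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(contig_lengths):
            fh.write(f"##contig=<ID={chrom},length={contig_lengths[chrom]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for indel, z in rows:
            gt = "1/1" if z is Zygosity.HOMOZYGOUS else "0/1"
            fh.write(
                f"{indel.chrom}\t{indel.pos}\t{indel.variant_id or '.'}\t"
                f"{indel.ref_allele}\t{indel.alt_allele}\t.\tPASS\t.\tGT\t{gt}\n"
            )


@dataclass
class CohortBundle:
    """In-memory handle on one simulated cohort plus its on-disk files."""

    config: SimulationConfig
    out_dir: Path
    reference: dict[str, str]
    transcripts: list[TranscriptModel]
    samples: list[str]
    planted: list[PlantedEvent]
    genotypes: dict[str, dict[str, Zygosity]]  # event indel id -> sample -> zygosity
    expressed: dict[tuple[str, str], bool]  # (sample, gene) -> expressed
    genomes: dict[str, PersonalizedGenome]
    truth: pd.DataFrame

    @property
    def fasta_path(self) -> Path:
        return self.out_dir / "reference.fa"

    @property
    def gtf_path(self) -> Path:
        return self.out_dir / "annotation.gtf"

    def vcf_path(self, sample: str) -> Path:
        return self.out_dir / "vcf" / f"{sample}.vcf"

    def sam_path(self, sample: str) -> Path:
        return self.out_dir / "sam" / f"{sample}.sam"


def build_cohort(config: SimulationConfig, out_dir: str | Path) -> CohortBundle:
    """Generate one cohort fixture bundle and write it to ``out_dir``.

    Reads are written as already-aligned SAM against each individual's
    personalized genome; the truth table (``truth.tsv``) lists every
    planted event with the outcome the pipeline is expected to reach
    given the realized genotypes, expression dropout and read support.
    """
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    (out_dir / "vcf").mkdir(parents=True, exist_ok=True)
    (out_dir / "sam").mkdir(parents=True, exist_ok=True)

    samples = [f"S{i:03d}" for i in range(config.n_samples)]

    # --- genes and reference genome -------------------------------------
    genes: list[_Gene] = []
    for i in range(config.n_genes):
        chrom = "chr1" if i < (config.n_genes + 1) // 2 else "chr2"
        strand = "+" if i % 2 == 0 else "-"
        genes.append(_build_gene(rng, config, f"GENE{i:02d}", chrom, strand))

    by_gene: dict[int, list[PlantedEvent]] = {}
    for ev in config.planted_events:
        by_gene.setdefault(ev.gene_index, []).append(ev)
    for gi, evs in by_gene.items():
        if len(evs) > 1:
            raise ValueError(f"multiple planted events target gene {gi}; geometry collides")

    # engineered intron prefixes must exist before genome assembly
    for ev in config.planted_events:
        g = genes[ev.gene_index]
        if ev.intron_index is None:
            ev.intron_index = max(1, (g.n_exons - 1) // 2)
        if ev.kind in ("gc_ag_activation_deletion", "coincidental_indel"):
            _engineer_intron(g, ev.intron_index, "GTAAGCTGT")

    reference: dict[str, str] = {}
    cursors: dict[str, int] = {}
    chunks: dict[str, list[str]] = {}
    for g in genes:
        cur = cursors.get(g.chrom, 0)
        chunks.setdefault(g.chrom, [])
        flank = _random_seq(rng, config.flank_len)
        chunks[g.chrom].append(flank)
        cur += config.flank_len
        g.locus_start = cur
        locus = g.locus_seq()
        chunks[g.chrom].append(locus)
        cur += len(locus)
        cursors[g.chrom] = cur
    for chrom in chunks:
        chunks[chrom].append(_random_seq(rng, config.flank_len))
        reference[chrom] = "".join(chunks[chrom])

    transcripts = [g.transcript_model() for g in genes]

    # --- planted indels and genotypes ------------------------------------
    spans_seen: list[tuple[str, int, int]] = []
    genotypes: dict[str, dict[str, Zygosity]] = {}
    for ei, ev in enumerate(config.planted_events):
        _plant(ev, genes[ev.gene_index], reference, rng)
        s, e = ev.indel.ref_span
        for c, ss, ee in spans_seen:
            if c == ev.indel.chrom and s < ee and e > ss:
                raise ValueError(
                    f"planted indel at {ev.indel.chrom}:{ev.indel.pos} collides "
                    "with another planted indel"
                )
        spans_seen.append((ev.indel.chrom, s, e))
        n_car = max(1, round(config.carrier_fraction * config.n_samples))
        carriers = sorted(rng.choice(config.n_samples, size=n_car, replace=False))
        gt: dict[str, Zygosity] = {}
        for ci in carriers:
            hom = rng.random() < config.hom_fraction
            gt[samples[ci]] = Zygosity.HOMOZYGOUS if hom else Zygosity.HETEROZYGOUS
        key = f"ev{ei}"
        genotypes[key] = gt
        ev.indel = dataclasses.replace(ev.indel, variant_id=key, genotype_by_sample=gt)

    # expression dropout: a carrier of an event may not express the gene
    expressed: dict[tuple[str, str], bool] = {}
    for s in samples:
        for g in genes:
            expressed[(s, g.name)] = True
    for ei, ev in enumerate(config.planted_events):
        g = genes[ev.gene_index]
        for s in sorted(genotypes[f"ev{ei}"]):
            if rng.random() < config.expression_dropout_prob:
                expressed[(s, g.name)] = False

    # the coincidental event also shows up in one non-carrier
    coincidental_extra: dict[int, str] = {}
    for ei, ev in enumerate(config.planted_events):
        if ev.kind == "coincidental_indel":
            non = [s for s in samples if s not in genotypes[f"ev{ei}"]]
            if not non:
                raise ValueError("coincidental event needs at least one non-carrier")
            coincidental_extra[ei] = non[int(rng.integers(len(non)))]

    # --- per-sample genomes, reads, files ---------------------------------
    genomes: dict[str, PersonalizedGenome] = {}
    truth_counts = {
        ei: {"carriers_with": 0, "carriers_without": 0, "noncarriers_with": 0}
        for ei in range(len(config.planted_events))
    }
    for s in samples:
        carried = [
            ev.indel
            for ev in config.planted_events
            if ev.indel.zygosity(s).is_carrier
        ]
        by_chrom: dict[str, list[Indel]] = {}
        for indel in sorted(carried, key=lambda v: (v.chrom, v.pos)):
            by_chrom.setdefault(indel.chrom, []).append(indel)
        genome = PersonalizedGenome.build(s, reference, by_chrom)
        genomes[s] = genome

        reads: list[_Read] = []
        for g in genes:
            if not expressed[(s, g.name)]:
                continue
            t = g.transcript_model()
            cmap = genome.maps[g.chrom]
            ev_here = next(
                (
                    (ei, ev)
                    for ei, ev in enumerate(config.planted_events)
                    if ev.gene_index == genes.index(g)
                ),
                None,
            )
            planted_here = ev_here[1] if ev_here else None
            zyg = (
                planted_here.indel.zygosity(s)
                if planted_here is not None
                else Zygosity.ABSENT
            )
            carrier_here = zyg.is_carrier

            for gi_intron, (left, right) in enumerate(t.introns(), start=1):
                # transcription-order index of this genomic intron
                if g.strand == "+":
                    t_index = gi_intron
                else:
                    t_index = g.n_exons - gi_intron
                pl, _ = cmap.lift_boundary(left)
                pr, _ = cmap.lift_boundary(right)
                skip_authentic = (
                    planted_here is not None
                    and planted_here.disrupts_authentic
                    and carrier_here
                    and t_index == planted_here.intron_index
                    and zyg is Zygosity.HOMOZYGOUS
                )
                if not skip_authentic:
                    depth = int(rng.poisson(config.coverage))
                    if depth:
                        reads += _make_junction_reads(
                            rng,
                            genome.sequences[g.chrom],
                            g.chrom,
                            pl,
                            pr,
                            depth,
                            config.read_length,
                        )

            ei_ev = ev_here[0] if ev_here else None
            show_event = (
                planted_here is not None
                and planted_here.expects_event
                and (carrier_here or s == coincidental_extra.get(ei_ev))
            )
            if show_event:
                b = (
                    genes[planted_here.gene_index].donor_boundary(planted_here.intron_index)
                    if planted_here.side == DONOR
                    else genes[planted_here.gene_index].acceptor_boundary(
                        planted_here.intron_index
                    )
                )
                auth_pers, _ = cmap.lift_boundary(b)
                novel = _novel_boundary(planted_here, auth_pers, g.strand)
                # the novel boundary replaces the authentic one on its own
                # side of the gap; the partner boundary stays authentic
                ordered_introns = list(t.introns())
                if g.strand == "+":
                    gl, gr = ordered_introns[planted_here.intron_index - 1]
                else:
                    gl, gr = ordered_introns[g.n_exons - 1 - planted_here.intron_index]
                pl, _ = cmap.lift_boundary(gl)
                pr, _ = cmap.lift_boundary(gr)
                is_left_boundary = (planted_here.side == DONOR) == (g.strand == "+")
                jl, jr = (novel, pr) if is_left_boundary else (pl, novel)
                depth = max(2, int(rng.poisson(config.coverage)))
                reads += _make_junction_reads(
                    rng,
                    genome.sequences[g.chrom],
                    g.chrom,
                    jl,
                    jr,
                    depth,
                    config.read_length,
                )
                if carrier_here:
                    truth_counts[ei_ev]["carriers_with"] += 1
                else:
                    truth_counts[ei_ev]["noncarriers_with"] += 1
            elif (
                planted_here is not None
                and planted_here.expects_event
                and carrier_here
            ):
                pass  # dropout: carrier without reads, counted below

            # spurious junctions only in genes without planted events
            if planted_here is None and rng.random() < config.noise_junction_rate:
                left, right = next(iter(t.introns()))
                pl, _ = cmap.lift_boundary(left)
                pr, _ = cmap.lift_boundary(right)
                if rng.random() < 0.5:
                    jl, jr = pl + 17, pr - 23  # both sides unannotated
                else:
                    jl, jr = pl, pr - 23  # one-side-consistent, no indel nearby
                reads += _make_junction_reads(
                    rng,
                    genome.sequences[g.chrom],
                    g.chrom,
                    jl,
                    jr,
                    2,
                    config.read_length,
                )

        chrom_lengths = {c: len(seq) for c, seq in genome.sequences.items()}
        _write_sam(out_dir / "sam" / f"{s}.sam", reads, chrom_lengths)
        vcf_rows = [
            (ev.indel, ev.indel.zygosity(s))
            for ev in config.planted_events
            if ev.indel.zygosity(s).is_carrier
        ]
        _write_vcf(
            out_dir / "vcf" / f"{s}.vcf",
            s,
            vcf_rows,
            {c: len(seq) for c, seq in reference.items()},
        )

    # dropout carriers without the event
    for ei, ev in enumerate(config.planted_events):
        if not ev.expects_event:
            continue
        g = genes[ev.gene_index]
        for s in genotypes[f"ev{ei}"]:
            if not expressed[(s, g.name)]:
                truth_counts[ei]["carriers_without"] += 1

    # --- truth table ------------------------------------------------------
    rows = []
    for ei, ev in enumerate(config.planted_events):
        c = truth_counts[ei]
        retained = (
            ev.expects_event
            and c["noncarriers_with"] == 0
            and c["carriers_with"] > c["carriers_without"]
        )
        rows.append(
            {
                "event_id": f"ev{ei}",
                "kind": ev.kind,
                "gene": ev.gene_name,
                "chrom": ev.indel.chrom,
                "pos": ev.indel.pos,
                "ref": ev.indel.ref_allele,
                "alt": ev.indel.alt_allele,
                "side": ev.side or "-",
                "event_class": ev.event_class or "-",
                "delta_bp": ev.delta_bp if ev.delta_bp is not None else 0,
                "expected_event": ev.expects_event,
                "expected_retained": retained,
                "carriers_with": c["carriers_with"],
                "carriers_without": c["carriers_without"],
                "noncarriers_with": c["noncarriers_with"],
            }
        )
    truth = pd.DataFrame(rows)

    write_fasta(reference, out_dir / "reference.fa")
    write_gtf(transcripts, out_dir / "annotation.gtf")
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    with open(out_dir / "samples.txt", "w") as fh:
        for s in samples:
            fh.write(s + "\n")

    return CohortBundle(
        config=config,
        out_dir=out_dir,
        reference=reference,
        transcripts=transcripts,
        samples=samples,
        planted=list(config.planted_events),
        genotypes=genotypes,
        expressed=expressed,
        genomes=genomes,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# worked-example fixtures


def table1_fixture() -> pd.DataFrame:
    """The packaged table of 12 published splice-altering indels.

    Columns include genomic position, REF/ALT alleles, gene symbol,
    splice-site side (A/D), event class (E/S) and PTC status; the two
    fully worked examples (TRAPPC2L, DECR1) have synthetic sequence
    contexts available via :func:`trappc2l_context` and
    :func:`decr1_context`.
    """
    with importlib.resources.files("indelsplice.data").joinpath(
        "table1_indels.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


@dataclass
class WorkedExampleContext:
    """Synthetic sequence context around one published indel."""

    reference: dict[str, str]
    transcripts: list[TranscriptModel]
    indel: Indel
    expected_side: str
    expected_class: str
    expected_delta: int
    gene: str

    def carrier_genome(self, sample: str = "carrier") -> PersonalizedGenome:
        by_chrom: dict[str, list[Indel]] = {self.indel.chrom: [self.indel]}
        return PersonalizedGenome.build(sample, self.reference, by_chrom)

    def novel_junction(self, genome: PersonalizedGenome) -> tuple[str, int, int]:
        """(chrom, left_end, right_start) of the novel junction, personalized."""
        t = self.transcripts[0]
        cmap = genome.maps[t.chrom]
        ordered = t.exons_transcription_order()
        # the affected intron index is stored on the context via the indel
        k = self._intron_index
        if self.expected_side == DONOR:
            b = ordered[k - 1].end if t.strand == "+" else ordered[k - 1].start
        else:
            b = ordered[k].start if t.strand == "+" else ordered[k].end
        auth_pers, _ = cmap.lift_boundary(b)
        sign = 1 if (self.expected_side == DONOR) == (t.strand == "+") else -1
        novel = auth_pers + sign * self.expected_delta
        introns = list(t.introns())
        gl, gr = introns[k - 1] if t.strand == "+" else introns[len(introns) - k]
        pl, _ = cmap.lift_boundary(gl)
        pr, _ = cmap.lift_boundary(gr)
        if (self.expected_side == DONOR) == (t.strand == "+"):
            return t.chrom, novel, pr
        return t.chrom, pl, novel

    _intron_index: int = 4


def _context_gene(
    rng: np.random.Generator,
    n_exons: int,
    affected_intron: int,
    intron_prefix: str | None,
    exon_tail_13: str | None,
) -> _Gene:
    cfg = SimulationConfig(
        seed=0, n_genes=1, exons_per_gene=(n_exons, n_exons), planted_events=[]
    )
    for _ in range(100):
        g = _build_gene(rng, cfg, "CTX", "ctx", "+")
        if intron_prefix is not None:
            _engineer_intron(g, affected_intron, intron_prefix)
        if exon_tail_13 is not None:
            ex = g.exon_seqs[affected_intron - 1]
            g.exon_seqs[affected_intron - 1] = ex[: -len(exon_tail_13)] + exon_tail_13
        # engineering must not plant a premature stop in the normal frame
        mrna = "".join(g.exon_seqs)
        cs, ce = g.cds_t
        from Bio.Seq import Seq

        if str(Seq(mrna[cs:ce]).translate()).find("*") == (ce - cs) // 3 - 1:
            return g
    raise RuntimeError("could not build a stop-free engineered context gene")


def trappc2l_context(seed: int = 7) -> WorkedExampleContext:
    """Synthetic context reproducing the duplicated-donor insertion geometry.

    A five-exon gene whose exon-4 donor region is engineered so the
    published 35-bp insertion (anchored 8 bases into intron 4) carries a
    duplicate of the donor-spanning sequence at its 3' end, recreating
    the donor motif exactly 35 bp downstream of the authentic site.
    """
    t1 = table1_fixture()
    row = t1[t1.gene == "TRAPPC2L"].iloc[0]
    ref_allele, alt_allele = row.ref, row.alt
    inserted = alt_allele[len(ref_allele) :]
    dup = inserted[-21:]  # 13 exonic + 8 intronic bases around the donor
    assert dup[13:15] == "GT"
    rng = np.random.default_rng(seed)
    # exon 4 ends with the duplicate's exonic part; intron 4 begins with its
    # intronic part except that the +8 anchor base must equal REF
    intron_prefix = dup[13:20] + ref_allele
    g = _context_gene(rng, 5, 4, intron_prefix, dup[:13])
    ctx = _finalize_context(g, row, affected_intron=4, side=DONOR, delta=35, cls=EXTENSION)
    genome = ctx.carrier_genome()
    t = ctx.transcripts[0]
    b, _ = genome.maps[t.chrom].lift_boundary(t.exons[3].end)
    # guard: the duplicated donor motif sits exactly delta bp downstream
    assert genome.sequences[t.chrom][b + 35 : b + 37] == "GT"
    return ctx


def decr1_context(seed: int = 11) -> WorkedExampleContext:
    """Synthetic context for GC-AG activation by a donor-region deletion.

    A ten-exon gene whose intron-8 5' sequence is engineered so the
    published GT>G deletion (removing intron base +8) strengthens a
    non-canonical GC donor 4 bp into the intron, extending exon 8 by 4 bp.
    """
    t1 = table1_fixture()
    row = t1[t1.gene == "DECR1"].iloc[0]
    rng = np.random.default_rng(seed)
    # +1..+10 = GTAAGCGTTG: GC donor at +5/+6, REF GT at +7/+8,
    # post-deletion base at +5 of the novel site changes T->G
    g = _context_gene(rng, 10, 8, "GTAAGCGTTG", None)
    ctx = _finalize_context(g, row, affected_intron=8, side=DONOR, delta=4, cls=EXTENSION)
    genome = ctx.carrier_genome()
    t = ctx.transcripts[0]
    b, _ = genome.maps[t.chrom].lift_boundary(t.exons[7].end)
    assert genome.sequences[t.chrom][b + 4 : b + 6] == "GC"
    return ctx


def _finalize_context(
    g: _Gene, row, affected_intron: int, side: str, delta: int, cls: str
) -> WorkedExampleContext:
    g.name = row.gene
    g.chrom = "ctx"
    g.locus_start = 150
    rng = np.random.default_rng(1)
    reference = {
        "ctx": _random_seq(rng, 150) + g.locus_seq() + _random_seq(rng, 150)
    }
    ref = reference["ctx"]
    b = g.donor_boundary(affected_intron) if side == DONOR else g.acceptor_boundary(
        affected_intron
    )
    if len(row.alt) > len(row.ref):  # insertion anchored at intron +8
        anchor = b + 7
    else:  # deletion anchored at intron +7 (REF spans +7/+8)
        anchor = b + 6
    observed = ref[anchor : anchor + len(row.ref)]
    if observed != row.ref:
        raise AssertionError(
            f"context engineering failed: reference has {observed!r}, "
            f"table says {row.ref!r}"
        )
    indel = Indel(
        "ctx",
        anchor + 1,
        row.ref,
        row.alt,
        variant_id=row.variant_id,
        genotype_by_sample={"carrier": Zygosity.HETEROZYGOUS},
    )
    ctx = WorkedExampleContext(
        reference=reference,
        transcripts=[g.transcript_model()],
        indel=indel,
        expected_side=side,
        expected_class=cls,
        expected_delta=delta,
        gene=row.gene,
    )
    ctx._intron_index = affected_intron
    return ctx


def simulate_context_reads(
    ctx: WorkedExampleContext,
    genome: PersonalizedGenome,
    n_reads: int = 8,
    seed: int = 5,
    read_length: int = 75,
    include_authentic: bool = True,
) -> list[_Read]:
    """Junction reads for a worked-example carrier (novel + authentic)."""
    rng = np.random.default_rng(seed)
    t = ctx.transcripts[0]
    cmap = genome.maps[t.chrom]
    chrom_seq = genome.sequences[t.chrom]
    reads: list[_Read] = []
    chrom, jl, jr = ctx.novel_junction(genome)
    reads += _make_junction_reads(rng, chrom_seq, chrom, jl, jr, n_reads, read_length)
    if include_authentic:
        for left, right in t.introns():
            pl, _ = cmap.lift_boundary(left)
            pr, _ = cmap.lift_boundary(right)
            reads += _make_junction_reads(
                rng, chrom_seq, chrom, pl, pr, max(2, n_reads // 2), read_length
            )
    return reads


def write_context_sam(
    ctx: WorkedExampleContext,
    genome: PersonalizedGenome,
    path: str | Path,
    **kwargs,
) -> None:
    reads = simulate_context_reads(ctx, genome, **kwargs)
    _write_sam(Path(path), reads, {c: len(s) for c, s in genome.sequences.items()})
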