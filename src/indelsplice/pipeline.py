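"""End-to-end cohort pipeline and final report.

For every individual: personalize the genome from their indel calls,
lift the annotation, collect junction reads, call candidate events and
associate indels.  Across the cohort: project events to reference
coordinates, apply the carrier/non-carrier filters, annotate coding
consequences, and emit one report row per retained (event, indel) pair
in the style of a published result table: position, alleles, gene,
splice-site side (A/D), event class (E/S), PTC status, allele frequency
and het/hom carrier counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import association as assoc
from .annotation import DONOR, lift_annotation, read_gtf
from .consequence import annotate_consequence
from .genome import PersonalizedGenome, read_fasta
from .junctions import (
    DEFAULT_MIN_NOVEL_ANCHOR,
    DEFAULT_MIN_READS,
    EXTENSION,
    call_events,
    extract_junctions_from_file,
)
from .variants import Indel, Zygosity, read_indels_vcf, select_nonoverlapping_indels

logger = logging.getLogger(__name__)

#: Exon extension/shrinkage events attributed to single-nucleotide variants
#: in the companion survey of the same cohort; used to express the indel
#: share of all such events as a percentage.
SNV_EVENT_COUNT = 371

REPORT_COLUMNS = [
    "position",
    "variant_id",
    "ref",
    "alt",
    "gene",
    "splice_site",
    "splicing_event",
    "delta_bp",
    "ptc",
    "nmd_escape",
    "af",
    "n_hetero",
    "n_homo",
    "carriers_with_event",
    "carriers_without_event",
    "noncarriers_with_event",
]


@dataclass
class PipelineConfig:
    """Paths and thresholds for one cohort run; defaults are the
    published filter values (2 junction reads, 5-bp novel anchor,
    -3/+6 donor and -18/+3 acceptor windows)."""

    reference_fasta: str
    gtf: str
    vcf_dir: str
    sam_dir: str
    out_dir: str | None = None
    samples: list[str] | None = None
    min_reads: int = DEFAULT_MIN_READS
    min_novel_anchor: int = DEFAULT_MIN_NOVEL_ANCHOR
    donor_window: tuple[int, int] = (assoc.DONOR_EXONIC, assoc.DONOR_INTRONIC)
    acceptor_window: tuple[int, int] = (assoc.ACCEPTOR_INTRONIC, assoc.ACCEPTOR_EXONIC)
    max_indel_len: int | None = None
    use_50nt_nmd_rule: bool = False
    clinvar_table: str | None = None
    gene_table: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("donor_window", "acceptor_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def discover_samples(vcf_dir: str | Path) -> list[str]:
    return sorted(p.stem for p in Path(vcf_dir).glob("*.vcf"))


def indel_event_fraction(n_indel_events: int, n_snv_events: int = SNV_EVENT_COUNT) -> float:
    """Indel-induced share of all exon extension/shrinkage events, in %."""
    return 100.0 * n_indel_events / (n_indel_events + n_snv_events)


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Run personalize -> lift -> call -> associate -> filter -> consequence.

    Returns the report as a DataFrame (one row per retained event/indel
    pair, sorted by genomic position) and, when ``config.out_dir`` is
    set, writes ``report.tsv`` plus a per-stage ``funnel.tsv``.
    """
    reference = read_fasta(config.reference_fasta)
    transcripts = read_gtf(config.gtf)
    samples = config.samples or discover_samples(config.vcf_dir)
    processed: list[str] = []

    funnel = {
        "samples": 0,
        "junction_reads": 0,
        "events_called": 0,
        "event_indel_candidates": 0,
        "retained": 0,
    }

    # variant registry across the cohort: identity -> (Indel, carriers)
    registry: dict[tuple, Indel] = {}
    carriers: dict[tuple, dict[str, Zygosity]] = {}

    # per reference-projected event key
    samples_with_event: dict[tuple, set[str]] = {}
    candidates: dict[tuple, set[tuple]] = {}
    representative: dict[tuple, tuple] = {}  # key -> (sample, event, ann, genome)

    for sample in samples:
        vcf_path = Path(config.vcf_dir) / f"{sample}.vcf"
        sam_path = Path(config.sam_dir) / f"{sample}.sam"
        if not vcf_path.exists() or not sam_path.exists():
            logger.warning("sample %s: missing VCF or SAM, skipped", sample)
            continue
        funnel["samples"] += 1
        processed.append(sample)

        all_indels = read_indels_vcf(vcf_path, samples=[sample])
        for v in all_indels:
            ident = (v.chrom, v.pos, v.ref_allele, v.alt_allele)
            registry.setdefault(ident, v)
            z = v.zygosity(sample)
            if z.is_carrier:
                carriers.setdefault(ident, {})[sample] = z

        by_chrom: dict[str, list[Indel]] = {}
        for chrom in sorted({v.chrom for v in all_indels}):
            on_chrom = [v for v in all_indels if v.chrom == chrom]
            by_chrom[chrom] = select_nonoverlapping_indels(
                on_chrom, sample=sample, max_len=config.max_indel_len
            )
        genome = PersonalizedGenome.build(sample, reference, by_chrom)
        ann = lift_annotation(transcripts, genome.maps, sample_id=sample)

        junctions = extract_junctions_from_file(
            sam_path, sample, valid_references=set(genome.sequences)
        )
        funnel["junction_reads"] += len(junctions)
        events = call_events(
            junctions,
            ann,
            min_reads=config.min_reads,
            min_novel_anchor=config.min_novel_anchor,
        )
        funnel["events_called"] += len(events)

        applied = {
            (v.chrom, v.pos, v.ref_allele, v.alt_allele): v
            for chrom_indels in by_chrom.values()
            for v in chrom_indels
        }
        for event in events:
            key = assoc.event_reference_key(event, genome.maps[event.chrom])
            samples_with_event.setdefault(key, set()).add(sample)
            if key not in representative:
                representative[key] = (sample, event, ann, genome)
            cands = assoc.associate(
                event,
                list(applied.values()),
                genome.maps[event.chrom],
                donor_extents=config.donor_window,
                acceptor_extents=config.acceptor_window,
            )
            for c in cands:
                ident = (
                    c.indel.chrom,
                    c.indel.pos,
                    c.indel.ref_allele,
                    c.indel.alt_allele,
                )
                candidates.setdefault(key, set()).add(ident)

    funnel["event_indel_candidates"] = sum(len(v) for v in candidates.values())

    rows = []
    for key in sorted(candidates):
        with_event = samples_with_event[key]
        for ident in sorted(candidates[key]):
            carrier_map = carriers.get(ident, {})
            noncarrier = [s for s in processed if s not in carrier_map]
            decision = assoc.cohort_filter(carrier_map, noncarrier, with_event)
            if not decision.retained:
                continue
            assert decision.noncarriers_with_event == 0  # re-validated
            assert decision.carriers_with_event > decision.carriers_without_event
            funnel["retained"] += 1

            sample, event, ann, genome = representative[key]
            t = next(
                tt for tt in ann.transcripts if tt.transcript_id == event.transcript_id
            )
            cons = annotate_consequence(
                t, event, genome, use_50nt_rule=config.use_50nt_nmd_rule
            )
            indel = registry[ident]
            af, n_het, n_hom = assoc.allele_frequency(
                Indel(
                    indel.chrom,
                    indel.pos,
                    indel.ref_allele,
                    indel.alt_allele,
                    indel.variant_id,
                    carrier_map,
                ),
                processed,
            )
            rows.append(
                {
                    "position": f"{indel.chrom}:{indel.pos}",
                    "variant_id": indel.variant_id or ".",
                    "ref": indel.ref_allele,
                    "alt": indel.alt_allele,
                    "gene": event.gene_name,
                    "splice_site": "D" if event.side == DONOR else "A",
                    "splicing_event": "E" if event.event_class == EXTENSION else "S",
                    "delta_bp": event.delta_bp,
                    "ptc": cons.category,
                    "nmd_escape": {True: "yes", False: "no"}.get(cons.nmd_escape, "-"),
                    "af": round(af, 4),
                    "n_hetero": n_het,
                    "n_homo": n_hom,
                    "carriers_with_event": decision.carriers_with_event,
                    "carriers_without_event": decision.carriers_without_event,
                    "noncarriers_with_event": decision.noncarriers_with_event,
                    "_chrom": indel.chrom,
                    "_pos": indel.pos,
                }
            )

    report = pd.DataFrame(rows, columns=REPORT_COLUMNS + ["_chrom", "_pos"])
    report = report.sort_values(["_chrom", "_pos"]).drop(columns=["_chrom", "_pos"])
    report = report.reset_index(drop=True)

    if config.clinvar_table or config.gene_table:
        report = join_annotations(report, config.clinvar_table, config.gene_table)

    for stage, n in funnel.items():
        logger.info("funnel %s: %d", stage, n)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "report.tsv", sep="\t", index=False)
        pd.DataFrame([funnel]).T.reset_index().rename(
            columns={"index": "stage", 0: "count"}
        ).to_csv(out / "funnel.tsv", sep="\t", index=False)
    return report


def _read_join_table(path: str | Path, key_col: str, value_col: str) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if key_col not in header or value_col not in header:
            raise ValueError(
                f"join table {path}: expected columns {key_col!r} and {value_col!r}, "
                f"got {header}"
            )
        ki, vi = header.index(key_col), header.index(value_col)
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) <= max(ki, vi):
                raise ValueError(f"join table {path}: malformed line {lineno}")
            out[parts[ki]] = parts[vi]
    return out


def join_annotations(
    report: pd.DataFrame,
    clinvar_table: str | Path | None = None,
    gene_table: str | Path | None = None,
) -> pd.DataFrame:
    """Left-join user-supplied variant/gene annotation tables.

    ``clinvar_table`` must have columns ``variant_id`` and
    ``significance``; ``gene_table`` columns ``gene`` and ``disease``.
    Unmatched rows get "-", as in published variant tables.
    """
    report = report.copy()
    if clinvar_table is not None:
        lut = _read_join_table(clinvar_table, "variant_id", "significance")
        report["clinvar"] = [
            lut.get(v, "-") for v in report.get("variant_id", pd.Series(dtype=str))
        ]
    if gene_table is not None:
        lut = _read_join_table(gene_table, "gene", "disease")
        report["disease_gene"] = [
            lut.get(v, "-") for v in report.get("gene", pd.Series(dtype=str))
        ]
    return report
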