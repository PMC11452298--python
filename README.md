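# indelsplice

Discovery of short insertions and deletions (indels) that induce **exon
extension/shrinkage events** — aberrant splicing at a novel donor or
acceptor site — from individual-specific genomes and spliced RNA-seq
alignments.

Aligning RNA-seq reads to the plain reference genome hides exactly the
events this package looks for: an indel shifts every downstream
coordinate and can itself carry the activated splice site, so reads
using the novel junction fail to align, or align at the wrong position.
`indelsplice` therefore works per individual: it rewrites the reference
with that individual's indels, lifts the gene annotation into the
personalized coordinates, and compares spliced junction reads against
the individual's own authentic splice-site positions.

It is intended for cohort analyses — a population variant panel plus
matching RNA-seq — by researchers studying splice-disrupting variation,
and includes a fully self-contained cohort simulator so the whole
pipeline is testable without any external data.

## Method

For each individual with indel calls (VCF) and spliced alignments
against their personalized genome (SAM/BAM):

1. **Personalize** — select the carried, non-overlapping indels (on
   overlap, the first in ascending positional order wins), splice each
   ALT allele into the reference, and keep an invertible coordinate map
   between reference and personalized coordinates.
2. **Lift** — map every exon boundary of the annotation through the
   coordinate map, so authentic donor/acceptor positions are correct for
   this individual.
3. **Call** — collect junction reads (CIGAR `N` gaps). A junction where
   exactly one side matches an annotated exon boundary and the other
   matches none is a candidate novel event; the novel boundary intronic
   of the displaced authentic boundary is an *extension* (E), exonic a
   *shrinkage* (S), with signed size `delta_bp`. Candidates must be
   covered by ≥ 2 junction reads, at least one of which aligns ≥ 5 bp on
   the novel side.
4. **Associate** — an indel is a candidate cause if its affected span
   intersects a window anchored at the **novel** boundary: −3/+6 bases
   (exonic/intronic) at a donor, −18/+3 (intronic/exonic) at an
   acceptor, regardless of distance from the authentic boundary.
5. **Filter across the cohort** — the pair (event, indel) is retained
   iff no non-carrier shows the event, and strictly more carriers show
   it than do not.
6. **Consequences** — the altered transcript is re-spliced from the
   personalized genome; frameshifts (`|delta_bp| mod 3 ≠ 0`) and
   premature termination codons (PTC) are detected by translation from
   the annotated start codon, and a PTC in the last exon is flagged as
   potentially escaping nonsense-mediated decay (NMD).

## Worked example

Simulate a cohort of 20 individuals with six planted indels (a
duplicated-donor insertion, a GC-AG-activating deletion, a donor-GT
deletion, an acceptor-region insertion, a neutral deep-intronic indel,
and a coincidental indel whose event also appears in a non-carrier),
then run the full pipeline:

```bash
indelsplice simulate --seed 42 --out sim
cat > config.yaml <<EOF
reference_fasta: sim/reference.fa
gtf: sim/annotation.gtf
vcf_dir: sim/vcf
sam_dir: sim/sam
out_dir: result
EOF
indelsplice run --config config.yaml
```

This prints (abridged):

```
 position variant_id  ref                                   alt    gene splice_site splicing_event  delta_bp  ptc ...
 chr1:345        ev0    A  ACCACTTCTGATCGGAAGCGAGGGTGGGGTTCGCAA  GENE00           D              E        35  PTC
chr1:2653        ev1   GA                                     G  GENE01           D              E         4  PTC
chr1:3736        ev2  TGT                                     T  GENE02           D              S        -4  PTC
chr1:5764        ev3    T                                   TGC  GENE03           A              E         2  PTC
```

Four rows, one per planted causal indel: the 35-bp duplicated-donor
insertion extends its exon by exactly the inserted length at the donor
(D/E, +35); the GC-AG deletion extends by 4 bp; the donor-GT deletion
shrinks the exon by 4 bp via a cryptic exonic donor; the acceptor-region
insertion extends by 2 bp. All four are frameshifts and produce a PTC.
The neutral indel produces no event, and the coincidental indel is
rejected because one non-carrier shows the same junction
(`sim/truth.tsv` lists the planted ground truth; `result/funnel.tsv`
the per-stage counts).

The same library functions are importable directly
(`indelsplice.apply_indels`, `lift_annotation`, `call_events`,
`associate`, `cohort_filter`, `annotate_consequence`, ...); see the
docstrings and `docs/methods.md`.

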