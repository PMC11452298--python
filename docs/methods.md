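# Methods

## Problem and model

A short indel can change splice-site usage in two ways: by disrupting an
authentic donor/acceptor motif, or by creating a novel one (including a
duplicated copy of the authentic site inside an insertion, and
non-canonical GC-AG donors strengthened by a nearby deletion). When the
novel site is used, the exon is extended (novel boundary intronic of the
authentic one) or shrunk (exonic). Because the indel itself shifts all
downstream coordinates — and may contain the novel site — such events
are only visible when reads are aligned to a genome that carries the
individual's indels. The pipeline's unit of evidence is the junction
read: a spliced alignment whose CIGAR `N` gap spans an intron, anchoring
aligned blocks on both sides.

## Coordinate conventions

All internal arithmetic uses 0-based, half-open intervals; 1-based
conversions happen only at the VCF/GTF boundary. An exon–intron boundary
is the between-base coordinate shared by the exon's half-open end and
the intron's start (or vice versa), so a junction gap `[left, right)`
matches an annotated intron exactly when both coordinates are equal.

The coordinate map built during personalization stores piecewise
offsets over reference segments plus the one-sided spans (reference
bases deleted, personalized bases inserted). Lifting a position inside a
deleted span returns a `deleted` status with the left-anchor coordinate;
boundaries inside deleted spans are anchored left and flagged
*disrupted* rather than dropped — indel-disrupted authentic sites are
precisely the causal class of interest. An insertion exactly at a
boundary lands after it (the boundary maps with the base to its right).
The map is exactly invertible outside one-sided spans, a property the
test suite exercises on random indel sets; it can be exported as a
UCSC-style chain file (hand-written writer: chain is a write-only format
for the libraries available here).

## Personalization rules

- Only indels are applied (equal-length substitutions never shift
  coordinates and are out of scope); multi-allelic records are split
  into biallelic ones first.
- Both heterozygous and homozygous indels are applied to the single
  personalized genome — one genome per individual, not per haplotype.
  Zygosity is retained for the cohort filters. This is an
  interpretation: with per-haplotype genomes, heterozygous novel sites
  would need diploid-aware alignment, which the downstream caller does
  not assume.
- Overlap between carried indels is defined on the reference-affected
  span `[pos, pos + len(REF))`; pure insertions occupy the 1-base anchor
  span. On overlap, the variant earlier in ascending positional order is
  kept (ties broken by input order). Indel length is unbounded by
  default; `max_indel_len` is a config parameter.

## Event calling

"Consistent with the annotation" means an exact base match to an exon
boundary of *any* transcript of any gene — no fuzzy window — so known
alternative isoforms are never called novel; the read-count and anchor
filters, not tolerant matching, absorb mapping noise. Junction reads
are treated as unstranded; donor/acceptor roles come from the matched
transcript's strand. Multi-gap reads contribute each gap independently.

A candidate group (consistent boundary, novel boundary) becomes an event
when it has at least `min_reads = 2` supporting reads and at least one
read whose novel-side block spans `min_novel_anchor = 5` aligned bases.
The anchor rule is satisfied by *any* one supporting read; a strict mode
requiring all reads would be a trivial variant, but the per-group
maximum is the literal reading of the coverage condition. When the
consistent boundary belongs to several transcripts, one event per
matched transcript is emitted and deduplicated per gene. Junctions
matching annotated boundaries on both sides but never as an annotated
intron (e.g. exon skipping) are classified `exotic` and excluded: they
are a different event class.

`delta_bp` is the signed displacement of the novel boundary from the
displaced authentic boundary of the matched intron: positive =
extension, negative = shrinkage.

## Indel association and cohort filters

The candidate window is anchored at the **novel** boundary and oriented
by transcript strand: donor −3/+6 (3 exonic + 6 intronic bases, the
9-base donor motif), acceptor −18/+3 (18 intronic + 3 exonic: the
polypyrimidine tract, the AG and the exon start). The sign orientation
(minus = exonic at donors, intronic at acceptors) follows the canonical
splice-motif extents. Distance from the authentic boundary is recorded
but never filtered on — causal indels can sit tens of bases from the
authentic site when the novel site is displaced.

An indel's footprint in personalized coordinates is the span its ALT
allele occupies, plus one extra base on the right for net deletions so
the deletion seam's two flanks are covered; the indel is a candidate
when this span intersects the window. All candidates are reported; no
ranking is attempted.

Events are compared across individuals in reference coordinates. The
identity key is `(chrom, gene, side, reference position of the authentic
boundary, delta_bp)`: the authentic boundary always has a reference
image (or a flagged left anchor when disrupted), and using the delta
instead of the novel boundary keeps the key total even when the novel
site lies inside inserted sequence with no reference preimage.

The cohort decision is deterministic, not a statistical test: retain iff
`noncarriers_with_event == 0` and
`carriers_with_event > carriers_without_event` (strict). Individuals are
counted when their own per-sample call passed the event-calling filters.
Carrier = heterozygous or homozygous. The reported allele frequency is
computed over the analyzed cohort, `(n_het + 2 n_hom) / 2N` — published
tables sometimes print population-panel frequencies instead, which can
differ.

## Coding consequences

The altered transcript is re-spliced from the personalized genome with
the novel boundary substituted for the authentic one. Translation starts
at the annotated start codon (standard nuclear code); a stop reached
strictly upstream of where the authentic stop codon sits in the altered
mRNA is a PTC. Categories: `Not in CDS` (non-coding transcript, or the
variable region entirely in UTR), `No PTC`, `PTC`, `start_lost` (event
removes the start codon) and `stop_lost` (event removes the authentic
stop codon — the upstream literature is silent on this case, so it is
reported as its own category rather than as PTC). Frame-preserving
events (`delta mod 3 = 0`) yield a PTC only when the gained segment
itself contains an in-frame stop. Codons containing N are treated as
unknown: translation stops and the record carries an ambiguity flag
instead of a PTC call.

NMD escape defaults to the simple last-exon rule — a PTC in the final
exon of the altered transcript escapes decay. The canonical refinement
(escape iff the PTC starts < 50 nt upstream of the final exon–exon
junction) is available via `use_50nt_rule` / the pipeline's
`use_50nt_nmd_rule` flag.

## Synthetic cohorts

The simulator emulates a population variant panel plus cohort RNA-seq at
desk scale. Defaults: 20 individuals, 8 multi-exon genes on both strands
across two chromosomes (4–6 exons of 90–150 bp, introns 150–300 bp,
canonical GT-AG except planted GC-AG cases), carrier fraction 0.3
(≈ 30% hom), mean junction coverage 10 reads, read length 75 bp,
expression dropout 0, spurious-junction rate 0.05. Coding sequences are
drawn from stop-free sense codons; every internal exon carries a short
motif (`ATAATTAATAAC`) that is silent in frame 0 but a stop in both
shifted frames, so frameshifting planted events deterministically
produce a PTC — a deliberate departure from uniform sequence randomness
that makes consequence expectations exact.

Planted kinds and their geometry:

- *duplicated_donor_insertion*: 35-bp net insertion anchored 8 bases
  into the intron, its 3′ 21 bases duplicating the donor-spanning
  sequence ending at the anchor; the duplicate recreates the donor motif
  exactly 35 bp downstream, so delta equals the net inserted length.
- *gc_ag_activation_deletion*: intron 5′ end engineered to `GTAAGCTGT`;
  deleting the +9 base leaves an active GC donor at +4 (extension +4).
- *splice_site_deletion*: the donor GT (+1/+2) is deleted; splicing
  falls back to a cryptic exonic donor 4 bp upstream (shrinkage −4).
- *acceptor_region_insertion*: `GC` inserted between intron −2 and −1
  creates a new AG two bases into the intron (extension +2).
- *neutral_indel*: 3-bp deletion 60 bases into an intron; no event.
- *coincidental_indel*: same geometry as the GC-AG case, but the novel
  junction is also planted in exactly one non-carrier, so the
  non-carrier filter must reject it.

Reads are written as already-aligned SAM against each individual's
personalized genome (the pipeline's own computation starts downstream of
alignment); every read's sequence is extracted from that genome, so the
SAM is internally consistent by construction and verified by
re-extraction in the tests. Junction gaps are placed uniformly with both
anchors ≥ 1 bp, so the 5-bp anchor filter is exercised on both sides of
its threshold. Expressing carriers receive at least the filter-minimum
two novel-junction reads (Poisson depth clamped from below), so the
truth table's carrier counts are exact; heterozygous carriers keep
authentic-junction reads, and homozygous carriers of site-*disrupting*
indels lose them. Expression dropout removes all of a carrier's reads
for the affected gene, which is what lets the carrier-majority filter
fail honestly at high dropout. All randomness flows from the single
config seed; identical seeds give byte-identical files.

What the simulator does **not** model: sequencing errors and quality
variation, alignment ambiguity and soft-clipping, fragment-length
effects, isoform mixtures, expression heterogeneity beyond binary
dropout, and linkage between variants. Passing tests therefore
demonstrate the correctness of the pipeline's logic on well-formed
input, not robustness to alignment artifacts in real data.

The packaged table of 12 published splice-altering indels
(`indelsplice.table1_fixture`) carries the reported alleles and event
annotations; the two fully worked examples are rebuilt as synthetic
sequence contexts (`trappc2l_context`, `decr1_context` — synthetic
stand-ins, not the real loci; real codon indices are not reproduced)
sufficient to exercise the caller, the association window and the
consequence annotator.

## Numerical and design notes

- Thresholds (`min_reads`, `min_novel_anchor`, window extents) are
  configuration with the published defaults; raising either threshold
  can only shrink the call set (property-tested).
- Report rows are sorted by reference position; re-running on identical
  inputs is byte-identical.
- Problem sizes in the test suite and acceptance script (kilobase-scale
  genes, cohorts of ~20, coverage 10) were chosen so that every planted
  event is comfortably above the filter thresholds while the full suite
  runs in seconds; the filters' behaviour near their thresholds is
  covered by dedicated randomized tests rather than by scaling the
  cohort.
- Missing per-sample inputs skip the sample with a logged warning; a
  transcript whose exons collapse or invert after lifting (e.g. an exon
  swallowed by a deletion) is excluded with a logged reason.

## Known limitations

- One personalized genome per individual: allele-specific splicing in
  heterozygotes is not modelled beyond retaining both junction classes.
- Exon skipping, intron retention and pseudo-exon activation are
  explicitly out of scope (`exotic`/`unannotated` junctions are
  classified but not called as events).
- The NMD rule is intentionally simple; the 50-nt variant is available
  but neither models decay efficiency quantitatively.
- Cohort identity keys assume the annotation names genes consistently
  across samples (true by construction here, since one GTF is lifted per
  individual).
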