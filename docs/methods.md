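# Methods

## The analysis model

`mutlog` implements the downstream half of an acute-mutagenesis
whole-exome study. Upstream (alignment, duplicate marking, somatic
calling) is assumed done; the inputs are per-sample VCFs with `DP` and
`AD`, a reference FASTA, capture-target BED, gene models (BED12), a sample
sheet, and optionally a per-interval coverage table.

**Somatic set.** Treated-sample calls are compared allele-aware
(contig, pos, ref, alt) against the non-treated control catalog and an
optional known-polymorphism list; anything shared is removed. The
remaining calls pass three filters, applied to the treated sample's own
fields: depth ≥ `min_depth` (default 6), alt reads ≥ `min_alt` (default
2), and VAF = `AD_alt / DP` strictly greater than `min_vaf_exclusive`
(default 0.10). "Strictly greater" is a deliberate reading of "higher
than 10%": a 3/30 call is rejected. VAF is defined operationally as
AD/DP; callers that report a model-based AF may disagree near the
threshold, which is a documented risk, not something we correct for.
Each rejection records the first failing rule in the order depth, alt,
vaf; depth 0 is rejected under the depth rule and never divides.

**Spectra.** Substitutions are collapsed onto the pyrimidine strand:
purine-reference calls are reverse-complemented, so the 12 ordered base
substitutions map exactly 2-to-1 onto the six classes C>A, C>G, C>T, T>A,
T>C, T>G (the reference:complement pair notation, e.g. C:G>T:A, is kept
as an alias). The context is the reference base 5' and 3' of the site;
when the triplet is reverse-complemented the context is reported 5'→3'
around the pyrimidine, matching the COSMIC/SBS convention. That yields a
6 × 16 matrix; contig-edge variants (an N flank) are counted in
`n_unclassified` so `bin total + unclassified = input size` always holds.
The CpG fraction of C>T is the count mass in NCG contexts over all C>T
counts — by construction of the collapse this covers CpG sites on both
strands; methylation status is not modeled. Context ranking sorts by
count descending with lexicographic tie-breaks for determinism.

**Regions.** Internally all coordinates are 0-based half-open
(BED-native); VCF's 1-based positions are converted at exactly one place.
A variant at 1-based p is exonic iff some exon [s, e) has s ≤ p−1 < e,
else intronic if inside a gene span, else intergenic. UTRs are not a
separate bucket. Overlapping genes: the reported gene_id is the
lexicographically smallest, and the full overlap list is kept — a variant
overlapping two genes counts toward both in recurrence.

**Recurrence and protection.** Gene-level (not position-level): a gene is
"mutated in condition c" iff ≥ 1 filtered SNV from any sample of c is
assigned to it; `exonic_only` restricts to exonic assignments. Recurrent
genes are those mutated in ≥ `min_conditions` (default 3) conditions,
sorted by count then gene_id; a threshold above the number of conditions
warns and returns empty. Whether "mutated" should mean any genic hit or
exonic-only is genuinely ambiguous in this kind of figure; both modes
exist and any-genic is the default. Protected loci are genes with exonic
hits under the UV-alone condition and **no genic hit at all** under the
TSA+UV condition — the stricter criterion keeps the protected set
disjoint from the TSA+UV mutated set by construction.

**Normalization.** Coverage of a target interval is
`read_length × n_reads / interval_length`. Size factors: per interval the
geometric mean of coverage across samples (computed in log space; immune
to sample order and to overflow on long interval lists), then per sample
the arithmetic mean of coverage/geometric-mean ratios over intervals.
This is intentionally the mean of ratios, not DESeq2's median — the
median variant sits behind `method="median"` for robustness comparisons.
Intervals with zero coverage in any sample are excluded (their geometric
mean would be zero) and the exclusion count is logged; if nothing
remains, the error message advises a fallback factor of 1.0 rather than
silently inventing one. Normalized count = raw count / size factor. The
averaging is over target intervals, not individual genomic positions:
intervals are the natural unit of the capture design and the ratio
algorithm.

## The synthetic study generator

The generator emulates the experimental design end-to-end so every stage
has a ground truth: a 100 kb two-contig genome of i.i.d. uniform ACGT
(an optional `cpg_boost` knob plants extra CG dinucleotides for
controllable CpG baselines), 30 non-overlapping genes of 3 × 150 bp exons
separated by 300 bp introns (strand random), targets covering every exon
± 20 bp plus random intergenic background intervals up to 140 total, and
100 bp reads. Gene placement is rejection sampling with 500 retries per
gene; an overcrowded configuration fails loudly naming the constraint.

The default panel holds 14 conditions plus one control: a UVB dose series
(10/20/30/40 mJ/cm², 72 h) in two donors, 4 h harvests at 30 mJ/cm²,
TSA pretreatment + UVB per donor, and TSA alone (including a repeat
treatment). UV-like conditions draw classes from
(0.10, 0.15, 0.30, 0.10, 0.25, 0.10) over (C>A, C>G, C>T, T>A, T>C, T>G)
— C>T dominant near 30%, T>C second near 25% — with context weights
ACG = TCG = 5 (others 1) inside C>T, which puts exactly half the C>T mass
on CpG contexts in expectation, and ATT = ATG = 6 inside T>C. Region
placement is (0.10, 0.20, 0.70) over exon/intron/intergenic for UV-like
conditions and (0.30, 0.40, 0.30) for TSA-alone conditions, reflecting
the more genic placement of HDAC-inhibitor-induced mutations. Variant
counts per condition (150–250) are chosen for test power: large enough
for 3-sigma binomial bounds to bite, small enough that the whole study
simulates in seconds.

A variant is realized by drawing (region, class, context) and then
sampling a genome position whose *actual* collapsed trinucleotide matches,
so the truth file is re-derivable from the emitted FASTA by construction;
a context absent from the genome raises an error naming the missing
trinucleotide. Depth ~ uniform{20..60}, VAF ~ uniform(0.2, 0.6), alt ~
Binomial(depth, VAF) — wide enough to exercise all three filter rules.
Shared polymorphism sites (default 30) are injected into every sample
including the control with per-sample filter-passing depths; the control
additionally holds background-only sites (default 20), enabling exact
subtraction tests. Planted gene hits (`plant_gene_hits`) deterministically
add one filter-passing exonic SNV per requested (condition, gene) for
recurrence/protection recovery fixtures. Per-interval read counts are
Poisson around `60× depth × scale` with per-sample scales ~ uniform(0.5, 2);
a zero-noise mode uses expectations exactly so proportionality tests have
closed forms. All child seeds spawn deterministically from the one config
seed; identical (config, seed) gives a byte-identical fixture.

What the generator does **not** emulate: caller error models, mapping
artifacts, tandem CC>TT dinucleotide events, indels, methylation,
transcription-strand asymmetry, and realistic human genome composition.
Passing tests therefore demonstrate correctness of the bookkeeping,
classification, counting and normalization algebra on data of known
provenance — not robustness to real-world calling noise.

## Numerical and degenerate-input choices

- Geometric means in log space; factors are exact to ~1e-15 on closed-form
  inputs and tested at 1e-9.
- Ties everywhere break lexicographically (context ranking, overlapping
  gene assignment, recurrence ordering) so outputs are reproducible.
- Empty inputs return empty-but-well-formed outputs (empty VCF → empty
  list; zero variants → all-zero spectrum; empty group → zero counts with
  NaN fractions flagged); undefined ratios (CpG fraction with no C>T) are
  returned as NaN with an explicit `defined` flag, never as 0.
- Stage counts (parsed → after subtraction → after filters) are asserted
  non-increasing in the run report.

## Known limitations

- Single-sample VCFs only; the control is a separate catalog, not a
  paired-normal genotype model.
- Recurrence is gene-level; positional hotspot recurrence is a possible
  extension, not implemented.
- The binomial detection model motivating depth correction is used only
  through the size factor; no explicit sensitivity model is fitted.
- Test and acceptance problem sizes (100 kb genome, ~3,000 SNVs,
  140 intervals) are the package's chosen study scale; statistical checks
  use 3-sigma binomial bounds at those sizes.
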