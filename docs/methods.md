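# Methods

## Scope and data model

`gbseval` evaluates SNP-calling pipelines for reduced-representation
(GBS-style) sequencing. It does not call variants or align reads; it
consumes per-pipeline genotype calls (VCF), a truth genotype set (VCF from
deep resequencing), optional per-site read-hit evidence, and optional raw
reads with a barcode table. Its own contributions are the evaluation
statistics (filters, concordance, overlap partitions, cause attribution,
demultiplexing loss) and a generator of fully labeled synthetic studies.

Sites are identified positionally by (chromosome, 1-based position, variant
class ∈ {SNP, indel}); alleles are excluded from the identity so that
catalogues from callers with different allele representations can be
intersected. Rationale: cross-pipeline overlap is a statement about *loci*,
and de novo pipelines anchored to a reference post hoc report positions
more reliably than allele orientations. An indel and a SNP at the same
coordinate are distinct sites. Multi-allelic records are dropped at load
(and accounted for in a load report); phased and unphased genotypes are
equivalent; half-missing diploid calls count as missing. Chromosome names
are compared after optional `chr`-prefix stripping and sites ordered under
a natural collation (digit runs compare numerically).

## Filters

All catalogues pass the same four rules, in a fixed order:

1. depth mask: calls with DP < `min_depth` (default 2) become missing;
2. missing data: sites with missing rate > `max_missing` (default 0.80)
   removed;
3. allele frequency: sites with MAF < `min_maf` (default 0.05) removed,
   MAF computed from called genotypes only;
4. heterozygous-locus purge: sites with het fraction > `het_locus_threshold`
   (default 0.50, strict inequality) removed from the otherwise-final
   catalogue.

The order is a design choice: depth masking changes both the missing rate
and allele counts, so it must run first; the het purge is described as a
removal from the final catalogue, so it runs last. Boundary semantics are
taken literally from the rule names: a site at exactly 80% missing or
exactly MAF 0.05 is retained, a site at exactly 50% het is retained.
All-missing sites are removed by the missing-data rule, never by MAF (their
MAF is reported as 0 by convention, het fraction 0). Comparisons carry a
1e-9 guard so that count-ratio floats at an exact boundary are not
misclassified. Filtering is idempotent; the audit log records each removed
site with the first rule it failed and the measured value.

## Concordance

A compared cell is a non-missing GBS call whose truth state is known;
accuracy is matching/compared. Heterozygote-vs-homozygote disagreements
count as full mismatches (no half credit), because in highly homozygous
inbred lines spurious hets are precisely the error of interest. Sites
absent from the truth matrix are handled under two conventions, both
computed on every report:

* **complete** (default): an absent position is homozygous-reference
  everywhere — appropriate when truth comes from near-complete
  whole-genome resequencing, where a position not in the truth VCF is
  monomorphic rather than unknown;
* **partial**: absent positions are excluded and counted separately.

Which convention a published comparison used is generally not stated, so
neither is asserted as canonical; the default follows the
near-complete-coverage argument. Conservation identity, checked in tests:
missing + compared(partial) + excluded(partial) + truth-missing = sites ×
samples. Report percentages are rounded to one decimal, half-up, matching
table conventions; counts are stored alongside and are authoritative.

## Overlap

Catalogues are site-key sets; pairwise overlap and the n-way partition
(each union site assigned to the exact subset of catalogues containing it)
are pure set arithmetic, and common counts are always derived from the
sets, never from printed percentages. Per-cell accuracy pools
matching/compared genotype counts over the cell's sites in every catalogue
of the subset; weighted means weight cells by pooled compared-genotype
counts, split into shared (subset size ≥ 2) and unique (size 1) groups.
Partitions are limited to 10 catalogues (2^k − 1 cells). Indels are
excluded from overlap by default (SNP catalogues are what is compared);
cross-platform overlap (same pipeline, two read sets) is the same
computation with integer-precision percentage views, since such figures
are conventionally quoted as whole percents.

## Error attribution

Unique inaccurate SNPs — sites with at least one mismatching compared cell
(configurable to a per-site accuracy threshold), inaccurate in exactly one
pipeline — descend a decision tree:

1. **mapping multiplicity**: a supporting read is multi-hit if its
   normal-reference hits span ≥ 2 distinct loci, where distinct means
   non-overlapping target intervals after merging (the notion of "distinct
   position" is otherwise undefined for overlapping secondary alignments).
   A site is multi-position if *any* supporting read is multi-hit
   (configurable to a majority rule); single-position sites are caller
   errors (sequencing/PCR noise reaching the caller).
2. **masked remap**: if every supporting read has zero hits on the
   hard-masked reference, the locus lives in repeat sequence ⇒ repetitive.
3. **paralogy**: a read with ≥ `min_hits` (2) hits, each at coverage ≥
   `min_coverage` (1.00, of the full read length) and identity ≥
   `min_identity` (0.96) ⇒ paralogous; the qualifying hit count feeds the
   mean-hits statistic. Loosening `min_identity` is monotone in the
   paralogous count (tested).

Multi-position sites failing both tests land in an explicit `unresolved`
terminal, and sites without evidence in a separate no-evidence column, so
the tree is a true partition: unique-position + multi-position +
no-evidence = unique inaccurate, and repetitive + paralogous + unresolved =
multi-position. Evidence is consumed from files (own TSV, BLAST outfmt-6
with a read→site map, or SAM with NM-derived identity) rather than by
invoking an aligner, keeping the stage hermetic; the synthetic generator is
the test oracle for it.

## Demultiplexing

A read is assigned to the unique sample whose barcode matches the read
prefix within `max_mismatch` (default 0 — the strictest convention) and is
followed by the enzyme remnant (`CWGC` for *Ape*KI, IUPAC-aware,
configurable per enzyme). Variable-length barcodes are resolved
longest-first; ties at the winning length are unassigned, never arbitrary.
Assigned reads are trimmed of barcode + remnant. Barcode tables are
validated at load: duplicates and remnant-ambiguous prefix pairs (one
barcode being a prefix of another with a remnant-compatible gap) are
refused. Read conservation (Σ per-sample + unassigned = total) is exact and
tested; `demux_delta` reports per-sample and unassigned-percentage deltas
between two runs over the same reads.

## Synthetic study generator

The generator emulates the statistical structure the evaluation assumes,
with every error traceable to a planted cause label.

**Genome.** Uniform-random sequence, default 1 Mb over 2 chromosomes
(`Gm01`, `Gm02`), a deliberate miniature of a crop genome: large enough for
thousands of restriction fragments, small enough to regenerate in well
under a minute. Planted features are placed non-overlapping with a 150 bp
margin: paralog families (default 16 families, 3 kb segments, copy number
2 + Poisson(0.4) for a mean of 2.4, inter-copy identity uniform on
0.96–1.00) and repeat families (default 8 families × 6 copies × 800 bp,
identity 0.98–1.00). The hard-masked companion genome replaces repeat
intervals — and only those — with N, mirroring the role of a
repeat-masked reference; segmental duplications are not masked, which is
exactly what makes the masked-remap test informative.

**Digestion.** Fragments are the intervals between consecutive occurrences
of the enzyme motif (`GCWGC`; the motif family is its own reverse
complement, so a forward scan covers both strands), retained when
100–400 bp — a typical size-selection window.

**Truth.** Default 5,000 polymorphic sites (10% short indels) placed on
fragments; alternate-allele frequency uniform on [0.05, 0.5]; 24 inbred
lines homozygous apart from a 1% residual heterozygosity. Truth is fully
called ("complete" convention), as deep WGS truth effectively is.

**Pipeline profiles.** Real pipelines are emulated as parametric error
profiles, not re-implemented: site sensitivity, per-cell genotype error at
structurally clean sites (cause `caller_error`), per-site paralog collapse
inside duplications (cause `paralog`: a fraction of calls drawn from
`het_conversion_range`, default U(0.15, 0.65), become het — partial
collapse, because fully collapsed loci are caught by the >50%-het purge
while partially collapsed ones survive into the catalogue), per-site
repeat mismapping (cause `repeat`: half the calls randomized), extra
per-cell missingness, and negative-binomial depth (mean 6, dispersion 2, a
standard GBS coverage model; depth-0 cells become missing, and depth-1
cells are later masked by minDP 2). Genotype errors are not applied inside
planted structure, keeping causes well separated so that label-recovery
tests are meaningful. Three named presets ship as defaults: an accurate
indel-capable caller, a short-tag caller with heavy paralog collapse, and
a conservative low-sensitivity caller with heavy missingness.

**Evidence.** Emitted consistent with context: clean-region sites get one
full-coverage identity-1.0 hit on both references; duplication sites get
one hit per family copy (identity 1.0 for the containing copy, the family
identity for the others) on both references; repeat sites get multi-hit
normal evidence and an explicit zero-hit masked entry. The observed mean
qualifying-hit count at paralogous sites is therefore the *site-weighted*
mean copy number, slightly above the 2.4 family-mean parameter (larger
families span more sites); tests compare against the label-derived planted
value.

**Reads.** barcode + remnant + fragment prefix, fixed 100 bp (substitution
error 0.001) or variable 50–135 bp (substitution 0.005 plus rare
single-base indels). Truth SNP alleles are written into inserts per the
sampled line (hets contribute either allele). Sequencing errors apply to
the insert; barcode corruption is a separate dial so assignment loss can
be planted and measured in isolation. Barcodes are 4–10 nt, prefix-free,
with same-length pairwise Hamming distance ≥ 3.

**Determinism.** All randomness descends from one seed via
`numpy.random.SeedSequence` spawning; identical parameters give
byte-identical output files.

## Scenario presets

* `error_recovery_params`: no planted structure, one profile with 2%
  genotype error and ~30% missingness — concordance should report
  accuracy ≈ 98% (binomial concentration over ~7.5 × 10⁴ compared cells).
* `accuracy_ordering_params`: three structure-free profiles at error rates
  0.01/0.03/0.08 — recovered accuracies must preserve the order.
* `attribution_mix_params`: three identical profiles over a
  structure-heavy genome (28 paralog families, 10 repeat families). With
  three pipelines corrupting a site independently at probability p, the
  site is uniquely inaccurate with probability 3p(1−p)²; the collapse and
  mismap probabilities (1/3) and the small clean-site cell error rate
  (6 × 10⁻⁴) invert that relation so unique inaccurate SNPs number ≥ 500
  and split roughly 60% paralog / 20% repeat / 20% caller error. Recovery
  is judged against the planted labels of the same analyzed sites, so the
  comparison is survivorship-free.

## Numerical and degenerate-input choices

Percentages round half-up (decimal arithmetic, not banker's rounding) to
one decimal, or to integers where whole-percent figures are conventional.
Boundary comparisons carry a 1e-9 epsilon. Empty denominators report 0
(accuracy of zero compared cells) or None/absent (weighted shared mean
with a single catalogue; mean hits with no paralogous sites). Zero-site
matrices round-trip through VCF, including the presence of a depth grid
(signalled by the DP header). The all-missing site, the single-pipeline
sharing case (labels not-applicable with a warning), missing-evidence
sites, and empty read streams all have defined, tested behavior.

## What passing tests do and do not show

The generator produces exactly the failure modes the attribution tree
tests for, with evidence consistent with labels by construction. Passing
therefore demonstrates that the evaluation machinery is correct and
self-consistent (conservation identities, boundary semantics, parameter
recovery under binomial noise), not that any real pipeline has a
particular accuracy: real reads carry mapping ambiguity, allele-specific
bias, PCR duplicates and base-quality structure the generator does not
model (no paired ends, no quality recalibration, no PCR duplicates). Mean
accuracy, missingness and catalogue-size ranges of the presets are merely
plausible for GBS on an inbred diploid panel; conclusions about real
pipelines require real truth sets.

## Known limitations

* Positional site identity can conflate different alleles at one
  coordinate across pipelines; a strict allele-aware mode exists for
  concordance inputs but overlap is positional by design.
* Attribution stops at unique inaccurate SNPs; shared inaccuracies are
  labeled but not classified (their causes are confounded across
  pipelines).
* The read simulator writes only SNP alleles into reads (not indels), and
  demultiplexing is single-end only.
* Venn-cell accuracy output is tabular; no proportional-area figure is
  drawn.
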