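# Methods

## Expression model and normalization

Input is a raw count table of mapped reads per transcript per sample:
four gland libraries (female abdominal, female prothoracic, male
abdominal, male prothoracic) and one anterior-abdomen control library,
one library per tissue, with no replicates — fold changes are therefore
descriptive ratios, not statistical estimates, and the calling rule is a
deterministic threshold rather than a test.

Stages run in a fixed, enforced order:

1. **Longest-isoform selection.** One transcript per gene, the longest;
   length ties break to the lexicographically smallest transcript id so
   the selection is reproducible.
2. **Pseudocount.** Cells with zero mapped reads are set to one read.
   Only zero cells are touched: the intent of the pseudocount is to
   keep unexpressed transcripts representable in log-ratio space, not
   to shrink all counts. A transcript absent from both a gland and the
   control sample gets 1/1 and a fold change of exactly 0.
3. **Depth.** depth = (count × read_length_bp) / length_bp with
   read_length_bp = 38 (the library read length). Depth is a
   coverage-like per-transcript quantity; no between-sample library-size
   normalization is applied, matching the original analysis.
4. **log2FC.** log2(depth_gland / depth_control) per gland sample.
   Transcript length and read length cancel, so log2FC equals
   log2(pseudocounted count ratio); the tests assert this invariance
   explicitly (read length 38 vs 100).

Depths are kept at full float precision internally; report TSVs round
to 4 decimals. Table readers accept a decimal-comma locale flag for
inputs written with `,` as the decimal separator.

## Gland-specificity rule

A transcript is gland-specific iff log2FC ≥ 4 (FC ≥ 16) in **all four**
gland tissues. The comparison is inclusive and exact — no epsilon —
because the rule is a definition: exactly 4.0 passes; a value of
3.9999999 produced by upstream rounding fails, which is why depths are
never rounded before calling. The threshold is configurable (the
historical stricter 64-fold rule is `threshold_log2=6`). A near-miss
report lists non-specific transcripts passing in ≥ k tissues (default
3) with their failing tissues, sorted by descending minimum log2FC;
this captures boundary cases such as a transcript at log2FC 3.1 in one
tissue and ≥ 4 in the other three.

## Annotation reconciliation

Gene-model fusions make old→new gene-set mappings many-to-one but never
one-to-many; the mapping is a function of the old id. Remapping
replaces each id by its target and de-duplicates order-stably; ids with
no mapping entry pass through unchanged by default (`on_missing="keep"`),
because genes annotated only in the new gene set have no old model.
Overlap analysis of 2–3 named lists builds an explicit membership matrix
from which all sizes are derived, so inclusion–exclusion identities hold
exactly by construction. Fusions in the synthetic generator are always
two-into-one; higher-order fusions are out of scope.

## Phenotype vocabulary

Gland morphology after knock-down takes exactly one of seven categories
(darker secretion, lighter secretion, irregular reservoir, less
secretion, colorless secretion, melanized content, size-decreased) or
wild-type-like. Category percentages are reported over phenotypic
(non-wild-type) genes and rounded to integer percent, so they sum to
100 ± 2.

GC-MS volatile profiles carry peak areas for MBQ, EBQ, 1-C15 and 1-C17
per gland region (abdominal, thoracic). The screen's "strong reduction"
is not quantified anywhere in the underlying protocol, so the package
makes the rule explicit: a compound class (benzoquinones = {MBQ, EBQ},
alkenes = {1-C15, 1-C17}) is *reduced* in a region iff **every**
compound of the class falls strictly below `reduction_fraction` × the
wild-type reference area there. The default fraction is 0.10 (10% of
reference): well below any plausible semi-quantitative "strong
reduction" reading while robust to peak-integration noise; it is
configurable and always echoed in reports. The call is monotone in the
fraction. The reference profile is the mean of designated wild-type
control profiles per region.

Volatile outcome categories per gene: benzoquinones reduced in both
regions (`bq_both`); all four region × class cells reduced
(`all_volatiles`, a subset of `bq_both`); alkenes reduced in both
regions without `bq_both` (`alkene_both`); any reduction with *no*
class reduced in both regions (`gland_specific`, i.e. restricted to one
gland region); and `any_change`. These satisfy
`all_volatiles ≤ bq_both ≤ any_change ≤ n` and
`bq_both + alkene_both + gland_specific = any_change`. The
`alkene_both` category is carried separately because the other three
published categories do not otherwise partition the any-change total.

## Synthetic data generator

The generator emulates the study's inputs, not its raw reads:

* **Catalogs**: uniform transcript lengths over a configurable range
  (default 300–5000 bp), configurable isoforms per gene.
* **Counts**: per-transcript negative binomial draws (gamma–Poisson
  mixture; dispersion α with variance μ + αμ², Poisson at α = 0). The
  expected count of transcript *t* in sample *s* is
  `baseline_mean × 2^log2fc(gene, tissue) × (library_size/10⁶) ×
  (length_bp/10³)` — i.e. `baseline_mean` is calibrated as the expected
  control count of a 1 kb transcript in a 1 M-read library. Draws are
  independent across transcripts, so the realized library total
  fluctuates around the nominal size; this is deliberate — the analysis
  normalizes per transcript only and never uses library totals, so
  multinomial allocation would add complexity without changing any
  downstream quantity.
* **Planted truth**: gland-specific genes carry the same log2 effect in
  all four gland tissues (default 6, baseline mean 50, dispersion 0.1 —
  a strong, clearly super-threshold signal with one library per tissue);
  null genes have effect 0 everywhere.
* **Randomness**: one seeded generator per operation; per-sample
  sub-streams are derived from (seed, sample label), so adding a sample
  leaves all other samples' counts bit-identical.
* **Screen tables**: morphology drawn from a configurable distribution
  over the eight labels (default emulating the phase-3 composition);
  for phenotypic genes each region × class cell is independently reduced
  with a configurable probability (benzoquinone cells 0.6, alkene cells
  0.3 by default, echoing the predominance of benzoquinone loss), with
  both compounds of a class moving together, as observed; reduced cells
  drop to 2% of the reference area. Wild-type-like genes keep the
  reference profile exactly.
* **Composition-specified tables**
  (`phenotype_table_from_composition`, `gene_lists_from_venn`): build
  synthetic tables/lists whose category counts or Venn region sizes are
  *exactly* a prescribed composition. These exist to reproduce
  published summary tables whose per-gene rows are not available; they
  verify the set/classification logic, not the upstream measurements.

What the simulations do **not** emulate: read-level artifacts (mapping
ambiguity, positional bias), correlated expression between genes,
isoform-level expression differences, batch effects, and GC-MS
measurement noise. Passing recovery tests therefore demonstrates the
correctness of the pipeline's logic under its stated model, not the
field performance of the 16×-rule on real libraries.

## Problem sizes and numerical choices

The acceptance computation simulates the full 16,593-transcript
catalog once and runs the recovery study at 200 genes × 20 seeds —
sizes chosen to give stable averages while keeping the whole
computation in the seconds range. Sensitivity under planted effect 6,
baseline 50, dispersion ≤ 0.1 exceeds 0.95 with false-positive rate
below 0.01; sensitivity degrades smoothly through effects 4.0 → 3.5 →
3.0 (≈0.25 → 0.07 → 0.01), vanishing well below the threshold.

Degenerate inputs are handled explicitly: empty catalogs are valid,
all-zero count matrices yield zero calls (every ratio is 1 after
pseudocounting), empty phenotype tables are rejected, and a zero
reference peak area is an error rather than a silent division.

## Known limitations

* Calls are transcript-level on the longest isoform; genes whose gland
  expression is isoform-specific in a shorter isoform can be missed.
* The one-library design means no variance estimate: the threshold rule
  cannot distinguish biological enrichment from single-library noise,
  which is inherent to the reproduced analysis.
* Fusion mappings support two-into-one only.
* Morphology is single-valued per gene; if a source table ever carries
  two categories for one gene it must be split upstream.
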