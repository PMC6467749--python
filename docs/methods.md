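# Methods

This note records the models, rules, parameters and design choices behind
`umi-mrd`, and what the synthetic-data experiments do and do not show.

## Simulation model

One simulated library corresponds to one amplicon assay applied to one DNA
sample. Its generative model:

1. **Templates.** `n_molecules` haploid genome-equivalents enter
   barcoding. Each receives an independent uniform random barcode of
   `barcode_length` (default 12 nt). Barcode collisions are allowed and
   occur at the birthday-bound rate (negligible at 12 nt and ≤ 10⁵
   molecules). Each configured variant allele is drawn per molecule as an
   independent Bernoulli(VAF); the realized mutant counts and molecular
   VAFs are recorded as ground truth — they, not the nominal VAF, are what
   consensus calling estimates.
2. **PCR.** Deterministic doubling for `pcr_cycles` cycles (default 20):
   every molecule is copied once per cycle, and each copy event introduces
   per-base substitution errors at `polymerase_error_rate` (default
   10⁻⁵/base/cycle), inherited by all descendants of the copy. This is the
   simplest model that produces the failure mode barcoding addresses:
   an early-cycle error is carried by a large fraction of its family.
3. **Sequencing.** `reads_to_sample` single-end reads are drawn uniformly
   (with replacement) from the final pool, then hit with independent
   per-base substitution errors at `sequencing_error_rate` (default
   10⁻³/base). Read layout is barcode + 6-nt constant spacer + insert;
   qualities are constant Q30 because no downstream rule uses them.

Because doubling gives every founder equally many descendants, the pool is
never materialised: a uniform pool draw is a uniform founder choice plus a
uniform random path through the founder's binary genealogy (original/copy
choice per cycle, so the number of copy events per read is
Binomial(cycles, ½)). Polymerase error draws attach to *lineage prefixes*;
reads of a family that descend through the same early copy share its
errors exactly. This is equivalent in distribution to materialising the
doubled pool and sampling reads with replacement.

One RNG stream per library, seeded explicitly; the ground-truth object
carries the generator state and amplification deep-copies it, so
(config, seed) determines the FASTQ byte-for-byte.

What the simulator does **not** model: indels, polymerase/sequence-context
bias, paired-end reads, quality-score profiles, fragment-length effects,
sample cross-contamination, and barcode chemistry details. Passing tests
therefore demonstrate the *logic* of error suppression and calling under
idealized substitution noise, not performance on real libraries.

## Consensus rules

Families are grouped by exact barcode match (single-mismatch merging is a
deliberate non-default; exact matching is the conservative reading and
mutated barcodes mostly produce sub-threshold singleton families that are
discarded). Per position within a family of size *s*:

- *s* < 10 — family excluded entirely;
- 10 ≤ *s* ≤ 20 — a base is called only with unanimous support
  (count = *s*);
- *s* > 20 — a base is called with support fraction ≥ 0.90.

The ≥ 0.90 comparison is done as `count / s >= 0.90` in IEEE arithmetic;
correctly-rounded division makes exact 9/10 ratios (27/30) compare equal,
so the boundary is inclusive. If no base wins, the position is called N
and drops out of the family-count denominator at that position
("informative families"); this keeps sub-threshold noise from inflating
either allele. Since the large-family fraction exceeds ½, at most one base
can win — ties are impossible by construction. Consensus is evaluated per
position, not per whole read, matching per-base MAF reporting.
Coordinates are 1-based inclusive throughout (VCF convention).

Two implementations are kept in exact agreement: a dataclass path for
small instances and a vectorised path for full runs, both property-tested
against a brute-force oracle on instances ≤ 50 reads.

## Panel design

Candidates (SNVs only) are scored
`w_vaf·min(VAF/0.30, 1) + w_cosmic·[COSMIC] + w_loc·loc + w_imp·imp` with
defaults w = 1 each, location weights exonic 1.0 / splice, UTR, intronic
0.25 / intergenic 0.0, impact weights high 1.0 / moderate 0.5 / low 0.1 /
none 0.0. The criteria are standard; the weights are this package's
(configurable) choice, since only the criteria — not weights — are
established practice. VAF saturates at 30%, the top of the tumor-VAF range
the design targets. Ties break by VAF descending then genomic position
ascending, making the ranking a total order independent of input order.

Panels take the top 2–8 assay-backed candidates (k capped at 8; a single
available candidate yields a size-1 panel with a warning rather than a
failure). Tumor verification requires consensus VAF ≥ 1% in the
deep-sequenced tumor library — an order of magnitude above the plasma
threshold; a patient with no verified mutation is ineligible for
monitoring. Visual inspection of alignments is replaced by an
accept-all automated filter stub (visual QC is not specifiable as an
algorithm). Assays are *short* iff target region length < 80 bp (strict).

## Plasma calling

Background noise is summarised per assay as mean + 3 SD of the MAFs at
informative non-panel positions (panel positions are excluded so a true
variant never inflates its own background; fewer than 5 usable positions
falls back to a zero threshold with a warning). Alternatives (per-position
maxima, matched-control subtraction) would also be defensible; mean + 3 SD
is the standard position-noise model and is configurable.

Detection per mutation: consensus VAF ≥ 0.05% (inclusive) AND strictly
above the background threshold. The 0.05% rule is applied per mutation,
not to any combined panel statistic. A position with zero informative
families is *not evaluable* — distinct from negative, since it is absence
of evidence. Sample positivity: ≥ 1 detected mutation; a sample with no
evaluable call is itself not evaluable.

The method's detection limit (0.1% VAF) and the positivity threshold
(0.05% VAF) are independent parameters: the first is the validated
sensitivity of the whole assay, the second the per-sample decision rule.

## Timelines

Day 0 is definitive treatment; exactly one treatment event per patient is
required and sample days must be unique. Baseline = latest evaluable
sample with day ≤ 0. Clearance is judged on the first *evaluable*
post-treatment sample. Molecular recurrence = first positive
post-treatment sample. Lead time = clinical recurrence day − molecular
recurrence day (positive: blood first). Summary percentages are rounded
half-up to integers (6/7 → 86%).

## Synthetic cohort

`umi_mrd.fixtures.generate_fixtures` writes an 8-patient cohort with 2–8
assays per patient (one 95-bp long amplicon, the rest < 80 bp), a tumor
library per assay, and baseline + longitudinal plasma draws at scripted
true VAFs encoding the clinically interesting shapes: non-clearance with a
+22-day lead, a first positive draw 13 days after clinical recurrence, a
baseline-negative patient turning positive 156 days before the clinic, two
distant-metastasis patients negative in follow-up, and one patient with no
tumor-verified mutations. Study conditions per library: plasma 3000
molecules (~10 ng cell-free DNA equivalent) and 60,000 reads (~20 per
family); tumor 1500 molecules and 30,000 reads. At these depths the
smallest scripted VAF (0.12%, ≈ 3.6 mutant molecules expected) has a
per-mutation dropout probability of a few percent, but sample-level calls
(any of ≥ 2 mutations) are robust. A `scale` parameter shrinks the cohort
for smoke runs; narrative-level assertions are only meaningful at full
scale. The scripted days and VAFs are reconstructions of a plausible
clinical course, not data.

## Problem sizes and numerical choices

- Detection-limit experiment: 3 replicates × 25,000 molecules × 750,000
  reads (~30/family), sequencing error 0.3%/base, polymerase error
  10⁻⁵/base/cycle, 20 cycles; VAF 0.1% must be positive in all replicates
  and VAF 0 negative in all. At these settings the expected mutant
  consensus count is ~25 against a background that consensus suppresses to
  ~0, and the 0.05% rule needs ≥ 13 mutant families — roughly 2.5 SD below
  the mean, so a rare unlucky replicate is possible and is reported as a
  failure, not retried.
- VAF-recovery checks use 8000 molecules / 200,000 reads and require
  agreement with the realized molecular VAF within 3 binomial SE.
- Error-suppression check: 2000 families of mean size 25 at raw error
  0.5%/base must yield consensus MAF < 0.05% at every position.
- Degenerate inputs: empty template pool raises; empty candidate list
  yields an empty panel with a warning; zero informative families
  propagates as not-evaluable rather than zero.

## Known limitations

Substitution-only error model; exact-match family grouping only; no
duplex (two-strand) consensus; no quality weighting; single-threaded
consensus (outputs are deterministic and independent of any scheduling);
the cohort generator encodes one fixed narrative rather than sampling
random clinical courses.
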