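# Methods

`covgeno` genotypes a multi-gene deletion inside a tandem paralog array from
targeted-capture read depth, estimates the diploid copy number of an
unlinked multi-copy gene family, diagnoses the multimapping artifacts that
conserved paralog exons create, and tests whether the two structural-variant
axes segregate independently.  This note documents the models, the defaults
and why they were chosen, what the synthetic cohorts do and do not emulate,
and the numerical conventions the implementation commits to.

## Coverage model

Depth is computed on the reference span of each aligned read, clipped to
exon boundaries.  The mean depth of an exon is (sum of clipped spans) /
(exon length), which equals the average of the per-base pileup exactly; the
mean depth of a gene is the length-weighted mean over its exons.  A read
counts as overlapping an exon when at least one base of its span intersects
it.  Two mapping-filter profiles are canonical:

* **unique** — duplicates removed, MAPQ < 30 removed, multimapped reads
  removed.  Used for deletion genotyping, where cross-paralog reads are the
  enemy.
* **all** — duplicates removed, everything else kept.  Used for copy-number
  estimation of high-identity families, whose reads *cannot* map uniquely;
  filtering them would discard the dose signal itself.

A read is called multimapped when its MAPQ falls below 30 or it carries a
secondary/supplementary flag.  MAPQ is a proxy: short-read aligners assign
low mapping quality exactly when near-equal alternative placements exist,
so the cutoff that defines the "unique" profile doubles as the multimap
definition.  The multimap fraction of an exon is computed over
duplicate-free reads (duplicates are removed before anything else, matching
the filter order) and is profile-independent.

## Deletion genotyping

Per sample, the deletion ratio is

    r = mean(depth of deletion-member genes) / mean(depth of retained
        array-reference genes)

under the unique profile.  Gene means are averaged *unweighted* across
genes: capture efficiency varies per target, and a long gene should not
dominate the ratio.  (A length-weighted variant is available via
`gene_weighting="length"`.)  A diploid expects r ~ 1 with the deletion on
neither haplotype, ~ 0.5 on one, ~ 0 on both, giving the step-function
call:

| call      | band                |
|-----------|---------------------|
| HomoDel   | r < 0.10            |
| Het       | 0.35 <= r <= 0.65   |
| HomoRef   | r >= 0.80           |
| Ambiguous | anything else       |

The HomoDel bound (10% of reference coverage) is the established rule for
"effectively absent"; the Het band is symmetric about the expected 0.5 and
deliberately conservative; 0.80 for HomoRef quantifies "similar coverage",
which has no canonical value — it is a package choice, recorded in every
output's metadata header and configurable.  The fourth class is also a
package choice: real cohorts contain intermediate ratios, and forcing them
into three classes would hide QC failures; Ambiguous keeps them visible.
Samples with zero reference depth are reported as Uninformative (capture
failure), never silently classified.

Exons flagged as multimapping artifacts can be excluded from the
deleted-set mean; the affected gene is re-averaged over its remaining exons
with length weights, and a gene whose exons are all excluded drops out of
the mean entirely.

## Copy-number estimation

The target family's diploid copy number is

    cn = 2 * target_mean / reference_mean

computed under the **all** profile.  `target_mean` averages the designated
target exons (exons 2 and 3 of each family gene, named in the feature file,
never inferred positionally) — length-weighted within a gene, unweighted
across genes.  `reference_mean` averages a panel of single-copy reference
genes (arithmetic mean by default; median available as a robustness option
against a single failed capture target).  The factor 2 makes the estimate a
diploid dose, because the reference genes are present at two copies per
genome.  On a high-identity family the unique profile discards most reads
and strictly underestimates cn — the package reproduces this in simulation,
which is precisely why the all profile is the default for this estimator.

## Multimapping-artifact diagnosis

When a deleted paralog shares a near-identical exon with a retained
paralog, reads from the retained copy align to the deleted one, producing
spurious coverage on a gene that is physically absent.  Two independent
evidence sources flag such exons:

* **sequence identity** — optimal global alignment identity (match +1,
  mismatch −1, linear gap −2; identity = matches / aligned columns) between
  each deletion-member exon and every exon of retained same-family
  paralogs.  Global alignment is appropriate because the compared exons are
  full-length homologs; a seeded local search on real data will give
  somewhat different values, which is accepted and expected.  Threshold:
  best cross-paralog identity ≥ 95%, the conventional cutoff for
  "effectively indistinguishable to a short read".
* **observed multimapping** — the cohort-median multimap fraction of the
  exon ≥ 0.9.  The median over the cohort, not per-sample values, because
  the artifact signature is population-level; 0.9 sits between the ~0.8
  background typical of paralog-family exons and the ~0.95 level of a truly
  conserved exon pair.

Either source suffices (reasons `high_identity`, `high_multimap`, or
`both`); flags feed the genotyper's exclusion list.  A helper converts
identity to an expected ambiguous-read fraction by a binomial argument: a
read of length L against a partner at per-base divergence d stays ambiguous
when its Binomial(L, d) mismatch count is within the aligner's scoring
margin (default 5% of L).  This is a heuristic for building intuition and
simulator settings, not a calibrated aligner model.

## Rank-sum association

Independence of copy number and deletion genotype is tested with the
two-sided Wilcoxon/Mann-Whitney rank-sum test on the three pairwise class
comparisons (HomoRef vs HomoDel, Het vs HomoRef, Het vs HomoDel), with
Ambiguous and Uninformative samples excluded and empty comparisons reported
as not evaluable.  U uses midranks.  For tie-free samples with
n1 + n2 ≤ 12 the p-value is exact by full enumeration of all C(n1+n2, n1)
labelings (≤ 924, so the worst case is trivial); ties or larger samples use
the normal approximation with tie correction and a 0.5 continuity
correction.  Two-sided p-values follow the doubling convention
p = min(1, 2 × smaller tail); the convention and the continuity flag are
recorded in the result object because alternative conventions differ in the
tails.  With all observations tied the variance is zero and p = 1 by
definition.  Realistic cohort sizes are far into the asymptotic regime; the
exact path matters for small subgroup comparisons and for testing.

Genotype-frequency summaries report per-region class counts and the
deletion-allele frequency q = (2·HomoDel + Het) / (2·(HomoRef + Het +
HomoDel)); Ambiguous samples are counted but excluded from q's denominator.

## The synthetic cohort generator

The generator emulates exon-capture depth over a toy diploid genome with a
20-gene tandem toxin array (genes 11–16 deleted on one haplotype, ~6 of 20,
emulating a contiguous six-paralog deletion), one copy-number-target gene
family and 10 single-copy nontoxin reference genes on a second chromosome.
Defaults are the study conditions:

* `mean_depth` 30 — capture depth for a diploid single-copy target; per
  exon base the expectation is `mean_depth × c / 2` where c is the summed
  haplotype copy count (2/1/0 for HomoRef/Het/HomoDel over deletion
  members; the sample's diploid copy number for the target family).
* exons: 3 per array gene × 150 bp (capture probes are exon-scale);
  reads: fixed 100 bp, uniform start within the exon, simulated per-exon as
  independent counts — no fragmentation model, since the analysis consumes
  only mean depth and multimap fractions.  Read counts are Poisson by
  default; a negative-binomial option (size 10) is provided because capture
  depth is often overdispersed, but no empirical dispersion estimate
  exists for these data, so the size default is a flagged pure choice.
* `dup_rate` 0.05 — PCR duplicates are extra flagged copies of real reads,
  so the duplicate-free signal keeps its expected depth.
* cross-mapping: the default locus carries one conserved-exon pair — the
  last two exons of deleted gene 12 against retained gene 17 at ambiguous
  fraction 0.95 and sequence identity 97.5%.  The sink exon receives its
  own copy-scaled signal plus the source gene's copy-scaled signal, and
  every read landing there is multimapped (MAPQ 0) with probability 0.95,
  else spuriously unique.  Consequences, all observed in simulation: in
  deletion homozygotes the sink exons show ~95% multimapped reads while
  unique-profile depth stays near zero; under the all profile those samples
  drift toward Ambiguous unless the exons are excluded; in carriers of the
  intact array the unique-profile depth of the conserved exons is cratered
  by the MAPQ filter, as on real data.
* copy-number target: reads are multimapped at a 0.8 background rate
  (high-identity family), and per-sample diploid copy number is uniform on
  {2..8}, drawn independently of the array genotype.  The two loci sit on
  different chromosomes, so their independence holds by construction — the
  association stage's null calibration is meaningful, but passing it says
  nothing about linkage in any real population.
* regions: a 119-sample "core" at genotype frequencies (0.97, 0.025, 0.005)
  plus a 20-sample "northwest" at (0.30, 0.15, 0.55) — a rare deletion
  overall that dominates one peripheral region, matching the observed
  range-wide pattern of ~123/5/11 in 139 individuals.

Randomness: one root seed per cohort; per-sample substreams are spawned by
counter (`numpy.random.SeedSequence.spawn`), so identical cohorts are
reproduced bit-for-bit regardless of generation order, and the orchestrated
run is byte-identical across repeats.

What the generator does **not** emulate: sequence-level read errors,
alignment itself, GC/mappability bias, capture-efficiency variation between
targets, transposable-element structure at the deletion breakpoints, and
linkage between loci.  Passing tests therefore demonstrate the estimators'
correctness under the stated depth model, not robustness to every real
capture pathology.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open internally; GFF3 converts at the
  boundary.  Strand is stored but ignored by coverage.
* Depth means are exact rational sums divided by lengths; the pileup
  equivalence tests require agreement with a brute-force per-base oracle to
  1e-9.
* Zero-read exons have depth 0 and multimap fraction 0 by convention.
* Classification band edges: HomoDel open at 0.10, Het closed at both
  edges, HomoRef closed at 0.80.
* Exact rank-sum tail counts use a 1e-12 tolerance when comparing U values
  (midranks are exact halves, so this only guards float noise).
* Problem sizes in the test-suite and acceptance checks (e.g. 10 cohorts of
  300 samples for genotype recovery, 50 samples per copy-number level, 400
  null cohorts for type-I calibration) were chosen so Monte-Carlo error is
  small against each tolerance while the whole suite stays desk-scale.

## Known limitations

* The genotyper assumes the deletion is a single contiguous allele shared
  by all carriers; partially overlapping deletions would produce
  intermediate per-gene ratios that land in Ambiguous rather than being
  resolved.
* Copy-number estimates are continuous dosages; no integer rounding or
  segmentation is attempted, and the estimator cannot attribute dose to
  individual family members (their reads are mutually ambiguous by
  construction).
* Identity values from the global aligner are not directly comparable to
  local-alignment identities from seeded search tools on sequences with
  large indels or partial homology.
* The exact rank-sum path does not handle ties (midrank enumeration with
  ties is out of scope); tied data always use the corrected normal
  approximation, which is accurate at the group sizes where ties are
  likely.
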