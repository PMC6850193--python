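# Methods

## The screening model

The pipeline screens a small case-control cohort for genes whose rare,
putatively protein-disrupting mutations are enriched in subjects with
rightward hemispheric language dominance (RHLD). The unit of testing is the
gene, not the variant: allelic heterogeneity is expected for monogenic
traits, so each subject is collapsed to a boolean "mutated / not mutated"
indicator per gene under each of two inheritance models, and the gene-level
2×2 table is tested exactly. This makes the test robust at small sample
size — significance is assessed against the actual configurations the
contingency table could take in these subjects — at the cost of power
against common variants of small effect, which are explicitly out of scope.

### Phenotype selection

RHLD status comes from fMRI hemispheric functional laterality indices
(HFLI; negative = rightward). The two-step rule is: (1) production
HFLI < −50 (stringent, production tasks lateralize most strongly), else
(2) all three task HFLIs (production, reading, listening) < −15. The −15
boundary stands in for the decision surface that a 3-D Gaussian-mixture
consensus clustering of the joint task distribution produced in the
original subject screening; since that clustering is defined elsewhere and
its fitted boundary is what matters downstream, the module implements the
threshold form and accepts a user-supplied classifier hook for
experimentation. All comparisons are strict inequalities. Subjects that
satisfy both steps are labelled by step 1.

### Variant filters

* **Severity**: keep protein-coding variants of MEDIUM or HIGH impact and
  noncoding variants of HIGH impact (in practice splice donor/acceptor
  changes); drop coding MEDIUM variants that PolyPhen explicitly calls
  *benign*. MEDIUM variants with no PolyPhen call are retained — only an
  explicit benign prediction removes a variant.
* **Cohort presence**: within each recruitment batch separately, variants
  carried (het or hom-alt) by ≥ 19 subjects are removed as likely
  platform-specific artifacts or undercatalogued common variants. Carriers
  are counted as genotype carriers, not allele occurrences.
* **Population frequency**: the working MAF is the maximum across all
  annotated population databases (gnomAD, ExAC, 1000 Genomes, ESP).
  Dominant model: max MAF < 1%. Recessive model: max MAF < 10%. Variants
  absent from every database are retained under both models — novel
  variants cannot be excluded on frequency.
* **Missing genotypes** count as reference: carrier status requires
  observed alternate alleles (conservative).

The MAF bounds follow from Hardy–Weinberg/penetrance arithmetic for a ~1%
trait (see `rhldscan.hwe`): a fully penetrant, fully explaining recessive
variant tops out at q = 0.10 (homozygote frequency 1%); at 50% penetrance —
plausible if a mutation randomizes rather than reverses laterality, as in
visceral situs genetics — the bound rises to q = √(0.01/0.5) ≈ 0.14. The
dominant solution uses the exact quadratic f·(2q(1−q)+q²) = t rather than
the 2q approximation. Both cutoffs are therefore inclusive: allelic or
genetic heterogeneity only lowers the per-variant bound.

### Monogenic models

*Dominant*: a gene is mutated for a subject if the subject carries at least
one qualifying variant (het or hom-alt) in it.

*Recessive*: a homozygous qualifying variant, or putative compound
heterozygosity — at least two distinct heterozygous qualifying variants in
the gene. Read-backed phase is usually unavailable at short read lengths,
so compound heterozygosity is presumed unless disproven: a gene is excluded
only when every pairing of its het variants is proven in cis (identical
read-phase labels). One unphased variant alongside a proven-cis pair
retains the gene, since it may pair in trans with either variant. Phase
enters the variant model as an optional per-subject label
(`PH_<subject>` column in the flat dialect; phased GT plus `PS` in VCF).

### Gene-level testing and calibration

Each gene with at least one mutated subject gets a one-tailed Fisher exact
test (conditional hypergeometric upper tail including the observed table,
alternative = case enrichment), computed in exact integer/rational
arithmetic and cross-checked in the tests against both brute-force
enumeration and an independent library implementation. Before testing, a
Welch two-sample t test verifies that per-subject mutated-gene totals do
not separate cases from controls (a difference would indicate platform
artifacts, not biology).

Multiple testing uses the adaptive calibration: y(x) = number of genes
mutated in ≥ x subjects, computed from the observed matrix for
x = 1..N; the reported thresholds are the smallest case-carrier counts x
(with zero control carriers) satisfying P < α and P < α / y(x)
respectively. Where no gene reaches x subjects, y(x) is taken as 1 — a
hypothetical lone test needs no correction. Genes mutated in at least one
control are flagged (`any_control_carrier`) *after* testing; excluding
them earlier would bias the multiple-testing count.

For the 33-case / 34-control design, the minimum nominally significant
count is 5 carriers (P = C(33,5)/C(67,5) ≈ .0246); 10 carriers give
P ≈ .000373. Published descriptions of this design print .0267 for the
5/0 configuration and .000186 for 11/0, which do not equal the standard
hypergeometric tail (.02457 and .000151) although the 10/0 value .000373
matches it exactly; the convention behind the two discrepant figures is
not stated, and this package implements the standard tail throughout.

### Gene-set mutational load

For a candidate set (≥ 10 genes; smaller sets are parsed but flagged
ineligible), every (subject, mutated gene ∈ set) pair is one *instance*; a
gene counts once per subject regardless of how many variants it carries.
With k instances in the test group out of n in the contrast, enrichment is
the upper tail of Binomial(n, p₀) at k, where p₀ is always the
subject-count share of the test group in the contrast universe — 33/67 for
the full cohort, recomputed for subgroup contrasts (e.g. 33/53 for cases
versus right-handed controls, or batch-restricted universes). No
correction across sets is applied; raw P values are reported with the
number of sets tested. The binomial tail is delegated to an established
exact-test routine and verified against direct pmf summation.

## Synthetic cohorts

No genomes accompany the study design, so the generator produces cohorts
with the statistical structure the analysis assumes, and they are the
substrate for every end-to-end test:

* **Design**: 67 subjects — 33 cases, 34 controls (14 left-, 20
  right-handed) — in two batches: a 39-subject batch with all three task
  HFLIs and handedness-balanced controls, and a 28-subject batch with
  production HFLI only and right-handed controls. One case is right-handed.
* **Laterality**: HFLIs are drawn from two Gaussian components with modes
  ±60 and SD 15 (cases rightward, controls leftward), matching the
  qualitative bimodal separation of the source cohorts; the exact
  parameters are configuration, not claims.
* **Mutation structure**: per-subject per-gene mutation indicators are
  independent Bernoulli draws over a 20 000-gene universe, targeting 240
  dominant and 50 recessive mutated genes per subject — inside the
  per-subject ranges observed across the study's sequencing protocols
  (dominant 154–300, recessive 31–77). Dominant events are materialized as
  private heterozygous variants with max MAF < 1% or database-absent;
  recessive events as homozygotes or compound-het pairs with MAF in
  [1%, 10%), so the two models stay independently controlled. Extra
  proven-in-cis het pairs (5% of the recessive rate) exercise the phase
  discard rule without depleting the target counts, and chaff variants
  (benign MEDIUM, LOW impact, common, noncoding, batch-recurrent) exercise
  every filter.
* **MAF distribution**: mixture of database-absent (30%) and log-uniform
  frequencies, reported by 1–2 simulated databases with the secondary one
  lower, so the max-across-sources rule is exercised.
* **Implants**: an optional causal gene (carriers land in cases with the
  configured penetrance; materialized as one shared variant, like a
  recurrent mutation) and an optional set-level rate-ratio applied to case
  subjects within one named set.
* **Two speeds**: `generate` emits full variant tables that round-trip the
  filters byte-identically under a fixed seed; `sample_matrix` draws
  matrices directly for replicate-heavy studies (2000-replicate null
  calibration, 200-replicate power checks), at a scaled-down default of
  2000 genes and rates 40/10 chosen to keep full test-suite runs in tens
  of seconds on one core.

What passing tests on these cohorts shows: the filters, models and exact
tests implement their rules correctly, type-I error of the load test is
conservative (≤ 6% at nominal 5% under the null), and implanted effects of
the designed magnitude are recovered. What they cannot show: behavior under
linkage disequilibrium, population stratification, batch-correlated
annotation error, or realistic gene-length variation — the generator draws
genes exchangeably and variants independently, which real genomes do not.

## Numerical and design choices

* Fisher tails use exact `Fraction` arithmetic (cached); binomial tails use
  the exact binomial test from scipy. Ties in burden ranking break by gene
  symbol.
* The 2×2 invariants reject P outside (0, 1] and negative counts;
  degenerate QC comparisons (zero variance in both groups) are reported
  with an explicit flag rather than NaN.
* Coordinates are 1-based fully closed (VCF convention); multi-allelic VCF
  records are refused with a pointer to upstream normalization; a variant
  annotated to several genes is modelled as one record per gene.
* Matrix serialization is a subject × gene 0/1 TSV with the model name
  embedded in the index header; phenotype, variant-flat and GMT formats
  round-trip exactly (tested field-by-field).
* The pipeline runner rounds P values to 3–4 significant figures for
  display in the JSON report while machine outputs (TSV) carry full
  precision.

## Limitations

* The compound-het rule presumes trans phase when phase is unknown; with
  short reads this overcalls recessive genes by design (inclusive
  screening).
* The adaptive Bonferroni denominator y(x) is taken at the tested count x,
  coupling the correction to the observed mutation landscape; it is not a
  family-wise error proof, only the calibration the screening design uses.
* Set-level testing treats instances as independent Bernoulli trials;
  correlated mutation counts within subjects (e.g. through sequencing
  depth) would make the null anti-conservative. The per-subject count QC
  test is the guard against the severe version of this.
* UK-Biobank-style single-variant association and all upstream processing
  (alignment, calling, annotation, stratification QC) are out of scope;
  annotations are consumed as given.
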