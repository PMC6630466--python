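# Methods

This note documents the models, conventions and numerical choices behind
`mirvar`, in the spirit of a statistical-software methods appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Seed-match model

A mature microRNA's seed is its nucleotides 2–8 (1-based, 5′→3′). The
scanner recognises the four canonical site classes on the transcript
sense strand (DNA alphabet): `8mer`, `7mer-m8`, `7mer-A1`, `6mer`,
defined by exact complementarity to seed positions 2–8 or 2–7, with the
A of `7mer-A1`/`8mer` matched as a literal adenosine opposite mature
position 1 (the standard convention — it is not a complementarity
requirement). Matching happens after mapping U→T on motifs; `N` never
matches. Coordinates are 0-based half-open throughout the library; the
1-based VCF convention is converted exactly once, at the VCF parser.

All four site classes contain the reverse complement of seed 2–7 (the
"core"); `8mer`/`7mer-m8` extend it by one 5′ base. When several classes
match around one locus the scanner reports only the most specific class
per *core anchor* (the position where the core match begins), with
precedence `8mer` > `7mer-m8` > `7mer-A1` > `6mer`. Anchoring on the
core rather than on the raw motif start is what makes the precedence
well defined: an `8mer` at start *s* subsumes the `7mer-m8` at *s* and
the `7mer-A1`/`6mer` at *s*+1, all of which share the core anchor
*s*+1. The relative order of `7mer-m8` and `7mer-A1` (which co-occur at
an anchor only inside an `8mer`) follows the standard efficacy
hierarchy. Overlapping sites of *different* families are all reported.

The default "target" set is {`8mer`, `7mer-m8`, `7mer-A1`}; `6mer`
sites are opt-in via configuration, reflecting mainstream prediction
practice. "Highly expressed" microRNAs default to the top half of the
supplied expression table (a negative `expression_threshold` in
`RunConfig` selects this rule; any non-negative value is used as an
absolute cut-off, applied as ≥). Both knobs are open choices: the
analyses this package supports do not pin either, so they are
configuration with documented defaults.

## Target/near-target pairs

Only biallelic SNVs are considered; indels and multi-allelic records are
excluded at parse time with counts logged. For a SNP and a seed family,
both allele-substituted sequences are scanned restricted to windows
whose half-open interval contains the SNP position — the pair concept is
about the SNP base itself toggling the site. A pair exists iff exactly
one allele carries ≥ 1 overlapping site of an allowed class; the target
allele's most specific overlapping site (leftmost on ties) provides the
reported coordinates. A SNP that leaves sites on both alleles (e.g. by
converting one allowed class into another, or by opening a second
overlapping site of the same family) is *not* a pair and is logged; this
target→target case is a deliberate, documented resolution of an
ambiguity in the pair definition. A SNP toggling sites of two different
families yields two independent pairs.

Pairs are defined per family, not per mature sequence; reports expand
the family to all mature names. Polarization is the total function over
(ancestral = target?) × (target in reference?) with `unpolarized` for
unknown ancestral state; the ancestral allele is read from INFO/AA,
upper-cased, and any value outside {REF, ALT} collapses to unknown.

The analysis window keeps pairs with pooled (global) target-allele
frequency in [0.01, 0.99], boundaries inclusive; the global frequency is
the pooled-count ratio over all samples, never a mean of group
frequencies. High-throughput experimental support means the pair's gene
and any family member co-occur in an interaction row whose evidence set
intersects {PAR-CLIP, HITS-CLIP}.

## Fst estimators

Three estimators are exposed, always by name, because they answer
slightly different questions:

* `wright_variance` — Var(p)/(p̄(1−p̄)) with equal population weights and
  population (ddof = 0) variance; no sample-size correction. Defined on
  frequency vectors, so it is the only estimator applicable to printed
  frequency tables; by convention it returns 0 when p̄ ∈ {0, 1}.
* `hudson` — the two-population count-based estimator
  N/D with N = (p̂₁−p̂₂)² − p̂₁(1−p̂₁)/(n₁−1) − p̂₂(1−p̂₂)/(n₂−1) and
  D = p̂₁(1−p̂₂) + p̂₂(1−p̂₁), combined across >2 populations and across
  loci as a ratio of averages (sum of N over pairs/loci divided by sum
  of D). This is the package default: it is reproducible from counts
  alone and the ratio-of-averages combination is the recommended way to
  aggregate Fst.
* `weir_cockerham` — the 1984 variance-component estimator θ̂ in its
  allele-frequency (haploid-sample) form, since the module contract
  supplies allele counts rather than genotypes; multi-locus values are
  ratios of summed components. For equal sample sizes it coincides
  numerically with the Hudson form; they differ under unequal sizes.

Negative estimates are preserved in stored results (the unbiased
estimators fluctuate below zero at low differentiation — for identical
subpopulation counts their expectation is 0 but any single evaluation is
≤ 0, of order −1/n); clamping to [0, 1] happens only in human-readable
report tables and in the Fst histogram. Differentiation filtering uses
a strict `Fst > threshold` (default 0.7) and sorts descending with SNP
id as tie-break; the distribution report uses an inclusive
`Fst ≥ threshold` (default 0.3), matching the different phrasings the
two summaries correspond to.

`P_Fst` is the add-one empirical upper-tail percentile
(1 + #{null ≥ obs})/(N + 1) — never exactly zero, monotone
non-increasing in the observed value. The null is a user-supplied
genome-wide Fst file when available, otherwise Balding–Nichols
simulation (999 loci, F = 0.15 by default) matched to the observed
sample sizes. An empirical percentile is one reasonable operationale of
a "significant differentiation" P value; callers with a real
genome-wide distribution should supply it.

## Association analyses

**Latitude model.** Each sampled population's collection geography is
summarised by the plate carrée centroid (arithmetic mean of signed
latitudes and longitudes), then the absolute latitude is taken.
Hemisphere-symmetric collection points therefore cancel — a documented
limitation of the flat centroid; no spherical geodesic centroid is
attempted. Populations on the migrated-samples exclusion list (default
CHD, CEU, ASW, ACB, GIH, STU, ITU; overridable) never enter the
regression. The model is OLS frequency = α + β·|lat| via statsmodels,
reporting slope, intercept, R², adjusted R² and the two-sided slope
t-test p-value; it requires ≥ 3 populations and a non-constant
predictor (a constant response is reported with R² = 0 rather than
NaN). Fst for the latitude analysis can be computed across sampled
populations; the report tables use the five continental
super-populations, matching their column structure.

**Paired shift test.** Differences are taken b − a (EUR − AFR in the
report layer). Zero differences are dropped before ranking (Wilcoxon's
original policy, the common software default), their count logged; if
every difference is zero the test is undefined and an error is raised
rather than a fabricated p = 1. The two-sided p-value uses the exact
signed-rank null for n ≤ 25 without ties (scipy), otherwise the normal
approximation with continuity and tie correction; the switch point is
configurable. The shift estimate is the Hodges–Lehmann pseudomedian —
the median of all Walsh averages (dᵢ+dⱼ)/2, i ≤ j — and the 95% CI
inverts the signed-rank distribution: with critical value c (largest
integer with P(W ≤ c) ≤ α/2, exact DP for n ≤ 25, normal-with-continuity
otherwise), the interval is the (c+1)-th smallest to (c+1)-th largest
Walsh average. Walsh enumeration is O(n²) memory; the implementation is
intended for n up to ~10⁴ pairs, and the synthetic shift analyses use n
in the thousands. Swapping the two vectors negates the estimate and both
interval ends and leaves p unchanged, by symmetry of the construction.

## Synthetic cohorts: what they emulate and what they do not

The generator emulates the data environment of a population resequencing
panel around polymorphic target sites: UTR FASTA, mature-microRNA FASTA,
a VCF with diploid genotypes and ancestral-allele annotations, a
sample→population→super-population panel, latitude metadata with two
collection points per population (symmetric about the true centroid, so
the centroid code path is exercised), an expression table and an
interaction table.

Frequencies follow the Balding–Nichols model: population frequency ~
Beta(p̄(1−F)/F, (1−p̄)(1−F)/F) around an ancestral frequency p̄ drawn
from Beta(0.8, 0.8) truncated to [0.05, 0.95] (so loci populate the
0.01–0.99 analysis window), with F = 0.15 by default — a value in the
range typical of human continental differentiation. Genotypes are
Hardy–Weinberg binomial draws within populations. Default cohort shape
is 10 sampled populations (two per continental group) of 30 diploids;
the estimator-recovery analyses use 5 populations × 100 diploids and
2,000 loci. Planted SNP classes: site-disrupting (reference carries the
site), site-creating (reference carries a broken site) and neutral; each
candidate is accepted only after the scanner itself, run in reverse,
confirms the intended toggle for the planted family and no effect for
any other family — so classifier tests against this ground truth are
exact, not statistical. The ancestral allele is the target allele with
probability 0.5 by default; knobs exist for unknown and mislabelled
ancestral states. Designated "latitude" SNPs replace the
Balding–Nichols draw with frequency = 0.8 − 0.01·|lat| + N(0, 0.02),
clipped to [0.02, 0.98]; an `afr_skew` option gives site-creating SNPs
the high-AFR/low-elsewhere profile of an ancestral site lost outside
Africa.

What the generator does *not* model: linkage between SNPs, demographic
history (growth, bottlenecks, migration), selection, sequencing or
genotyping error, and realistic UTR base composition. Passing tests on
these cohorts therefore demonstrate correctness of the machinery —
scanning, classification, counting, estimation — under known truth, not
performance on real 1000 Genomes-scale data, where ancestral-allele
error, linked selection and cryptic structure all add noise the
generator omits by design. Genome-scale reproduction of published
result tables from real downloads is a supported workflow (the parsers
speak the real dialects) but not part of the test surface.

## Determinism and numerical conventions

All randomness flows through `numpy.random.default_rng` seeded from a
single configuration value; the same seed yields byte-identical fixture
files and byte-identical pipeline outputs (checked in the tests). Tables
are sorted with explicit tie-breaks (descending Fst, then SNP id).
Super-population frequencies in reports are rounded to 4 decimals;
stored global frequencies to 6. Degenerate inputs fail loudly with typed
errors (empty nulls, zero allele totals, all-zero difference vectors,
constant designs) rather than returning sentinel values.

## Known limitations

* No thermodynamic or context scoring of sites, no 3′-supplementary
  pairing, no conservation scoring: site presence is purely motif-based.
* UTR-local coordinates only; no genome liftover or BED-against-genome
  intersection.
* The Weir–Cockerham form assumes allele counts (no within-population
  heterozygosity term); with genotype-level inbreeding it would differ
  from the full genotypic estimator.
* The signed-rank CI uses the normal approximation of the critical
  value above n = 25; for n in the tens of thousands the Walsh-average
  enumeration dominates memory and the test, though correct, is not
  optimised for the million-pair regime.
* No multiple-testing correction across SNPs is applied anywhere, by
  design; downstream users filtering many SNPs should add their own.
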