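# Methods

## The analysis

`cnvburden` implements a case-control analysis of rare copy-number variants
(CNVs) called from genotyping arrays, of the kind used to search for risk
loci in neuropsychiatric cohorts. The pipeline has five stages.

### 1. Consensus ("stringent") calling

Array CNV callers disagree on presence and breakpoints, so only variants
supported by at least two independent algorithms are kept. Within one
sample, two calls support the same variant iff they have the same type
(DEL/DUP), come from different algorithms, and match at reciprocal overlap

    RO(a, b) = min( |a ∩ b| / |a| , |a ∩ b| / |b| ) ≥ 0.5.

Support is the connected component of this relation; a component becomes
one stringent CNV iff it contains ≥ 2 distinct algorithms. The emitted
interval is the **intersection** of the component's members (conservative:
it cannot inflate a borderline call's gene content); when a chained
component has an empty global intersection the member with the most probes
is used. A union mode is available (`boundary="union"`). The 0.5 RO
threshold is reused for cross-algorithm matching, parental matching and
frequency matching so the pipeline has a single overlap semantics; each use
is separately configurable.

Coordinates are 0-based half-open internally; GFF3 and other 1-based
inclusive inputs are converted at the reader boundary. CNVs are strandless.

### 2. Rarity filtering

Stringent CNVs from cases and controls are pooled within strata matched on
ancestry, genotyping platform and sex. A CNV's frequency is the number of
distinct stratum subjects (the carrier included) owning at least one
same-type CNV at RO ≥ 0.5, divided by the number of stratum subjects — so
a private variant in a stratum of n subjects has frequency 1/n, and the
frequency filter can retain nothing in strata smaller than
1/max_frequency = 200 subjects. The cascade, in order:

| filter     | rule                                    | default |
|------------|-----------------------------------------|---------|
| frequency  | pooled subject frequency ≤ max          | 0.5 %   |
| stability  | fraction of CNV length inside the copy-number-stable genome map ≥ min | 75 % |
| size       | length ≥ min                            | 15 kb   |
| probes     | supporting array probes ≥ min           | 10      |

The retained set is the conjunction of the four criteria and therefore
order-free; the audit trail's "first failed filter" labels follow the order
above. Stability is interpreted as a length fraction over the union of
regions annotated stable in the supplied BED map — the only computable
reading when the map carries no internal scores. The frequency denominator
is subjects (not chromosomes), and the carrier's own call is included; both
choices are explicit because published descriptions of this filter rarely
state them.

Rare CNVs are annotated with any overlap (≥ 1 bp) against a curated list of
genomic-disorder loci, reporting both the fraction of the locus covered and
the fraction of the CNV covered; the enrichment re-run excludes CNVs whose
covered fraction is ≥ 0.5 by default rather than applying a hard rule at
annotation time.

### 3. Trio inheritance

Each rare CNV of a trio proband is matched against each parent's
**stringent** (pre-rarity) calls: a parent carries the variant iff it has a
same-type call at RO ≥ 0.5. Matching against pre-rarity parental calls
prevents a parent's frequency-filtered common variant from faking a de novo
event — the in-silico analogue of validating de novo calls in parental DNA.
Status is de_novo / maternal / paternal / biparental (the fourth kept for
completeness although transmissions from both parents are rare). The cohort
de novo rate counts probands with ≥ 1 de novo CNV over all trios, reported
as a percentage to one decimal.

### 4. Global burden

Per subject: number of rare CNVs, their total length, the *gene rate*
(distinct genes intersected, gene-body overlap by default, coding-exon mode
available), and counts per size class {15–100 kb, 100–500 kb, > 500 kb,
> 1 Mb} overall and by type. The size classes follow the conventional
reporting ranges verbatim and are therefore partly nested (> 500 kb
contains > 1 Mb); both are reported and documented as nested.

The burden test is a binomial logistic regression

    case ~ gene_rate + n_cnvs + total_length(standardized)

with significance from the 1-df deviance (likelihood-ratio) test of
dropping the gene rate; two-sided. Total length is standardized before
fitting because bp-scale coefficients are numerically fragile; the reported
covariate coefficient is on the standardized scale. The stratified table
runs the same regression per (size class × type) with the class **count**
as the predictor of interest (an any-CNV indicator mode is a configuration
away). Degenerate inputs — constant predictors, complete separation
(detected by non-finite or implausibly large coefficients), fewer than two
cases or controls — yield a flagged result carrying a diagnostic note, never
a silent number.

### 5. Gene-set enrichment

Per subject and gene set, the statistic is the number of distinct set genes
with ≥ 1 coding exon impacted by the subject's rare CNVs of a given class
(DEL, DUP, or both). The test is the deviance test of

    case ~ set_count + total_gene_count + platform

against the model without `set_count`; `total_gene_count` (the subject's
total coding-exon gene count for the same CNV class) is the global-burden
penalty that stops large CNVs from driving every set, and platform enters
as a categorical covariate. "Corrected for gene count and global burden" is
implemented as this single total-gene-count covariate; a second covariate
can be supplied through the design if needed. Descriptive odds ratios for
subjects with exactly one and with two-plus set genes hit (vs none) come
from a categorical variant of the same model. The suite runs each set ×
class × {all loci, known loci excluded}; Benjamini–Hochberg q-values are
computed within each (class, exclusion) family across sets, with untestable
sets (set count constant in the cohort) excluded from the family size m.
Significance tiers 0.15 (primary) and 0.275 (relaxed) are named in the
configuration. The deviance test is two-sided, with effect direction
reported.

BH step-up: q_i = min over ranks j ≥ rank(i) of p_(j)·m/j, capped at 1;
the raw quantity is proportional to m, so excluding untestable sets from m
makes the remaining q-values smaller, never larger.

## The synthetic-data generator

No genotype-level data accompany the analysis this package operationalizes,
so every stage is exercised on simulated cohorts with the same statistical
structure. The generator emulates:

* a genome of non-overlapping genes (default 3000 genes of 10 kb, 8 coding
  exons each, over 300 Mb on 3 chromosomes) — dense relative to the human
  genome so that desk-scale cohorts produce gene hits at workable rates;
* a copy-number-stability map covering a configurable fraction of the
  genome (default 85 %), and curated "known loci" spanning gene clusters;
* per-subject background CNVs, Poisson with mean 2.8 per subject, sizes
  log-uniform on [15 kb, 3 Mb] (reported variants in such cohorts span
  roughly 16 kb–5 Mb and no size distribution is published; log-uniform
  covers every size class without letting multi-Mb events dominate);
* polymorphic loci at fixed coordinates with population frequencies 1–4 %
  (above the 0.5 % rarity threshold, so the frequency filter must remove
  their carriers);
* a planted case enrichment: case CNV placement is accepted by rejection so
  that the odds of hitting a gene of the target set (default: an 840-gene
  set, the size of the FMRP-target compendium) are multiplied by ω exactly
  (hits accepted outright, non-hits with probability 1/ω); default ω = 1.75,
  the effect size this analysis is designed to detect;
* trios: parents are simulated first (null mechanism) and transmit each CNV
  with probability 0.5, which keeps inheritance truth well-defined and the
  proband's expected CNV count at the configured mean; each proband gains a
  de novo event with probability 0.023;
* call emission: each true CNV is reported by each of 3 algorithms with
  dropout 0.1, breakpoints jittered ±500 bp (symmetric uniform, truncated
  to keep intervals valid), probe counts derived from length and a
  platform-specific probe spacing (~1.1–1.2 kb).

Background events are resampled until mutually unique at RO ≥ 0.5 (and
non-colliding with polymorphic loci), so the generator's rarity labels are
exact and filter recall/precision can be scored against them. Every planted
fact goes into a truth ledger; `truth_compare` scores consensus recovery,
frequency-filter decisions and de novo calls against it. A fixed seed
reproduces the full output bit-for-bit.

The configured mean of 2.8 CNVs per subject is the *planted* (pre-filter)
rate; the realized rare-set mean is lower (≈ 2.1–2.4) because the stability
and probe filters remove genuinely placed events. The worked-example per-
subject means (2.81 cases / 2.92 controls) are computed from published
cohort totals, not from the simulation.

What the generator does **not** emulate: array intensity and B-allele
structure, linkage disequilibrium, locus-specific mutation hotspots,
ancestry stratification of CNV frequencies, mosaicism, and gene-length
variation. Passing tests therefore demonstrate correctness of the filtering
and testing machinery under the stated statistical model, not robustness to
platform artefacts in real intensity data.

### Count-level kernel

Calibration and power studies need hundreds of replicates, for which
genome-scale simulation is wasteful. `simulate_count_table` draws the
sufficient per-subject quantities directly from the same assumptions: total
coding gene count T ~ Poisson(4) (≈ 2.8 CNVs × ~1.4 genes), set counts
Binomial(T, f) with f the set's fraction of the gene catalog, platform by
mixture, and case status from logit P(case) = b0 + log(ω)·target_count +
0.05·(T − E T) + 0.1·platform, with quota (retrospective) sampling, which
preserves odds ratios. With ω = 1 the target coefficient is exactly zero,
giving the null for type-I-error calibration; with ω = 1.75 the fitted
per-unit odds ratio is an estimate of ω, used for parameter-recovery checks
(median over 200 replicates within 15 % of ω at 250 cases / 1750 controls).

## Numerical choices and degenerate inputs

* Logistic fits use statsmodels GLM (binomial family, IRLS, maxiter 200);
  deviance differences a hair below zero from convergence noise are clamped
  to zero (p = 1).
* Separation is flagged when any coefficient of interest exceeds 15 in
  absolute value or is non-finite.
* A zero-length region set gives covered fraction 0.0, not an error.
* Consensus output is canonicalized by sorting calls before component
  construction, so results are independent of input order; all output
  tables are sorted, making same-seed runs byte-identical.
* Frequency strata below 200 subjects retain nothing (a private variant
  already exceeds 0.5 %); this is a property of the definition, not a bug,
  and the pool sizes are reported so it is visible.

## Problem sizes

Unit tests run cohorts of 300–1100 subjects on a 120 Mb / 600-gene genome;
filter- and de novo-recovery checks run 2000–1350 subjects at the full
cohort shape (250/1750 and 174 trios); calibration uses 500 null and 60
power replicates of 2000 subjects at the count level. These sizes were
chosen so the full suite completes in about a minute while every check
retains the power it needs.

## Known limitations

* The cross-algorithm consensus rule (RO ≥ 0.5, intersection boundaries)
  is one defensible choice among several used in practice; both knobs are
  exposed.
* Enrichment p-values are asymptotic chi-square; with very sparse set
  counts the deviance statistic is conservative rather than exact, which is
  why untestable and separated sets are flagged instead of reported.
* The biparental status is kept although its real-data frequency is tiny.
* Mosaic events are not modelled as a class; a free-text annotation can be
  carried alongside.
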