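# Methods

## Study design being modelled

The pipeline implements a dual-caller case-control CNV association
design.  Per-sample deletion/duplication calls arrive from two
algorithms: caller A, a PennCNV-style six-state HMM over B-allele
frequency (BAF) and log R ratio (LRR), and caller B, a Birdsuite-style
call set in which common copy-number polymorphisms are genotyped
(Canary, confidence-scored) and rare CNVs are found by an HMM (Birdseye,
LOD-scored).  The two call sets are QC-filtered and analyzed
independently; only loci where both callers independently pass
multiple-testing correction are reported as consensus findings.  The
calling algorithms themselves are out of scope — their outputs are this
package's inputs.

## Coordinates and conventions

All in-memory intervals are 1-based and inclusive at both ends
(`length = end − start + 1`); BED input is converted at the import
boundary.  Chromosome labels are bare autosome numbers; sex-chromosome
records are dropped on import.  Report spans print `end − start` as the
length column, matching the convention of the published tables this
layout mirrors (both lengths are exposed on the call object).  The
genome build is carried as metadata only; no liftover is performed.

## Quality control

Pre-calling sample filters: > 5 % missing genotypes; discordant reported
vs computed sex; for duplicate pairs, the lower-call-rate member.
Post-calling sample filters for caller A: LRR-SD above the cohort Tukey
fence Q3 + 1.5·IQR; BAF median outside [0.45, 0.55]; BAF drift > 0.005;
|waviness| > 0.04; per-sample call count above its cohort fence.  For
caller B: call count above its cohort fence (or an explicit threshold).
Quartiles use linear interpolation (R type 7); the realized fences are
data-dependent, so thresholds such as "> 92 calls/sample" are outputs of
the rule, never constants.  Fences are computed on the full cohort
jointly; computing them per status would couple the filter to the
outcome.

Call filters: ≥ 20 supporting markers for every call; Birdseye calls
additionally need LOD ≥ 10 and Canary calls confidence < 0.1.  Adjacent
same-type calls in one sample are re-merged when the gap is **strictly**
less than 20 % of the joint span including the gap (ties do not merge;
overlapping calls always merge).  The pass repeats to a fixed point, so
merging is idempotent; the merged call's copy number keeps the
carrier-consistent extreme (minimum for deletions, maximum for
duplications) and marker counts are summed.  Merging is confined to one
(sample, chromosome, type, caller) group.  Segmental-duplication overlap
is flag-only by default; an exclusion mode drops calls with more than
50 % of their own length (one-way fraction) inside the segdup set.

## Segment-based scan

Each marker covered by at least one filtered call of a given type is
tested for case enrichment with the one-sided Fisher exact test;
duplications and deletions are tested separately, per caller.  The
Bonferroni denominator m for a (type, caller) stratum is the number of
covered markers in that stratum — reproducing the property that the
duplication and deletion test counts differ between callers.  A marker is
significant when p ≤ α/m (α = 0.05 by default).  Maximal runs of markers
that are adjacent **in the marker map** (base-pair gaps are irrelevant;
the scan is marker-indexed) form regions; region boundaries are the
first/last marker positions and region carriers are the union of
per-marker carrier sets (a sample counts once if any covered marker is
covered by one of its calls — carrying ≥ 1 marker, not the full region).
Consensus regions keep same-type overlapping regions significant in both
callers and span the union of the per-caller spans; headline counts come
from caller A with caller-B statistics retained alongside.  Cross-caller
concordance for a region is |carriers_A ∩ carriers_B| / |carriers_A|.

Consensus regions are additionally fit with a logistic regression of
case status on carrier state adjusting for age, sex and the top three
principal components (statsmodels maximum likelihood; Wald p reported;
perfect separation is reported as an explicit error state rather than a
divergent estimate, detected via the fitter's separation error or a
carrier coefficient beyond ±15).

## Association statistics

`fisher_one_sided` computes P(X ≥ a) under the central hypergeometric
with the table's margins using exact big-integer binomial sums, rounded
once to float — so it agrees with exhaustive enumeration identically.

`odds_ratio_cmle` maximizes the Fisher noncentral hypergeometric
log-likelihood over log ψ by golden-section search (bracket seeded at the
continuity-corrected sample log-OR; xtol 1e-11 in log ψ).  The estimate
is +∞ / 0 when the observed count sits at the top/bottom of the support,
and conventionally 1 for single-point supports.  This conditional MLE is
the odds ratio printed by standard Fisher-test implementations; it is
systematically slightly nearer 1 than the cross-product ratio, which is
exposed separately for comparison.  `odds_ratio_conditional_ci` inverts
the noncentral tail probabilities by bisection on log ψ (the exact
conditional interval).

## Gene-based analysis

A sample is a carrier for (gene, type) when ≥ 1 bp of one of its calls
of that type intersects the gene ± 20 kb window (clamped at position 1).
Deletions and duplications are tested separately with the same Fisher /
cMLE machinery.  The Bonferroni denominator is the number of gene loci
overlapped by calls from **both** callers — recomputed from the data,
since it is a realized count.  Duplicate gene symbols at distinct loci
are distinct rows (identity is (symbol, locus)).  A gene is "supported by
both callers" when its row is Bonferroni-significant in each caller's own
analysis.  A candidate-gene screen reports carrier counts for a named
gene list (e.g. the three HHT genes ACVRL1, ENG, SMAD4), with zero-carrier
genes reported explicitly.

## Rare-CNV burden

Rare filtering restricts to caller-A calls with length > 100 kb, then
jointly applies three exclusions whose criteria are each computed on a
fixed basis so their order is immaterial: (1) samples above the cohort
Tukey fence on total per-sample call count or total kb span (computed on
the full input call set — per-sample totals, not the large-call subset,
whose mostly-zero counts would make the fence degenerate); (2) calls at
loci carried by > 1 % of all samples, where loci are single-linkage
clusters of calls with ≥ 50 % reciprocal overlap (the clustering rule is
exposed in config since external tools do not document theirs); (3)
calls with ≥ 50 % of their length inside a known-common-CNV catalogue.

Burden is either the per-individual call count or the number of distinct
genes whose padded windows the individual's calls hit.  The one-sided
test statistic is mean(cases) − mean(controls); labels are permuted with
a seeded generator and the empirical p is (1 + #{perm ≥ obs})/(n_perm+1),
switching to exhaustive enumeration of all label assignments when
C(n, n_cases) ≤ n_perm (no add-one correction there — the observed
assignment is a member of the enumeration).  Strata: overall, and type ×
size bins (100–200 kb, 200–500 kb, 500–1000 kb, > 1 Mb], plus optional
candidate-pathway restrictions (calls intersecting the set's padded gene
windows).  The alternative is fixed to case excess.

## ΔΔC_T copy-number calling

Per sample, ΔC_T = mean(C_T target) − mean(C_T reference) over
replicates; ΔΔC_T is taken against a diploid calibrator sample's ΔC_T or
against the cohort-mean ΔC_T (both reference modes used in validation
practice); CN = 2·2^(−ΔΔC_T), integer call by nearest rounding.  A
calibrator of true copy number n_cal ≠ 2 biases every estimate by the
factor 2/n_cal (tested analytically).  Array-vs-qPCR concordance is the
fraction of shared samples with identical state.

## Synthetic-data generator

`simulate.SimConfig` defaults encode the study conditions the package
targets: 270 cases / 457 controls (post-QC cohort sizes); case age
~N(38.7, 17.6) vs control ~N(50, 14); ~54 %/50 % female; 26 % of cases
saliva-derived DNA; background call lengths log-normal with a 35 kb
median; one planted duplication CNVR with carrier frequencies 0.237
(cases) / 0.057 (controls) — the profile of a strongly enriched common
duplication; cross-caller concordance 0.4, matching the 36–65 % range
such call sets show in practice.  The genome is scaled down to 4
chromosomes × 2,000 markers at 1 kb spacing so a full cohort generates in
well under a second and 100-seed recovery experiments run in minutes;
the background rate (3 calls/sample) is likewise scaled to the genome
rather than genome-wide realism.

Caller A reports every true call.  Caller B reproduces each background
call with probability `caller_B_sensitivity` and Gaussian boundary
jitter (sd 2 kb).  For planted regions, B's carrier indicator is drawn
with P(B | A) = `caller_B_sensitivity` while preserving the configured
marginal frequency — emulating two callers that each detect an
association at full power but agree on only a fraction of individual
carriers, which is what dual-caller studies actually observe (each
caller's own carrier frequency is similar while per-sample concordance
is low).  Modelling B as a thinned subsample of A instead would make
any consensus criterion at realistic multiplicity essentially
unattainable at 40 % concordance, which contradicts the observed
behaviour of such designs.  Background calls are redrawn away from
planted spans so the realized carrier frequency at a planted region
converges to the configured one.

QC metrics are drawn inside their passing ranges except for a configured
fraction of samples, each given exactly one planted violation.  A single
seed drives named substreams (samples, QC, background, planted, caller B,
genes, qPCR), so adding a component never perturbs another's draws;
identical configs give bit-identical cohorts.

What the generator does **not** emulate: LRR/BAF signal-level noise,
batch and plate effects, DNA-source (blood vs saliva) call-count biases,
linkage between markers, realistic gene density, or segmental-duplication
artifacts.  Passing recovery tests therefore demonstrate the correctness
of the statistical machinery under the generator's idealized carrier
model, not the callers' behaviour on real intensity data.

## Numerical choices and degenerate inputs

* Fisher p-values: exact rationals, no asymptotics, valid for any margins.
* cMLE: golden section, xtol 1e-11 on log ψ (agrees with a dense-grid +
  golden brute-force maximizer to better than 1e-6 relative).
* Conditional CI: bisection on log ψ over [−60, 60].
* Logistic model: statsmodels Newton MLE, max 100 iterations.
* Mann-Whitney size comparison: exact for small untied samples, normal
  approximation with tie correction otherwise (scipy `method='auto'`);
  groups with fewer than two calls yield an undefined p with a note.
* Merge rule, segdup exclusion, known-common overlap: boundary
  conventions are strict (<) for the merge fraction and segdup fraction,
  inclusive (≥) for the known-common 50 % rule, following the wording of
  the respective rules.
* Permutation p never falls below 1/(n_perm+1); ties count toward the
  tail (a ≥ comparison with 1e-12 slack against float drift).
* Empty cohorts, missing calibrators, unknown covariates, out-of-genome
  planted regions and degenerate tables raise `ValidationError` rather
  than returning numbers.

## Problem sizes used in the test suite

The acceptance-style experiments run at deliberately scaled-down sizes
chosen once: the Fisher oracle sweep covers every table with N ≤ 30; the
cMLE oracle comparison uses 1,000 random tables with margins up to 200;
merge properties use 10,000 random call sets; burden calibration uses
2,000 replicates of 60 samples with 999 permutations each; planted-CNVR
recovery uses 100 seeds at full cohort size (270/457) on the scaled
genome.  Together the suite completes in well under a minute per
component on one CPU.

## Known limitations

* Carrier counting over regions uses ≥ 1-marker coverage; studies that
  require full-region coverage will count fewer carriers.
* The both-caller Bonferroni denominator counts (symbol, locus) rows;
  published analyses are sometimes ambiguous between symbols and loci.
* The rare-CNV locus clustering (single-linkage, 50 % reciprocal
  overlap) approximates external tools' undocumented overlap grammars.
* The waviness factor is consumed as a given per-sample metric; its
  defining formula is array-platform-specific and not recomputed here.
* No plotting: the manual LRR/BAF inspection step of array studies has
  no automated counterpart in this package.
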