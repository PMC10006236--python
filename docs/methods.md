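# Methods

This note documents the statistical model behind each stage, the defaults
and why, what the synthetic-data generator does and does not emulate, and
the numerical choices that were genuinely open.

## Gene selection

Each gene carries two oriented comparisons: Set A (healthy smokers vs
healthy non-smokers) and Set B (smokers with lung cancer vs healthy
smokers). A comparison is called *up* or *down* when the oriented fold
change (larger group mean over smaller, always ≥ 1, with direction carried
separately) is at least 1.5 **and** p < 0.05; otherwise *no_change*. Fold
change is stored as a max/min ratio with an explicit direction flag to
avoid sign ambiguity for down-regulation. Categories: (up, down) → (a);
(down, up) → (b), which is excluded for DNA-repair genes because a higher
repair capacity is not a plausible susceptibility signature; (no_change,
down) → (c); everything else, including any *inconclusive* status, is
excluded. "Inconclusive" is operationalized as missing data or conflicting
directions across cell types — the source screens report it without
defining it — and an optional pre-aggregation step (`consensus_status`)
reduces per-cell-type calls to one status by majority direction, requiring
more than two concordant cell types. Thresholds (1.5, 0.05) are exposed as
parameters.

## DHS–expression correlation

For a DHS with per-sample DNase signal `s` and the target gene's
expression vector `e` (same samples), the statistic is Pearson r after
masking samples below a minimum signal/expression floor. The floors are
not published; the default is the 10th percentile of each vector,
configurable, chosen to drop near-zero measurements without discarding
informative samples. Significance uses a permutation null: a seeded sample
(without replacement, up to 10 000) of DHS signal vectors from *other*
chromosomes is correlated against the same expression vector on the same
masked samples, and

    p_perm = (1 + #{null: |r_null| ≥ |r|}) / (1 + m).

The add-one (Phipson–Smyth) form keeps p strictly positive; the null is
two-sided because both positively and negatively correlated DHSs are
retained. Per gene, significant DHSs within ±100 kb of the TSS (distance
measured from the interval midpoint — the anchor is otherwise undefined)
are ranked by |r|, ties at the k-th rank broken by genomic coordinate for
determinism, and at most k = 10 are kept. Variant assignment uses BED
half-open semantics: a 1-based position p lies in [start, end) iff
start ≤ p−1 < end; multi-overlaps duplicate the variant record.

## Regulatory cascade

Filters run in a fixed order, with survivor sets asserted nested and
counts non-increasing on every run:

1. membership in a selected DHS;
2. a regulatory-evidence flag (rSNP-style curation);
3. regulatory score class at least as strong as class 4, under the total
   order 1a < 1b < … < 1f < 2a < 2b < 2c < 3a < 3b < 4 < 5 < 6;
4. a lung cis-eQTL with p < 0.05 and an unambiguous risk allele;
5. presence in a lung-tissue DHS.

**Risk-allele inference.** The risk allele is the allele pushing
expression toward the direction the gene shows in the cancer group: the
eQTL effect allele when sign(beta) matches that direction (positive with
*up*, negative with *down*), else the opposite allele. Significant entries
that disagree, or a zero beta, make the variant ambiguous and it is
dropped. eQTL betas are stored against a named effect allele since
database orientation conventions vary.

**TF-binding impacts.** Allele-specific impacts are recorded, not
filtered on, because binding predictions describe mechanism for the
surviving variants rather than gating the statistical evidence; a
configuration flag makes the stage eliminative if desired. A variant's
score for one motif is the best log2-odds (PWM vs background) over all
motif placements containing the variant, with each allele substituted.
The impact p-value is the exact probability that a random motif-length
sequence under the background model scores at least the observed best
score, computed by dynamic-programming convolution over the score
distribution discretized at 0.01 log-odds units — exact for short motifs
with bounded memory; scoring uses the same integer grid, so the DP equals
brute-force enumeration. Zero-probability PWM cells score −∞ and their
sequences never reach a finite threshold. Scanning is forward-strand; for
strand-ambiguous motifs callers can score the reverse complement
explicitly. Direction is *gain* when the alternate allele scores higher
and its match has p < 0.001, *loss* symmetrically, else *none*.

**Chromatin domains.** The 25-state chromatin vocabulary collapses
deterministically: labels containing Enhancer/H3K27ac → enhancer, then
TSS/Promoter → promoter, remaining states → repressed_or_insulator.
Unknown labels are errors rather than silently binned.

**Derived sets.** Variants with pooled (population-averaged) minor-allele
frequency strictly above 0.01 form the polymorphic subset; the genotyping
shortlist additionally requires promoter chromatin and a lung eQTL
p < 0.01. Cancer-cohort eQTL confirmation applies Benjamini–Hochberg FDR
at q < 0.05.

## Enrichment and LD

Annotation enrichment compares a study set against a seeded uniform sample
(without replacement) from the pooled TSS ± 100 kb variant universe.
Fisher's exact p is two-sided under the common "sum of outcomes no more
probable than observed" convention; the odds-ratio estimator is the
transparent sample cross-product (a·d)/(b·c) — not the conditional MLE —
with the Haldane–Anscombe +0.5 correction only when a cell is zero, and a
Woolf log-normal 95% CI. LD expansion collects partners at r² ≥ 0.8
(inclusive), every variant partnering itself; transitive evidence flags a
variant whose LD block intersects an association catalog, with enrichment
tested against the LD partners of a random universe whose size is a
parameter. A helper computes r² from phased haplotypes only for the
generator's internal consistency; real LD tables are inputs.

## Risk scores

The unweighted genetic risk score is literally the sum of risk-allele
copies across the panel — an integer in [0, 2·|loci|] with population mean
2·Σfᵢ. Missing genotypes fail loudly by default; optional imputation
substitutes the expected dosage 2f for a named population. Published
population-level scores on other scales are not reconstructible from this
definition and are not reproduced. Weighted scores are out of scope.

## Case–control statistics

Hardy–Weinberg uses the Pearson χ² against expected counts from the MLE
allele frequency, df = 1, with 0/0 cells contributing nothing (so
monomorphic markers give χ² = 0). Allelic association uses the Pearson χ²
without continuity correction (Yates optional) and the cross-product OR
with Woolf CI. Genetic models are maximum-likelihood logistic regressions
on risk-allele dosage (additive 0/1/2), carrier status (dominant), or
homozygous-risk status (recessive), OR = exp(coef) with Wald CI/p;
recessive fits require at least one homozygous-risk subject per status
group and otherwise report the model as unavailable. Adjusted models enter
age and pack-years linearly and expand categorical covariates to
indicators; the default adjustment list is age, sex, pack-years, alcohol,
tobacco chewing, betel quid, wood smoke, coal smoke, asbestos, pesticide.
Missing genotypes are handled complete-case per marker. Subgroup analysis
splits at a covariate cutpoint (pack-years at 47 by convention here,
configurable) and tests effect modification by the Wald p of the
genotype×stratum product term in the pooled model. Genotype-combination
analysis cross-classifies two markers and compares each cell to a
reference cell by 2×2 cross-product, flagging cells under a minimum count.
Pack-years = (units smoked per day / 20) × years smoked.

Confidence-interval conventions are Woolf (2×2) and Wald (models); point
estimates, not intervals, are the reproducibility surface, since interval
methods vary across software.

## Survival

Kaplan–Meier product-limit estimation with the median defined as the
earliest time the curve reaches 0.5 (undefined, reported "NR", when the
curve plateaus above it). Two-group log-rank with df 1. Cox proportional
hazards via partial likelihood with **Efron** tie handling (the default of
the standard survival software this field uses), HR = exp(coef) with Wald
CI/p; monotone likelihoods (no events in a genotype group) are reported as
non-estimable rather than fitted. Genotypes collapse dominantly (reference
homozygote vs carrier). Time is months from the start of chemotherapy.
Regimen stratification subsets by a predicate over the ordered regimen
sequence (first line, or an exact first/second/third-line prefix); subsets
that cannot support a fit return an insufficient-sample report instead of
raising, mirroring blank cells in small-regimen tables. Responders are
complete/partial responses; non-responders stable/poor/progressive.

## Synthetic data

One master seed drives independent named substreams
(`default_rng([seed, stream_id])`), so equal configurations reproduce
byte-identical tables and no two stages share a stream. Defaults mirror
the study design the package targets: 101 cases / 401 controls, 20
samples per expression group, 10 DHSs per gene within ±100 kb, planted
fold change 2 (above the 1.5 threshold), planted DNase–expression
correlation 0.9, eQTL slope −0.4, per-allele odds ratio 2.5, hazard ratio
2.0 with 30% censoring, 22 pass-all variants among 300 with a 3-variant
promoter shortlist.

Expression noise is log-normal (normal on log2 scale, sd 0.5), the
standard multiplicative intensity model. Covariates: age truncated normal
on [30, 90] centered in the sixties, heavily male sex (a smoking cohort),
pack-years from simulated consumption through the formula above, Bernoulli
environmental exposures, categorical regimen sequences of up to three
lines and response labels. Case status follows a logistic model on the
first marker's dosage at ~15% baseline prevalence, sampled to quota from a
large Hardy–Weinberg population, which preserves the odds ratio. Survival
times are exponential with a dominant carrier effect; censoring is
exponential with per-subject hazard λ·ρ/(1−ρ) so the expected censored
fraction is exactly ρ.

Null variants are assigned deterministic failure stages (outside any DHS;
flag false; score class 5/6; eQTL p = 0.5 or conflicting entries) cycling
over the non-planted variants, so cascade stage counts have exact expected
values — noise enters only through continuous measurements, never through
which filter a variant fails.

The bundled genotype-count fixture expands published genotype-by-status
counts into 101 case and 401 control records whose per-marker
cross-tabulations match the counts exactly. Control genotype sums below
401 (399 and 397 for two markers) are represented as per-marker missing
genotypes — per-marker genotyping failure is the only reading consistent
with complete-case totals. The fixture assigns marker genotypes
independently within status (the joint distribution across markers is not
published), so single-marker statistics are exact while two-marker
cross-classifications are illustrative only.

What the generator does **not** emulate: raw sequencing reads, realistic
genome-wide variant density, LD structure from recombination maps,
batch/platform effects in expression, or informative censoring. Passing
tests therefore demonstrate correctness of the estimators and bookkeeping
under the stated generative model, not robustness to those real-data
complications.

## Known limitations

* The additive-model logistic MLE for one fixture marker is 1.6966; a
  published table shows 1.69, consistent with truncation rather than
  rounding at two decimals. Point estimates elsewhere agree at printed
  precision.
* PWM scanning is single-strand; palindromic or reverse-strand motifs
  need explicit reverse-complement scoring.
* The permutation null reuses the query's sample mask for null vectors;
  alternative masking conventions would change p values slightly for
  heavily masked samples.
* Exact Fisher enumeration and the DP impact p-value are exact only on the
  discretized grids documented above (integer counts; 0.01 log-odds).
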