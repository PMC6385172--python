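# Methods

This note documents the statistical procedures `purityconn` implements,
the generative model behind its synthetic cohorts, the numerical choices
that matter, and what the simulation results do and do not establish.

## Tumour signatures

Each tumour sample is contrasted with the pooled normal-tissue reference.
Genes are first filtered on expression: a gene is kept when its mean CPM
over the normal pool is at least 0.5 (the pool is the common reference of
every per-sample contrast, so it is also the filter population; equality
keeps the gene). On the kept genes the per-sample statistic is a z-test on
x = log2(CPM + 1):

    z = (x − μ) / (s · sqrt(1 + 1/n_normal)),

where μ and s are the normal-pool mean and SD of x, s is floored at 0.1 to
avoid zero-variance artefacts at low counts, and the sqrt term accounts
for predicting a single new observation. Two-sided normal p-values are
corrected with Benjamini–Hochberg; genes enter the signature at FDR
strictly below 1% (up if z > 0, down if z < 0). A single-sample z-test
against a reference pool was chosen over a count-model GLM because the
contrast is one sample versus a pool — there is no within-group replication
on the tumour side for a dispersion estimate — and because it is
transparent, deterministic and directly testable; the test suite verifies
the BH step against an independent step-up implementation and the
detection behaviour on spiked genes.

## Drug signatures

For one drug, expression profiles across concentrations, cell lines,
exposure durations and batches are fitted per gene by ordinary least
squares with concentration as a linear term and the other three factors
dummy-coded. The signature value is the t-statistic of the concentration
slope (a t rather than the raw slope so genes remain comparable across
noise levels), and the drug's ranking is all universe genes in descending
t, ties broken lexicographically by gene id for determinism. Nuisance
factors observed at a single level are dropped; a rank-deficient design is
an error that names the aliased term.

## Connectivity scores

The score of a signature against a drug ranking of N genes uses the
classic unweighted bidirectional running-sum statistic. For a gene set
with ascending ranks V(1..n),

    a = max_j ( j/n − V(j)/N ),    b = max_j ( V(j)/N − (j−1)/n ),
    ES = a if a ≥ b else −b.

The connectivity score is (ES_up − ES_down)/2, which lies in [−1, 1];
when ES_up and ES_down are both nonzero with the same sign the drug moves
both halves of the signature the same way — neither mimicry nor reversal —
and the score is defined as exactly 0. An empty up or down set contributes
ES = 0. Scores are undefined when fewer than 10 signature genes intersect
the drug universe. The unweighted (exponent-0) statistic was chosen over a
weighted variant because the zero rule's behaviour, including the
prevalence of exact zeros among observed scores, depends only on ranks.

Two numerical facts worth knowing: the statistic is antisymmetric under
ranking reversal only up to the 1/N rank grid, and the winning side (a vs
b) can flip when the two deviations tie within 2/N — the property tests
account for both. Significance uses a permutation null: random disjoint
up/down sets of the observed sizes, p = (1 + #{|s*| ≥ |s|})/(B + 1), so p
is never zero. Under this null, one-sided signatures give exactly uniform
p; two-sided signatures are super-uniform because concordant random draws
are zeroed (an atom of p = 1), so the negative-and-significant rate at
α = 0.05 calibrates to α/2 ≈ 0.025, which the suite checks.

A "statistically significant negative" score is defined as score < 0 with
permutation p < 0.05; the negative-enrichment rate of a drug is the
fraction of defined scores meeting that criterion.

## Purity analyses

Per drug, scores are associated with estimated tumour purity by Spearman
rank correlation (tie-corrected t-approximation for n ≥ 10, exact
enumeration of rank permutations below, so toy examples reproduce to full
precision), by the p-value of the linear regression slope, and by a
rank-sum test between samples above and at-or-below 80% purity (the
boundary goes to the low group). Signature genes are classified per
(gene, direction): a significant (P < 0.05) Spearman correlation of
expression with purity in the direction of the gene's dysregulation marks
it *more* differentially expressed with purity, the opposite sign *less*,
and non-significance *insensitive*; filtering removes the *less* class.
Tertile comparisons bin samples at purity 60 and 72 (low < 60 ≤ mid ≤ 72 <
high) and rank-sum test adjacent tertiles. Rate differences between
groups use the Pearson chi-square on the raw 2×2 counts without
continuity correction. Rank-sum tests throughout use the tie-corrected
normal approximation without continuity correction; fully tied inputs
return p = 1.

## HIF stratification

A sample is *more likely* HIF-activated when both reference HIF
inhibitors give strictly negative scores, *less likely* otherwise (zeros
count as otherwise). The mean of the two reference scores serves as the
continuous HIF-activation proxy for the covariate models. Stratified
analyses simply rerun the purity associations and rate comparisons within
each stratum.

## Covariate models

The univariate screen picks its test by variable arity — rank-sum for two
groups, Kruskal–Wallis for more, Spearman for continuous — and applies
Bonferroni over the screened variables. The multivariable models are
linear mixed models: covariates as fixed effects, each batch variable
(batch id, plate id, ship date, tissue source site) an independent
random-intercept variance component; with no random terms the fit reduces
to OLS. Fixed-effect p-values use the t distribution at n − k residual
degrees of freedom; multi-level categorical terms are tested jointly with
an F-type test (per-level dropping would fragment categories). The mixed
fits agree with lme4's REML estimates to numerical precision (checked in
the suite via Rscript). Missingness follows the cohort's convention: VHL
status and mRNA subtype keep "missing" as a category; stage, arm calls
and the p53 count are complete-case. Estimated purity is never allowed as
a predictor of itself. R² for mixed models is computed on the
fixed-effects fitted values (marginal), since only a single R² is
reported per model.

Backward elimination drops the term with the largest joint P ≥ 0.05 and
refits until all remaining terms are significant (intercept-only if none
survive). Stability selection repeats the elimination on row-resamples
with replacement and keeps variables retained at least 50% of the time;
resamples that lose a categorical level are skipped and counted.
Bootstrap coefficient p-values are 2·min(frac(b* ≤ 0), frac(b* ≥ 0)) over
refits on resamples, floored at 1/B and displayed as "<1/B" when the
resampled sign never crosses zero. Repeated k-fold cross-validation
reports pooled out-of-fold R² per repeat next to the in-sample R²; a
category level unseen in a training fold keeps a zero coefficient
(minimum-norm least squares). The bootstrap and elimination loops refit
the fixed-effects model; the variance components are estimated on the
full fit. Default problem sizes follow the procedure definitions
(B = 1,000 for stability, B = 10,000 for p-values); cross-validation
defaults to 100 repeats in the packaged analyses, a problem size chosen
so a full run completes in seconds while the repeat-to-repeat spread of
out-of-fold R² is already far smaller than the effects of interest.

Note one calibration fact: a pure-noise covariate survives backward
elimination exactly when its p-value falls below α, so the expected drop
rate is 1 − α = 95% — a correctly implemented procedure will fluctuate
around, not above, that rate.

## The synthetic cohort

The generator produces the study conditions every simulation test runs
under. Cohort defaults mirror the real setting where known: 538 tumours
against 72 normals; arm-level alteration frequencies 87.3% (3p loss),
58.7% (5q gain), 41.1% (14q loss); purity centred at 72% with SD 10 and a
floor of 30%; batch variables with 15/18/15/20 levels. The reduced
`desk_config` (1,200 genes, 300 tumours, 40 normals, same module geometry
and effect sizes) is used for worked examples and the simulation studies;
mechanisms are rank-based and scale-stable, and the full-size default
reproduces the same patterns.

Generative model, per tumour: 3p loss ~ Bernoulli(0.873); if 3p is
intact, a VHL hit with probability 0.4; HIF activation = 3p loss OR VHL
hit. Activation is *graded*: activated samples draw a strength
s ~ U(0.4, 1) that scales both the HIF expression shift and the purity
deficit — purity = clip(72 − 15·s + N(0, 10), 30, 100), giving activated
tumours a mean deficit of about 10 points. The graded form matches the
"probability of HIF activation" framing: with a binary all-or-nothing
effect the reference-inhibitor labels become either uninformative or
deterministic, neither of which the observed 58% concordance supports,
and the activated-versus-not purity gap implied by the real cohort (a
17-point median gap for the discordant high-purity samples; an m3-subtype
coefficient of −12.5) is far larger than the 3p coefficient alone
suggests.

Genes carry module labels (hif, stromal, p53, null) and within-module
signs. The HIF module has induced and repressed halves — the pathway both
up- and down-regulates targets — and the stroma expresses the same
vascular programme at 1.4 log2 units (tumour cells at 2.0·s), so part of
the apparent HIF signal in an impure sample genuinely comes from
non-cancerous cells. The stromal module likewise has a stroma-enriched
half and a stroma-absent epithelial half, so admixture moves both tails
of the bulk profile; this signed structure is what makes reversal scores
well-defined rather than zeroed at random by the same-sign rule whenever
a shared gene core happens to land in one tail of a drug ranking. Each
p53-pathway alteration (count ~ Poisson(2.5) truncated at 15) shifts 15
additional p53-module genes in the tumour profile, inflating the
signature and diluting the HIF genes in the ranking comparison. Bulk mean
expression is the purity-weighted linear-scale mixture of the tumour-cell
and stromal profiles; normals are stroma-free baseline tissue; counts are
negative-binomial (dispersion 0.1) at library sizes of 0.8–1.2 million.

The screen programs two HIF-reversing reference drugs, one
stroma-reversing drug and nulls: a reversal drug's per-gene concentration
slope is −1·(module sign) on its target module and zero elsewhere, plus
per-cell-line gene intercepts, duration and batch offsets, and Gaussian
noise (SD 0.3). Batches are assigned randomly per profile so omitting the
batch term biases slopes by a realized-design-dependent amount the tests
can verify in closed form.

What the generator does **not** emulate: gene–gene correlation beyond the
module shifts, realistic library-size/dispersion heterogeneity,
methylation arrays or copy-number segmentation, cell-line-specific drug
response, or the histological heterogeneity behind the discordant
methylation clusters. Passing simulation tests therefore demonstrate that
the *procedures* recover the mechanisms they were designed for at
realistic effect sizes — not that those mechanisms have the same effect
sizes in any real cohort.

## The packaged discordant-sample table

The 24-record table of ccRCC samples with papillary/chromophobe-like
methylomes ships with the package (SHA-256 checked on load). Its three
statistics — 15 records above 80% purity, 15 of 21 called records without
3p loss, and the 12 vs 12 re-evaluation comparison in which the
ccRCC-like group has the lower median reference-inhibitor score — are
recomputed, never stored. The rank-sum p-value for the re-evaluation
comparison uses mid-ranks with tie-corrected normal approximation; the
table contains many exact-zero scores, so the tie policy materially
affects the p-value and is fixed and documented here. Transcription note:
in the source table the purity and score columns visually abut for
zero-score rows; the parse (e.g. purity 83.9, score 0.0) is the only one
consistent with the in-text counts.

## Pipeline and reproducibility

The pipeline runs simulate → signatures → connectivity → purity →
stratify → models → discordant, each stage reading and writing serialized
artifacts only, with a manifest of thresholds and per-stage seeds. One
global seed is expanded into per-stage substreams keyed by stage name, so
stage randomness is independent of execution order; reruns with the same
configuration are bit-identical. Analysis constants sit in `RunConfig`:
CPM filter 0.5, signature FDR 1%, minimum 10 genes per score, α = 0.05,
purity split at 80%, tertile cutpoints (60, 72), two reference HIF drugs.

## Known limitations

* The per-sample z-test ignores count overdispersion beyond the SD floor;
  it is calibrated on the generator's negative-binomial noise but will be
  anticonservative on data with gene-wise dispersion far above the pool
  estimate.
* The permutation null treats genes as exchangeable within the drug
  ranking; correlated gene modules make it liberal for signatures
  concentrated in one module.
* Backward elimination and bootstrap loops refit fixed effects only;
  variance components are not re-estimated per resample.
* The purity-sensitivity classification is marginal per gene and does not
  model the joint tumour/stroma composition.
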