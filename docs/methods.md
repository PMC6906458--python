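# Methods notes

## Scope and data model

`cnascape` links segment-level somatic copy-number alterations (CNAs) to
continuous tumor phenotypes (gene-expression signature scores, or any
per-sample continuous/binary trait) in two ways: a per-gene dual-statistic
association landscape, and an elastic-net prediction protocol over
segment-mean CNA features. All inputs are plain-text formats: SEG
(tab-separated, 1-based inclusive coordinates), BED-like 4/5-column gene
tables, GMT signature archives, genes × samples TSV matrices, MAF mutation
tables, and sample-indexed clinical TSVs. Coordinates are converted to
0-based half-open internally and back on write, so every reader/writer pair
is a lossless round trip; chromosome labels are stored without a `chr`
prefix; missing values are written as `NA`. Strand is read but ignored by
all overlap computations, since copy number is strand-agnostic.

## Expression normalization

The count pipeline is order-fixed and flag-enforced: upper-quartile scaling
(each sample rescaled so the 75th percentile of its positive values equals
`scale`, default 1000 — the transform is invariant to that constant), then
log2(x+1), then a filter keeping genes expressed in **strictly more than**
70% of samples ("expressed" means value > 0 for counts, non-missing for
array-like data), then per-gene median centering, then per-sample
standardization to mean 0 / sd 1. The scale constant and +1 pseudocount are
conventional choices; both are configurable. Attempting a stage out of order
raises.

## Gene- and segment-level CNA

Gene scores come from CBS-style segmentation by the *extreme* method: a gene
fully inside one segment takes that segment's value; a gene overlapping
several segments takes the overlapped value of **maximum magnitude** (the
GISTIC2 convention — the strongest gain or the deepest loss); a gene with no
overlapping segment is missing. Any shared base counts as overlap. A tie
between equal-magnitude gain and loss resolves to the gain and is logged.
Segment features are arithmetic means of non-missing member-gene values over
predefined segment memberships; a segment whose members are all missing is
missing. Panel restriction (e.g. to a clinical sequencing panel's genes)
intersects the gene matrix before segment aggregation.

## Association landscape

For one signature, per gene: (i) Spearman rank correlation between the
signature score and the gene's CNA score, two-sided p from the t
approximation t = ρ√((n−2)/(1−ρ²)) — adequate at the cohort sizes this is
designed for (hundreds to ~10³ samples); genes with fewer than 10 paired
non-missing samples or a constant CNA vector are skipped; (ii) one-sided
Fisher exact tests for over-representation of gain (score > +0.3) or loss
(score < −0.3) among the top score quartile vs all others, computed exactly
as hypergeometric upper tails; samples missing that gene's CNA are excluded
from its 2×2 table, and degenerate margins give p = 1. The ±0.3 thresholds
are the conventional shallow-event cutoffs on a log2-ratio-like scale and
are configurable; they can equally be applied to discretized calls since
the threshold operates on whatever score the matrix carries.

BH adjustment is applied separately per statistic family (correlation, gain,
loss), each across all genes for that signature. Joint calls at q < 0.01 on
both arms, with the correlation sign fixing direction: `positive_gain`
(candidate driver) or `negative_loss` (candidate repressor). By construction
the called set is a subset of each marginally significant set.

The subtype-adjusted variant replaces the rank correlation with ordinary
least squares of score on CNA plus subtype indicator covariates (fixed
effects, fitted by Frisch–Waugh–Lovell projection; subtypes with fewer than
3 samples are dropped from the covariates). The CNA coefficient's sign and
two-sided t-test replace ρ and its p; the Fisher arm and joint-call logic
are unchanged, so an association that is purely subtype composition loses
its correlation arm and drops out.

## Elastic-net protocol

Objective (glmnet parameterization): (1/n)·loss + λ·[α‖β‖₁ + (1−α)/2‖β‖₂²],
logistic loss for binary phenotypes, squared error for continuous ones.
Features are standardized internally for penalty comparability across
segments; coefficients are reported on the original scale. Solvers are
scikit-learn's saga (logistic) and coordinate-descent `ElasticNet`
(gaussian); CV path scans run warm-started at a loose tolerance (1e-4),
final fits at 1e-7 with a convergence check.

Protocol defaults: stratified 70/30 split (per cross-classified stratum,
`round(0.7·n)` samples to train; continuous strata such as overall survival
are median-binned; strata smaller than 2 are pooled); α grid 0.1–1.0 by 0.1;
per α, 100 log-spaced λ from λ_max = max_j |x_jᵀ(y−ȳ)|/(n·α) down to
10⁻³·λ_max; 200 Monte-Carlo CV rounds, each a y-stratified 75/25 sub-split
of the training set scored by accuracy at probability cutoff 0.5 (MSE for
the gaussian variant); exact metric ties resolve to the largest λ, then the
largest α (the sparsest candidate). Rounds whose sub-training set is
single-class are redrawn and logged. Evaluation is trapezoidal ROC AUC with
features aligned by name; "highly predictable" means AUC > 0.75 on every
designated test set. The permutation null permutes labels over samples and
repeats the entire split/tune/fit/evaluate pipeline per permutation.
Selected segment coefficients re-map to member genes; a gene in several
selected segments carries their sum (the only order-independent merge),
with a warning. Subtype-restricted and multi-cohort pooled training are pure
configuration: filter or concatenate the inputs and stratify on tumor type.

One master seed drives each estimator; derived per-stage seeds are recorded
in the model report together with the grid actually explored (alphas,
n_lambda, n_rounds, cv_train_frac), so protocol fidelity is auditable from
the report alone.

## Survival

Ten-year disease-specific survival: deaths from other causes are censored at
their time; any follow-up beyond 120 months is truncated to 120 and
censored; disease deaths within 120 months are events. Risk groups use the
tertile rule (top third vs bottom two-thirds) on observed scores or model
probabilities; Kaplan–Meier estimation and the k-group log-rank test come
from lifelines (χ² with k−1 df; the two-group case is the primary design),
with per-group events/total reported.

## Synthetic cohorts

The generator emulates the statistical skeleton the method assumes, not a
real genome: `n_chromosomes` of contiguous genes (10 kb pitch, 5 kb bodies)
partitioned into `n_segments` blocks that never span a chromosome. Per
sample and segment, a gain occurs with probability 0.3 (value +0.5·U[1,2]),
a loss with probability 0.3 (−0.5·U[1,2]), else 0 — magnitudes straddle the
±0.3 call thresholds so both called and sub-threshold events occur. Gene
CNA adds N(0, 0.05) jitter to the segment value; when jitter is nonzero the
SEG file is emitted at per-gene resolution (probe-level CBS), so the
file route reproduces the in-memory matrix exactly. The latent phenotype is
P = Σ_k w_k·S̄_k + ε with ε ~ N(0, 0.25), S̄_k the sample's mean CNA over
segment k; the reference design point is one driver segment with w = 1.
Signature genes (30, drawn outside driver segments) have expression
x_g = P + N(0, 1); background genes are N(0, 1). Survival is exponential
with baseline hazard ln2/120 per month (≈54% 10-year disease-specific event
rate) doubled (configurable log-HR) in the top-P third, plus an independent
other-cause hazard of 0.002/month and administrative censoring at 240
months. Mutations are per-gene Bernoulli records (10% emitted as `Silent`
to exercise variant-class filtering), optionally rate-coupled to P.
Everything is deterministic in the config seed, including emitted bytes.

The confounded scenario (`confounded_config`) sets three subtypes, driver
weight 0, and lets one subtype raise both the driver's gain probability
(+0.5, with loss probability 0.2 so probabilities stay ≤1) and the
signature mean (+1.0). The shift was chosen so the planted confound is
unambiguous — the unadjusted landscape must call the driver genes while the
adjusted one must not; a weaker shift left the correlation arm borderline
rather than confounded, which tests nothing.

What passing on these cohorts does **not** show: robustness to realistic
allele frequencies, ploidy/purity, platform batch effects, correlated
background expression, or non-proportional hazards — none of which the
generator emulates. The reference design point (n = 600, 2000 genes, 40
segments, master seed 20191211) and the reduced tuning grid used by the
end-to-end evaluations (3 α × 20 λ, 50 CV rounds) are the package's chosen
evaluation sizes; the protocol itself defaults to the full 10 × 100 × 200
configuration.

## Numerical and design choices

- "Over 70%" expression filtering and ">5%" mutation frequency are strict
  inequalities (literal readings); mutation filtering always drops `IGH*`
  and `HLA*` symbols and admits a keep-list that bypasses the frequency rule.
- Dichotomization: #high = ⌈n/3⌉ (tertile) or ⌈n/4⌉ (quartile); boundary
  ties break by ascending sample id after score, making labels deterministic
  and invariant to strictly monotone score transforms.
- BH q-values are computed by the step-up formula directly and cross-checked
  against statsmodels in the test suite; Fisher p-values are exact
  hypergeometric tails, cross-checked against explicit enumeration.
- Degenerate inputs raise early with the offending sample/gene named:
  all-zero samples (UQ normalization), zero-variance samples
  (standardization), constant outcomes (λ grid), single-class evaluation
  sets, cohorts under 20 samples (splitting), under 6 samples or constant
  scores (dichotomization), non-positive survival times.
- Model evaluation amortization in the replicate survival analysis:
  hyperparameters are tuned once on the first replicate and re-fit per
  replicate — tuning selects (α, λ) for a design, not a dataset.
- Known limitations: the logistic solver's `saga` path is the runtime
  bottleneck for large grids; the association landscape tests genes one by
  one (no recurrence-peak calling); the subtype adjustment uses fixed, not
  random, intercepts; Cox modeling and competing-risks estimators are out of
  scope (the 10-year processing censors rather than models competing risks).
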