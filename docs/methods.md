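# Methods

This note documents the statistical procedures implemented in `assistnet`,
the assumptions behind them, and the design choices made where the
methodology left room for judgement. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Instrument model

The WHO-ASSIST 3.0 screens ten substance categories (tobacco, alcohol,
cannabis, cocaine, amphetamine-type stimulants (ATS), inhalants, sedatives,
hallucinogens, opioids, other). Per substance, Q2 records frequency of use
in the past 3 months on five ordinal levels and Q3–Q7 record five harm
domains (urge to use; health/social/legal/financial problems; failure to
meet normal expectations; concern expressed by close others; failed
attempts to cut down). The substance-specific involvement score is the sum
of the published item weights (Q2: 0/2/3/4/6; Q3: 0/3/4/5/6; Q4: 0/4/5/6/7;
Q5: 0/5/6/7/8; Q6/Q7: 0/3/6, where 3 is "yes, but not in the past 3
months"). Q5 is not administered for tobacco, so the attainable maxima are
39 (most substances) and 31 (tobacco). The weight table ships as an
editable YAML config rather than hard-coded constants, with per-substance
overrides, so instrument revisions do not require code changes.

Decisions:

* **Missing items.** A substance's score is missing whenever any of its
  contributing items is missing; no partial sums. This is conservative and
  keeps per-variable missing counts interpretable.
* **Dichotomisation.** "Use" is any Q2 answer other than "never". Harm
  flags are past-3-month events: any non-"never" level for Q3–Q5 (those
  items ask about the past 3 months directly), and only the "yes, in the
  past 3 months" level for Q6/Q7. Harm reports without corresponding use
  are legal (the instrument allows lifetime-pattern answers) but surfaced
  in a QC column rather than silently erased.
* **Grouping.** The four-group classification is a strict precedence rule:
  any ATS use → `ats`; else cannabis use → `cannabis_no_ats`; else any
  other substance → `alcohol_tobacco_other`; else `none`. A group is
  missing when a higher-precedence flag is missing and nothing positive
  overrides it. By construction cannabis use is universal in the cannabis
  group and ATS use is absent outside the ATS group; the groups partition
  participants with resolvable data.
* ASSIST Q8 (injection) and the low/moderate/high risk cut-offs are out of
  scope; they feed no quantity this package reports.

## Zero-order network

Association between two binary indicators is the tetrachoric correlation:
the ρ of a standard bivariate normal, thresholded at the margins'
quantiles, that best explains the observed 2×2 table. The estimator is the
standard two-step one — thresholds fixed from the margins, then a bounded
1-D maximisation of the multinomial likelihood over ρ, with orthant
probabilities from the bivariate normal CDF. When any cell is zero, 0.5 is
added to every cell (continuity correction) so thresholds stay finite. The
test suite checks the estimator against an independent grid-search oracle
whose orthant probabilities come from 1-D quadrature, to |Δ| < 10⁻³, and
checks consistency on simulated latent-normal data.

Edges are displayed when the two-sided Fisher exact test (point-probability
rule, as in `scipy.stats.fisher_exact`) gives p below 0.05 (configurable).
Pairwise-complete observations are used per pair, maximising information;
constant columns are dropped with a warning. The default node set is use
plus four harm indicators per substance (urge, problems, failed
expectations, concerns); the failed-cut-down flag can be included with a
switch.

The layout is non-metric (ordinal) MDS on dissimilarities
d = √(2(1−r_t)) ∈ [0, 2]: SMACOF iterative majorisation with
monotone-regression disparities from a classical-scaling start. The
procedure is deterministic; raw stress never increases across iterations
(a property test verifies this) and the reported value is Kruskal
stress-1. With ~50 indicator nodes, stress around 0.2–0.3 is expected —
the configuration is a 2-D summary, not an exact embedding.

## Gaussian graphical model

Nodes are the ten log-transformed involvement scores ln(score+1); the +1
offset handles the zero scores of non-users. Complete cases only — the
dominant missingness pattern (see generator below) is participants skipping
the whole ASSIST section, so complete-case loss is small and the likelihood
stays simple. The sample correlation matrix (ML denominator n) feeds two
stages:

1. **Glasso path.** 100 penalties log-spaced from λ_max (the largest
   absolute off-diagonal, giving the empty graph) down to λ_max/100. Each
   distinct nonzero pattern along the path is refit without penalty and
   scored by the extended BIC, EBIC(γ) = −2ℓ + (p+|E|)·ln n + 4γ|E|·ln p,
   with γ = 0.5 for path selection (sparsity-favouring default).
2. **Stepwise search.** From the EBIC-best path graph, all single-edge
   additions and removals are evaluated — each refit exactly by
   zero-constrained maximum likelihood — and the best strictly-improving
   move under EBIC(γ = 0, i.e. plain BIC) is accepted until none exists.
   Ties within 10⁻⁹ prefer removals, then lexicographic edge order, for
   determinism.

The zero-constrained MLE uses iterative proportional scaling over edge
cliques: each 2×2 block update forces the fitted covariance to match S on
that clique, converging to the unique maximum of the constrained
likelihood; at convergence the fitted covariance equals S on the diagonal
and on every retained edge, and the precision is exactly zero elsewhere.
The glasso solver itself is `sklearn.covariance.graphical_lasso` run to
near machine precision behind this module's interface; its KKT conditions
are re-verified after every solve (residual < 10⁻⁶), and the test suite
compares the penalised objective against a generic convex-optimizer oracle.
Path solves use a looser tolerance since they only propose candidate
graphs, each refit exactly afterwards.

Edge weights of the final model are partial correlations
r_p(i,j) = −ω_ij/√(ω_ii ω_jj), exactly zero off the selected graph. The
final network is always an unregularised refit — reported weights carry no
lasso shrinkage.

## Centrality

On the selected partial-correlation network: strength Σ_j |w_ij| (local,
unsigned), expected influence Σ_j w_ij (local, signed; equal to strength on
all-positive networks), and the global indices on geodesics with edge
length 1/|w_ij| — closeness 1/Σ_j d(i,j) and betweenness with fractional
splitting over tied shortest paths. Absent edges carry infinite length; on
a disconnected network closeness sums over reachable nodes only and the
profile is flagged. Rankings are descending with lexicographic tie-breaks,
and a summary names nodes top-ranked on at least three of the four
indices. z-standardised columns (mean 0, sd 1 with the n−1 denominator
across nodes) accompany the raw values. Betweenness is validated against
an exhaustive path-enumeration oracle on small graphs.

## Descriptive comparisons and regression

Categorical variables are compared across groups by the chi-square test of
independence without continuity correction; ordinal/continuous variables by
the Kruskal–Wallis test with tie correction (equivalent to the tie-corrected
rank-sum test for two groups). Expected cell counts below 1 trigger a
warning recommending Fisher's exact test. Missing rows are excluded
per variable. No multiple-testing adjustment is applied anywhere — the
workflow is exploratory and adjustment would inflate type-II error.

Group membership (reference: no recent substance use) is modelled by
multinomial logistic regression, fit by Newton's method. Age enters in
years untransformed; the six clinical scale totals (PHQ-9, GAD-7, RRS-10,
PSQI, CAS, PQ-16) are z-scored so their RRRs are per-SD. Rows whose group
cannot be resolved are dropped before imputation: the group is the analysis
stratum, not something to impute. Diverging coefficients (>15 on the
standardised scale) or a singular Newton Hessian raise an error naming the
offending terms — the symptom of separation.

Missing covariates are handled by chained-equation multiple imputation:
predictive mean matching (Bayesian linear regression, k = 5 donors) for
continuous variables, logistic draws for binaries, polytomous draws for
categoricals, each with posterior/asymptotic parameter perturbation so that
between-imputation variance is honest. Defaults are m = 20 imputations and
10 cycles per chain (both configurable; the validation suites use smaller
values to keep runtimes reasonable). The complete outcome participates as
a predictor in every imputation model, per standard MICE practice. Fits
are pooled by Rubin's rules — pooled point = mean; total variance
T = Ū + (1+1/m)B — with Barnard–Rubin degrees of freedom for intervals and
p-values, and effects reported as RRR = exp(pooled coefficient). With no
missing data the pooled fit coincides with the single complete-data fit.

## Synthetic cohort generator

The generator exists so that every stage of the pipeline can be exercised
and validated end-to-end: the motivating cohort's raw records are not
publicly available, so the generator emulates their statistical structure.

* **Copula core.** Each participant draws a 10-dimensional latent normal
  with correlation R. Per-substance ordered cut-points turn the latent
  value into the Q2 level; the outermost cut-point is set by the target
  use prevalence (population values: tobacco 33%, alcohol 63%, cannabis
  27%, ATS 7.6%, cocaine 3.3%, sedatives 11%, hallucinogens 5%, opioids
  3.6%, inhalants 2%, other 4%), and the inner cut-points by a per-substance
  frequency mix among users (heavier daily shares for tobacco and cannabis).
  By construction the population tetrachoric correlation of any pair of use
  indicators equals the configured latent correlation, which the test suite
  verifies by simulation.
* **Harm items.** Conditional on the Q2 level, each harm item is endorsed
  with a configured probability increasing in use level (e.g. urge: 0.35 →
  0.90 from occasional to daily use); endorsed frequency-type items draw a
  severity level whose distribution also shifts with use level, and Q6/Q7
  draw a "prior to 3 months" answer at 0.4× the past-3-month probability.
  Non-users answer "never" throughout.
* **Covariates and groups.** Demographics (age 12–25, centred near median
  18; 65% female; 30% LGBTIQA+; metro/regional; education/employment;
  primary diagnosis) and six clinical scale totals (truncated normals
  within instrument bounds) are drawn first. Group membership then follows
  a multinomial logit whose log-RRRs are configurable — the `paper_like`
  preset uses the reference cohort's published effect sizes — and whose
  intercepts are solved (Newton) so the cohort-mean group probabilities
  equal the copula-implied ones. Each participant's substance pattern is
  then drawn from the copula *conditional on their group* by pool-based
  rejection. With matched intercepts this mixture reproduces the
  unconditional copula exactly, so covariate effects coexist with the
  calibrated dependence structure; the known limitation is that substance
  patterns *within* a group do not depend on covariates.
* **Missingness.** The generic operation is cell-level MCAR at a
  configured rate (≤ 0.2). The preset instead emulates the dominant
  real-world pattern: ~3.6% of participants skip the entire ASSIST section
  (matching a per-variable missing count near 40/1107), plus 3% cell-level
  MCAR on demographic and clinical covariates — "around 5%" missingness
  overall, while keeping complete-case loss for the score network small.
  MCAR keeps the validity of the MI machinery provable.
* **Calibration.** Involvement scores are zero-inflated discretised sums,
  so their correlations are attenuated relative to the latent scale —
  strongly for rare substances. The preset therefore targets the
  *score-scale* partial-correlation matrix (headline edges
  tobacco–cannabis 0.48 > ATS–hallucinogens 0.30 > tobacco–alcohol 0.28 >
  ATS–cocaine 0.26 > sedatives–opioids 0.21, secondary ATS edges of
  0.13–0.18 so that ATS is the strongest hub, and a weak 0.03 positive
  background everywhere else) and finds the latent R by a damped
  Monte-Carlo fixed point: simulate scores, measure their partial
  correlations, shift the latent partials by the residual, shrinking back
  whenever the implied precision loses positive definiteness.
  `scripts/calibrate_preset.py` runs this at n = 400 000 per iteration and
  freezes the result (achieved score-scale partials within ~0.02 of
  target) into the package data. The stepwise estimator conditions on a
  pruned neighbourhood, which nudges recovered strong edges slightly above
  the full-model value (about +0.02 for the tobacco–cannabis edge at
  n ≈ 1100) — a property of the selection procedure, not of the generator.
* **What passing tests do not show.** The generator emulates marginal
  prevalences, a latent-copula dependence structure, covariate effects on
  group membership and MCAR missingness. Real cohorts additionally feature
  informative missingness, within-group covariate–pattern dependence,
  measurement error correlated across instruments, and site effects; tests
  passing on synthetic data demonstrate the estimators' correctness under
  the stated model, not robustness to those violations.

## Pipeline

Stages run in a fixed order (instrument → descriptives → zero-order network
→ GGM → centrality → grouping → regression) behind one configuration.
Every stage derives its seed from the root seed and the stage's fixed
index, so toggling stages never perturbs the others — disabling the GGM
leaves all remaining outputs bit-identical. Each written file carries a
hash of the content-determining configuration plus the seed; identical
configurations reproduce byte-identical bundles. Stage failures are
recorded in an error manifest and dependent stages are skipped, keeping the
partial bundle. Centrality is defined on the partial-correlation network
and is therefore skipped when the GGM stage is disabled.

## Problem sizes in the validation suites

The acceptance-style suites use the scales at which the methods are meant
to operate while keeping a laptop-friendly runtime: 20 synthetic cohorts of
n = 1107 for network recovery and the centrality headline; 50 random tables
plus n = 10 000 consistency draws for the tetrachoric oracle; 50
simulations of n = 2000 for 6-node structure recovery; and 20 cohorts of
n = 5000 with 5% MCAR, m = 3 imputations and 3 chain cycles for the
regional-effect (RRR = 3) recovery check. The full MI default (m = 20,
10 cycles) is exercised at small n in unit tests.

## Known limitations

* Tetrachoric estimation assumes an underlying bivariate normal; severe
  zero cells are handled by a blunt 0.5 continuity correction.
* The GGM treats log scores as Gaussian; they are bounded, discrete and
  zero-inflated. The calibration makes the *synthetic* truth live on the
  score scale, but on real data the Gaussian working model remains an
  approximation (as it does in the workflow this package implements).
* Stepwise search is greedy: it guarantees EBIC no worse than its path
  start, not a global optimum.
* MICE's categorical models fall back to marginal draws if a within-cycle
  fit fails (rare; logged), which weakens that variable's imputation model
  rather than aborting the chain.
* Closeness on disconnected networks is a within-component convention, not
  comparable across components of different sizes.
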