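# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions a careful user should know.

## Indicator coding and aggregation

Each of the five restrictive-context indicators is coded 1/0 per
ever-married woman from questionnaire-style raw responses: child marriage
(first cohabitation before age 18), no decision-making power (sole or
joint participation in *none* of four household decisions), wife-beating
justifiable (*any* of five reasons endorsed), physical violence in the
past 12 months (*any* listed act at frequency "often" or "sometimes"),
and less-than-secondary education. The violence item is asked only of the
domestic-violence (DV) subsample — a design feature, not missingness — and
is missing by construction outside it; any other missing raw response is
an error, never imputed.

Community prevalences are weighted means: survey weights for four
indicators, DV weights (survey weight divided by the subsample fraction)
for the violence item over DV-flagged rows. Whether the original
workflow weighted this aggregation is not documented; weighted is the
default here because the sampling design is non-proportional, and an
unweighted mode is retained for oracle tests. "Community" is an opaque
grouping key (in the motivating design, the 47 urban/rural governorate
strata of a national family health survey).

## Reliability

Cronbach's alpha is the raw covariance-based form, `K/(K-1) * (1 -
trace(S)/sum(S))` with n−1 denominators, reported in the classic
item-analysis layout (sign, item-test and item-rest correlations, average
interitem covariance among the remaining items, alpha-if-deleted). Items
whose deletion would raise alpha are flagged but never dropped: the
violence item typically behaves this way yet carries distinct substantive
information, so retention is a deliberate default. With K = 2 the
alpha-if-deleted column is undefined and reported as NaN.

## Factor index (GCCI)

One-factor principal-factor extraction: the prevalence columns are
standardized (community-level, n−1 SDs), the correlation matrix gets its
diagonal replaced by squared multiple correlations (SMC), and the leading
eigenpair of this reduced matrix gives loadings `sqrt(lambda_1) * v_1`,
signed so their sum is positive (higher score = more restrictive).
Uniqueness is `1 - loading^2` by definition. Orthogonal rotation of a
single factor is the identity, so no rotation step exists.

Two conventions matter:

* **Proportion of variance** is `lambda_1 / (sum of positive eigenvalues
  of the reduced matrix)` — the principal-factor convention, which can be
  near 1 even when the factor explains far less of the *total* (raw)
  item variance. Comparisons against a divide-by-K figure will disagree;
  this is the documented, intended denominator.
* **Scoring** is regression (Thomson): coefficients `R^{-1} @ loadings`,
  scores `Z @ coefficients`. Scores have exactly mean 0 on the fitting
  data and variance at most 1; they are *not* rescaled to unit variance.

The default solution is non-iterated (SMC communalities, one
eigen-decomposition) — the common statistical-package default for this
workflow. `fit_one_factor(..., iterate=True)` refines communalities to
convergence; the iterated solution removes the small downward bias of SMC
communalities on strongly loading items (about 0.06 on a true loading of
0.9 in our recovery tests) and is what the loading-recovery test uses.
A loading below 0.3 in magnitude triggers a warning, never an automatic
drop.

## Categorization (GCCS)

1-D k-means is solved *exactly* by dynamic programming over interval
split points (optimal clusters of sorted scalars are contiguous
intervals). This replaces seeded Lloyd iteration and removes seed and tie
ambiguity: ties in score are broken by stable input order. The
Calinski–Harabasz pseudo-F `(B/(k-1))/(W/(n-k))` selects k over a default
range 3–5; `W = 0` (duplicate-point clusters) is reported as +infinity
with a warning, and CH ties prefer the smaller k. For k = 4 the ordinal
labels use the field vocabulary (least/less restrictive, restrictive,
most restrictive); other k get "level i of k". Labels ascend with
cluster mean score.

A practical caution from our own simulations: with *small* well-separated
groups (≈12 points each) CH frequently prefers k one above the truth in
1-D, because optimally splitting a Gaussian cluster removes ~64% of its
within-SS. Group sizes ≳40 make selection stable. The selected k should
be read as a descriptive choice, not an inferential estimate.

## Concentration index

Individuals are ranked by their community's ordinal category with
midpoint fractional ranks (cumulative population share below + half own
share, weights = survey weights), ordered least → most restrictive so
rank runs 0 → 1 with restrictiveness. The Wagstaff index is
`(2/mu) * Cov_w(y, R)` with the weighted covariance normalized by total
weight; the binary correction divides by `(1 - mu)`. Under this direction
a risk concentrated in restrictive communities gives a **positive** index
(reversing the order exactly negates it; a flag exposes the choice).
`mu` at 0 or 1 is an error — the index is undefined for degenerate
outcomes. The grouped and individual-level computations agree to
1e-12, and the index is invariant to uniform weight rescaling.

## Multilevel model

The random-intercept logistic likelihood is maximized with **adaptive
Gauss–Hermite quadrature** (default 12 nodes): per cluster, Newton's
method locates the mode of the log-concave integrand and the quadrature
grid is recentred and rescaled by the curvature there. At `sigma2_u = 0`
the rule is exact, and the marginal log-likelihood equals the ordinary
logistic log-likelihood to machine precision — a built-in correctness
anchor. The optimizer works on `(beta, log sigma2_u)` with L-BFGS-B
(log-variance bounded at e^-20 ≈ 0 so the boundary is reachable);
standard errors come from the numerically differentiated observed
information, with the SE of `sigma2_u` by the delta method. Agreement
with lme4's `glmer` (nAGQ = 25) on shared data is ~1e-3 in all
parameters in our cross-check test.

The likelihood is **unweighted**: the survey weights serve descriptive
representation, and the variance-decomposition arithmetic this package
reproduces is consistent with unweighted components. A weighted
pseudo-likelihood is out of scope.

Variance decomposition uses the latent-variable convention with level-1
variance fixed at `pi^2/3 ≈ 3.29`: `ICC = sigma2_u/(sigma2_u + pi^2/3)`,
and `PCV = (sigma2_ref - sigma2_model)/sigma2_ref * 100` with the
*preceding* ladder model as reference. The ladder is: Model 1 null;
Model 2 + individual attributes (age grand-mean-centered; education
dummies, ref less-than-secondary; wealth-quintile dummies, ref poorest;
early marriage; child death); Model 3 + GCCS dummies (ref: most
restrictive category). The LR test compares Models 2 and 3 on the usual
chi-square with df = number of added dummies; identical models give
statistic 0 and p = 1.

One identification caveat: with singleton clusters `sigma2_u` sits on a
likelihood ridge (inflating the variance while rescaling `beta` leaves
the implied marginal probabilities almost unchanged), so its point value
is meaningless there even though the fit itself is sound; the test suite
asserts marginal-probability equivalence with ordinary logistic
regression rather than a particular `sigma2_u`.

## Synthetic-data generator

The generator is a first-class module encoding the study conditions under
which everything is tested: 47 communities of 435 ever-married women
(≈20,400 total), a 50% DV subsample with inversely inflated DV weights,
five community-clustered binary indicators, and a multiparity outcome
with a community random intercept.

The data-generating model is a **single shared latent factor** on the
logit scale: community j draws `eta_j ~ N(0,1)`; indicator k is
`Bernoulli(expit(a_k + b_k * eta_j))`. Defaults `a = (-1.579, -1.361,
-1.780, -2.138, -0.738)` and `b = (1.0, 0.6, 0.8, 0.35, 1.2)` were
calibrated once by numerical integration so the five community-prevalence
means land near (0.21, 0.22, 0.17, 0.11, 0.36), with the violence
indicator loading weakest — mirroring its weak item statistics. The
outcome adds independent covariates (age uniform 15–49 with log-OR 0.131
per year; education and wealth effects around log 0.84…0.41; early
marriage log 2.81; child death log 4.99), a context effect `0.46 * eta_j`
and an independent residual community intercept with SD 0.46, so the
total latent level-2 variance is `0.46^2 + 0.46^2 ≈ 0.42` and the share
explainable by the context factor is exactly 50% — a known truth used by
the PCV-recovery test. The early-marriage covariate equals the
child-marriage indicator, so it is correlated with `eta_j` by
construction; all other covariates are independent of context.

What the generator does **not** emulate: indicator-specific community
variance is off by default (the `indicator_noise_sd` option turns it on),
so the five prevalences are nearly deterministic in `eta_j` and the
default survey yields a much higher alpha (~0.93) and common-variance
share (~99%) than real multi-cause survey data; household rosters,
nonresponse, informative weighting and spatial structure are absent.
Passing tests therefore certify the *estimators* (coding, aggregation,
factor arithmetic, clustering optimality, index and likelihood
computations), not the realism of any substantive value computed from the
synthetic survey.

Raw questionnaire columns (cohabitation age, decision participation,
beating-justification reasons, three violence-act frequencies, education
level) are generated consistently with the drawn indicator values, so the
coding rules are exercised end to end; re-coding the raw columns
reproduces the generated flags exactly.

## Problem sizes and numerical defaults

The default test suite runs the full pipeline at the 47 × 435 design
(~70 s total), the mixed-model recovery at J = 100, n_j = 100 over 20
replicates, and the LR-test size study at J = 30, n_j = 10 over 500
replicates with 7 quadrature nodes — sizes chosen so each check has
enough Monte-Carlo resolution for its stated tolerance. Quadrature:
12 nodes default (7 vs 15 differ by < 1e-3 log-likelihood in tests);
optimizer tolerance 1e-8 on the objective; within-SS prefix-sum
arithmetic in the DP is exact to ~1e-10, which is the tolerance used for
the ANOVA identity `B + W = TSS`.

## Known limitations

* No multi-factor retention (the method is fixed at one factor), no
  tetrachoric/ordinal alpha, no Erreygers correction or CI decomposition,
  no random slopes or survey-weighted variance estimation.
* CH-based k selection inherits the small-group instability noted above.
* The concentration index here uses grouped individual-level ranks over
  the ordinal categories; analyses ranking communities as units would
  differ slightly.
* Index values are comparable only within one indicator set and
  population; the construction travels across surveys, the numbers do
  not.
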