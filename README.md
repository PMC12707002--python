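# gcci — a community-level gendered cultural context index

`gcci` builds a **community-level index of gendered cultural
restrictiveness** from individual-level survey microdata (DHS-style family
health surveys of ever-married women), and quantifies how that context
stratifies binary reproductive-health risks and explains community-level
variance in clustered outcomes.

It is written for epidemiologists and demographers who have survey
microdata with a community/stratum identifier and want to move beyond
individual-level gender attributes to a measured *context*: the package
takes care of indicator coding, weighted aggregation, index construction,
ordinal categorization, inequality measurement and multilevel variance
decomposition, with a synthetic-data generator so the whole pipeline is
testable without restricted microdata.

## The method

Five binary indicators of a restrictive context are coded per woman
(married before 18; participates in none of four household decisions;
endorses wife-beating for any of five reasons; physical violence by the
husband in the past 12 months, asked of the domestic-violence subsample;
highest education below secondary) and aggregated to weighted prevalences
per community $j$, giving a $J \times 5$ matrix.

1. **Reliability** — Cronbach's $\alpha = \frac{K}{K-1}\left(1 -
   \frac{\sum_k \sigma^2_k}{\sigma^2_{\text{total}}}\right)$ with the full
   item-analysis table (item-test/item-rest correlations, average
   interitem covariance, alpha-if-deleted).
2. **Index (GCCI)** — one-factor principal-factor extraction on the
   prevalence correlation matrix $R$ (diagonal replaced by squared
   multiple correlations), loadings $\ell = \sqrt{\lambda_1}\,v_1$,
   uniqueness $1-\ell_k^2$, and regression (Thomson) scores with
   coefficients $R^{-1}\ell$; scores have mean 0 and variance $\le 1$.
3. **Categories (GCCS)** — globally optimal 1-D $k$-means by dynamic
   programming; $k$ selected by the Calinski–Harabasz pseudo-F
   $CH(k) = \frac{B_k/(k-1)}{W_k/(n-k)}$; clusters labeled least → most
   restrictive by ascending mean score.
4. **Inequality** — Wagstaff concentration index
   $CI = \frac{2}{\mu}\,\mathrm{Cov}_w(y_i, R_i)$ over fractional ranks
   $R_i$ of the ordered categories, with the binary-outcome correction
   $CI/(1-\mu)$.
5. **Variance decomposition** — random-intercept logistic regression
   (adaptive Gauss–Hermite quadrature), latent-scale
   $ICC = \sigma^2_u/(\sigma^2_u + \pi^2/3)$, proportional change in
   level-2 variance (PCV) across the null / individual-attributes /
   +GCCS model ladder, and the likelihood-ratio test for the GCCS block.

## Worked example

```python
from gcci import (SyntheticConfig, generate_survey, community_prevalence,
                  cronbach_alpha, fit_one_factor, score_communities,
                  select_k, risk_gradient_table, model_ladder)

df = generate_survey(SyntheticConfig())        # 47 communities, ~20k women
cp = community_prevalence(df)                  # weighted 47 x 5 prevalences
print(cronbach_alpha(cp.prevalence).alpha)     # 0.935
model = fit_one_factor(cp)
scores = score_communities(model, cp)          # GCCI: mean 0, SD 0.997
gccs = select_k(scores.score, scores.community_id)   # CH selects k = 5 here
table, ci = risk_gradient_table(df, gccs, ["multiparity"])
print(table.round(2))
ladder = model_ladder(df, gccs)
print(ladder.summary_frame().round(3))
```

On the default synthetic survey this prints a multiparity gradient rising
from 7.0% (least restrictive category) to 22.0% (most restrictive) with a
corrected concentration index of **0.22** — the risk is concentrated in
restrictive communities — and a model ladder whose level-2 variance falls
from 0.386 (null, ICC 10.5%) to 0.259 after adding the GCCS (ICC 7.3%,
PCV 22.6%, LR $\chi^2_4$ = 11.3, p = 0.024).

The `examples/` directory holds one narrative script per capability, and
the same workflow is scriptable from a shell:

```bash
gcci simulate --seed 1 --out survey.csv
gcci all --input-csv survey.csv --out results/
```

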