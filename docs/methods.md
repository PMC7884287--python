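# Methods

## The model

The package evaluates demand-reduction tobacco-control policies through an
ecological country-year panel. The outcome is age-standardized current
smoking prevalence $y_{c,t}$ (proportion in $(0,1)$) for country $c$ in year
$t$, modelled per (sex, age-group) stratum on the logit scale:

$$
\operatorname{logit}(y_{c,t}) = \beta_0 + \beta_p P_{c,t-1}
 + \beta_w W_{c,t-1} + \beta_e E_{c,t-1} + \beta_r R_{c,t-1}
 + \alpha_c + \delta_c R_{c,t-1} + \varepsilon_{c,t}
$$

where $P, W, E \in \{2,\dots,5\}$ are WHO achievement scores for smoke-free,
health-warning and advertising-ban legislation (entered as numeric linear
covariates because the quantities of interest are per-unit-increment
effects), and $R$ is the relative income price (RIP),

$$ R = 100 \cdot \frac{182.5 \times \text{price}}{\text{GDP per capita}}, $$

the percentage of per-capita GDP needed to buy half a 20-pack per day for a
year (182.5 packs). Prices and GDP are both in international dollars, so $R$
is comparable across countries and years. $\alpha_c$ is a country random
intercept, $\delta_c$ a country random slope on RIP
($(\alpha_c,\delta_c)\sim N(0,\Psi)$ with an unstructured $2\times2$
covariance by default; a diagonal $\Psi$ is available via
`re_structure="independent"`), and $\varepsilon_{c,t}$ is i.i.d. residual
noise. Covariates enter with a one-year lag: prevalence in year $t$ is
matched to the policy wave of year $t-1$.

A score of 1 means "no known or no recent data" and is treated as missing,
not as a policy level; country-years with any missing covariate are dropped
listwise (year-level exclusion — a country missing one wave still
contributes its other waves). The logit transform clamps its argument into
$[\epsilon, 1-\epsilon]$ with $\epsilon = 10^{-6}$ so that synthetic extreme
values cannot produce infinities; observed prevalences are interior and
unaffected.

## Estimation

`PolicyMixedModel.fit()` estimates the model through statsmodels' `MixedLM`.
The default criterion is REML, which gives unbiased variance components and,
in our replicate studies, better-calibrated Wald intervals; plain ML is
available (`method="ml"`) and is required by the likelihood-ratio test
comparing the mixed model against the fixed-effects-only linear model
(`lrt_random_effects`; the $\chi^2$ reference with one df per extra
covariance parameter is conservative because the null pins variances to the
boundary of the parameter space).

Numerical choices:

* The optimizer runs Powell first, then BFGS. With a small random-slope
  variance (the realistic regime here: RIP slope heterogeneity of order
  $10^{-3}$) gradient-based optimizers alone frequently fail to converge;
  Powell is slower but reliable, and results carry a `converged` flag.
* The covariance of the fixed effects starts from the model-based GLS
  expression $(\sum_i X_i' V_i^{-1} X_i)^{-1}$ evaluated at the estimated
  variance components (the numerically differentiated Hessian can lose
  positive definiteness when a variance component sits near zero; the GLS
  form cannot) and adds the Kenward-Roger small-sample adjustment for the
  extra variability induced by estimating the variance parameters. Plug-in
  GLS standard errors are known to be too small in exactly this near-boundary
  random-slope regime (Kackar-Harville); the adjustment restores interval
  calibration, and our implementation agrees with R's `pbkrtest::vcovAdj`
  to four significant digits. Because $V$ is linear in the variance
  parameters the adjustment's second-derivative term vanishes; an
  indefinite boundary estimate of the correction is clipped to its positive
  semidefinite part.
* An exactly linear response (all variance components zero, the noiseless
  synthetic limit) degenerates the mixed likelihood. `fit()` detects it
  (OLS residual mean square below $10^{-12}$) and returns the exact
  least-squares solution with zero variance components.
* Wald $z$ inference is used for coefficient $p$-values and confidence
  intervals (`df_method="normal"` in the results object). Satterthwaite
  degrees of freedom are not available from the backend; with 150+ countries
  the difference is negligible.

Effect sizes are reported as relative percent changes in prevalence:
$100\,[\operatorname{expit}(\operatorname{logit}(p_0)+\beta\Delta)-p_0]/p_0$
at a baseline $p_0$ equal to the observation-weighted mean prevalence of the
stratum's panel (the published convention is not stated; the rare-outcome
alternative $100[e^{\beta\Delta}-1]$ coincides with this as $p_0\to0$).
RIP effects are reported at $\Delta = 10$ percentage points, computed as a
$\Delta=10$ shift on the logit scale; for effects of this size it is
numerically indistinguishable from ten times the per-unit change. Interval
endpoints transform the Wald CI endpoints, which is exact because the
conversion is monotone in $\beta$.

Multicollinearity is checked with variance inflation factors
($\mathrm{VIF}_j = 1/(1-R_j^2)$ over the four fixed-effect covariates);
generated panels sit well below the conventional threshold of 2.

## Counterfactual projection

Four headline scenarios are evaluated for outcome year 2017, restricted to
the "balanced" countries with complete scores, price and GDP in both 2008
and 2016:

1. **Status quo 2008** — scores and RIP replaced by their 2008 values.
2. **Price floor** — pack price raised to $\max(\text{observed}, I\$7.73)$
   (the 90th percentile of pooled country-year prices; recomputable from
   data via `compute_price_floor`), RIP recomputed with the same-year GDP.
3. **Top scores** — $P=W=E=5$ everywhere (overrides set the value exactly).
4. **Combined** — 2 and 3 together.

This ordering follows the published results table, which differs from the
narrative methods text in the order of scenarios 2 and 3.

Prediction uses fixed effects only: each country's observed 2017 prevalence
is shifted on the logit scale by $\beta \cdot (\text{counterfactual} -
\text{observed 2016})$ covariate deltas. Anchoring at observed prevalence
keeps country levels (the role the random effects played in fitting) while
excluding random effects from the prediction itself; the alternative
reading — rebuilding the absolute linear predictor from scratch — is not
used because it would discard country levels entirely. Scenario 1 rolls
back covariates only, not the prevalence anchor.

Aggregation is population-weighted: global prevalence
$\sum_c p_c w_c / \sum_c w_c$ and smoker counts $\sum_c p_c w_c$ with $w_c$
the stratum population. Because the models use age-standardized prevalence,
age-group smoker counts are proportionally rescaled so that the three age
bands sum exactly to the sex-specific 15-plus envelope (conservation holds
to $10^{-9}$ relative error by construction and is asserted in tests).

Uncertainty: the fixed-effect vector is drawn 1,000 times (default) from a
multivariate normal centred at the estimates with the fitted covariance
(eigenvalue clipping repairs numerically non-PSD inputs, with a warning);
each scalar result's 95% UI is the 2.5th-97.5th empirical percentile range
(NumPy linear interpolation). Draws are taken independently per stratum
model; no cross-stratum covariance is available to propagate. A note on
coverage: the UI reflects coefficient uncertainty only, matching the
prediction's fixed-effects-only design.

## The synthetic-data generator

`GeneratorConfig`/`generate_panel_data` emulate the study's data layout with
the model's exact generative structure, so every downstream stage can be
scored against known truth. Defaults (chosen once, as study conditions):

| parameter | default | rationale |
|---|---|---|
| `n_countries` | 175 | size of the real analysis panel |
| `policy_years` | 2008-2016 biennial | WHO reporting waves; outcomes one year later |
| `fixed_effects` slopes | (-0.011, -0.021, -0.019, -0.009) | logit-scale magnitudes matching the reported per-unit effects |
| stratum intercepts | e.g. male 15+: -0.30, female 15+: -2.30 | anchor typical prevalence near observed 2017 global levels (men ~37%, women ~7%) |
| `sd_intercept` | 0.5 | wide country heterogeneity in baseline prevalence |
| `sd_slope` | 0.002 | small RIP-slope heterogeneity (near-boundary regime) |
| `sd_resid` | 0.05 | residual year-to-year noise on the logit scale |
| `score_drift` | 0.3 | probability a score steps up one level per wave; reproduces the observed strengthening of legislation |
| `missing_rate` | 0.06 | fraction of policy rows with one score masked as 1, matching the ~823/875 complete country-years of the real panel |
| `price_params`, `price_trend` | log I$3.10 ± 0.55, +0.14/wave | lognormal prices with country offsets; the trend reproduces the observed I$3.10 → I$5.38 mean-price path |
| `gdp_params`, `gdp_trend` | log I$12,000 ± 0.9, +0.04/wave | realistic income spread; prices rise faster than income, so affordability declines for most countries |

Scores follow a capped step-up Markov chain (never decreasing except through
the missingness mask); policy adoption is generated independently of income,
a modelling choice, since the joint distribution is not documented.
Missingness is observational: a latent true score drives prevalence while
the recorded score is masked as 1. The "both sexes" stratum is generated as
its own stratum with its own intercept, mirroring how it is modelled. One
$(\alpha_c, \delta_c)$ pair is drawn per country and shared across strata.

What the generator does **not** emulate: survey sampling error and the
smoothing of the upstream prevalence-estimation process, compliance versus
legislation-on-paper, price heterogeneity within countries, and any feedback
from prevalence to policy adoption. Passing tests therefore demonstrate
internal validity (the pipeline recovers what its own model generates), not
that the model is correctly specified for real data.

## Validation studies and problem sizes

`tobaccopolicy.evaluation` runs three studies, used by both the test suite
and `scripts/acceptance.py`:

* **Parameter recovery** — 100 replicate panels of 150 countries × 5 waves,
  single stratum, coefficients $(-0.3, -0.011, -0.021, -0.019, -0.009)$:
  mean fixed effects within 10% relative bias; per-coefficient 95% CI
  coverage within [90%, 99%].
* **Noiseless exactness** — all random SDs zero: coefficients recovered to
  $10^{-6}$; the identity scenario changes nothing.
* **UI calibration** — 200 replicates, 1,000 draws each: the 95% UI for
  global counterfactual prevalence under the top-score scenario covers the
  truth (computed with the generating coefficients from the same observed
  anchor) in at least 90% of replicates.

These sizes keep a full validation run in the range of minutes on a single
core while leaving Monte-Carlo noise well below the margins being asserted.

## Known limitations

* Ecological design: effects are associations at the country-year level.
* The one-year covariate lag likely understates policies that take longer
  to bite; longer lags would cost data points.
* Wald intervals use normal quantiles with Kenward-Roger-adjusted
  standard errors; replicate studies put their coverage near 95-98%,
  mildly conservative for the RIP coefficient whose slope variance sits
  near the boundary.
* The LRT reference distribution is boundary-conservative.
* Cross-stratum estimates are treated as independent in projections.
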