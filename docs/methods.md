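# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, the numerical conventions, and what the synthetic-data
validation does and does not establish.

## Lag-augmented causality testing

The core test asks whether the lagged history of one or more causal
variables improves the prediction of an outcome beyond the outcome's own
history, on series that may be integrated.  A VAR is estimated in levels,
equation by equation by OLS on the common design `[1, y_{t-1}, …,
y_{t-(p+dmax)}]` (all variables at every lag).  The Wald restriction
covers only lags `1..p` of the restricted variables in the outcome
equation; the `dmax` extra lags absorb the nonstandard asymptotics that
unit roots would otherwise inject into the restricted coefficients, so
the statistic keeps its χ² limit without differencing or cointegration
pre-testing.  The cost is efficiency — `dmax` unrestricted lag blocks are
estimated but never tested — which is the accepted trade on short macro
panels where pre-testing errors are expensive.

Conventions:

* **Degrees of freedom** are `p × (number of restricted variables)` —
  the count of restricted coefficients.  Joint tests restrict several lag
  blocks at once (df = p·k); submodels restrict one block (df = p) on the
  *same* fitted VAR, so joint and individual evidence are directly
  comparable.
* **Coefficient covariance** is the homoskedastic OLS form
  `s²(X′X)⁻¹` with `s² = RSS/(T−n_coef)`, matching the standard Wald
  construction; no HAC correction is applied (the test's asymptotics
  assume a correctly specified VAR, and T is far too small for kernel
  variance estimation to help).
* **P-values** come from the asymptotic χ²; no small-sample F correction.
  On n ≈ 33 this over-rejects mildly — measured size at the 5% level is
  ≈ 0.08 on random-walk pairs (see the acceptance suite) — which is the
  known finite-sample behavior of Wald tests in short lag-augmented VARs.
* `p` and `dmax` are resolved *per model* (each model's variable subset
  gets its own AIC selection and ADF profile), not globally.

## Lag selection

AIC over `p = 1..max_p`, computed as `ln det(Σ̂) + 2·m·n_coef/T` on the
common estimation sample trimmed for `max_p` lags, so all candidates are
scored on identical rows and the criterion values are comparable.  When
the argmin exceeds the cap (default 3), the cap is applied and recorded:
on 23–33 annual observations a 4- or 5-lag bivariate VAR spends 9–11
coefficients per equation, and the capped order is the defensible choice.
`max_p` defaults to 5.

## Unit-root testing and dmax

Integration order per variable is the smallest `d ≤ d_cap` (default 2)
whose d-th difference rejects the ADF unit-root null at α = 0.05; if none
does, `d_cap` is returned and flagged.  ADF lag length is chosen by AIC
up to Schwert's bound `⌊12(n/100)^0.25⌋`, shrunk when the series is
short; the deterministic term defaults to a constant, with
constant+trend available for series where trend matters.  The KPSS test
(null of stationarity) is available as a complementary check for short
samples where ADF has little power; its long-run-variance bandwidth
defaults to the short rule `⌊4(n/100)^0.25⌋`, which preserves power
against random walks at moderate n.  Decisions everywhere are keyed to
p < 0.05.

## Mediation classification

The verdict for a triple (X, M, Y) is a pure function of six significance
booleans, applied in fixed order:

1. joint not significant and X→Y not significant → `no_effect`;
2. X→M, M→Y, joint, and the M block all significant →
   `partial_mediation` if the X block is also significant, else
   `full_mediation`;
3. joint significant with neither individual block significant →
   `joint_synergy`;
4. otherwise, X→Y significant → `direct_only`;
5. fallback (joint significant but no direct path and no complete chain)
   → `no_effect`.

The rule set is total — all 2⁶ patterns map to exactly one label, which a
property test enforces — and each verdict carries the rule firings that
produced it.  Significance is a strict α threshold (a p-value of 0.0566
at α = 0.05 is *not* significant; no borderline band is encoded), but all
six p-values are reported so near-misses remain visible.  The classifier
tests direction only; indirect-effect magnitudes and proportion mediated
are out of scope.

## Structural stability

**Bai–Perron.**  Pure structural change (all coefficients shift).  Every
admissible segment's SSR is computed from prefix Gram matrices; the
partition for a given break count is the exact dynamic-programming
minimizer, and the count is chosen sequentially: sup-F(l+1|l) — the best
additional within-regime break — is accepted while its p-value clears
α = 0.10, the conventional liberal level for break screening (stability
screening and causality testing deliberately use different thresholds).
Minimum segment length is `max(⌈trim·n⌉, q+1)` with trim = 0.15; up to 5
breaks by default.  P-values interpolate Monte Carlo quantiles of the
asymptotic limit (a q-dimensional standardized Brownian-bridge sup
functional, 120k replications on a 2000-point grid; the simulated 95%
point for q = 1, 8.66, agrees with the classical tabulated ≈ 8.58), with
the sequential test's p given by `1 − G(F)^(l+1)`.  Reported break dates
index the last observation of each pre-break regime.

**CUSUM / CUSUM-SQ.**  Standardized one-step-ahead recursive residuals
(computed by rank-one updates, validated against statsmodels).  The CUSUM
path is their scaled cumulative sum against the classical linear
boundaries `±a(√m + 2t/√m)`; the boundary parameter and the p-value come
from simulated quantiles of `sup |W(t)|/(1+2t)`, which reproduce the
classical 10%/5%/1% constants (0.850/0.948/1.143) to three decimals.  The
CUSUM-SQ path is the cumulative squared-residual share against parallel
bands; since `√(m/2)·(s_t − t/m)` converges to a Brownian bridge, its
p-value uses the Kolmogorov distribution of the maximum deviation.  Both
p-values are documented approximations and may differ from other
implementations in the third decimal.  A numerically exact fit (residual
scale below 1e-10 of the data scale) is reported as the null path, not
crossed.

Instability in a model is flagged but does not gate the causality
battery: per-regime re-estimation on 20–30 observations is not feasible,
so the report surfaces the warning and proceeds.

## Stratification

K-means on standardized features (z-scores; raw-scale clustering is
available via `scale=False` since published WSS values are sometimes on
the raw scale), Euclidean distance, best of `n_init = 25` random starts
under a master seed.  Cluster labels are arbitrary, so groups are named
post hoc by center ordering on the first feature (higher = high-income).
The cluster count comes from the WSS elbow (largest relative drop) among
k whose silhouette clears 0.5, with the diagnostics for every k reported
so a weak-structure warning is visible when nothing clears the threshold.

Cross-group comparison of two χ² statistics has no exact standard test;
the documented choice here is the Wilson–Hilferty cube-root transform of
each statistic to an approximately standard-normal deviate and the
contrast `z = (z_low − z_high)/√2` (positive = stronger evidence in the
low-income group), two-sided p.  A property test checks the contrast is
N(0,1) to Kolmogorov distance < 0.02 under the null.  Results with
mismatched df are flagged but still compared.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
short annual spans (named presets 23, 33, and 11 years, matching the
global food-insecurity, food-price, and country-level windows), lagged
causal links with 1–6 period delays, mediated chains with or without a
direct path, I(1)/I(2) variables (cumulated after simulating the
stationary core, so the differenced output reproduces it exactly),
coefficient breaks at declared dates, and two-cluster country
cross-sections at a chosen separation.  Innovations are Gaussian;
validation rejects stationary cores with companion spectral radius
≥ 0.99 so near-unit ambiguity must be declared as integration instead.
Burn-in is 100 periods.  Identical seed and truth give bit-identical
output.

What passing on this generator shows: the estimators, restrictions and
decision rules do what they claim under the model class the method
assumes.  What it does not show: robustness to the features real macro
panels add — measurement revisions, cross-series correlated shocks,
heavy-tailed crisis innovations, and near-cointegrated dynamics.  The
generator deliberately does not calibrate to any real series' moments.

## Problem sizes

The test suite and the acceptance script run the stages at the scales
their claims are stated for: 1,000 random-walk pairs (n = 33) for size,
500 replications (n = 100) for power, 200 replications each for mediation
recovery (n = 150), break localization (n = 100), and CUSUM-SQ power
(n = 200), 500 for CUSUM size, 50 cross-sections (99 countries) for
clustering, and 200 draws (n = 300) for lag selection.

## Known limitations

* Wald p-values are asymptotic; expect mild over-rejection below n ≈ 40.
* The sequential break test inherits the liberal 10% screening level;
  with very low noise it will localize even modest shifts, and with n
  under ~30 trimming leaves few admissible partitions.
* The mediation rules are boolean: evidence just above and far above the
  threshold read the same (p-values are reported to mitigate this).
* Income stratification supports exactly the two-group contrast; more
  groups cluster fine but are not compared pairwise.
* Nominal vs real price indices is a data choice the package cannot make;
  panels are consumed as given (real-terms indices by default convention).
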