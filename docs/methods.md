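# Methods

## Scoring model

The Margin Risk Index treats the post-treatment resection margin as a
biological specimen with four prognostic axes: immune organisation
(tertiary lymphoid structure density), residual tumor burden (Pan-CK⁺
foci and Ki-67 proliferation), molecular residual disease (TP53/NOTCH1
driver mutations and PD-L1 RNA fold-change versus normal mucosa) and
effector immune contexture (CD8⁺/FoxP3⁺ ratio, Granzyme B⁺ density).
Each axis maps to a 0/1/2 score through fixed thresholds; the composite
is the weighted sum 0.30/0.25/0.25/0.20 on [0, 2], with the
histopathology weight largest because TLS density is the strongest
single predictor in the reference analysis.  Weights and thresholds are
constants of the index, not fitted quantities; re-deriving them from
data is out of scope.

Decisions where the rubric wording left gaps:

* **Category gaps.** The printed category bins (0–0.8, 0.9–1.4, 1.5–2.0)
  omit the attainable composites 0.85 and 1.45.  The composite is
  rounded half-up to one decimal before category lookup (0.85 →
  intermediate, 1.45 → high), which matches the one-decimal bin labels
  and preserves monotonicity; the raw score is kept unrounded.
* **Discordant sub-criteria** within a two-marker domain take the
  maximum (worse) level — a conservative rule; the rubric only defines
  concordant archetypes.
* **Band edges** are closed risk-conservatively: Ki-67 exactly 20,
  PD-L1 exactly 1- or 2-fold, Granzyme B exactly 50 or 200, and
  CD8/FoxP3 ratios in [1, 2) are all intermediate; Pan-CK in (0, 5) is
  intermediate; TLS bands are [3, ∞) / [1, 3) / [0, 1).  The
  histopathology high-risk band uses <1 TLS/mm² (the tabulated
  definition) rather than strict absence.
* **Undefined CD8/FoxP3 ratio.** CD8 present with zero FoxP3 encodes as
  +inf (level 0); neither cell type encodes as NaN (level 2 — no
  cytotoxic infiltrate).
* **Override.** A margin ≤2 mm forces the high category without
  changing the numeric score, independent of the separate close/clear
  (≤5 mm) covariate; both are stored.

Exhaustive enumeration of the 81 domain-score combinations (exposed as
`enumerate_score_table`) verifies the score grid (multiples of 0.05,
range [0, 2]) and that the category is monotone non-decreasing in every
domain score.

## Cohort simulator

The generator reproduces the statistical structure the analyses assume,
not any individual patient data.

* **Biomarkers.** Per domain, a band is drawn from a probability triple
  (defaults: the tabulated cohort frequencies of the lead sub-marker —
  TLS 35.4/43.8/20.8%, Pan-CK 31.9/40.3/27.8%, driver mutations
  47.2/38.9/13.9%, CD8/FoxP3 37.5/42.4/20.1%), then raw values are drawn
  uniformly inside the band's interval so that re-scoring recovers the
  band exactly.  Both sub-markers of a domain are drawn inside the same
  band (concordant profiles).  Unbounded bands carry documented caps
  (TLS high [3, 10] /mm², Pan-CK high [5, 15], Ki-67 high (20, 60],
  PD-L1 high (2, 8], ratio low [2, 6], Granzyme B high (200, 500]);
  mutation counts in the ≥2 band are drawn from {2, 3, 4}.
* **Clinical covariates** are sampled independently at the tabulated
  category marginals (training and validation variants are packaged).
  Margin distance is uniform on 1–5 mm within close margins and 5–15 mm
  within clear ones, so a quarter of close margins trigger the 2 mm
  override.
* **Outcomes.** Each endpoint (locoregional control, distant-metastasis-
  free survival) gets a latent proportional-hazards event time with
  hazard h₀(t)·exp(lp), where lp sums the configured log-hazard ratios
  of the patient's non-reference levels.  The packaged training effects
  are the adjusted hazard ratios of the reference analysis
  (differentiation 1.56/2.19 LRC, pathologic response 1.45/2.06 LRC,
  MRIx 1.89/3.15 LRC; 1.62/2.00, 1.92/1.78, 2.18/3.54 DMFS); the
  validation variant swaps in the validation high-risk effects
  (2.95 LRC, 3.22 DMFS), keeps the remaining effects, and carries the
  traditional margin covariate with no independent effect.  A separate
  domain-effect configuration drives hazards directly from the four
  domain scores at the domain-level effect sizes (5.92/6.75 TLS high,
  7.11 tumor burden LRC, 9.40 molecular DM, 3.80/4.25 immune); the two
  unstated high-risk values are fixed at 5.0 to preserve the stated
  within-endpoint ordering, and intermediate levels carry half the
  high-risk log-hazard.
* **Censoring** is administrative, uniform on 24–72 months (the stated
  follow-up range); optional exponential dropout is available but off by
  default.
* **Baseline calibration.** For the exponential family the marginal
  event fraction has a closed form: P(event | lp) =
  1 − (e^{−ra} − e^{−rb})/(r(b−a)) with r = λ·e^{lp} and censoring
  window [a, b], mixed over the exact joint distribution of lp
  (enumerating covariate levels, with the MRIx-category distribution
  derived exactly from the 81 band combinations plus the override
  probability).  `calibrate_baseline_rate` solves for λ by root
  bracketing so cohort event fractions hit the observed 18.1% (LRC) and
  21.5% (DMFS).  The enumeration treats lp covariates as independent,
  which is exact for the packaged defaults (the only dependence —
  override linking margin class and category — carries a zero margin
  effect).

What the simulator deliberately does **not** emulate: correlations
between domains or between domains and clinical covariates (only
marginals are known), dependence between the two endpoints beyond shared
covariates, competing risks, informative censoring, and measurement
error in the raw assays.  Tests passing on these cohorts therefore
validate the arithmetic and the estimators under a correctly-specified
proportional-hazards world, not the index's clinical performance on real
patients; in particular the real-data concordance indexes cannot be
reproduced without patient data.

## Survival kernels

All estimators are implemented in-package and cross-checked in the test
suite against independent references (lifelines, statsmodels) on shared
conventions:

* **Cox PH**: Newton–Raphson on the partial likelihood, Efron tie
  handling by default (Breslow available; the two coincide on tie-free
  data, asserted in tests), deterministic start at 0, step-halving,
  convergence at score max-norm < 1e-8 within 100 iterations.  Because
  accumulated rounding bounds the attainable score norm on large
  cohorts, iteration also stops when the Newton decrement falls below
  1e-13·(1+|loglik|) — at that point the remaining ascent is below
  floating-point noise.  Standard errors come from the inverse observed
  information; intervals are Wald, exp(coef ± 1.96·se).  Singular
  information or diverging coefficients return a flagged, not raised,
  result.
* **Harrell's C**: usable pairs are those whose earlier observed time is
  an event; a censored subject tied in time with an event counts as
  outliving it; tied event times are not orderable; score ties count
  0.5.  Explicit pair enumeration (vectorised) is used up to n = 2000
  and an exactly equivalent Fenwick-tree scan above; equivalence is
  asserted on random instances with tied times and scores.
* **Log-rank**: k-sample statistic with the hypergeometric
  variance-covariance summed over event times, df = k−1.
* **LRT/AIC**: χ² = 2·Δloglik with df = Δk for nested fits on identical
  rows; AIC = −2·loglik + 2k.  The stepwise chain comparison
  clinical+margin → clinical+MRIx replaces one term with another and is
  not strictly nested; it is computed as 2·Δloglik with the χ² reference
  as an approximation (flagged in the API via `check_nested=False`).
* **Calibration**: predicted event probabilities by a fixed horizon
  (default 36 months) are decile-grouped; the observed group probability
  is 1 − KM(horizon) within the group, which handles censoring; χ² =
  Σ n_g(obs−pred)²/(pred(1−pred)) on df = g−2, degenerate groups merged.
  The df = g−2 convention presumes predictions estimated from the data
  (the usual setting, used throughout the pipeline); fixed external
  probabilities would follow χ²(g) instead.

## Pipeline conventions

* All nested-model comparisons are fitted on the identical complete-case
  row set; excluded row counts are logged.
* Reference levels are fixed: well differentiation, pathologic complete
  response, low-risk MRIx, clear margin.
* Baseline tables use Pearson χ² (no continuity correction), switching
  to Fisher's exact test for 2×2 tables with any expected cell <5;
  larger sparse tables keep χ² with a flag, since no exact r×k test is
  available in the stack.  Percentages are rounded half-up to one
  decimal for display only.
* External validation applies the frozen scoring configuration with no
  re-estimation and adjusts for differentiation, pathologic response and
  traditional margin status; calibration uses the 36-month horizon.
* The domain-association analysis BH-adjusts its eight log-rank
  p-values; domain levels without patients are dropped with a warning.

## Problem sizes and randomness

Simulation-based checks use sizes chosen to make the tested property
sharp at desk scale: marginal-frequency and round-trip checks at
n = 10,000 (3 binomial SEs), effect-size recovery at n = 20,000 (Monte
Carlo error on the high-risk hazard ratio ≈ 5%, against a 10%
tolerance), Hosmer–Lemeshow behaviour over 200 replicates of n = 2,000,
and null-calibration uniformity over 500 replicates of n = 600 — the
smallest size at which the 6-parameter likelihood-ratio χ² asymptotics
are accurate enough for a Kolmogorov–Smirnov uniformity check.  Every
stochastic component takes an explicit seed (`SimulationConfig.seed`,
function-level `rng` arguments); identical configuration and seed
reproduce cohorts byte-for-byte.

## Known limitations

* Weights and cut-points are constants; the index is not refitted, and
  no machinery is provided to re-derive weights from new cohorts.
* Printed confidence intervals in the reference analysis are asymmetric
  in a way Wald intervals cannot reproduce; intervals here are Wald and
  should be treated as the package's own convention.
* No time-varying covariates, frailty, stratified baselines, competing
  risks or proportional-hazards diagnostics.
* The simulator's independence assumptions (above) make it a tool for
  verifying estimators and power, not for forecasting real-cohort
  operating characteristics.
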