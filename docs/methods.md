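# Methods

This note records the statistical model, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and
the design decisions taken where more than one defensible choice existed.

## Two-sample MR model

All estimators consume a harmonized set of per-SNP effect pairs
(β̂ₓⱼ, σₓⱼ, β̂ᵧⱼ, σᵧⱼ) referring to a shared effect allele, with the two
traits measured in non-overlapping samples. Standard summary-statistic MR
assumptions apply: effects are linear and homogeneous, σₓ and σᵧ are known,
and the NOME approximation (no measurement error in β̂ₓ beyond what the
weak-instrument filter controls) underlies the IVW weights.

- **IVW** uses weights σᵧⱼ⁻² and, by default, a multiplicative
  random-effects SE — the fixed-effect SE inflated by max(1, √(Q/(k−1))).
  This is the mainstream default for trait screens because it is robust to
  mild heterogeneity without changing the point estimate.
- **MR-Egger** first orients every row so β̂ₓⱼ ≥ 0 (the convention under
  which the intercept estimates *directional* pleiotropy relative to the
  exposure-increasing allele), then fits a free-intercept weighted
  regression; slope and intercept SEs carry the over-dispersion inflation
  max(1, √(Q′/(k−2))). P-values are two-sided normal throughout — no
  t-correction — which matches how OR/CI/p triples from such analyses are
  normal-theory consistent.
- **Weighted median**: ratio weights β̂ₓⱼ²/σᵧⱼ² (the inverse variance of
  the Wald ratio to first order), cumulative-weight interpolation at 0.5
  with the standard −w/2 offset, and a seeded parametric bootstrap SE
  (default 1,000 replicates).
- **Modes**: normal-kernel density of the Wald ratios with the modified
  Silverman bandwidth φ·0.9·min(sd, IQR/1.349)·k^(−1/5) (φ = 1 by
  default; if IQR = 0 the sd alone is used so distinct ratios never get a
  zero bandwidth). The point estimate is the density argmax on a fixed
  10,000-point grid spanning mean ± 5 sd of the ratios — deterministic
  given the data. Bootstrap replicates use a coarser 1,024-point grid; the
  grid quantization is far below the bootstrap SE, and the point estimate
  itself always uses the full grid. All ratios identical is a degenerate
  case: the common ratio is returned with SE 0 and a warning.

## Instrument selection

Defaults: exposure p < 5×10⁻⁵; outcome-association removal at p < 0.05;
greedy clumping by ascending p (ties broken by SNP id) with r² < 0.001
within 10,000 kb; F = (β/σ)² ≥ 10; optional user-supplied confounder SNP
exclusion list. All thresholds are strict inequalities. The clump window
is configurable down to a literal 10 kb (`clump_window_kb=10`) for
compatibility with descriptions that give the window in base pairs; the
10,000 kb default is the field convention. The LD provider is an abstract
callable so a real r² panel can be plugged in; the shipped behavior is
distance-only, exact for panels of independent SNPs.

**The outcome-association filter is a screening guard, not part of the
estimator.** Removing SNPs with outcome p < 0.05 protects a hypothesis
*screen* against variants acting on the outcome directly, but whenever a
true effect exists it preferentially deletes the instruments carrying the
signal (they are the ones with real outcome associations), biasing the
estimate toward zero, and under the null it truncates the outcome effects
into under-dispersion, making the IVW test conservative. The package
therefore applies it in the forward screen (`run_screen`) — faithfully to
the workflow it implements — but not inside mediation legs
(`run_mediation`), which are estimation tasks, and not in the
statistical-validation studies (`mrmediate.studies`), which validate the
estimators' own calibration and bias. `prepare_instruments` exposes the
choice as `apply_outcome_filter`.

In the reverse-MR leg the filter is kept deliberately: when a candidate
trait truly causes the outcome, the outcome's apparent instruments are the
candidate's own SNPs, and the candidate-association filter is precisely
what stops them from manufacturing a spurious reverse signal. A
consequence worth knowing: a trait *purely* downstream of the outcome
never reaches the reverse stage (the forward screen's outcome filter
already blocks it); the reverse filter matters for traits with both an own
forward path and a reverse path.

## Sensitivity battery

Cochran's Q is computed at the fixed-effect IVW estimate (df k−1) or the
Egger fit (df k−2) with weights σᵧⱼ⁻², and referred to the upper
chi-square tail. Leave-one-out refits IVW k times and flags omissions that
change the sign of the estimate or move it outside the full-set CI.
Heterogeneity and pleiotropy verdicts are reported, never silently acted
on: instrument removal happens only through MR-PRESSO in the pipeline, and
whole mediation legs are excluded only on the Egger-intercept flag.

MR-PRESSO is implemented from the published algorithm: the observed RSS of
each β̂ᵧⱼ about its leave-one-out IVW prediction is ranked within a null
distribution built by redrawing β̂ᵧⱼ ~ N(prediction, σᵧⱼ) and recomputing
the leave-one-out RSS per draw (vectorized across simulations); the global
p-value is the (1+r)/(n_sim+1) tail rank. Per-SNP outliers are the SNPs
whose observed squared residual exceeds its simulated null at the
Bonferroni-adjusted level, tested only when the global test is significant.
Defaults n_sim = 1,000, sig = 0.05, seed mandatory in the pipeline; the
distortion test is out of scope. Flagging more than ⌈k/2⌉ SNPs raises a
degeneracy warning.

## Mediation

The mediated effect is exactly β₁β₂ with the first-order delta-method SE;
its 95% CI is symmetric (point ± 1.959964·SE), consistent with how such
tables are printed. The proportion CI scales the mediated-effect CI by
100/total — i.e. the total effect is treated as fixed, which is exactly
the arithmetic that reproduces published proportion intervals from their
mediated-effect intervals; a seeded parametric-bootstrap alternative
(`proportion_ci_bootstrap`) propagates uncertainty in all three legs for
users who want it. Proportions are reported sorted (low, high), negative
under suppression (opposite signs) with a warning.

`run_mediation` computes all three legs itself with the same estimation
rules, so the identities mediated + direct = total hold exactly within a
row. The mediator→outcome leg excludes SNPs that qualify as instruments
for the exposure: when a direct exposure→outcome path exists, a shared
instrument violates the second leg's exclusion restriction and its Wald
ratio converges to (θ₁θ₂+θd)/θ₁ rather than θ₂. Univariable legs only;
multivariable adjustment is out of scope.

## Synthetic-data generator

`simulate_triple` draws, per SNP: MAF ~ U(0.05, 0.5); membership in the
exposure-causal fraction (γⱼ ~ N(0, 0.15²)), a *disjoint* mediator-causal
fraction (δⱼ ~ N(0, 0.15²)), or neither; true effects
mediator = θ₁γ + δ and outcome = (θ₁θ₂+θd)γ + θ₂δ + sign(γ)·α, with α the
directional pleiotropy drawn for a fraction of the exposure's causal SNPs.
The mediator-specific δ SNPs are what make two-step mediation identifiable:
without them the second leg has no instruments of its own and θ₂ cannot be
separated from the direct path. Pleiotropy is oriented by sign(γ) — i.e.
relative to the exposure-increasing allele — which is the sense in which
pleiotropy is "directional" and what the Egger intercept estimates;
coding-symmetric injection would cancel to zero under Egger orientation.

Estimated effects add independent noise with the standardized-trait SE
(2p(1−p)n)^(−1/2), inflated by (φ(1−φ))^(−1/2) for the binary outcome at
case fraction φ = 0.5. Defaults mirror the emulated study design: exposure
panel n = 3,757, mediator panel n = 8,299, binary outcome n = 10,000, 500
independent SNPs placed on 22 chromosomes at a spacing beyond the clump
window, and the (θ₁, θ₂, θd) = (0.4, 0.3, 0.1) triple whose true mediation
proportion is 54.5%. `simulate_panel` builds a many-trait screen with
disjoint per-trait SNP blocks and a shared outcome.

Not emulated: LD structure (SNPs are independent; the clump interface
accepts an external r² provider), realistic allele-frequency spectra,
sample overlap, winner's-curse-free replication designs, and case-control
ascertainment beyond the balanced-fraction SE inflation. Passing tests
therefore demonstrate correctness of the estimators and workflow under the
stated model, not robustness to LD misspecification or overlap bias.

## Validation studies and problem sizes

`mrmediate.studies` fixes the validation conditions: null calibration over
2,000 seeded replicates (300 SNPs, all structural effects zero; MR-PRESSO
at n_sim = 500), IVW recovery over 200 replicates with ~45 instruments from
n = 10,000 samples and a true effect of 0.3, Egger-intercept recovery under
30% directional pleiotropy (injected mean 0.015), and mediation recovery
over 100 full two-step runs. These sizes give Monte-Carlo SEs comfortably
below the quantities being checked (e.g. ±0.5% on a 5% rejection rate,
±0.002 on the IVW mean) while keeping a full run under a minute. The
mediation proportion's small upward finite-sample bias (≈1–2 points on
54.5%) is the ratio nonlinearity E[1/T̂] > 1/E[T̂] of the plug-in
estimator, and shrinks with instrument strength.

## Numerical notes and edge cases

- Wald-ratio estimators drop SNPs with β̂ₓ = 0 (with a warning); `ivw`
  requires k ≥ 2, `egger` and the median/modes k ≥ 3, MR-PRESSO k ≥ 4.
- TSV output writes floats with the shortest bit-exact representation and
  input parses with full round-trip precision, so write→read is the
  identity.
- Harmonization resolves strand complements before allele comparison;
  palindromic SNPs default to `drop_ambiguous` with an EAF window of
  0.42–0.58 (the conservative common practice), and retained palindromes
  are strand-checked by allele frequency.
- Invalid summary rows are dropped with logged counts rather than failing
  the file; p-values disagreeing with 2·Φ(−|β/σ|) by more than 2× are
  flagged but kept (inputs may carry exact p-values from other tests).
- Per-trait seeds in the pipeline are derived by hashing the configured
  seed with the trait ids, so results are independent of panel order and
  byte-identical across runs.
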