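# mrmediate

Two-sample Mendelian randomization (MR) and two-step mediation analysis from
GWAS summary statistics.

MR uses genetic variants as instrumental variables to estimate the causal
effect of an exposure on an outcome from summary-level association data
alone, exploiting the random assignment of alleles at conception.
`mrmediate` implements the complete workflow used in summary-statistic
causal screens of molecular traits (immune cell phenotypes, plasma
metabolites) against disease endpoints: instrument selection, allele
harmonization, five causal estimators, a sensitivity battery, reverse-MR
filtering, false-discovery-rate evidence tiers, and two-step mediation that
apportions an exposure→outcome effect through an intermediate trait. A
seeded synthetic-GWAS generator with known causal structure makes every
stage testable without external data.

It is aimed at statistical geneticists and epidemiologists who want a
scriptable, fully reproducible pipeline over plain-text summary statistics.

## The model

For SNP *j*, let (β̂ₓⱼ, σₓⱼ) and (β̂ᵧⱼ, σᵧⱼ) be the estimated per-allele
effects on exposure and outcome in two non-overlapping samples. Under valid
instruments each Wald ratio β̂ᵧⱼ/β̂ₓⱼ estimates the causal effect θ.

- **IVW** (primary): θ̂ = Σⱼ β̂ₓⱼβ̂ᵧⱼσᵧⱼ⁻² / Σⱼ β̂ₓⱼ²σᵧⱼ⁻², the
  zero-intercept weighted regression of β̂ᵧ on β̂ₓ; multiplicative
  random-effects SE by default.
- **MR-Egger**: the same regression with a free intercept; the intercept
  estimates average directional pleiotropy.
- **Weighted median**: consistent if ≥50% of the weight comes from valid
  instruments; bootstrap SE.
- **Simple / weighted mode**: kernel-density mode of the Wald ratios.
- **Sensitivity**: Cochran's Q heterogeneity, Egger-intercept pleiotropy
  test, leave-one-out stability, and MR-PRESSO (simulation-based residual
  sum of squares) global and per-SNP outlier tests.

Instruments satisfy: exposure association p < 5×10⁻⁵, LD clumping
(r² < 0.001 within 10,000 kb), outcome association p ≥ 0.05, MR-PRESSO
outlier removal, and single-SNP F = (β/σ)² ≥ 10.

Two-step mediation: with β₁ the exposure→mediator and β₂ the
mediator→outcome IVW estimates, the mediated effect is β₁β₂ (delta-method
SE √(β₁²σ₂² + β₂²σ₁²)), the direct effect is total − β₁β₂, and the
mediation proportion is 100·β₁β₂/total. Screens are tiered by
Benjamini–Hochberg FDR: q < 0.05 "strong", 0.05 ≤ q < 0.20 "suggestive".

## Worked example

`python examples/04_mediation.py` simulates a triple with known structure
(θ₁ = 0.4, θ₂ = 0.3, direct = 0.1 — true mediation proportion
0.12/0.22 = 54.5%) and decomposes it:

```
beta1 (exposure->mediator) = 0.402 +- 0.018  (true 0.4)
beta2 (mediator->outcome)  = 0.338 +- 0.036  (true 0.3)
total effect               = 0.239 +- 0.034  (true 0.22)
mediated = beta1*beta2     = 0.1359 [0.1049, 0.1670], p = 1.0e-17
direct   = total-mediated  = 0.1027
proportion mediated        = 57.0% [43.9%, 70.0%]  (true 54.5%)
pleiotropy flags: none
```

Each leg is an IVW fit on independently selected instruments; the
proportion CI scales the mediated-effect CI by the total effect. The other
examples cover I/O and harmonization (`01`), instrument selection (`02`),
the five estimators plus the sensitivity battery (`03`), and the full
screen → reverse-MR → mediation workflow with FDR tiers and an exclusion
log (`05`).

A thin CLI wraps the same functions:

```sh
mrmediate simulate --seed 11 --out-dir sim/
mrmediate all --exposure sim/exposure.tsv --mediator sim/mediator.tsv \
    --outcome sim/outcome.tsv --seed 5 --out-dir out/
```

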