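"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator emulates the study design every stage of the pipeline
consumes: a continuous exposure panel (immune-trait-like, default n=3,757),
a continuous mediator panel (metabolite-like, default n=8,299) and a binary
outcome on the log-odds scale, measured in three non-overlapping samples of
independent SNPs.

Structural model per SNP j (effects in SD units of the trait):

- a ``prop_causal`` fraction of SNPs carries an exposure effect
  gamma_j ~ N(0, gamma_sd²);
- a disjoint ``prop_mediator_causal`` fraction carries a mediator-specific
  effect delta_j ~ N(0, gamma_sd²) — these are the mediator's own
  instruments, without which the mediator->outcome leg of two-step MR has
  nothing to stand on;
- true mediator effect  = theta_xm*gamma_j + delta_j;
- true outcome effect   = (theta_xm*theta_my + theta_xy_direct)*gamma_j
  + theta_my*delta_j + sign(gamma_j)*alpha_j, where alpha_j is a direct
  (pleiotropic) outcome effect ~ N(pleiotropy_mean, pleiotropy_sd²) for a
  ``pleiotropy_frac`` fraction of the exposure's causal SNPs.  Directional
  pleiotropy is oriented relative to the exposure-increasing allele
  (``sign(gamma_j)``), the convention under which a nonzero
  ``pleiotropy_mean`` biases the Wald ratios in a common direction and is
  what the Egger intercept estimates;
- estimated betas add independent N(0, se_j²) noise per trait with
  se_j = (2 p_j (1-p_j) n)^(-1/2) for standardized continuous traits,
  inflated by (phi(1-phi))^(-1/2) at case fraction phi for the binary
  outcome.

SNPs are placed on 22 chromosomes at spacing beyond the default clump
window, so distance-clumping is a no-op by construction and the instrument
count is governed purely by the association thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import COLUMNS, GwasSumStats

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_ALL_PAIRS = _NONPALINDROMIC_PAIRS + _PALINDROMIC_PAIRS

#: Base-pair spacing between simulated SNPs on a chromosome — beyond the
#: default 10,000 kb clump window.
SNP_SPACING_BP = 10_000 * 1000 + 1


@dataclass
class SimulationConfig:
    """Ground-truth structural parameters for a synthetic triple.

    Sample-size defaults mirror the study design the generator emulates
    (immune-trait exposures n=3,757; metabolite mediators n=8,299); the
    binary outcome sample defaults to 10,000 at a balanced case fraction.
    ``theta_my`` and ``theta_xy_direct`` are on the log-odds scale.
    """

    n_snp: int = 500
    n_exposure: int = 3757
    n_mediator: int = 8299
    n_outcome: int = 10_000
    prop_causal: float = 0.1
    prop_mediator_causal: float = 0.1
    gamma_sd: float = 0.15
    theta_xm: float = 0.4
    theta_my: float = 0.3
    theta_xy_direct: float = 0.1
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.05
    maf_range: tuple = (0.05, 0.5)
    case_fraction: float = 0.5
    palindromic_snps: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        problems = []
        for name in ("prop_causal", "prop_mediator_causal", "pleiotropy_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                problems.append(f"{name}={v} outside [0,1]")
        if self.prop_causal + self.prop_mediator_causal > 1:
            problems.append("prop_causal + prop_mediator_causal > 1 (sets must be disjoint)")
        for name in ("n_exposure", "n_mediator", "n_outcome"):
            if getattr(self, name) < 100:
                problems.append(f"{name} < 100")
        if self.n_snp < 1:
            problems.append("n_snp < 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            problems.append(f"maf_range={self.maf_range} not within (0, 0.5]")
        if not 0 < self.case_fraction < 1:
            problems.append("case_fraction outside (0,1)")
        if self.seed is None:
            problems.append("seed is mandatory")
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))


@dataclass
class SimulationTruth:
    """Per-SNP true effects and the structural parameters that generated them."""

    snp: np.ndarray
    gamma: np.ndarray          # exposure effects (0 for non-causal)
    delta: np.ndarray          # mediator-specific effects
    alpha: np.ndarray          # direct (pleiotropic) outcome effects
    beta_exposure: np.ndarray
    beta_mediator: np.ndarray
    beta_outcome: np.ndarray
    theta_xm: float
    theta_my: float
    theta_xy_direct: float
    true_total: float = field(init=False)
    true_mediated: float = field(init=False)
    true_proportion_pct: float = field(init=False)

    def __post_init__(self) -> None:
        self.true_mediated = self.theta_xm * self.theta_my
        self.true_total = self.true_mediated + self.theta_xy_direct
        self.true_proportion_pct = (
            100.0 * self.true_mediated / self.true_total if self.true_total != 0 else float("nan")
        )


def _snp_map(n_snp: int, prefix: str = "rs"):
    """Ids, chromosomes and positions: 22 chromosomes, clump-window-proof spacing."""
    j = np.arange(n_snp)
    snp = np.array([f"{prefix}{i + 1}" for i in j])
    chrom = (j % 22 + 1).astype(str)
    bp = 1 + (j // 22) * SNP_SPACING_BP
    return snp, chrom, bp


def _alleles(rng: np.random.Generator, n_snp: int, palindromic: bool):
    pairs = _ALL_PAIRS if palindromic else _NONPALINDROMIC_PAIRS
    idx = rng.integers(0, len(pairs), n_snp)
    ea = np.array([pairs[i][0] for i in idx])
    oa = np.array([pairs[i][1] for i in idx])
    return ea, oa


def _observe(rng, true_beta, se, snp, chrom, bp, ea, oa, eaf, n, trait_id, trait_type):
    """One trait's noisy summary statistics around its true per-SNP effects."""
    beta_hat = rng.normal(true_beta, se)
    pval = 2.0 * stats.norm.sf(np.abs(beta_hat / se))
    np.clip(pval, np.nextafter(0, 1), 1.0, out=pval)
    df = pd.DataFrame({
        "SNP": snp, "CHR": chrom, "BP": bp, "EA": ea, "OA": oa,
        "EAF": eaf, "BETA": beta_hat, "SE": se, "P": pval,
        "N": np.full(len(snp), n, dtype=np.int64),
    })[COLUMNS]
    return GwasSumStats(trait_id, trait_type, df)


def simulate_triple(cfg: SimulationConfig):
    """Generate (exposure, mediator, outcome, truth) for one seeded replicate.

    Identical configs (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snp
    snp, chrom, bp = _snp_map(n)
    ea, oa = _alleles(rng, n, cfg.palindromic_snps)
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], n)

    u = rng.random(n)
    exp_causal = u < cfg.prop_causal
    med_causal = (u >= cfg.prop_causal) & (u < cfg.prop_causal + cfg.prop_mediator_causal)

    gamma = np.where(exp_causal, rng.normal(0.0, cfg.gamma_sd, n), 0.0)
    delta = np.where(med_causal, rng.normal(0.0, cfg.gamma_sd, n), 0.0)
    alpha = np.zeros(n)
    if cfg.pleiotropy_frac > 0:
        pleio = exp_causal & (rng.random(n) < cfg.pleiotropy_frac)
        alpha = np.where(pleio, rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, n), 0.0)

    beta_x = gamma
    beta_m = cfg.theta_xm * gamma + delta
    beta_y = (cfg.theta_xm * cfg.theta_my + cfg.theta_xy_direct) * gamma \
        + cfg.theta_my * delta + np.where(gamma < 0, -1.0, 1.0) * alpha

    var_g = 2.0 * maf * (1.0 - maf)
    se_x = (var_g * cfg.n_exposure) ** -0.5
    se_m = (var_g * cfg.n_mediator) ** -0.5
    phi = cfg.case_fraction
    se_y = (var_g * cfg.n_outcome) ** -0.5 / np.sqrt(phi * (1.0 - phi))

    exposure = _observe(rng, beta_x, se_x, snp, chrom, bp, ea, oa, maf,
                        cfg.n_exposure, "sim_exposure", "continuous")
    mediator = _observe(rng, beta_m, se_m, snp, chrom, bp, ea, oa, maf,
                        cfg.n_mediator, "sim_mediator", "continuous")
    outcome = _observe(rng, beta_y, se_y, snp, chrom, bp, ea, oa, maf,
                       cfg.n_outcome, "sim_outcome", "binary")
    truth = SimulationTruth(snp, gamma, delta, alpha, beta_x, beta_m, beta_y,
                            cfg.theta_xm, cfg.theta_my, cfg.theta_xy_direct)
    return exposure, mediator, outcome, truth


def simulate_panel(cfg: SimulationConfig, n_traits: int, n_causal_traits: int,
                   theta_panel: float | None = None):
    """A screening panel: ``n_traits`` exposures sharing one binary outcome.

    The first ``n_causal_traits`` traits carry a causal effect on the outcome
    (``theta_panel``, defaulting to the config's total effect
    theta_xm*theta_my + theta_xy_direct); each trait has its own disjoint SNP
    block, so the outcome file covers ``n_traits * n_snp`` SNPs.

    Returns (traits, outcome, labels) with ``labels[t]`` True for the
    injected causal traits.
    """
    if n_causal_traits > n_traits:
        raise ValueError("n_causal_traits cannot exceed n_traits")
    theta = (cfg.theta_xm * cfg.theta_my + cfg.theta_xy_direct
             if theta_panel is None else theta_panel)
    rng = np.random.default_rng(cfg.seed)
    total_snp = cfg.n_snp * n_traits
    snp, chrom, bp = _snp_map(total_snp)
    ea, oa = _alleles(rng, total_snp, cfg.palindromic_snps)
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], total_snp)
    var_g = 2.0 * maf * (1.0 - maf)
    se_x = (var_g * cfg.n_exposure) ** -0.5
    phi = cfg.case_fraction
    se_y = (var_g * cfg.n_outcome) ** -0.5 / np.sqrt(phi * (1.0 - phi))

    causal_snp = rng.random(total_snp) < cfg.prop_causal
    gamma = np.where(causal_snp, rng.normal(0.0, cfg.gamma_sd, total_snp), 0.0)

    labels = [t < n_causal_traits for t in range(n_traits)]
    beta_y_true = np.zeros(total_snp)
    traits = []
    for t in range(n_traits):
        block = slice(t * cfg.n_snp, (t + 1) * cfg.n_snp)
        beta_x_true = np.zeros(total_snp)
        beta_x_true[block] = gamma[block]
        if labels[t]:
            beta_y_true[block] = theta * gamma[block]
        traits.append(_observe(
            rng, beta_x_true[block], se_x[block], snp[block], chrom[block],
            bp[block], ea[block], oa[block], maf[block], cfg.n_exposure,
            f"sim_trait_{t:03d}", "continuous"))
    outcome = _observe(rng, beta_y_true, se_y, snp, chrom, bp, ea, oa, maf,
                       cfg.n_outcome, "sim_outcome", "binary")
    return traits, outcome, labels


def with_seed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``cfg`` with a different seed (for replicate loops)."""
    return replace(cfg, seed=int(seed))
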