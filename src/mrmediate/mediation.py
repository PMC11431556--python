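"""Two-step MR mediation: decompose an exposure->outcome effect through a mediator.

The mediated (indirect) effect is the product of coefficients
``beta1 * beta2`` — beta1 the IVW effect of the exposure on the mediator,
beta2 the IVW effect of the mediator on the outcome — with a first-order
delta-method standard error sqrt(beta1²·se2² + beta2²·se1²).  The direct
effect is total - mediated, and the mediation proportion is
100·mediated/total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import Z95, ivw, pval_from_estimate
from .instruments import InstrumentSelectionConfig, prepare_instruments, select_exposure_snps
from .sensitivity import egger_intercept_test
from .sumstats import GwasSumStats, HarmonizedSet

logger = logging.getLogger(__name__)


@dataclass
class MediationResult:
    """One (exposure, mediator, outcome) decomposition — a mediation-table row."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    total: float
    se_total: float
    mediated: float
    mediated_se: float
    mediated_ci_low: float
    mediated_ci_high: float
    mediated_pval: float
    direct: float
    proportion_pct: float
    proportion_ci: tuple
    flags: list = field(default_factory=list)


def mediated_effect(beta1: float, se1: float, beta2: float, se2: float):
    """Product-of-coefficients mediated effect with delta-method uncertainty.

    Returns (point, se, (ci_low, ci_high), pval); the 95% CI is
    point -+ 1.959964*se and the p-value two-sided normal.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("se1 and se2 must be positive")
    point = beta1 * beta2
    se = float(np.sqrt(beta1 ** 2 * se2 ** 2 + beta2 ** 2 * se1 ** 2))
    if se == 0:  # both coefficients exactly zero
        return point, se, (point, point), 1.0
    ci = (point - Z95 * se, point + Z95 * se)
    return point, se, ci, pval_from_estimate(point, se)


def direct_effect(total: float, mediated: float) -> float:
    """Direct effect: total minus mediated."""
    return total - mediated


def mediation_proportion(mediated: float, total: float) -> float:
    """Mediation proportion in percent, 100*mediated/total.

    Negative when the mediated and total effects have opposite signs
    (inconsistent mediation / suppression), which is logged.
    """
    if total == 0:
        raise ValueError("mediation proportion undefined for total effect 0")
    pct = 100.0 * mediated / total
    if pct < 0:
        logger.warning("mediated and total effects have opposite signs "
                       "(suppression); proportion is negative")
    return pct


def proportion_ci(mediated_ci, total: float):
    """Proportion CI by scaling the mediated-effect CI by 100/total.

    Treats the total effect as fixed (its uncertainty is dominated by the
    mediated effect's in typical two-step settings); always returned sorted
    (low, high).  See :func:`proportion_ci_bootstrap` for an alternative
    that propagates uncertainty in the total.
    """
    if total == 0:
        raise ValueError("proportion CI undefined for total effect 0")
    a, b = (100.0 * mediated_ci[0] / total, 100.0 * mediated_ci[1] / total)
    return (min(a, b), max(a, b))


def proportion_ci_bootstrap(beta1, se1, beta2, se2, total, se_total,
                            n_boot: int = 10_000, seed: int | None = None,
                            level: float = 0.95):
    """Seeded parametric-bootstrap CI for the mediation proportion.

    Draws (beta1, beta2, total) from independent normals and takes the
    percentile interval of 100*beta1*beta2/total.  Draws where the total
    crosses zero are rare under any detectable total effect but can inflate
    the tails; they are retained (the percentile interval is robust to
    them), so a very weak total effect yields an honestly wide interval.
    """
    rng = np.random.default_rng(seed)
    b1 = rng.normal(beta1, se1, n_boot)
    b2 = rng.normal(beta2, se2, n_boot)
    t = rng.normal(total, se_total, n_boot)
    props = 100.0 * b1 * b2 / t
    alpha = (1 - level) / 2
    lo, hi = np.quantile(props, [alpha, 1 - alpha])
    return float(lo), float(hi)


def assemble_mediation(exposure_id, mediator_id, outcome_id,
                       beta1, se1, beta2, se2, total, se_total,
                       flags=None) -> MediationResult:
    """Build a MediationResult from the three leg estimates (exact identities hold)."""
    point, se, ci, pval = mediated_effect(beta1, se1, beta2, se2)
    direct = direct_effect(total, point)
    prop = mediation_proportion(point, total) if total != 0 else float("nan")
    pci = proportion_ci(ci, total) if total != 0 else (float("nan"), float("nan"))
    return MediationResult(
        exposure_id, mediator_id, outcome_id,
        float(beta1), float(se1), float(beta2), float(se2),
        float(total), float(se_total),
        float(point), float(se), float(ci[0]), float(ci[1]), float(pval),
        float(direct), float(prop), pci, list(flags or []),
    )


def run_mediation(exposure: GwasSumStats, mediator: GwasSumStats, outcome: GwasSumStats,
                  cfg: InstrumentSelectionConfig | None = None,
                  ivw_model: str = "multiplicative_random"):
    """Full two-step MR mediation for one (exposure, mediator, outcome) triple.

    - beta1: IVW of exposure->mediator, instruments selected on the exposure;
    - beta2: IVW of mediator->outcome, instruments selected on the mediator,
      excluding SNPs that also qualify as exposure instruments (so the leg's
      exclusion restriction holds in the presence of a direct
      exposure->outcome path);
    - total: IVW of exposure->outcome with the same instrument rules as the
      main screen.

    The Egger intercept is tested on each leg and significant legs
    (p < 0.05) flagged.  Returns (MediationResult | None, reason) — the
    result is withheld with a reason string when any leg has too few
    instruments.
    """
    cfg = cfg or InstrumentSelectionConfig()

    h1 = prepare_instruments(exposure, mediator, cfg, apply_outcome_filter=False)
    if h1.k < 2:
        return None, f"exposure->mediator leg has {h1.k} instrument(s)"
    est1 = ivw(h1, model=ivw_model)

    exposure_instruments = set(select_exposure_snps(exposure, cfg.exposure_p_threshold).data["SNP"])
    cfg2 = InstrumentSelectionConfig(
        exposure_p_threshold=cfg.exposure_p_threshold,
        outcome_p_threshold=cfg.outcome_p_threshold,
        clump_r2=cfg.clump_r2,
        clump_window_kb=cfg.clump_window_kb,
        f_min=cfg.f_min,
        excluded_snps=cfg.excluded_snps | exposure_instruments,
    )
    h2 = prepare_instruments(mediator, outcome, cfg2, apply_outcome_filter=False)
    if h2.k < 2:
        return None, f"mediator->outcome leg has {h2.k} instrument(s)"
    est2 = ivw(h2, model=ivw_model)

    h3 = prepare_instruments(exposure, outcome, cfg, apply_outcome_filter=False)
    if h3.k < 2:
        return None, f"exposure->outcome leg has {h3.k} instrument(s)"
    est3 = ivw(h3, model=ivw_model)

    flags = []
    for name, h in (("exposure->mediator", h1), ("mediator->outcome", h2),
                    ("exposure->outcome", h3)):
        if h.k >= 3:
            _, _, p = egger_intercept_test(h)
            if p < 0.05:
                flags.append(f"egger_intercept:{name}")

    res = assemble_mediation(
        exposure.trait_id, mediator.trait_id, outcome.trait_id,
        est1.beta, est1.se, est2.beta, est2.se, est3.beta, est3.se,
        flags=flags,
    )
    return res, None
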