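"""Seeded simulation studies: calibration, parameter recovery, mediation recovery.

These drive both the statistical-validation tests and the reproduction
script.  Each study returns plain floats computed from scratch at call time;
instrument sets are built with the estimation chain (association selection,
clumping, harmonization, weak-instrument filter) — the outcome-association
screen is a forward-screening guard, not part of the estimator contract
being validated (see the methods note).

Problem sizes follow the canonical validation conditions: ~50 instruments
from GWAS samples of 10,000, a true causal effect of 0.3, and the
(0.4, 0.3, 0.1) mediation triple whose true mediated proportion is
0.12/0.22 = 54.5%.
"""

from __future__ import annotations

import numpy as np

from .estimators import egger, ivw
from .instruments import prepare_instruments
from .mediation import run_mediation
from .sensitivity import cochran_q, mr_presso
from .simulate import SimulationConfig, simulate_triple, with_seed

#: Null-simulation conditions (all structural effects zero).
NULL_CONFIG = SimulationConfig(
    n_snp=300, n_exposure=10_000, n_mediator=10_000, n_outcome=10_000,
    prop_causal=0.15, prop_mediator_causal=0.0,
    theta_xm=0.0, theta_my=0.0, theta_xy_direct=0.0, seed=0)

#: Recovery conditions: ~50 instruments, true causal effect 0.3.
RECOVERY_CONFIG = SimulationConfig(
    n_snp=750, n_exposure=10_000, n_mediator=10_000, n_outcome=10_000,
    prop_causal=0.1, prop_mediator_causal=0.0,
    theta_xm=0.0, theta_my=0.0, theta_xy_direct=0.3, seed=0)

#: Directional-pleiotropy conditions: 30% of instruments carry a direct
#: outcome effect with mean 0.05, so the mean pleiotropy is 0.015.
PLEIOTROPY_CONFIG = SimulationConfig(
    n_snp=750, n_exposure=10_000, n_mediator=10_000, n_outcome=10_000,
    prop_causal=0.1, prop_mediator_causal=0.0,
    theta_xm=0.0, theta_my=0.0, theta_xy_direct=0.3,
    pleiotropy_frac=0.3, pleiotropy_mean=0.05, pleiotropy_sd=0.01, seed=0)

#: Mediation triple (0.4, 0.3, 0.1): true mediated proportion 54.5%.
MEDIATION_CONFIG = SimulationConfig(seed=0)


def _estimation_instruments(exposure, outcome):
    return prepare_instruments(exposure, outcome, apply_outcome_filter=False)


def _replicate_seeds(seed: int, n: int) -> np.ndarray:
    """Decorrelated per-replicate seeds below 2^31 from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) % (2 ** 31)


def null_calibration(seed: int, n_reps: int = 2000, presso_n_sim: int = 500,
                     alpha: float = 0.05):
    """Rejection rates of IVW, Cochran's Q and the MR-PRESSO global test
    under the all-null simulation; each should sit near ``alpha``.

    Returns dict with rates (fractions) and the replicate count used.
    """
    rej_ivw = rej_q = rej_presso = n_used = 0
    seeds = _replicate_seeds(seed, n_reps)
    for r in range(n_reps):
        e, _, o, _ = simulate_triple(with_seed(NULL_CONFIG, seeds[r]))
        h = _estimation_instruments(e, o)
        if h.k < 4:
            continue
        n_used += 1
        rej_ivw += ivw(h).pval < alpha
        rej_q += cochran_q(h, "ivw")[2] < alpha
        g, _, _ = mr_presso(h, n_sim=presso_n_sim, seed=int(seeds[r]))
        rej_presso += g < alpha
    return {
        "ivw_rejection_rate": rej_ivw / n_used,
        "q_rejection_rate": rej_q / n_used,
        "presso_rejection_rate": rej_presso / n_used,
        "n": n_used,
    }


def ivw_recovery(seed: int, n_reps: int = 200):
    """Mean IVW estimate across replicates of the recovery conditions.

    Returns dict with the mean estimate, its bias against the true 0.3,
    the Monte-Carlo SE of the mean, and the mean instrument count.
    """
    betas, ks = [], []
    seeds = _replicate_seeds(seed, n_reps)
    for r in range(n_reps):
        e, _, o, _ = simulate_triple(with_seed(RECOVERY_CONFIG, seeds[r]))
        h = _estimation_instruments(e, o)
        if h.k < 2:
            continue
        betas.append(ivw(h).beta)
        ks.append(h.k)
    betas = np.asarray(betas)
    return {
        "mean_beta": float(betas.mean()),
        "bias": float(betas.mean() - RECOVERY_CONFIG.theta_xy_direct),
        "mc_se": float(betas.std(ddof=1) / np.sqrt(len(betas))),
        "mean_k": float(np.mean(ks)),
        "n": len(betas),
    }


def egger_pleiotropy_recovery(seed: int, n_reps: int = 200):
    """Mean Egger intercept under 30% directional pleiotropy.

    The injected mean pleiotropy per instrument is
    pleiotropy_frac * pleiotropy_mean = 0.015.
    """
    cfg = PLEIOTROPY_CONFIG
    target = cfg.pleiotropy_frac * cfg.pleiotropy_mean
    intercepts = []
    seeds = _replicate_seeds(seed, n_reps)
    for r in range(n_reps):
        e, _, o, _ = simulate_triple(with_seed(cfg, seeds[r]))
        h = _estimation_instruments(e, o)
        if h.k < 3:
            continue
        _, intercept, _, _ = egger(h)
        intercepts.append(intercept)
    intercepts = np.asarray(intercepts)
    return {
        "mean_intercept": float(intercepts.mean()),
        "target": float(target),
        "mc_se": float(intercepts.std(ddof=1) / np.sqrt(len(intercepts))),
        "n": len(intercepts),
    }


def mediation_recovery(seed: int, n_reps: int = 100):
    """Mean recovered mediation proportion across full two-step runs.

    True proportion is 100 * theta_xm*theta_my / (theta_xm*theta_my +
    theta_xy_direct) = 54.5% under the default triple.
    """
    cfg = MEDIATION_CONFIG
    props = []
    seeds = _replicate_seeds(seed, n_reps)
    for r in range(n_reps):
        e, m, o, _ = simulate_triple(with_seed(cfg, seeds[r]))
        res, _ = run_mediation(e, m, o)
        if res is not None:
            props.append(res.proportion_pct)
    props = np.asarray(props)
    truth = 100.0 * cfg.theta_xm * cfg.theta_my / (
        cfg.theta_xm * cfg.theta_my + cfg.theta_xy_direct)
    return {
        "mean_proportion_pct": float(props.mean()),
        "true_proportion_pct": float(truth),
        "mc_se": float(props.std(ddof=1) / np.sqrt(len(props))),
        "n": len(props),
    }
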