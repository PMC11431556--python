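"""Sensitivity diagnostics: heterogeneity, pleiotropy, leave-one-out, MR-PRESSO.

Verdicts are reported, never silently acted on — the pipeline excludes
instruments only via the MR-PRESSO outlier test, and excludes whole
mediation legs only on the Egger-intercept flag.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import MrEstimate, egger, ivw, pval_from_estimate
from .sumstats import HarmonizedSet

logger = logging.getLogger(__name__)


@dataclass
class SensitivityReport:
    """Battery of diagnostics for one exposure/outcome instrument set."""

    q_ivw: float
    q_ivw_df: int
    q_ivw_pval: float
    q_egger: float | None
    q_egger_df: int | None
    q_egger_pval: float | None
    egger_intercept: float | None
    egger_intercept_se: float | None
    egger_intercept_pval: float | None
    loo: list = field(default_factory=list)  # (snp_id, MrEstimate, flagged)
    loo_flagged: list = field(default_factory=list)
    presso_global_pval: float | None = None
    presso_outliers: list = field(default_factory=list)


def cochran_q(h: HarmonizedSet, method: str = "ivw"):
    """Cochran's Q heterogeneity statistic.

    Q = sum_j w_j * resid_j² with w_j = 1/se_y_j² and resid_j the residual of
    beta_y_j from the fitted model (IVW: through the origin at the
    fixed-effect estimate, df k-1; Egger: free intercept, df k-2).  The
    p-value is the upper chi-square tail.
    """
    d = h.data
    bx = d["beta_x"].to_numpy(float)
    by = d["beta_y"].to_numpy(float)
    sy = d["se_y"].to_numpy(float)
    k = len(bx)
    w = sy ** -2.0
    if method == "ivw":
        if k < 2:
            raise ValueError("cochran_q(ivw) requires k >= 2")
        beta = float(np.sum(bx * by * w) / np.sum(bx * bx * w))
        resid = by - beta * bx
        df = k - 1
    elif method == "egger":
        if k < 3:
            raise ValueError("cochran_q(egger) requires k >= 3")
        sign = np.where(bx < 0, -1.0, 1.0)
        bxo, byo = bx * sign, by * sign
        sw = w.sum()
        xbar = np.sum(w * bxo) / sw
        ybar = np.sum(w * byo) / sw
        slope = float(np.sum(w * (bxo - xbar) * (byo - ybar)) / np.sum(w * (bxo - xbar) ** 2))
        resid = byo - (ybar - slope * xbar) - slope * bxo
        df = k - 2
    else:
        raise ValueError(f"unknown method {method!r}")
    q = float(np.sum(w * resid ** 2))
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept_test(h: HarmonizedSet):
    """Egger intercept with se and two-sided normal p (directional-pleiotropy test)."""
    _, intercept, intercept_se, pval = egger(h)
    return intercept, intercept_se, pval


def leave_one_out(h: HarmonizedSet, ivw_model: str = "multiplicative_random"):
    """k IVW fits, each omitting one SNP.

    Returns a list of (snp_id, MrEstimate, flagged); an omission is flagged
    when it changes the sign of beta or moves it outside the full-set CI —
    the classic single-SNP-dominance check.
    """
    k = h.k
    if k < 3:
        raise ValueError("leave_one_out requires k >= 3")
    full = ivw(h, model=ivw_model)
    snps = h.data["SNP"].to_numpy()
    out = []
    for j in range(k):
        mask = np.ones(k, dtype=bool)
        mask[j] = False
        est = ivw(h.subset(mask), model=ivw_model)
        flagged = (np.sign(est.beta) != np.sign(full.beta)) or not (
            full.ci_low <= est.beta <= full.ci_high
        )
        out.append((str(snps[j]), est, bool(flagged)))
    return out


def _loo_predictions(bx, by, w):
    """Leave-one-out IVW slope for each SNP, vectorized.

    beta_{-j} = (S1 - bx_j by_j w_j) / (S2 - bx_j² w_j).
    """
    s1 = np.sum(bx * by * w)
    s2 = np.sum(bx * bx * w)
    return (s1 - bx * by * w) / (s2 - bx * bx * w)


def mr_presso(h: HarmonizedSet, n_sim: int = 1000, seed: int | None = None,
              sig: float = 0.05):
    """MR-PRESSO global pleiotropy test and per-SNP outlier test.

    Global: the observed residual sum of squares of each beta_y_j about its
    leave-one-out IVW prediction beta_{-j}*bx_j is ranked within a null
    distribution built from ``n_sim`` parametric simulations (beta_y_j drawn
    N(beta_{-j}*bx_j, se_y_j), leave-one-out RSS recomputed per draw);
    global_pval = (1 + #{RSS_sim >= RSS_obs}) / (n_sim + 1).

    Outliers: each SNP's observed squared residual ranked in its own
    simulated null, Bonferroni-adjusted at ``sig``.  ``corrected`` is the
    IVW estimate after removing outliers (None if fewer than 2 SNPs remain).

    Returns (global_pval, outliers, corrected).  Bit-reproducible for a
    fixed seed.
    """
    k = h.k
    if k < 4:
        raise ValueError("mr_presso requires k >= 4 instruments")
    if n_sim < 100:
        warnings.warn(f"mr_presso with n_sim={n_sim} < 100 gives a coarse p-value")
    d = h.data
    bx = d["beta_x"].to_numpy(float)
    by = d["beta_y"].to_numpy(float)
    sy = d["se_y"].to_numpy(float)
    w = sy ** -2.0

    beta_loo = _loo_predictions(bx, by, w)
    pred = beta_loo * bx
    obs_res2 = (by - pred) ** 2
    rss_obs = float(obs_res2.sum())

    rng = np.random.default_rng(seed)
    by_sim = rng.normal(pred, sy, size=(n_sim, k))
    # per-simulation leave-one-out predictions (vectorized over sims)
    s1 = np.sum(bx * by_sim * w, axis=1, keepdims=True)
    s2 = float(np.sum(bx * bx * w))
    beta_loo_sim = (s1 - bx * by_sim * w) / (s2 - bx * bx * w)
    res2_sim = (by_sim - beta_loo_sim * bx) ** 2
    rss_sim = res2_sim.sum(axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    outliers: list[str] = []
    if global_pval < sig:
        p_snp = (1 + np.sum(res2_sim >= obs_res2, axis=0)) / (n_sim + 1)
        outlier_mask = p_snp < sig / k  # Bonferroni
        outliers = [str(s) for s in d["SNP"].to_numpy()[outlier_mask]]
        if len(outliers) > math.ceil(k / 2):
            warnings.warn(
                f"mr_presso flagged {len(outliers)}/{k} SNPs as outliers; "
                "instrument set may be degenerate")

    corrected = None
    if outliers:
        mask = ~d["SNP"].isin(outliers).to_numpy()
        if mask.sum() >= 2:
            corrected = ivw(h.subset(mask))
    else:
        corrected = ivw(h) if k >= 2 else None
    return global_pval, outliers, corrected


def sensitivity_report(h: HarmonizedSet, n_sim: int = 1000, seed: int | None = None,
                       sig: float = 0.05, ivw_model: str = "multiplicative_random") -> SensitivityReport:
    """Assemble the full diagnostic battery for one instrument set."""
    k = h.k
    q, df, qp = cochran_q(h, "ivw")
    qe = dfe = qpe = None
    eint = eint_se = eint_p = None
    loo: list = []
    flagged: list = []
    if k >= 3:
        qe, dfe, qpe = cochran_q(h, "egger")
        eint, eint_se, eint_p = egger_intercept_test(h)
        loo = leave_one_out(h, ivw_model=ivw_model)
        flagged = [snp for snp, _, fl in loo if fl]
    g = None
    outliers: list = []
    if k >= 4:
        g, outliers, _ = mr_presso(h, n_sim=n_sim, seed=seed, sig=sig)
    return SensitivityReport(
        q_ivw=q, q_ivw_df=df, q_ivw_pval=qp,
        q_egger=qe, q_egger_df=dfe, q_egger_pval=qpe,
        egger_intercept=eint, egger_intercept_se=eint_se, egger_intercept_pval=eint_p,
        loo=loo, loo_flagged=flagged,
        presso_global_pval=g, presso_outliers=outliers,
    )
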