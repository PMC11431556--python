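"""Causal estimators for two-sample MR.

Five methods operate on a :class:`~mrmediate.sumstats.HarmonizedSet` of
per-SNP effect pairs (beta_x, se_x, beta_y, se_y):

- :func:`ivw` — inverse-variance-weighted meta-analysis of Wald ratios,
  equivalently the zero-intercept weighted regression of beta_y on beta_x
  with weights 1/se_y²; the primary estimator.
- :func:`egger` — the same regression with a free intercept; a nonzero
  intercept estimates directional horizontal pleiotropy.
- :func:`weighted_median` — the weighted median of per-SNP Wald ratios;
  consistent when at least half the weight comes from valid instruments.
- :func:`mode_estimate` — simple or weighted mode of the Wald-ratio density
  (normal-kernel smoothing, modified Silverman bandwidth).
- :func:`wald_ratio` — single-instrument fallback.

All p-values are two-sided normal-theory.  Estimates are reported on the
beta scale together with the odds-ratio scale (exp of beta and its CI).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sumstats import HarmonizedSet

logger = logging.getLogger(__name__)

Z95 = float(stats.norm.ppf(0.975))  # 1.959964...


@dataclass
class MrEstimate:
    """One method's causal estimate.

    ``beta`` is the causal effect per unit (SD) of exposure, on the log-odds
    scale when the outcome is binary; ``or_point``/``or_low``/``or_high``
    are its exponentiated (odds-ratio) counterparts.
    """

    method: str
    beta: float
    se: float
    pval: float
    ci_low: float
    ci_high: float
    or_point: float
    or_low: float
    or_high: float
    n_snp: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def pval_from_estimate(beta: float, se: float) -> float:
    """Two-sided normal-theory p-value, 2*Phi(-|beta/se|)."""
    if se <= 0:
        raise ValueError("se must be positive")
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def to_odds_ratio(beta: float, se: float, level: float = 0.95):
    """Odds-ratio point and confidence limits, exp(beta -+ z*se)."""
    if se < 0:
        raise ValueError("se must be non-negative")
    if not 0 < level < 1:
        raise ValueError("level must be in (0,1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def _estimate(method: str, beta: float, se: float, n_snp: int, level: float = 0.95) -> MrEstimate:
    """Assemble an MrEstimate from a beta and normal-theory se."""
    if se > 0:
        p = pval_from_estimate(beta, se)
        z = stats.norm.ppf(0.5 + level / 2.0)
        lo, hi = beta - z * se, beta + z * se
    else:  # degenerate (e.g. all ratios identical): point mass
        p, lo, hi = (1.0 if beta == 0 else 0.0), beta, beta
    o, ol, oh = float(np.exp(beta)), float(np.exp(lo)), float(np.exp(hi))
    return MrEstimate(method, float(beta), float(se), p, float(lo), float(hi), o, ol, oh, int(n_snp))


def _arrays(h: HarmonizedSet):
    d = h.data
    return (d["beta_x"].to_numpy(float), d["se_x"].to_numpy(float),
            d["beta_y"].to_numpy(float), d["se_y"].to_numpy(float))


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> MrEstimate:
    """Single-SNP causal estimate beta_y/beta_x with first-order se |se_y/beta_x|."""
    if beta_x == 0:
        raise ValueError("wald_ratio undefined for beta_x = 0")
    return _estimate("wald_ratio", beta_y / beta_x, abs(se_y / beta_x), 1)


def ivw(h: HarmonizedSet, model: str = "multiplicative_random") -> MrEstimate:
    """Inverse-variance-weighted estimate.

    beta = sum(bx*by/se_y²) / sum(bx²/se_y²).  Under ``fixed`` the se is
    (sum bx²/se_y²)^(-1/2); under ``multiplicative_random`` (default) it is
    inflated by max(1, sqrt(Q/(k-1))) with Q Cochran's Q at the IVW estimate,
    the standard guard against heterogeneity.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    bx, _, by, sy = _arrays(h)
    k = len(bx)
    if k < 2:
        raise ValueError("ivw requires k >= 2 instruments; use wald_ratio for k = 1")
    w = sy ** -2.0
    denom = float(np.sum(bx * bx * w))
    beta = float(np.sum(bx * by * w)) / denom
    se = denom ** -0.5
    if model == "multiplicative_random":
        q = float(np.sum(w * (by - beta * bx) ** 2))
        se *= max(1.0, np.sqrt(q / (k - 1)))
    return _estimate("ivw", beta, se, k)


def egger(h: HarmonizedSet):
    """MR-Egger regression.

    Rows are first oriented so every beta_x >= 0 (the InSIDE-respecting
    convention), then beta_y is regressed on beta_x with a free intercept
    and weights 1/se_y².  The slope se carries multiplicative
    over-dispersion inflation max(1, sqrt(Q'/(k-2))).

    Returns
    -------
    (slope, intercept, intercept_se, intercept_pval)
        ``slope`` is an :class:`MrEstimate`; the intercept triple estimates
        the average directional pleiotropy.
    """
    bx, _, by, sy = _arrays(h)
    k = len(bx)
    if k < 3:
        raise ValueError("egger requires k >= 3 instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = sy ** -2.0
    # closed-form weighted least squares with intercept
    sw = w.sum()
    xbar = np.sum(w * bx) / sw
    ybar = np.sum(w * by) / sw
    sxx = np.sum(w * (bx - xbar) ** 2)
    if sxx == 0:
        raise ValueError("egger undefined: no spread in |beta_x|")
    slope = float(np.sum(w * (bx - xbar) * (by - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = by - intercept - slope * bx
    q = float(np.sum(w * resid ** 2))
    infl = max(1.0, np.sqrt(q / (k - 2)))
    slope_se = float(sxx ** -0.5) * infl
    intercept_se = float(np.sqrt(1.0 / sw + xbar ** 2 / sxx)) * infl
    est = _estimate("egger", slope, slope_se, k)
    return est, intercept, intercept_se, pval_from_estimate(intercept, intercept_se)


def _ratios_weights(h: HarmonizedSet, drop_zero_bx: bool = True):
    """Per-SNP Wald ratios r_j = by/bx and weights bx²/se_y² (ratio inverse variance)."""
    bx, sx, by, sy = _arrays(h)
    nz = bx != 0
    if drop_zero_bx and not nz.all():
        warnings.warn(f"dropping {int((~nz).sum())} SNP(s) with beta_x = 0 from ratio-based estimator")
        bx, sx, by, sy = bx[nz], sx[nz], by[nz], sy[nz]
    r = by / bx
    w = (bx / sy) ** 2
    return r, w, bx, sx, by, sy


def _weighted_median(r: np.ndarray, w: np.ndarray) -> float:
    """Weighted median by cumulative-weight interpolation at 0.5.

    With sorted ratios and normalized weights, s_j = cumsum(w)_j - w_j/2;
    the estimate interpolates linearly between the ratios bracketing
    s = 0.5.
    """
    order = np.argsort(r, kind="stable")
    r, w = r[order], w[order]
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] <= 0.5:
        return float(r[-1])
    below = int(np.searchsorted(s, 0.5, side="left")) - 1
    return float(r[below] + (r[below + 1] - r[below]) * (0.5 - s[below]) / (s[below + 1] - s[below]))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int | None = None) -> MrEstimate:
    """Weighted-median causal estimate with parametric-bootstrap se.

    Weights are the Wald-ratio inverse variances approximated by bx²/se_y².
    The se resamples (beta_x, beta_y) from normals centred on their
    estimates with their SEs, ``n_boot`` times (seeded).
    """
    r, w, bx, sx, by, sy = _ratios_weights(h)
    k = len(r)
    if k < 3:
        raise ValueError("weighted_median requires k >= 3 instruments")
    beta = _weighted_median(r, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        nz = bxb != 0
        boots[b] = _weighted_median(byb[nz] / bxb[nz], (bxb[nz] / sy[nz]) ** 2)
    se = float(np.std(boots, ddof=1))
    return _estimate("weighted_median", beta, se, k)


_MODE_GRID_POINTS = 10_000
_MODE_BOOT_GRID_POINTS = 1024


def _mode_bandwidth(r: np.ndarray, phi: float) -> float:
    """Modified Silverman bandwidth: phi * 0.9 * min(sd, IQR/1.349) * k^(-1/5)."""
    sd = float(np.std(r, ddof=1)) if len(r) > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(r, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return phi * 0.9 * spread * len(r) ** (-0.2)


def _kde_argmax(r: np.ndarray, w: np.ndarray, bandwidth: float, n_grid: int) -> float:
    """Argmax over a fixed grid of the weighted normal-kernel density."""
    lo = r.mean() - 5.0 * np.std(r, ddof=1)
    hi = r.mean() + 5.0 * np.std(r, ddof=1)
    grid = np.linspace(lo, hi, n_grid)
    z = (grid[:, None] - r[None, :]) / bandwidth
    dens = np.exp(-0.5 * z * z) @ (w / w.sum())
    return float(grid[int(np.argmax(dens))])


def mode_estimate(h: HarmonizedSet, weighted: bool = True, phi: float = 1.0,
                  n_boot: int = 1000, seed: int | None = None) -> MrEstimate:
    """Mode-based causal estimate (simple or weighted).

    The per-SNP Wald ratios are smoothed with a normal kernel (bandwidth
    ``phi`` x 0.9 x min(sd, IQR/1.349) x k^(-1/5)); the estimate is the
    density argmax on a 10,000-point grid spanning mean +- 5 sd of the
    ratios.  ``weighted`` uses ratio inverse-variance weights, else uniform.
    The se is a seeded parametric bootstrap (coarser 1,024-point grid per
    replicate).
    """
    r, w_iv, bx, sx, by, sy = _ratios_weights(h)
    k = len(r)
    if k < 3:
        raise ValueError("mode_estimate requires k >= 3 instruments")
    method = "weighted_mode" if weighted else "simple_mode"
    w = w_iv if weighted else np.ones(k)
    bandwidth = _mode_bandwidth(r, phi)
    if bandwidth == 0:  # all ratios identical
        warnings.warn("all Wald ratios identical; mode is the common ratio with se 0")
        return _estimate(method, float(r[0]), 0.0, k)
    beta = _kde_argmax(r, w, bandwidth, _MODE_GRID_POINTS)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        nz = bxb != 0
        rb = byb[nz] / bxb[nz]
        wb = (bxb[nz] / sy[nz]) ** 2 if weighted else np.ones(nz.sum())
        bwb = _mode_bandwidth(rb, phi)
        if bwb == 0:
            boots[b] = rb[0]
        else:
            boots[b] = _kde_argmax(rb, wb, bwb, _MODE_BOOT_GRID_POINTS)
    se = float(np.std(boots, ddof=1))
    return _estimate(method, beta, se, k)


def all_estimators(h: HarmonizedSet, n_boot: int = 1000, seed: int | None = None,
                   ivw_model: str = "multiplicative_random") -> dict[str, MrEstimate]:
    """Run every estimator the instrument count allows; keys are method names."""
    out: dict[str, MrEstimate] = {}
    k = h.k
    if k == 0:
        return out
    if k == 1:
        row = h.data.iloc[0]
        if row["beta_x"] != 0:
            out["wald_ratio"] = wald_ratio(row["beta_x"], row["se_x"], row["beta_y"], row["se_y"])
        return out
    out["ivw"] = ivw(h, model=ivw_model)
    if k >= 3:
        out["egger"] = egger(h)[0]
        out["weighted_median"] = weighted_median(h, n_boot=n_boot, seed=seed)
        out["weighted_mode"] = mode_estimate(h, weighted=True, n_boot=n_boot, seed=seed)
        out["simple_mode"] = mode_estimate(h, weighted=False, n_boot=n_boot, seed=seed)
    return out
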