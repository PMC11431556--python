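"""Workflow orchestration: forward screen, reverse-MR filter, mediation screen.

Each stage is a plain function over :class:`~mrmediate.sumstats.GwasSumStats`
collections; the CLI in :mod:`mrmediate.cli` is a thin wrapper.  Every
excluded trait or pair is recorded with a machine-readable reason code, and
identical inputs + config + seed give byte-identical output tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import all_estimators, ivw
from .instruments import InstrumentSelectionConfig, prepare_instruments
from .mediation import MediationResult, run_mediation
from .multiplicity import assign_tier, bh_fdr
from .sensitivity import SensitivityReport, mr_presso, sensitivity_report
from .sumstats import GwasSumStats

logger = logging.getLogger(__name__)

CANDIDATE_P = 0.05


@dataclass
class PipelineConfig:
    """Configuration shared by every pipeline stage.

    ``seed`` drives all stochastic components (bootstrap SEs, MR-PRESSO
    simulations); each trait gets a stable per-trait derived seed, so
    results do not depend on panel order.
    """

    instruments: InstrumentSelectionConfig = field(default_factory=InstrumentSelectionConfig)
    reverse_p_threshold: float = 5e-5
    ivw_model: str = "multiplicative_random"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    presso_sig: float = 0.05
    palindrome_policy: str = "drop_ambiguous"
    seed: int = 0

    def derived_seed(self, *labels) -> int:
        """Deterministic per-item seed below 2^31, stable across runs."""
        h = 2166136261
        for token in (str(self.seed), *map(str, labels)):
            for ch in token.encode():
                h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
        return h % (2 ** 31)


@dataclass
class ScreenRow:
    """One exposure's screen result (a forest-plot row)."""

    exposure_id: str
    outcome_id: str
    n_snp: int
    estimates: dict
    sensitivity: SensitivityReport | None
    outliers_removed: list
    pval_ivw: float
    fdr_q: float = float("nan")
    tier: str = "none"
    candidate: bool = False


@dataclass
class Exclusion:
    """Machine-readable exclusion-log entry."""

    stage: str
    item: str
    reason: str
    detail: str = ""


def run_screen(exposures, outcome: GwasSumStats, cfg: PipelineConfig | None = None):
    """Two-sample MR screen of every exposure against one outcome.

    Per exposure: instrument selection -> harmonization -> filters ->
    MR-PRESSO outlier removal -> all estimators -> sensitivity battery.
    BH-FDR is applied across the screen's IVW p-values; rows with
    P_IVW < 0.05 are marked candidates.

    Returns (rows, exclusions).
    """
    cfg = cfg or PipelineConfig()
    exposures = list(exposures)
    if not exposures:
        raise ValueError("run_screen requires at least one exposure")
    rows: list[ScreenRow] = []
    exclusions: list[Exclusion] = []
    for exposure in exposures:
        h = prepare_instruments(exposure, outcome, cfg.instruments,
                                palindrome_policy=cfg.palindrome_policy)
        if h.k == 0:
            exclusions.append(Exclusion("screen", exposure.trait_id, "no_instruments"))
            logger.info("screen: %s skipped (no instruments)", exposure.trait_id)
            continue
        seed = cfg.derived_seed(exposure.trait_id, outcome.trait_id)
        removed: list = []
        if h.k >= 4:
            _, outliers, _ = mr_presso(h, n_sim=cfg.presso_n_sim, seed=seed, sig=cfg.presso_sig)
            if outliers:
                keep = ~h.data["SNP"].isin(outliers).to_numpy()
                if keep.sum() >= 2:
                    h = h.subset(keep)
                    removed = outliers
        estimates = all_estimators(h, n_boot=cfg.n_boot, seed=seed, ivw_model=cfg.ivw_model)
        if not estimates:
            exclusions.append(Exclusion("screen", exposure.trait_id, "no_estimable_effect"))
            continue
        primary = estimates.get("ivw") or estimates.get("wald_ratio")
        sens = None
        if h.k >= 2:
            sens = sensitivity_report(h, n_sim=cfg.presso_n_sim, seed=seed,
                                      sig=cfg.presso_sig, ivw_model=cfg.ivw_model)
        rows.append(ScreenRow(exposure.trait_id, outcome.trait_id, h.k,
                              estimates, sens, removed, primary.pval))
    if rows:
        q = bh_fdr([r.pval_ivw for r in rows])
        for r, qv in zip(rows, q):
            r.fdr_q = float(qv)
            r.tier = assign_tier(qv).label
            r.candidate = r.pval_ivw < CANDIDATE_P
    return rows, exclusions


def reverse_mr_filter(candidates, exposures_by_id, outcome: GwasSumStats,
                      cfg: PipelineConfig | None = None):
    """Drop candidates that the outcome itself causally influences.

    For each candidate ScreenRow, MR is run with the outcome as exposure
    (instrument threshold ``cfg.reverse_p_threshold``) and the trait as
    outcome; candidates with reverse P_IVW < 0.05 are removed and logged.
    Candidates whose reverse leg has fewer than 2 instruments cannot be
    tested and are retained with a log entry.

    The reverse leg applies the full instrument chain, including the
    candidate-trait-association filter: when the candidate truly causes the
    outcome, the outcome's apparent instruments are the candidate's own SNPs
    in disguise, and the filter is what keeps them from producing a spurious
    "reverse" signal.

    Returns (retained_rows, exclusions).
    """
    cfg = cfg or PipelineConfig()
    rev_cfg = InstrumentSelectionConfig(
        exposure_p_threshold=cfg.reverse_p_threshold,
        outcome_p_threshold=cfg.instruments.outcome_p_threshold,
        clump_r2=cfg.instruments.clump_r2,
        clump_window_kb=cfg.instruments.clump_window_kb,
        f_min=cfg.instruments.f_min,
        excluded_snps=cfg.instruments.excluded_snps,
    )
    retained: list[ScreenRow] = []
    exclusions: list[Exclusion] = []
    for row in candidates:
        trait = exposures_by_id[row.exposure_id]
        h = prepare_instruments(outcome, trait, rev_cfg,
                                palindrome_policy=cfg.palindrome_policy)
        if h.k < 2:
            logger.info("reverse: %s untestable (%d reverse instruments); retained",
                        row.exposure_id, h.k)
            retained.append(row)
            continue
        est = ivw(h, model=cfg.ivw_model)
        if est.pval < 0.05:
            exclusions.append(Exclusion("reverse", row.exposure_id, "reverse_causal",
                                        f"reverse_p={est.pval:.3g}"))
        else:
            retained.append(row)
    return retained, exclusions


@dataclass
class MediationRow:
    """A mediation-table row: the decomposition plus its FDR tier."""

    result: MediationResult
    fdr_q: float = float("nan")
    tier: str = "none"


def run_mediation_screen(retained_exposures, mediators, outcome: GwasSumStats,
                         cfg: PipelineConfig | None = None):
    """Two-step mediation screen over retained exposures and candidate mediators.

    Exposure->mediator pairs are screened (P_IVW < 0.05); pairs whose
    mediator also passes the mediator->outcome screen are assembled via
    :func:`~mrmediate.mediation.run_mediation`.  The qualifying screens use
    the same instrument rules as the mediation legs they gate (no
    outcome-association filter), so a qualifying pair and its leg estimate
    always rest on the same instruments.  Results with a significant
    Egger intercept on any leg are flagged and excluded (reason
    ``egger_intercept``).  The final table is FDR-tiered on the mediated
    p-values.

    Returns (mediation_rows, exclusions).
    """
    cfg = cfg or PipelineConfig()
    exclusions: list[Exclusion] = []
    # mediator -> outcome screen, once per mediator
    mediator_ok: dict[str, bool] = {}
    for mediator in mediators:
        h = prepare_instruments(mediator, outcome, cfg.instruments,
                                palindrome_policy=cfg.palindrome_policy,
                                apply_outcome_filter=False)
        if h.k < 2:
            mediator_ok[mediator.trait_id] = False
            continue
        mediator_ok[mediator.trait_id] = ivw(h, model=cfg.ivw_model).pval < CANDIDATE_P
    rows: list[MediationRow] = []
    for exposure in retained_exposures:
        for mediator in mediators:
            pair = f"{exposure.trait_id}->{mediator.trait_id}"
            h1 = prepare_instruments(exposure, mediator, cfg.instruments,
                                     palindrome_policy=cfg.palindrome_policy,
                                     apply_outcome_filter=False)
            if h1.k < 2:
                exclusions.append(Exclusion("mediation", pair, "no_instruments"))
                continue
            if ivw(h1, model=cfg.ivw_model).pval >= CANDIDATE_P:
                exclusions.append(Exclusion("mediation", pair, "exposure_mediator_null"))
                continue
            if not mediator_ok[mediator.trait_id]:
                exclusions.append(Exclusion("mediation", pair, "mediator_outcome_null"))
                continue
            res, reason = run_mediation(exposure, mediator, outcome, cfg.instruments,
                                        ivw_model=cfg.ivw_model)
            if res is None:
                exclusions.append(Exclusion("mediation", pair, "leg_failure", reason or ""))
                continue
            egger_flags = [f for f in res.flags if f.startswith("egger_intercept")]
            if egger_flags:
                exclusions.append(Exclusion("mediation", pair, "egger_intercept",
                                            ";".join(egger_flags)))
                continue
            rows.append(MediationRow(res))
    if rows:
        q = bh_fdr([r.result.mediated_pval for r in rows])
        for r, qv in zip(rows, q):
            r.fdr_q = float(qv)
            r.tier = assign_tier(qv).label
    return rows, exclusions


# ---------------------------------------------------------------------------
# tabular serialization


def screen_table(rows) -> pd.DataFrame:
    """Screen rows as a tidy table: one line per (exposure, method)."""
    recs = []
    for r in rows:
        for method, est in r.estimates.items():
            recs.append({
                "exposure": r.exposure_id, "outcome": r.outcome_id,
                "method": method, "nsnp": est.n_snp,
                "beta": est.beta, "se": est.se,
                "ci_low": est.ci_low, "ci_high": est.ci_high,
                "or": est.or_point, "or_low": est.or_low, "or_high": est.or_high,
                "pval": est.pval,
                "fdr_q": r.fdr_q, "tier": r.tier, "candidate": r.candidate,
                "q_ivw_pval": r.sensitivity.q_ivw_pval if r.sensitivity else float("nan"),
                "egger_intercept_pval": (r.sensitivity.egger_intercept_pval
                                         if r.sensitivity and r.sensitivity.egger_intercept_pval is not None
                                         else float("nan")),
                "presso_outliers_removed": ",".join(r.outliers_removed),
            })
    return pd.DataFrame(recs)


def mediation_table(rows) -> pd.DataFrame:
    """Mediation rows in the published-table shape (CIs sorted low, high)."""
    recs = []
    for r in rows:
        m = r.result
        recs.append({
            "exposure": m.exposure_id, "mediator": m.mediator_id, "outcome": m.outcome_id,
            "beta1": m.beta1, "se1": m.se1, "beta2": m.beta2, "se2": m.se2,
            "total": m.total, "se_total": m.se_total,
            "mediated": m.mediated, "mediated_se": m.mediated_se,
            "mediated_ci_low": m.mediated_ci_low, "mediated_ci_high": m.mediated_ci_high,
            "direct": m.direct,
            "proportion_pct": m.proportion_pct,
            "proportion_ci_low": m.proportion_ci[0], "proportion_ci_high": m.proportion_ci[1],
            "pval": m.mediated_pval, "fdr_q": r.fdr_q, "tier": r.tier,
            "flags": ";".join(m.flags),
        })
    return pd.DataFrame(recs)


def exclusion_table(exclusions) -> pd.DataFrame:
    return pd.DataFrame([{"stage": e.stage, "item": e.item,
                          "reason": e.reason, "detail": e.detail} for e in exclusions],
                        columns=["stage", "item", "reason", "detail"])
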