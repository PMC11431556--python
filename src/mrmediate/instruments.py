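"""Instrument-variable selection for two-sample MR.

Five filters produce the instrument set for an exposure/outcome pair:

1. exposure-association threshold (default p < 5e-5);
2. removal of SNPs associated with the outcome (p < 0.05);
3. LD clumping (greedy, distance + optional r² provider);
4. pleiotropic-outlier removal — lives in :mod:`mrmediate.sensitivity`
   (MR-PRESSO) and is applied by the pipeline;
5. weak-instrument removal, F = (beta/se)² < 10.

All thresholds are strict inequalities.  Every filter is a pure subset
operation on its input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .sumstats import GwasSumStats, HarmonizedSet, harmonize

logger = logging.getLogger(__name__)


@dataclass
class InstrumentSelectionConfig:
    """Thresholds governing instrument selection.

    ``clump_window_kb`` defaults to the conventional 10,000 kb window; set it
    to 10 to reproduce a literal 10,000 base-pair window.  ``excluded_snps``
    holds confounder-associated variants supplied by the user (e.g. known
    alcohol/smoking loci) to exclude from every analysis.
    """

    exposure_p_threshold: float = 5e-5
    outcome_p_threshold: float = 0.05
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    f_min: float = 10.0
    excluded_snps: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        bad = []
        for name in ("exposure_p_threshold", "outcome_p_threshold", "clump_r2", "f_min"):
            if getattr(self, name) <= 0:
                bad.append(name)
        if self.clump_window_kb < 0:
            bad.append("clump_window_kb")
        if self.exposure_p_threshold >= 1:
            bad.append("exposure_p_threshold (must be < 1)")
        if bad:
            raise ValueError(f"invalid InstrumentSelectionConfig fields: {bad}")
        self.excluded_snps = frozenset(self.excluded_snps)


def select_exposure_snps(exposure: GwasSumStats, threshold: float = 5e-5) -> GwasSumStats:
    """SNPs associated with the exposure at p < ``threshold`` (strict), order preserved."""
    return exposure.subset((exposure.data["P"] < threshold).to_numpy())


def filter_outcome_associated(h: HarmonizedSet, threshold: float = 0.05) -> HarmonizedSet:
    """Remove rows whose outcome p-value is below ``threshold`` (strict)."""
    return h.subset((h.data["pval_y"] >= threshold).to_numpy())


def clump(records: GwasSumStats, r2_max: float = 0.001, window_kb: int = 10_000,
          ld=None) -> GwasSumStats:
    """Greedy LD clumping.

    SNPs are visited in ascending p-value order (ties broken by SNP id for
    determinism); a SNP is accepted iff no previously accepted SNP on the
    same chromosome lies within ``window_kb`` AND — when an ``ld`` provider
    is given — has r² > ``r2_max`` with it.  Without a provider distance
    alone governs, which is exact for panels of independent SNPs.

    Parameters
    ----------
    ld : callable, optional
        ``ld(snp_a, snp_b) -> float`` returning pairwise r².
    """
    df = records.data.reset_index(drop=True)
    if df.empty:
        return records
    chrom_arr = df["CHR"].to_numpy()
    bp_arr = df["BP"].to_numpy()
    snp_arr = df["SNP"].to_numpy()
    order = np.lexsort((snp_arr, df["P"].to_numpy()))  # ascending p, ties by id
    window_bp = int(window_kb) * 1000
    keep = np.zeros(len(df), dtype=bool)
    kept_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for i in order:
        c, bp, snp = chrom_arr[i], bp_arr[i], snp_arr[i]
        blocked = False
        if window_bp > 0:
            for bp2, snp2 in kept_by_chrom.get(c, ()):
                if abs(int(bp) - bp2) <= window_bp:
                    if ld is None or ld(snp, snp2) > r2_max:
                        blocked = True
                        break
        if not blocked:
            keep[i] = True
            kept_by_chrom.setdefault(c, []).append((int(bp), snp))
    return GwasSumStats(records.trait_id, records.trait_type,
                        df.loc[keep].reset_index(drop=True))


def f_statistic(beta, se):
    """Single-SNP instrument-strength F-statistic, (beta/se)²."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("f_statistic requires se > 0")
    return (beta / se) ** 2


def filter_weak_instruments(h: HarmonizedSet, f_min: float = 10.0) -> HarmonizedSet:
    """Remove rows with exposure F = (beta_x/se_x)² strictly below ``f_min``."""
    if h.k == 0:
        return h
    f = f_statistic(h.data["beta_x"], h.data["se_x"])
    return h.subset(f >= f_min)


def exclude_snps(h: HarmonizedSet, excluded) -> HarmonizedSet:
    """Remove rows whose SNP id is in ``excluded`` (e.g. confounder-linked variants)."""
    excluded = set(excluded)
    if not excluded or h.k == 0:
        return h
    mask = ~h.data["SNP"].isin(excluded).to_numpy()
    n = int((~mask).sum())
    if n:
        logger.info("excluded %d confounder-listed SNPs from %s->%s", n, h.exposure_id, h.outcome_id)
    return h.subset(mask)


def load_exclusion_list(path) -> frozenset:
    """Read a one-SNP-per-line text file into an exclusion set."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def prepare_instruments(
    exposure: GwasSumStats,
    outcome: GwasSumStats,
    cfg: InstrumentSelectionConfig | None = None,
    ld=None,
    palindrome_policy: str = "drop_ambiguous",
    apply_outcome_filter: bool = True,
) -> HarmonizedSet:
    """Full instrument-selection pipeline for one exposure/outcome pair.

    Order: exposure-p selection -> clumping -> harmonization -> outcome-p
    filter -> weak-instrument filter -> confounder exclusion.  Each stage
    logs its surviving count so the order can be audited.  Pleiotropic
    outlier removal (MR-PRESSO) is applied afterwards by the pipeline.

    ``apply_outcome_filter=False`` skips the outcome-association filter: it
    is a screening guard against variants acting on the outcome directly,
    and is counterproductive when the goal is to *estimate* a non-null
    effect (it removes precisely the instruments carrying the signal, and
    is therefore skipped within mediation legs).
    """
    cfg = cfg or InstrumentSelectionConfig()
    sel = select_exposure_snps(exposure, cfg.exposure_p_threshold)
    logger.debug("%s: %d SNPs pass exposure p<%g", exposure.trait_id, sel.n_snp, cfg.exposure_p_threshold)
    sel = clump(sel, cfg.clump_r2, cfg.clump_window_kb, ld=ld)
    logger.debug("%s: %d SNPs after clumping", exposure.trait_id, sel.n_snp)
    h = harmonize(sel, outcome, palindrome_policy=palindrome_policy)
    if apply_outcome_filter:
        h = filter_outcome_associated(h, cfg.outcome_p_threshold)
    h = filter_weak_instruments(h, cfg.f_min)
    h = exclude_snps(h, cfg.excluded_snps)
    logger.debug("%s->%s: %d instruments after all filters", exposure.trait_id, outcome.trait_id, h.k)
    return h
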