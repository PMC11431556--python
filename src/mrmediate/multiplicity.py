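"""Benjamini-Hochberg FDR control and evidence-tier labels.

Screens label each association by its BH-adjusted q-value: q < 0.05 is
"strong" evidence, 0.05 <= q < 0.20 "suggestive", and anything else "none".
The FDR family defaults to one screen (all exposures against one outcome).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

STRONG_Q = 0.05
SUGGESTIVE_Q = 0.20


@dataclass(frozen=True)
class EvidenceTier:
    label: str  # strong | suggestive | none
    fdr_q: float


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order.

    q_(i) = min_{j>=i} p_(j)*m/j on the ascending sort, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr requires a non-empty p-value vector")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def assign_tier(q: float) -> EvidenceTier:
    """Evidence tier for one q-value (strict boundaries at 0.05 and 0.20)."""
    if not 0 <= q <= 1:
        raise ValueError("q must lie in [0, 1]")
    if q < STRONG_Q:
        label = "strong"
    elif q < SUGGESTIVE_Q:
        label = "suggestive"
    else:
        label = "none"
    return EvidenceTier(label, float(q))
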