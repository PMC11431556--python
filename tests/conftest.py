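"""Shared builders for the test suite.

Harmonized sets are built directly from arrays where a test exercises an
estimator, and from the synthetic generator where a test exercises the
pipeline.
"""

import numpy as np
import pandas as pd
import pytest

from mrmediate import GwasSumStats, HarmonizedSet, prepare_instruments
from mrmediate.sumstats import COLUMNS, HARMONIZED_COLUMNS


def make_harmonized(beta_x, se_x, beta_y, se_y, exposure_id="X", outcome_id="Y"):
    """HarmonizedSet straight from effect arrays (alleles/positions arbitrary)."""
    beta_x = np.asarray(beta_x, float)
    k = len(beta_x)
    df = pd.DataFrame({
        "SNP": [f"rs{i+1}" for i in range(k)],
        "CHR": ["1"] * k,
        "BP": np.arange(1, k + 1) * 1_000_000,
        "EA": ["A"] * k, "OA": ["G"] * k,
        "eaf_x": np.full(k, 0.3), "beta_x": beta_x,
        "se_x": np.broadcast_to(np.asarray(se_x, float), (k,)).copy(),
        "pval_x": np.full(k, 1e-8), "n_x": np.full(k, 10_000),
        "eaf_y": np.full(k, 0.3),
        "beta_y": np.asarray(beta_y, float),
        "se_y": np.broadcast_to(np.asarray(se_y, float), (k,)).copy(),
        "pval_y": np.full(k, 0.5), "n_y": np.full(k, 10_000),
    })[HARMONIZED_COLUMNS]
    return HarmonizedSet(exposure_id, outcome_id, df)


def random_harmonized(rng, k=20, beta=0.2, noise=0.05):
    """A random but well-behaved instrument set around a true ratio ``beta``."""
    bx = rng.uniform(0.05, 0.3, k) * rng.choice([-1.0, 1.0], k)
    sx = rng.uniform(0.005, 0.02, k)
    sy = rng.uniform(0.01, 0.06, k)
    by = beta * bx + rng.normal(0.0, noise, k) * sy
    return make_harmonized(bx, sx, by, sy)


def make_sumstats(trait_id="trait", trait_type="continuous", **cols):
    """GwasSumStats from keyword columns; unspecified columns get sane defaults."""
    n = len(next(iter(cols.values())))
    defaults = {
        "SNP": [f"rs{i+1}" for i in range(n)],
        "CHR": ["1"] * n,
        "BP": list(np.arange(1, n + 1) * 1_000_000),
        "EA": ["A"] * n, "OA": ["G"] * n,
        "EAF": [0.3] * n, "BETA": [0.1] * n, "SE": [0.01] * n,
        "P": [1e-8] * n, "N": [10_000] * n,
    }
    defaults.update(cols)
    df = pd.DataFrame(defaults)[COLUMNS]
    df["BP"] = df["BP"].astype(np.int64)
    df["N"] = df["N"].astype(np.int64)
    return GwasSumStats(trait_id, trait_type, df)


def estimation_instruments(exposure, outcome, cfg=None):
    """Instrument set for effect estimation: selection + clumping +
    harmonization + F filter, without the outcome-association screen."""
    return prepare_instruments(exposure, outcome, cfg, apply_outcome_filter=False)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
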