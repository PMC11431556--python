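"""GWAS summary statistics: containers, delimited-text I/O, and allele harmonization.

A trait's per-SNP association results are held in :class:`GwasSumStats`
(a thin wrapper around a canonical-schema :class:`pandas.DataFrame`), and an
exposure/outcome pair aligned to a shared effect allele in
:class:`HarmonizedSet` — the input every causal estimator consumes.

Canonical columns: ``SNP CHR BP EA OA EAF BETA SE P N`` (positions 1-based;
``BETA`` is per effect allele, on the log-odds scale for binary traits and in
SD units for continuous traits).
"""

from __future__ import annotations

import csv
import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Canonical column order for summary-statistic tables.
COLUMNS = ["SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Header synonyms accepted without an explicit dialect map (GWAS-Catalog style
#: and other common exports, all matched case-insensitively).
DEFAULT_SYNONYMS = {
    "SNP": {"snp", "rsid", "rs_id", "variant_id", "markername", "id"},
    "CHR": {"chr", "chrom", "chromosome"},
    "BP": {"bp", "pos", "position", "base_pair_location"},
    "EA": {"ea", "effect_allele", "a1", "allele1"},
    "OA": {"oa", "other_allele", "a2", "allele2", "non_effect_allele"},
    "EAF": {"eaf", "effect_allele_frequency", "freq", "af", "maf"},
    "BETA": {"beta", "effect", "b"},
    "SE": {"se", "standard_error", "stderr"},
    "P": {"p", "pval", "p_value", "pvalue"},
    "N": {"n", "samplesize", "sample_size", "n_total"},
}


@dataclass
class GwasSumStats:
    """One trait's GWAS summary statistics.

    Parameters
    ----------
    trait_id : str
        Identifier for the trait (e.g. a GWAS accession).
    trait_type : {"continuous", "binary"}
        For binary traits ``BETA`` is interpreted as a log-odds ratio.
    data : pandas.DataFrame
        Canonical-schema table (see :data:`COLUMNS`); one row per SNP,
        ``SNP`` unique.
    """

    trait_id: str
    trait_type: str = "continuous"
    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=COLUMNS))

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        if self.data["SNP"].duplicated().any():
            dups = self.data.loc[self.data["SNP"].duplicated(), "SNP"].head(3).tolist()
            raise ValueError(f"duplicate SNP ids in {self.trait_id}: {dups} ...")

    @property
    def n_snp(self) -> int:
        return len(self.data)

    def subset(self, mask) -> "GwasSumStats":
        """Row-subset preserving order and metadata."""
        return GwasSumStats(self.trait_id, self.trait_type, self.data.loc[mask].reset_index(drop=True))


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs aligned to a shared effect allele.

    ``data`` holds one row per shared SNP with columns ``SNP CHR BP EA OA
    eaf_x beta_x se_x pval_x n_x eaf_y beta_y se_y pval_y n_y``; every row's
    ``beta_x`` and ``beta_y`` refer to the same effect allele.
    """

    exposure_id: str
    outcome_id: str
    data: pd.DataFrame

    @property
    def k(self) -> int:
        """Number of SNPs (instruments) in the set."""
        return len(self.data)

    def subset(self, mask) -> "HarmonizedSet":
        return HarmonizedSet(self.exposure_id, self.outcome_id, self.data.loc[mask].reset_index(drop=True))


HARMONIZED_COLUMNS = [
    "SNP", "CHR", "BP", "EA", "OA",
    "eaf_x", "beta_x", "se_x", "pval_x", "n_x",
    "eaf_y", "beta_y", "se_y", "pval_y", "n_y",
]


def _validate(df: pd.DataFrame, trait_id: str) -> pd.DataFrame:
    """Drop rows violating the record invariants; log counts.

    Rows whose p-value disagrees with the normal-theory value implied by
    beta/se by more than a factor of two are flagged (logged) but retained:
    inputs may carry exact p-values from other tests.
    """
    n0 = len(df)
    ea = df["EA"].astype(str).str.upper()
    oa = df["OA"].astype(str).str.upper()
    ok = (
        ea.isin(_BASES)
        & oa.isin(_BASES)
        & (ea != oa)
        & (df["SE"] > 0)
        & (df["EAF"] > 0)
        & (df["EAF"] < 1)
        & (df["P"] > 0)
        & (df["P"] <= 1)
        & (df["N"] > 0)
        & (df["BP"] >= 1)
    )
    ok &= df[["EAF", "BETA", "SE", "P", "N", "BP"]].notna().all(axis=1)
    dropped = int(n0 - ok.sum())
    if dropped:
        logger.warning("%s: dropped %d/%d rows failing record invariants", trait_id, dropped, n0)
    out = df.loc[ok].copy()
    out["EA"] = ea[ok]
    out["OA"] = oa[ok]
    # consistency flag only — never a drop
    with np.errstate(divide="ignore", invalid="ignore"):
        implied = 2.0 * stats.norm.sf(np.abs(out["BETA"] / out["SE"]))
    ratio = np.where(implied > 0, out["P"] / implied, np.inf)
    off = (ratio > 2.0) | (ratio < 0.5)
    # very small p-values underflow; only flag where implied is representable
    off &= implied > 1e-300
    if off.any():
        logger.info(
            "%s: %d rows carry p-values differing >2x from 2*Phi(-|beta/se|) (kept)",
            trait_id, int(off.sum()),
        )
    return out.reset_index(drop=True)


def _resolve_columns(header, dialect):
    """Map file columns to canonical names via dialect, then synonyms."""
    mapping = {}
    if dialect:
        rev = {v: k for k, v in dialect.items()}  # dialect: canonical -> file column
        for col in header:
            if col in rev:
                mapping[col] = rev[col]
    lowered = {c.lower(): c for c in header}
    for canon, syns in DEFAULT_SYNONYMS.items():
        if canon in mapping.values():
            continue
        for syn in sorted(syns):
            if syn in lowered and lowered[syn] not in mapping:
                mapping[lowered[syn]] = canon
                break
    return mapping


def read_sumstats(path, trait_id=None, trait_type="continuous", dialect=None) -> GwasSumStats:
    """Read a delimited summary-statistics file into a validated :class:`GwasSumStats`.

    Parameters
    ----------
    path : str or pathlib.Path
        Tab- or comma-delimited text with a header row; gzip accepted.
    trait_id : str, optional
        Defaults to the file stem.
    dialect : dict, optional
        Map ``{canonical_name: file_column}`` for non-standard headers;
        common synonyms (GWAS-Catalog style) are recognised automatically.

    Raises
    ------
    ValueError
        If a required column cannot be located, or the file is empty.
    """
    # sniff the delimiter from the header, then parse with full float
    # precision (the default reader rounds the 17th significant digit)
    opener = gzip.open if str(path).endswith(".gz") else open
    try:
        with opener(path, "rt") as fh:
            header = fh.readline()
    except OSError as exc:
        raise ValueError(f"unreadable summary-statistics file {path}: {exc}") from exc
    if not header.strip():
        raise ValueError(f"empty summary-statistics file: {path}")
    sep = "\t" if "\t" in header else ","
    try:
        df = pd.read_csv(path, sep=sep, compression="infer",
                         float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError, csv.Error) as exc:
        raise ValueError(f"unreadable or empty summary-statistics file {path}: {exc}") from exc
    if df.empty and df.columns.size == 0:
        raise ValueError(f"empty summary-statistics file: {path}")
    mapping = _resolve_columns(df.columns, dialect)
    df = df.rename(columns=mapping)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: required column(s) not found: {missing}")
    df = df[COLUMNS].copy()
    df["CHR"] = df["CHR"].astype(str)
    df["BP"] = df["BP"].astype(np.int64)
    df["N"] = df["N"].astype(np.int64)
    tid = trait_id if trait_id is not None else _stem(path)
    return GwasSumStats(tid, trait_type, _validate(df, tid))


def _stem(path) -> str:
    import os
    base = os.path.basename(str(path))
    for suf in (".gz", ".tsv", ".csv", ".txt"):
        if base.endswith(suf):
            base = base[: -len(suf)]
    return base


def write_sumstats(sumstats: GwasSumStats, path) -> None:
    """Write canonical TSV; ``read_sumstats`` of the result round-trips exactly.

    Floats are written with the shortest representation that round-trips
    bit-exactly, so sign and at least six significant digits are always
    preserved.
    """
    sumstats.data.to_csv(path, sep="\t", index=False, columns=COLUMNS,
                         float_format=lambda v: repr(float(v)))


def harmonize(
    exposure: GwasSumStats,
    outcome: GwasSumStats,
    palindrome_policy: str = "drop_ambiguous",
    maf_window: float = 0.08,
) -> HarmonizedSet:
    """Align exposure and outcome effects to the exposure's effect allele.

    Shared SNPs are matched by allele pair, resolving strand flips
    (A<->T, C<->G complements) before comparison; where the outcome's effect
    allele equals the exposure's other allele the outcome beta sign is
    flipped and its EAF replaced by 1-EAF.  Palindromic SNPs (A/T or C/G
    pairs) are handled per ``palindrome_policy``:

    - ``drop_ambiguous`` (default): drop those whose EAF on either side lies
      within ``maf_window`` of 0.5 (default window 0.42-0.58); the rest are
      aligned by letter, with a frequency check flipping strand when the two
      EAFs fall on opposite sides of 0.5.
    - ``drop_all``: drop every palindromic SNP.
    - ``keep``: keep all, aligned by letter with the same frequency check.

    Allele pairs matching neither directly nor by complement are dropped.
    Zero shared SNPs yields an empty set with a warning (not an error).
    """
    if palindrome_policy not in ("drop_ambiguous", "drop_all", "keep"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    x = exposure.data.rename(columns={
        "EAF": "eaf_x", "BETA": "beta_x", "SE": "se_x", "P": "pval_x", "N": "n_x"})
    y = outcome.data[["SNP", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]].rename(columns={
        "EA": "EA_y", "OA": "OA_y",
        "EAF": "eaf_y", "BETA": "beta_y", "SE": "se_y", "P": "pval_y", "N": "n_y"})
    m = x.merge(y, on="SNP", how="inner")
    if m.empty:
        logger.warning("harmonize(%s, %s): zero shared SNPs", exposure.trait_id, outcome.trait_id)
        return HarmonizedSet(exposure.trait_id, outcome.trait_id,
                             pd.DataFrame(columns=HARMONIZED_COLUMNS))

    ea_x, oa_x = m["EA"].to_numpy(), m["OA"].to_numpy()
    ea_y, oa_y = m["EA_y"].to_numpy(), m["OA_y"].to_numpy()
    comp = np.vectorize(_COMPLEMENT.get)
    cea_y, coa_y = comp(ea_y), comp(oa_y)

    palindromic = oa_x == comp(ea_x)
    direct = (ea_y == ea_x) & (oa_y == oa_x)
    swapped = (ea_y == oa_x) & (oa_y == ea_x)
    comp_direct = (cea_y == ea_x) & (coa_y == oa_x)
    comp_swapped = (cea_y == oa_x) & (coa_y == ea_x)

    keep = np.ones(len(m), dtype=bool)
    flip = np.zeros(len(m), dtype=bool)

    nonpal = ~palindromic
    match_nonpal = direct | swapped | comp_direct | comp_swapped
    keep[nonpal] = match_nonpal[nonpal]
    flip[nonpal] = (swapped | comp_swapped)[nonpal]

    # palindromic: letters alone cannot distinguish strand; align by letter,
    # then let allele frequency arbitrate
    match_pal = direct | swapped
    keep[palindromic] = match_pal[palindromic]
    flip[palindromic & swapped] = True
    if palindrome_policy == "drop_all":
        keep[palindromic] = False
    elif palindrome_policy == "drop_ambiguous":
        lo, hi = 0.5 - maf_window, 0.5 + maf_window
        ambiguous = (
            ((m["eaf_x"] > lo) & (m["eaf_x"] < hi))
            | ((m["eaf_y"] > lo) & (m["eaf_y"] < hi))
        ).to_numpy()
        keep[palindromic & ambiguous] = False

    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("harmonize(%s, %s): dropped %d unresolvable/ambiguous SNPs",
                    exposure.trait_id, outcome.trait_id, n_drop)

    m = m.loc[keep].reset_index(drop=True)
    flip = flip[keep]
    palindromic = palindromic[keep]
    m.loc[flip, "beta_y"] = -m.loc[flip, "beta_y"]
    m.loc[flip, "eaf_y"] = 1.0 - m.loc[flip, "eaf_y"]

    # frequency-based strand resolution for retained palindromes
    if palindromic.any():
        opposite = palindromic & (
            ((m["eaf_x"] < 0.5) & (m["eaf_y"] > 0.5))
            | ((m["eaf_x"] > 0.5) & (m["eaf_y"] < 0.5))
        ).to_numpy()
        m.loc[opposite, "beta_y"] = -m.loc[opposite, "beta_y"]
        m.loc[opposite, "eaf_y"] = 1.0 - m.loc[opposite, "eaf_y"]

    return HarmonizedSet(exposure.trait_id, outcome.trait_id, m[HARMONIZED_COLUMNS])
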