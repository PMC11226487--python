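"""Reading, validation, and harmonization of GWAS summary statistics.

Summary statistics live in pandas DataFrames with canonical column names
(``snp_id``, ``chrom``, ``pos``, ``effect_allele``, ``other_allele``, ``eaf``,
``beta``, ``se``, ``pval``, ``n``). ``harmonize`` aligns an exposure and an
outcome GWAS onto the exposure's effect-allele frame and computes per-SNP
Wald ratios, delta-method ratio standard errors, and instrument-strength F
statistics (F = beta**2 / se**2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DuplicateSNPError, EmptyInputError

#: Canonical field names, in output order.
CANONICAL_FIELDS = (
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
)

#: Fields that must be present and non-missing in every record.
REQUIRED_FIELDS = (
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pval",
)

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Columns carried by a harmonized-instrument table.
INSTRUMENT_FIELDS = (
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta_exp", "se_exp", "pval_exp", "eaf_exp",
    "beta_out", "se_out", "pval_out", "eaf_out",
    "ratio", "ratio_se", "f_stat",
)


@dataclass
class ColumnMap:
    """Maps canonical field names to the column headers of a source file."""

    mapping: dict = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP.mapping))
    na_values: tuple = ("NA", "NaN", "nan", "")
    delimiter: str = "\t"

    def __post_init__(self):
        if len(self.delimiter) != 1:
            raise ConfigurationError(f"delimiter must be a single character, got {self.delimiter!r}")
        missing = [f for f in REQUIRED_FIELDS if f not in self.mapping]
        if missing:
            raise ConfigurationError(f"column map lacks required fields: {missing}")


DEFAULT_COLUMN_MAP = ColumnMap(
    mapping={
        "snp_id": "SNP", "chrom": "chr", "pos": "pos",
        "effect_allele": "effect_allele", "other_allele": "other_allele",
        "eaf": "eaf", "beta": "beta", "se": "se", "pval": "pval", "n": "n",
    }
)


@dataclass
class LoadReport:
    """Row accounting for one summary-statistics load."""

    n_read: int = 0
    n_kept: int = 0
    drops: dict = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return self.n_read - self.n_kept


def read_summary_stats(path, colmap: ColumnMap | None = None):
    """Read a delimited GWAS summary-statistics file.

    Rows violating record invariants (non-positive SE, p outside (0, 1],
    identical alleles, non-ACGT alleles, eaf outside [0, 1], pos < 1, or
    missing required values) are dropped and counted per reason in the
    returned :class:`LoadReport`. Input row order is preserved. Gzip input
    is handled transparently by file extension.

    Returns
    -------
    (DataFrame, LoadReport)
    """
    colmap = colmap or DEFAULT_COLUMN_MAP
    raw = pd.read_csv(path, sep=colmap.delimiter, na_values=list(colmap.na_values),
                      compression="infer", dtype=str)
    missing = [src for src in colmap.mapping.values() if src not in raw.columns]
    if missing:
        raise ConfigurationError(f"{path}: mapped columns absent from header: {missing}")

    df = pd.DataFrame({canon: raw[src] for canon, src in colmap.mapping.items()})
    for canon in CANONICAL_FIELDS:
        if canon not in df.columns:
            df[canon] = np.nan
    df = df[list(CANONICAL_FIELDS)]

    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].str.upper()
    df["chrom"] = df["chrom"].astype(str)

    report = LoadReport(n_read=len(df))
    checks = {
        "missing_required": df[list(REQUIRED_FIELDS)].isna().any(axis=1),
        "nonpositive_se": df["se"] <= 0,
        "pval_out_of_range": (df["pval"] <= 0) | (df["pval"] > 1),
        "bad_allele": ~(df["effect_allele"].isin(_VALID_ALLELES)
                        & df["other_allele"].isin(_VALID_ALLELES)),
        "identical_alleles": df["effect_allele"] == df["other_allele"],
        "eaf_out_of_range": df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1)),
        "bad_pos": df["pos"] < 1,
    }
    bad = pd.Series(False, index=df.index)
    for reason, mask in checks.items():
        mask = mask.fillna(False) & ~bad
        k = int(mask.sum())
        if k:
            report.drops[reason] = k
        bad |= mask

    kept = df.loc[~bad].reset_index(drop=True)
    kept["pos"] = kept["pos"].astype(np.int64)
    report.n_kept = len(kept)
    if report.n_kept == 0:
        raise EmptyInputError(f"{path}: no valid summary-statistic rows")
    return kept, report


def write_summary_stats(df: pd.DataFrame, path,
                        colmap: ColumnMap | None = None) -> None:
    """Write records as a delimited table in the dialect ``colmap`` maps
    (default headers: SNP, chr, pos, effect_allele, ... as read back by
    :func:`read_summary_stats` with no configuration)."""
    colmap = colmap or DEFAULT_COLUMN_MAP
    cols = [c for c in CANONICAL_FIELDS if c in df.columns]
    df[cols].rename(columns=colmap.mapping).to_csv(
        path, sep=colmap.delimiter, index=False)


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return a2 == a1.map(_COMPLEMENT)


def _check_unique(df: pd.DataFrame, label: str) -> None:
    dup = df["snp_id"][df["snp_id"].duplicated()]
    if len(dup):
        raise DuplicateSNPError(f"duplicate snp_id in {label}: {sorted(set(dup))[:5]}")


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindrome_policy: str = "drop_ambiguous",
              eaf_window: tuple = (0.42, 0.58)) -> pd.DataFrame:
    """Align outcome effects onto the exposure's effect allele per SNP.

    Only SNPs present in both GWAS are considered. Outcome records whose
    alleles are swapped relative to the exposure have ``beta`` negated and
    ``eaf`` replaced by ``1 - eaf``; strand flips (complement-allele matches)
    are resolved by complementing the outcome alleles first. SNPs with
    incompatible allele pairs are dropped.

    Palindromic SNPs (A/T or C/G) cannot be strand-resolved from alleles:

    * ``drop_ambiguous`` (default): dropped when either study's eaf lies in
      the open ambiguity window (default (0.42, 0.58)) or is missing;
      otherwise aligned by allele frequency.
    * ``freq_infer``: aligned by allele frequency whenever both eafs are
      present (flip when the frequencies sit on opposite sides of 0.5);
      dropped when either eaf is missing.
    * ``keep``: aligned by allele letters as written.

    Returns a harmonized-instrument table with Wald ``ratio`` = beta_out /
    beta_exp, first-order delta-method ``ratio_se`` = se_out / |beta_exp|,
    and ``f_stat`` = (beta_exp / se_exp)**2. Instruments with beta_exp == 0
    (undefined ratio) are dropped.
    """
    if palindrome_policy not in ("drop_ambiguous", "freq_infer", "keep"):
        raise ConfigurationError(f"unknown palindrome_policy {palindrome_policy!r}")
    _check_unique(exposure, "exposure")
    _check_unique(outcome, "outcome")

    m = exposure.merge(outcome, on="snp_id", suffixes=("_exp", "_out"), how="inner")
    if m.empty:
        return pd.DataFrame(columns=list(INSTRUMENT_FIELDS))

    ea_e, oa_e = m["effect_allele_exp"], m["other_allele_exp"]
    ea_o, oa_o = m["effect_allele_out"], m["other_allele_out"]
    ea_oc, oa_oc = ea_o.map(_COMPLEMENT), oa_o.map(_COMPLEMENT)

    direct = (ea_o == ea_e) & (oa_o == oa_e)
    swapped = (ea_o == oa_e) & (oa_o == ea_e)
    comp = (ea_oc == ea_e) & (oa_oc == oa_e)
    comp_swapped = (ea_oc == oa_e) & (oa_oc == ea_e)
    palin = _is_palindromic(ea_e, oa_e)

    compatible = direct | swapped | comp | comp_swapped
    flip = (~direct) & (swapped | (~comp & comp_swapped))

    # For palindromic SNPs letter matching is strand-ambiguous; realign.
    if palindrome_policy == "keep":
        flip = np.where(palin, swapped, flip)
        drop_palin = pd.Series(False, index=m.index)
    else:
        eaf_e, eaf_o = m["eaf_exp"], m["eaf_out"]
        no_freq = eaf_e.isna() | eaf_o.isna()
        freq_flip = (eaf_e - 0.5) * (eaf_o - 0.5) < 0
        flip = np.where(palin, freq_flip.fillna(False), flip)
        lo, hi = eaf_window
        in_window = (((eaf_e > lo) & (eaf_e < hi)) | ((eaf_o > lo) & (eaf_o < hi)))
        if palindrome_policy == "drop_ambiguous":
            drop_palin = palin & (no_freq | in_window.fillna(True))
        else:  # freq_infer
            drop_palin = palin & no_freq

    keep = compatible & ~drop_palin & (m["beta_exp"] != 0)
    m = m.loc[keep].copy()
    flip = np.asarray(flip, dtype=bool)[np.asarray(keep)]

    m.loc[flip, "beta_out"] = -m.loc[flip, "beta_out"]
    m.loc[flip, "eaf_out"] = 1.0 - m.loc[flip, "eaf_out"]

    out = pd.DataFrame({
        "snp_id": m["snp_id"],
        "chrom": m["chrom_exp"],
        "pos": m["pos_exp"],
        "effect_allele": m["effect_allele_exp"],
        "other_allele": m["other_allele_exp"],
        "beta_exp": m["beta_exp"], "se_exp": m["se_exp"],
        "pval_exp": m["pval_exp"], "eaf_exp": m["eaf_exp"],
        "beta_out": m["beta_out"], "se_out": m["se_out"],
        "pval_out": m["pval_out"], "eaf_out": m["eaf_out"],
    }).reset_index(drop=True)
    out["ratio"] = out["beta_out"] / out["beta_exp"]
    out["ratio_se"] = out["se_out"] / out["beta_exp"].abs()
    out["f_stat"] = (out["beta_exp"] / out["se_exp"]) ** 2
    return out[list(INSTRUMENT_FIELDS)]


def write_instruments(insts: pd.DataFrame, path) -> None:
    """Write a harmonized-instrument table as TSV with canonical headers."""
    insts.to_csv(path, sep="\t", index=False)
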