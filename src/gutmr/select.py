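"""Instrument selection: p-value screening, greedy LD clumping, F filtering.

The selection pipeline mirrors standard two-sample MR practice: screen the
exposure GWAS at a p-value threshold (default 1e-5, strict), prune to
approximately independent index SNPs by greedy clumping (default r-squared
< 0.001 within a 10,000 kb window), and exclude weak instruments at F > 10.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .exceptions import ConfigurationError


@dataclass
class ClumpParams:
    p_threshold: float = 1e-5
    r2_threshold: float = 0.001
    window_kb: int = 10_000

    def __post_init__(self):
        if not (0 < self.p_threshold < 1):
            raise ConfigurationError("p_threshold must be in (0, 1)")
        if not (0 <= self.r2_threshold <= 1):
            raise ConfigurationError("r2_threshold must be in [0, 1]")
        if self.window_kb <= 0:
            raise ConfigurationError("window_kb must be positive")


class LDTable:
    """Symmetric pairwise r-squared lookup.

    Absent pairs return ``None``; r2(x, x) is always 1. Built from a dict of
    ``(snp_a, snp_b) -> r2`` or a three-column TSV (snp_a, snp_b, r2).
    """

    def __init__(self, pairs: dict | None = None):
        self._r2 = {}
        for (a, b), v in (pairs or {}).items():
            if not (0 <= v <= 1):
                raise ConfigurationError(f"r2 out of [0,1] for pair ({a},{b}): {v}")
            self._r2[frozenset((a, b))] = float(v)

    @classmethod
    def read_table(cls, path) -> "LDTable":
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        return cls({(r.snp_a, r.snp_b): r.r2 for r in df.itertuples()})

    def write_table(self, path) -> None:
        rows = []
        for key, v in sorted(self._r2.items(), key=lambda kv: sorted(kv[0])):
            pair = sorted(key)
            a, b = (pair[0], pair[0]) if len(pair) == 1 else pair
            rows.append((a, b, v))
        pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(path, sep="\t", index=False)

    def r2(self, a: str, b: str):
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)))

    def __len__(self):
        return len(self._r2)


def screen_pvalue(records: pd.DataFrame, p_threshold: float = 1e-5) -> pd.DataFrame:
    """Keep exactly the records with pval strictly below the threshold."""
    return records.loc[records["pval"] < p_threshold].reset_index(drop=True)


def clump(records: pd.DataFrame, ld: LDTable | None = None,
          params: ClumpParams | None = None) -> pd.DataFrame:
    """Greedy LD clumping.

    Candidates are sorted by ascending pval (ties broken by chrom, pos,
    snp_id). The best remaining record becomes an index SNP; every remaining
    record on the same chromosome within ``window_kb`` whose r-squared with
    the index is >= ``r2_threshold`` is discarded. Missing-pair semantics:
    with no LD table at all, any pair inside the window counts as r2 = 1
    (pure distance pruning); with a table that lacks the pair, r2 = 0.

    Returns index SNPs in selection (p-value) order.
    """
    params = params or ClumpParams()
    if records.empty:
        return records.reset_index(drop=True)
    cand = records.sort_values(
        ["pval", "chrom", "pos", "snp_id"], kind="mergesort"
    ).reset_index(drop=True)
    window_bp = params.window_kb * 1000

    alive = [True] * len(cand)
    kept_idx = []
    snp = cand["snp_id"].to_numpy()
    chrom = cand["chrom"].to_numpy()
    pos = cand["pos"].to_numpy()
    for i in range(len(cand)):
        if not alive[i]:
            continue
        kept_idx.append(i)
        for j in range(i + 1, len(cand)):
            if not alive[j] or chrom[j] != chrom[i]:
                continue
            if abs(int(pos[j]) - int(pos[i])) > window_bp:
                continue
            r2 = 1.0 if ld is None else (ld.r2(snp[i], snp[j]) or 0.0)
            if r2 >= params.r2_threshold:
                alive[j] = False
    return cand.iloc[kept_idx].reset_index(drop=True)


def filter_weak(instruments: pd.DataFrame, f_min: float = 10.0) -> pd.DataFrame:
    """Keep exactly the instruments with F statistic strictly above f_min."""
    return instruments.loc[instruments["f_stat"] > f_min].reset_index(drop=True)
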