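"""Synthetic two-sample GWAS summary statistics with known ground truth.

Emulates the statistical structure of a microbiome-exposure /
binary-disease-outcome MR design: per-SNP exposure effects gamma_j with
sampling noise, outcome effects on the log-odds scale generated as
theta * gamma_j plus a configurable pleiotropy term alpha_j, independent
exposure/outcome noise (non-overlapping cohorts), and a taxonomy panel whose
default rank composition is 9 phyla, 16 classes, 20 orders, 32 families, and
119 genera (196 taxa).

Default conditions: 15 instruments per taxon (the real panels carry 4-19
SNPs per taxon after selection), exposure effect magnitudes uniform on
(0.05, 0.3) with random sign, exposure SEs uniform on (0.02, 0.05) (mean
per-SNP F well above the F > 10 bar, with a weak tail the filter removes),
outcome SEs uniform on (0.05, 0.15) as appropriate for a few hundred cases
against ~390k controls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .select import LDTable

#: Default rank composition of the taxonomy panel.
DEFAULT_RANK_COUNTS = {"phylum": 9, "class": 16, "order": 20, "family": 32, "genus": 119}

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
                 ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimulationConfig:
    """Generator settings; the defaults are the package's study conditions."""

    n_snp: int = 15
    theta: float = 0.0
    gamma_range: tuple = (0.05, 0.3)
    se_exp_range: tuple = (0.02, 0.05)
    se_out_range: tuple = (0.05, 0.15)
    pleiotropy_mode: str = "none"  # none | balanced | directional | outlier
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    n_outlier: int = 0
    outlier_scale: float = 10.0
    maf_range: tuple = (0.05, 0.5)
    n_null_snps: int = 0
    n_outcome_snps: int = 0  # SNPs directly associated with the outcome only
    window_kb: int = 10_000
    palindromic: bool = False
    snp_prefix: str = "rs"
    pos_offset: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_snp < 1:
            raise ConfigurationError("n_snp must be >= 1")
        for name in ("se_exp_range", "se_out_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigurationError(f"{name} must be a positive interval")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "outlier"):
            raise ConfigurationError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_mode == "outlier" and self.n_outlier < 1:
            raise ConfigurationError("outlier mode needs n_outlier >= 1")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery and calibration tests."""

    theta: float
    gamma: list = field(default_factory=list)
    alpha: list = field(default_factory=list)
    outlier_ids: list = field(default_factory=list)
    snp_ids: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _records(snp_ids, chrom, pos, ea, oa, eaf, beta, se, n):
    pval = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return pd.DataFrame({
        "snp_id": snp_ids, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se,
        "pval": np.clip(pval, np.finfo(float).tiny, 1.0),
        "n": n,
    })


def simulate_summary_pair(config: SimulationConfig):
    """Generate one exposure/outcome pair of summary-statistics tables.

    Per associated SNP j: gamma_j ~ U(gamma_range) with random sign; observed
    exposure beta = gamma_j + N(0, se_exp_j); true outcome effect
    theta * gamma_j + alpha_j with alpha_j set by ``pleiotropy_mode``;
    observed outcome beta = truth + N(0, se_out_j). ``n_null_snps`` extra
    SNPs carry gamma = 0 (for screening tests) and ``n_outcome_snps`` extra
    SNPs affect the outcome only (instruments for reverse-direction runs).
    Positions are spaced beyond the clumping window so default clumping keeps
    every associated SNP. Fully reproducible from ``config.seed``.

    Returns (exposure records, outcome records, GroundTruth).
    """
    rng = np.random.default_rng(config.seed)
    j = config.n_snp
    total = j + config.n_null_snps + config.n_outcome_snps

    gamma = rng.uniform(*config.gamma_range, size=j) * rng.choice([-1.0, 1.0], size=j)
    alpha = np.zeros(j)
    outlier_idx = np.array([], dtype=int)
    if config.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, config.alpha_sd, size=j)
    elif config.pleiotropy_mode == "directional":
        # directional means a nonzero-mean direct effect in the frame where
        # exposure effects are positive; it must co-flip with gamma's sign
        # (an allele recoding flips both), or recoding would wash it out
        alpha = np.sign(gamma) * rng.normal(config.alpha_mean, config.alpha_sd, size=j)

    se_exp = rng.uniform(*config.se_exp_range, size=total)
    se_out = rng.uniform(*config.se_out_range, size=total)
    if config.pleiotropy_mode == "outlier":
        outlier_idx = rng.choice(j, size=min(config.n_outlier, j), replace=False)
        alpha[outlier_idx] = config.outlier_scale * se_out[outlier_idx]

    gamma_full = np.concatenate([gamma, np.zeros(total - j)])
    truth_out = config.theta * gamma_full
    truth_out[:j] += alpha
    if config.n_outcome_snps:
        # genuine outcome loci: effect and SE sized like the exposure's
        # instrument-grade associations so they pass the reverse screen
        delta = (rng.uniform(*config.gamma_range, size=config.n_outcome_snps)
                 * rng.choice([-1.0, 1.0], size=config.n_outcome_snps))
        truth_out[j + config.n_null_snps:] = delta
        se_out[j + config.n_null_snps:] = rng.uniform(
            *config.se_exp_range, size=config.n_outcome_snps)

    beta_exp = gamma_full + rng.normal(0.0, se_exp)
    beta_out = truth_out + rng.normal(0.0, se_out)

    snp_ids = [f"{config.snp_prefix}{i + 1}" for i in range(total)]
    spacing = (config.window_kb + 1) * 1000
    chrom = [str(i % 22 + 1) for i in range(total)]
    pos = np.array([1 + config.pos_offset + (i // 22 + 1) * spacing
                    for i in range(total)], dtype=np.int64)
    pairs = _PALINDROMIC_PAIRS if config.palindromic else _ALLELE_PAIRS
    pick = rng.integers(0, len(pairs), size=total)
    ea = np.array([pairs[k][0] for k in pick])
    oa = np.array([pairs[k][1] for k in pick])
    eaf = rng.uniform(*config.maf_range, size=total)

    exposure = _records(snp_ids, chrom, pos, ea, oa, eaf, beta_exp, se_exp, 18340)
    outcome = _records(snp_ids, chrom, pos, ea, oa, eaf, beta_out, se_out, 392423)
    truth = GroundTruth(theta=config.theta, gamma=gamma.tolist(), alpha=alpha.tolist(),
                        outlier_ids=[snp_ids[i] for i in outlier_idx],
                        snp_ids=snp_ids[:j])
    return exposure, outcome, truth


def simulate_taxon_panel(rank_counts: dict | None = None, causal_fraction: float = 0.0,
                         base_config: SimulationConfig | None = None,
                         causal_theta: float = np.log(2.0)):
    """Generate a taxonomy panel of exposure GWAS against one shared outcome.

    One exposure summary-statistics table per taxon (disjoint SNP sets,
    disjoint position ranges); a ``causal_fraction`` share of taxa
    (deterministically the first k per rank, k = round(fraction * count))
    receive ``causal_theta``; the shared outcome table is the concatenation
    of every taxon's outcome records.

    When ``base_config.n_outcome_snps`` > 0, that many SNPs directly
    associated with the outcome only (exposure-null) are generated once and
    appended to the outcome table and to every taxon's exposure table, so
    that reverse-direction runs have instruments.

    Returns (exposures: dict taxon -> DataFrame, outcome: DataFrame,
    manifest: DataFrame[taxon, rank], truth: dict taxon -> GroundTruth).
    """
    if not (0.0 <= causal_fraction <= 1.0):
        raise ConfigurationError("causal_fraction must be in [0, 1]")
    rank_counts = dict(rank_counts or DEFAULT_RANK_COUNTS)
    if any(c < 1 for c in rank_counts.values()):
        raise ConfigurationError("rank counts must be >= 1")
    base = base_config or SimulationConfig()

    exposures, outcome_parts, truths, manifest_rows = {}, [], {}, []
    idx = 0
    for rank, count in rank_counts.items():
        n_causal = int(round(causal_fraction * count))
        for i in range(count):
            taxon = f"{rank}_{i + 1:03d}"
            cfg = SimulationConfig(
                **{**asdict(base),
                   "theta": causal_theta if i < n_causal else 0.0,
                   "n_outcome_snps": 0,
                   "snp_prefix": f"rs{idx + 1}_",
                   "pos_offset": idx * 500_000_000,
                   "seed": (base.seed * 1_000_003 + idx) % 2**31})
            exp_df, out_df, truth = simulate_summary_pair(cfg)
            exposures[taxon] = exp_df
            outcome_parts.append(out_df)
            truths[taxon] = truth
            manifest_rows.append((taxon, rank))
            idx += 1

    if base.n_outcome_snps > 0:
        # one shared block of outcome-specific instruments, exposure-null
        m = base.n_outcome_snps
        rng = np.random.default_rng((base.seed * 999_983 + 7) % 2**31)
        spacing = (base.window_kb + 1) * 1000
        delta = rng.uniform(*base.gamma_range, size=m) * rng.choice([-1.0, 1.0], size=m)
        se_o = rng.uniform(*base.se_exp_range, size=m)
        ids = [f"rsout_{k + 1}" for k in range(m)]
        chrom = [str(k % 22 + 1) for k in range(m)]
        pos = np.array([1 + (idx + 1) * 500_000_000 + (k // 22 + 1) * spacing
                        for k in range(m)], dtype=np.int64)
        pick = rng.integers(0, len(_ALLELE_PAIRS), size=m)
        ea = np.array([_ALLELE_PAIRS[k][0] for k in pick])
        oa = np.array([_ALLELE_PAIRS[k][1] for k in pick])
        eaf = rng.uniform(*base.maf_range, size=m)
        outcome_parts.append(_records(ids, chrom, pos, ea, oa, eaf,
                                      delta + rng.normal(0.0, se_o), se_o, 392423))
        for taxon in exposures:
            se_e = rng.uniform(*base.se_exp_range, size=m)
            exposures[taxon] = pd.concat(
                [exposures[taxon],
                 _records(ids, chrom, pos, ea, oa, eaf,
                          rng.normal(0.0, se_e), se_e, 18340)],
                ignore_index=True)

    outcome = pd.concat(outcome_parts, ignore_index=True)
    manifest = pd.DataFrame(manifest_rows, columns=["taxon", "rank"])
    return exposures, outcome, manifest, truths


def plant_ld_structure(records: pd.DataFrame, block_size: int, r2_within: float):
    """Regroup SNPs into proximal LD blocks and emit the pairwise r2 table.

    Consecutive groups of ``block_size`` SNPs are relocated onto a shared
    chromosome position neighborhood (1 kb apart, well inside the clumping
    window) and given pairwise r2 = ``r2_within``. When r2_within is at or
    above the clumping threshold, greedy clumping retains exactly one SNP
    (the best p-value) per block.

    Returns (LDTable, relocated records).
    """
    if block_size < 1:
        raise ConfigurationError("block_size must be >= 1")
    rec = records.reset_index(drop=True).copy()
    n = len(rec)
    n_blocks = (n + block_size - 1) // block_size
    chrom, pos, pairs = [], [], {}
    for b in range(n_blocks):
        members = list(range(b * block_size, min((b + 1) * block_size, n)))
        for k, i in enumerate(members):
            chrom.append(str(b % 22 + 1))
            pos.append(1 + (b // 22) * 50_000_000 + k * 1000)
        ids = rec.loc[members, "snp_id"].tolist()
        for a in range(len(ids)):
            for c in range(a + 1, len(ids)):
                pairs[(ids[a], ids[c])] = r2_within
    rec["chrom"] = chrom
    rec["pos"] = np.array(pos, dtype=np.int64)
    return LDTable(pairs), rec
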