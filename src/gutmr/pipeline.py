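"""End-to-end orchestration of the MR study.

For each exposure taxon x outcome: select instruments (p-value screen, LD
clumping, F filter), harmonize, estimate with IVW / MR-Egger / weighted
median / weighted mode, run diagnostics, apply the decision rules
(random-effects IVW when Cochran's Q p < 0.05; one MR-PRESSO-gated outlier
removal and re-estimation when its global p < 0.05), band significance
against rank-specific Bonferroni thresholds (alpha divided by the number of
taxa at the rank), and queue reverse-direction runs for suggestive or
corrected-significant taxa.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .diagnostics import DiagnosticsReport, cochran_q, leave_one_out, mr_presso
from .estimators import (
    IVW,
    EggerFit,
    MREstimate,
    mr_egger,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from .exceptions import ConfigurationError, GutMRError
from .io import harmonize
from .select import ClumpParams, LDTable, clump, filter_weak, screen_pvalue

RANKS = ("phylum", "class", "order", "family", "genus")
BANDS = ("corrected_significant", "suggestive", "null")


@dataclass
class PipelineConfig:
    """Flat study configuration; all randomness flows from ``seed``."""

    p_threshold: float = 1e-5
    r2_threshold: float = 0.001
    window_kb: int = 10_000
    f_min: float = 10.0
    alpha: float = 0.05
    n_boot: int = 1000
    n_sim: int = 1000
    phi: float = 1.0
    outlier_alpha: float = 0.05
    palindrome_policy: str = "drop_ambiguous"
    eaf_window: tuple = (0.42, 0.58)
    reverse_p_threshold: float = 1e-5
    reverse_all: bool = False
    seed: int = 0

    @property
    def clump_params(self) -> ClumpParams:
        return ClumpParams(p_threshold=self.p_threshold,
                           r2_threshold=self.r2_threshold,
                           window_kb=self.window_kb)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        if "eaf_window" in raw:
            raw["eaf_window"] = tuple(raw["eaf_window"])
        return cls(**raw)

    def to_file(self, path) -> None:
        d = asdict(self)
        d["eaf_window"] = list(d["eaf_window"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


class TaxonomyManifest:
    """Assigns each exposure taxon to a taxonomic rank."""

    def __init__(self, table: pd.DataFrame):
        if not {"taxon", "rank"}.issubset(table.columns):
            raise ConfigurationError("manifest needs 'taxon' and 'rank' columns")
        bad = set(table["rank"]) - set(RANKS)
        if bad:
            raise ConfigurationError(f"unknown ranks in manifest: {sorted(bad)}")
        if table["taxon"].duplicated().any():
            raise ConfigurationError("duplicate taxa in manifest")
        self.table = table.reset_index(drop=True)

    @classmethod
    def read_tsv(cls, path) -> "TaxonomyManifest":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def rank_counts(self) -> dict:
        return self.table["rank"].value_counts().to_dict()

    def rank_of(self, taxon: str) -> str:
        row = self.table.loc[self.table["taxon"] == taxon, "rank"]
        if row.empty:
            raise ConfigurationError(f"taxon {taxon!r} not in manifest")
        return row.iloc[0]

    def __len__(self):
        return len(self.table)

    def __iter__(self):
        return iter(self.table.itertuples(index=False))


def bonferroni_threshold(rank: str, manifest: TaxonomyManifest, alpha: float = 0.05) -> float:
    """alpha divided by the number of taxa at the given rank."""
    if not (0 < alpha < 1):
        raise ConfigurationError("alpha must be in (0, 1)")
    counts = manifest.rank_counts
    if rank not in counts:
        raise ConfigurationError(f"rank {rank!r} absent from manifest")
    return alpha / counts[rank]


def classify_significance(ivw_p: float, threshold: float, alpha: float = 0.05) -> str:
    """corrected_significant below the rank threshold; suggestive between the
    threshold and alpha; null at or above alpha."""
    if not (0 < threshold <= alpha):
        raise ConfigurationError("need 0 < threshold <= alpha")
    if ivw_p < threshold:
        return "corrected_significant"
    if ivw_p < alpha:
        return "suggestive"
    return "null"


@dataclass
class TaxonResult:
    """Verdict for one exposure-outcome pair."""

    taxon: str
    rank: str | None
    outcome: str
    status: str = "ok"  # ok | no_instruments | error
    n_snp: int = 0
    estimates: dict = field(default_factory=dict)  # method -> MREstimate
    egger: EggerFit | None = None
    diagnostics: DiagnosticsReport = field(default_factory=DiagnosticsReport)
    effects_model_used: str | None = None
    outliers_removed: list = field(default_factory=list)
    headline: MREstimate | None = None
    threshold: float = 0.05
    band: str = "null"
    wm_consistent: bool | None = None
    pleiotropy_flag: bool | None = None
    reverse: "TaxonResult | None" = None
    error: str | None = None


def pair_seed(master_seed: int, taxon: str, outcome: str) -> int:
    """Deterministic per-pair seed below 2**31 from the master seed."""
    return (master_seed * 1_000_003 + zlib.crc32(f"{taxon}|{outcome}".encode())) % 2**31


def _estimate_all(insts: pd.DataFrame, config: PipelineConfig, seed: int):
    """All available estimators plus diagnostics on one instrument set."""
    estimates, egger_fit = {}, None
    diag = DiagnosticsReport()
    n = len(insts)
    if n == 1:
        estimates["wald_ratio"] = wald_ratio(insts)
        return estimates, egger_fit, diag, None

    q_stat, q_df, q_pval = cochran_q(insts)
    diag.q_stat, diag.q_df, diag.q_pval = q_stat, q_df, q_pval
    model = "random" if q_pval < config.alpha else "fixed"
    headline = IVW(effects_model=model).fit(insts).estimate_
    estimates["ivw"] = headline
    if n >= 3:
        egger_fit = mr_egger(insts)
        estimates["egger"] = egger_fit.slope
        diag.egger_intercept = egger_fit.intercept
        diag.egger_intercept_se = egger_fit.intercept_se
        diag.egger_intercept_p = egger_fit.intercept_p
        estimates["weighted_median"] = weighted_median(
            insts, n_boot=config.n_boot, seed=(seed + 1) % 2**31)
        estimates["weighted_mode"] = weighted_mode(
            insts, phi=config.phi, n_boot=config.n_boot, seed=(seed + 2) % 2**31)
        diag.loo_table, diag.loo_stable = leave_one_out(insts, effects_model=model)
    return estimates, egger_fit, diag, model


def run_pair(exposure: pd.DataFrame, outcome: pd.DataFrame,
             ld: LDTable | None = None,
             config: PipelineConfig | None = None,
             taxon: str = "exposure", rank: str | None = None,
             outcome_name: str = "outcome",
             threshold: float | None = None,
             seed: int | None = None,
             p_threshold: float | None = None) -> TaxonResult:
    """Run selection -> harmonization -> estimation -> diagnostics -> verdict
    for one exposure-outcome pair.

    Fewer than two surviving instruments yields a ``no_instruments`` result
    with band ``null`` rather than an exception. When MR-PRESSO's global p
    falls below alpha, its flagged outliers are removed and estimation is
    re-run once on the reduced set.
    """
    config = config or PipelineConfig()
    threshold = config.alpha if threshold is None else threshold
    seed = pair_seed(config.seed, taxon, outcome_name) if seed is None else seed
    params = config.clump_params
    if p_threshold is not None:
        params = ClumpParams(p_threshold=p_threshold,
                             r2_threshold=config.r2_threshold,
                             window_kb=config.window_kb)

    res = TaxonResult(taxon=taxon, rank=rank, outcome=outcome_name, threshold=threshold)
    screened = screen_pvalue(exposure, params.p_threshold)
    clumped = clump(screened, ld, params)
    insts = harmonize(clumped, outcome, palindrome_policy=config.palindrome_policy,
                      eaf_window=config.eaf_window)
    insts = filter_weak(insts, config.f_min)
    res.n_snp = len(insts)
    if len(insts) < 2:
        res.status = "no_instruments"
        res.band = "null"
        return res

    # one PRESSO-gated outlier-removal pass
    if len(insts) >= 4:
        presso = mr_presso(insts, n_sim=config.n_sim, seed=seed,
                           outlier_alpha=config.outlier_alpha)
        res.diagnostics.presso_global_rss = presso.global_rss
        res.diagnostics.presso_global_p = presso.global_p
        res.diagnostics.presso_outliers = presso.outliers
        res.diagnostics.presso_distortion_coef = presso.distortion_coef
        res.diagnostics.presso_distortion_p = presso.distortion_p
        if presso.global_p < config.alpha and presso.outliers:
            reduced = insts.loc[~insts["snp_id"].isin(presso.outliers)]
            if len(reduced) >= 2:
                res.outliers_removed = list(presso.outliers)
                insts = reduced.reset_index(drop=True)
                res.n_snp = len(insts)

    estimates, egger_fit, diag, model = _estimate_all(insts, config, seed)
    diag.presso_global_rss = res.diagnostics.presso_global_rss
    diag.presso_global_p = res.diagnostics.presso_global_p
    diag.presso_outliers = res.diagnostics.presso_outliers
    diag.presso_distortion_coef = res.diagnostics.presso_distortion_coef
    diag.presso_distortion_p = res.diagnostics.presso_distortion_p
    res.estimates, res.egger, res.diagnostics = estimates, egger_fit, diag
    res.effects_model_used = model
    res.headline = estimates.get("ivw") or estimates.get("wald_ratio")
    res.band = classify_significance(res.headline.pval, threshold, config.alpha)
    if egger_fit is not None:
        res.pleiotropy_flag = egger_fit.intercept_p < config.alpha
    wm = estimates.get("weighted_median")
    if wm is not None:
        res.wm_consistent = bool(
            np.sign(wm.beta) == np.sign(res.headline.beta) and wm.pval < config.alpha)
    return res


def run_reverse(outcome_as_exposure: pd.DataFrame, exposure_as_outcome: pd.DataFrame,
                config: PipelineConfig | None = None,
                taxon: str = "outcome", outcome_name: str = "exposure",
                seed: int | None = None) -> TaxonResult:
    """The same machinery with the exposure and outcome roles swapped; the
    instrument screen uses ``config.reverse_p_threshold``."""
    config = config or PipelineConfig()
    return run_pair(outcome_as_exposure, exposure_as_outcome, ld=None, config=config,
                    taxon=taxon, outcome_name=outcome_name,
                    threshold=config.alpha, seed=seed,
                    p_threshold=config.reverse_p_threshold)


def run_panel(manifest: TaxonomyManifest, exposures: dict, outcomes: dict,
              ld: LDTable | None = None,
              config: PipelineConfig | None = None):
    """One result per taxon x outcome; suggestive or corrected taxa trigger a
    reverse-direction run. Per-taxon failures are recorded (status ``error``)
    and the panel continues.

    Returns (list of TaxonResult, summary DataFrame in the tabular result
    schema of :func:`results_table`).
    """
    config = config or PipelineConfig()
    results = []
    for row in manifest:
        taxon, rank = row.taxon, row.rank
        thr = bonferroni_threshold(rank, manifest, config.alpha)
        for out_name, out_df in outcomes.items():
            if taxon not in exposures:
                res = TaxonResult(taxon=taxon, rank=rank, outcome=out_name,
                                  status="error", error="missing exposure data",
                                  threshold=thr)
                results.append(res)
                continue
            seed = pair_seed(config.seed, taxon, out_name)
            try:
                res = run_pair(exposures[taxon], out_df, ld=ld, config=config,
                               taxon=taxon, rank=rank, outcome_name=out_name,
                               threshold=thr, seed=seed)
            except GutMRError as exc:  # record, keep going
                res = TaxonResult(taxon=taxon, rank=rank, outcome=out_name,
                                  status="error", error=str(exc), threshold=thr)
            if res.status == "ok" and (config.reverse_all or res.band != "null"):
                res.reverse = run_reverse(out_df, exposures[taxon], config=config,
                                          taxon=out_name, outcome_name=taxon,
                                          seed=(seed + 17) % 2**31)
            results.append(res)
    return results, results_table(results)


def _fmt(x, nd=6):
    return "" if x is None else f"{x:.{nd}g}"


def results_table(results: list) -> pd.DataFrame:
    """Flatten results into the study's tabular schema: one row per
    exposure-outcome pair with instrument count, per-method OR/CI/p, Egger
    intercept test, Cochran's Q, decision-rule outputs, and band."""
    rows = []
    for r in results:
        d = r.diagnostics
        row = {
            "Outcome": r.outcome, "Exposure": r.taxon, "Rank": r.rank or "",
            "SNP": r.n_snp, "status": r.status,
            "effects_model": r.effects_model_used or "",
            "outliers_removed": ",".join(r.outliers_removed),
            "band": r.band, "threshold": _fmt(r.threshold),
            "wm_consistent": "" if r.wm_consistent is None else str(r.wm_consistent),
            "pleiotropy_flag": "" if r.pleiotropy_flag is None else str(r.pleiotropy_flag),
        }
        h = r.headline
        row["IVW_OR"] = _fmt(h.or_ if h else None)
        row["IVW_CI"] = (f"({h.ci_low:.4g}, {h.ci_high:.4g})" if h else "")
        row["P_IVW"] = _fmt(h.pval if h else None)
        row["Egger_intercept"] = _fmt(d.egger_intercept)
        row["Egger_intercept_SE"] = _fmt(d.egger_intercept_se)
        row["P_MR_Egger_intercept"] = _fmt(d.egger_intercept_p)
        row["Cochrans_Q"] = _fmt(d.q_stat)
        row["P_Cochrans_Q"] = _fmt(d.q_pval)
        row["P_MR_PRESSO"] = _fmt(d.presso_global_p)
        row["loo_stable"] = "" if d.loo_stable is None else str(d.loo_stable)
        for method in ("egger", "weighted_median", "weighted_mode"):
            e = r.estimates.get(method)
            row[f"{method}_OR"] = _fmt(e.or_ if e else None)
            row[f"{method}_CI"] = (f"({e.ci_low:.4g}, {e.ci_high:.4g})" if e else "")
            row[f"P_{method}"] = _fmt(e.pval if e else None)
        rv = r.reverse.headline if (r.reverse and r.reverse.headline) else None
        row["reverse_status"] = r.reverse.status if r.reverse else ""
        row["reverse_P_IVW"] = _fmt(rv.pval if rv else None)
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
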