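import numpy as np
import pandas as pd
import pytest

from gutmr.io import harmonize
from gutmr.simulate import SimulationConfig, simulate_summary_pair


def make_records(rows):
    """Build a canonical summary-statistics frame from dict rows, filling
    required bookkeeping columns with simple defaults."""
    defaults = dict(chrom="1", pos=1000, effect_allele="A", other_allele="G",
                    eaf=0.3, beta=0.1, se=0.05, pval=1e-6, n=10000)
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults, snp_id=f"rs{i + 1}", pos=1000 + i * 25_000_000)
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)


def make_instruments(ratios, ratio_ses, beta_exp=0.2):
    """Instrument table with prescribed Wald ratios and ratio SEs (exposure
    betas are spread slightly so intercept regressions are well posed)."""
    ratios = np.asarray(ratios, dtype=float)
    ratio_ses = np.asarray(ratio_ses, dtype=float)
    bx = beta_exp * (1.0 + 0.05 * np.arange(len(ratios)))
    return pd.DataFrame({
        "snp_id": [f"rs{i + 1}" for i in range(len(ratios))],
        "beta_exp": bx, "se_exp": np.full_like(ratios, 0.02),
        "beta_out": ratios * bx, "se_out": ratio_ses * np.abs(bx),
        "ratio": ratios, "ratio_se": ratio_ses,
        "f_stat": (bx / 0.02) ** 2,
    })


@pytest.fixture
def clean_instruments():
    """15 harmonized instruments from a seeded simulation with a true slope
    of log(2) and no pleiotropy."""
    cfg = SimulationConfig(n_snp=15, theta=float(np.log(2.0)), seed=42,
                           gamma_range=(0.1, 0.3), se_exp_range=(0.015, 0.025))
    exp_df, out_df, truth = simulate_summary_pair(cfg)
    return harmonize(exp_df, out_df), truth
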