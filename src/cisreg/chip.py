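"""ChIP-qPCR fold enrichment ("signal over background") and its one-sided
one-sample t-test against 1.

Per replicate, the input-normalized signal for an antibody is
eff^-(Ct_ip - Ct_input_adjusted) where the input Ct is adjusted for its
dilution by log_eff(dilution); fold enrichment is the specific
antibody's signal divided by the mock (IgG) signal.  Amplification
efficiency defaults to perfect doubling (eff = 2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def fold_enrichment(table: pd.DataFrame, site: str,
                    input_dilution_factor: float = 1.0,
                    efficiency: float = 2.0) -> pd.Series:
    """Per-replicate fold enrichment at one target site.

    ``table`` is long-format with columns target_site, antibody
    ("specific" or "mock_igg"), fraction ("ip" or "input"), replicate,
    ct.  Specific and mock rows are paired by replicate index.
    """
    need = {"target_site", "antibody", "fraction", "replicate", "ct"}
    if not need.issubset(table.columns):
        raise ValueError(f"ChIP table needs columns {sorted(need)}")
    sub = table[table["target_site"] == site]
    if sub.empty:
        raise ValueError(f"no rows for site {site!r}")
    if (sub["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    idx = sub.set_index(["antibody", "fraction", "replicate"])["ct"]
    reps = sorted(sub.loc[(sub["antibody"] == "specific") &
                          (sub["fraction"] == "ip"), "replicate"].unique())
    if not reps:
        raise ValueError(f"site {site!r}: no specific-antibody IP replicates")
    dilution_shift = np.log(input_dilution_factor) / np.log(efficiency)
    fes = {}
    for rep in reps:
        signals = {}
        for ab in ("specific", "mock_igg"):
            for frac in ("ip", "input"):
                if (ab, frac, rep) not in idx.index:
                    raise ValueError(f"site {site!r}: missing {ab}/{frac} Ct for replicate {rep}")
            ct_ip = idx.loc[(ab, "ip", rep)]
            ct_input = idx.loc[(ab, "input", rep)] - dilution_shift
            signals[ab] = efficiency ** (-(ct_ip - ct_input))
        fes[rep] = signals["specific"] / signals["mock_igg"]
    return pd.Series(fes, name="fold_enrichment")


def enrichment_significance(fe_values) -> tuple[float, float]:
    """One-sample t of mean fold enrichment against 1, upper-tailed."""
    fe = np.asarray(fe_values, dtype=float)
    if fe.size < 2:
        raise ValueError("need >= 2 fold-enrichment values")
    if fe.var(ddof=1) == 0:
        raise ValueError("fold-enrichment values have zero variance")
    res = stats.ttest_1samp(fe, popmean=1.0, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def chip_report(table: pd.DataFrame, site: str, input_dilution_factor: float = 1.0,
                efficiency: float = 2.0) -> dict:
    """Fold enrichment per replicate plus the one-sided t-test summary."""
    fe = fold_enrichment(table, site, input_dilution_factor, efficiency)
    t, p = enrichment_significance(fe.to_numpy())
    return {"site": site, "fold_enrichment": fe, "mean_fe": float(fe.mean()),
            "t": t, "p": p}
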