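"""Dual-luciferase reporter statistics.

Relative activity is the firefly/Renilla ratio normalized so the blank
(empty-effector) control group's mean is exactly 1.00.  Dose-response
comparisons use a two-sided pooled-variance Student t between adjacent
dose groups with Holm step-down correction.  Synergy between two
effectors is tested against the pooled-sum null: the pool of all n_A x
n_B pairwise sums of the single-effector relative activities defines
both the percentile confidence interval for the additive expectation and
the resampling distribution for a one-sided (upper tail) bootstrap
p-value on the combined group's mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class SumPool:
    """All-pairs sums of two groups' relative activities with percentile CI."""

    values: np.ndarray
    ci_low: float
    ci_high: float
    confidence: float

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")


@dataclass(frozen=True)
class SynergyResult:
    observed_mean: float
    pool: SumPool
    p_value: float
    n_boot: int
    seed: int


def relative_activity(table: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Per-well firefly/Renilla ratios normalized to the control-group mean.

    Returns a copy of the table with ``ratio`` and ``relative`` columns;
    the control group's mean relative activity is exactly 1.00.
    """
    need = {"group", "firefly", "renilla"}
    if not need.issubset(table.columns):
        raise ValueError(f"luciferase table needs columns {sorted(need)}")
    if (table["renilla"] <= 0).any():
        raise ValueError("Renilla luminescence must be positive")
    out = table.copy()
    out["ratio"] = out["firefly"] / out["renilla"]
    ctrl = out.loc[out["group"] == control_group, "ratio"]
    if ctrl.empty:
        raise ValueError(f"control group {control_group!r} has no wells")
    out["relative"] = out["ratio"] / ctrl.mean()
    return out


def collapse_technical(table: pd.DataFrame, value: str = "relative") -> pd.DataFrame:
    """Average technical replicates into their biological replicate."""
    keys = ["group", "bio_replicate"]
    if not set(keys).issubset(table.columns):
        raise ValueError("table needs group and bio_replicate columns")
    return table.groupby(keys, as_index=False)[value].mean()


def dose_response_tests(groups: Sequence[tuple[str, Sequence[float]]]) -> pd.DataFrame:
    """Adjacent-pair Student t-tests over increasing doses, Holm-adjusted.

    ``groups`` is ordered by dose.  Each adjacent pair gets a two-sided
    pooled-variance t-test; a pair where both groups have zero variance
    is flagged (p = NaN) and excluded from the Holm family.
    """
    if len(groups) < 2:
        raise ValueError("need at least two dose groups")
    rows = []
    for (name_a, a), (name_b, b) in zip(groups[:-1], groups[1:]):
        a, b = np.asarray(a, float), np.asarray(b, float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"groups {name_a!r}/{name_b!r} need >= 2 wells each")
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            rows.append({"pair": f"{name_a} vs {name_b}", "t": np.nan,
                         "p_raw": np.nan, "error": "zero variance in both groups"})
            continue
        res = stats.ttest_ind(a, b, equal_var=True)
        rows.append({"pair": f"{name_a} vs {name_b}", "t": float(res.statistic),
                     "p_raw": float(res.pvalue), "error": ""})
    df = pd.DataFrame(rows)
    ok = df["p_raw"].notna()
    df["p_holm"] = np.nan
    if ok.any():
        df.loc[ok, "p_holm"] = multipletests(df.loc[ok, "p_raw"], method="holm")[1]
    return df


def pooled_sum_null(group_a: Sequence[float], group_b: Sequence[float],
                    confidence: float = 0.95) -> SumPool:
    """All-pairs sum pool of two effector groups with its percentile CI.

    The CI is the central linear-interpolation empirical quantile
    interval at (1-c)/2 and 1-(1-c)/2.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both effector groups must be non-empty")
    if not (0 < confidence < 1):
        raise ValueError("confidence must lie in (0, 1)")
    values = np.add.outer(a, b).ravel()
    tail = (1 - confidence) / 2
    lo, hi = np.quantile(values, [tail, 1 - tail])
    return SumPool(values=values, ci_low=float(lo), ci_high=float(hi),
                   confidence=confidence)


def synergy_bootstrap_p(pool: SumPool, combined_group: Sequence[float],
                        n_boot: int = 100_000, seed: int = 0) -> SynergyResult:
    """One-sided bootstrap test of the combined mean against the sum pool.

    Each iteration draws len(combined_group) values from the pool with
    replacement and records the mean; p = (1 + #{boot mean >= observed
    mean}) / (n_boot + 1).  Deterministic under a fixed seed.
    """
    combined = np.asarray(combined_group, dtype=float)
    if combined.size == 0:
        raise ValueError("combined group must be non-empty")
    if pool.values.size == 0:
        raise ValueError("sum pool is empty")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    observed = float(combined.mean())
    rng = np.random.default_rng(seed)
    k = combined.size
    exceed = 0
    chunk = max(1, min(n_boot, 2_000_000 // k))
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        draws = rng.choice(pool.values, size=(m, k), replace=True)
        exceed += int((draws.mean(axis=1) >= observed).sum())
        done += m
    p = (1 + exceed) / (n_boot + 1)
    return SynergyResult(observed_mean=observed, pool=pool, p_value=float(p),
                         n_boot=n_boot, seed=seed)


def synergy_test(table: pd.DataFrame, control_group: str, group_a: str, group_b: str,
                 combined: str, confidence: float = 0.95, n_boot: int = 100_000,
                 seed: int = 0) -> SynergyResult:
    """End-to-end synergy test from a raw luciferase table.

    Normalizes to the control, averages technical into biological
    replicates, builds the pooled-sum null from the two single-effector
    groups, and bootstrap-tests the combined group's mean.
    """
    rel = relative_activity(table, control_group)
    per_bio = (collapse_technical(rel) if "bio_replicate" in rel.columns else
               rel.rename(columns={"ratio": "_r"}))
    def values(g):
        v = per_bio.loc[per_bio["group"] == g, "relative"].to_numpy()
        if v.size == 0:
            raise ValueError(f"group {g!r} has no wells")
        return v
    pool = pooled_sum_null(values(group_a), values(group_b), confidence=confidence)
    return synergy_bootstrap_p(pool, values(combined), n_boot=n_boot, seed=seed)
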