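"""Expression quantification rules: 2^-ddCt qPCR relative quantification,
tissue-panel normalization, the hepatopancreas-enriched-gene conjunction
rule, and reciprocal-best-hit orthologue mapping.

The qPCR model is the classic comparative-Ct method: per replicate,
dCt = Ct_target - Ct_reference; ddCt = mean dCt(tissue) - mean
dCt(calibrator); RQ = 2^-ddCt.  Confidence intervals are t-intervals on
the dCt scale transformed through 2^-x, which keeps them positive and
asymmetric around RQ, matching how fold-change error bars behave.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

BLAST_TAB_COLUMNS = ["query", "subject", "pident", "length", "mismatch", "gapopen",
                     "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


@dataclass(frozen=True)
class RQResult:
    gene: str
    tissue: str
    rq: float
    ci_low: float
    ci_high: float
    n_replicates: int


def delta_delta_ct(table: pd.DataFrame, gene: str, calibrator_tissue: str,
                   reference_gene: str, confidence: float = 0.95) -> list[RQResult]:
    """Relative quantification of ``gene`` across tissues by 2^-ddCt.

    ``table`` is long-format with columns gene, tissue, replicate, ct.
    The reference gene's Ct must be present for every (tissue, replicate)
    of the target.  CIs use a t-quantile with df = n-1 on the mean dCt,
    transformed through 2^-x (bounds swapped so ci_low <= ci_high); with
    a single replicate the CI is returned as NaN.
    """
    required = {"gene", "tissue", "replicate", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    tgt = table[table["gene"] == gene].set_index(["tissue", "replicate"])["ct"]
    ref = table[table["gene"] == reference_gene].set_index(["tissue", "replicate"])["ct"]
    if tgt.empty:
        raise ValueError(f"no rows for target gene {gene!r}")
    missing = tgt.index.difference(ref.index)
    if len(missing):
        raise ValueError(f"reference gene {reference_gene!r} missing Ct for {list(missing)[:3]}")
    dct = tgt - ref.loc[tgt.index]
    per_tissue = dct.groupby(level="tissue").agg(["mean", "std", "count"])
    if calibrator_tissue not in per_tissue.index:
        raise ValueError(f"calibrator tissue {calibrator_tissue!r} absent from table")
    calib_mean = per_tissue.loc[calibrator_tissue, "mean"]
    out = []
    for tissue, row in per_tissue.iterrows():
        ddct = row["mean"] - calib_mean
        rq = float(2.0 ** (-ddct))
        n = int(row["count"])
        if n >= 2 and np.isfinite(row["std"]):
            margin = stats.t.ppf((1 + confidence) / 2, df=n - 1) * row["std"] / np.sqrt(n)
            lo, hi = 2.0 ** (-(ddct + margin)), 2.0 ** (-(ddct - margin))
        else:
            lo = hi = float("nan")
        out.append(RQResult(gene=gene, tissue=str(tissue), rq=rq,
                            ci_low=float(lo), ci_high=float(hi), n_replicates=n))
    return out


def normalize_to_max_tissue(results: Sequence[RQResult]) -> list[RQResult]:
    """Rescale so the highest-RQ tissue sits at 1.0 (CI bounds rescale too)."""
    if not results:
        raise ValueError("no RQ results to normalize")
    scale = max(r.rq for r in results)
    if scale <= 0:
        raise ValueError("all RQ values are zero")
    return [RQResult(gene=r.gene, tissue=r.tissue, rq=r.rq / scale,
                     ci_low=r.ci_low / scale, ci_high=r.ci_high / scale,
                     n_replicates=r.n_replicates) for r in results]


def enriched_genes(matrix: pd.DataFrame, sample_organs: Mapping[str, str],
                   focal_organs: Sequence[str] = ("digestive_gland", "hepatopancreas"),
                   other_organs: Sequence[str] | None = None, alpha: float = 0.05,
                   mode: str = "pairwise", bh_correct: bool = False
                   ) -> tuple[set[str], pd.DataFrame]:
    """Genes enriched in *both* focal digestive samples versus other organs.

    A gene qualifies iff for every other organ, each focal organ's
    samples show higher mean expression with one-sided Welch-t p < alpha
    on log2(x+1)-transformed abundances.  ``mode='pooled'`` pools all
    other organs into one comparison group instead of testing each
    pairwise.  Returns (qualifying gene set, full comparison table).
    """
    organs_by_sample = dict(sample_organs)
    cols_by_organ: dict[str, list[str]] = {}
    for sample, organ in organs_by_sample.items():
        if sample in matrix.columns:
            cols_by_organ.setdefault(organ, []).append(sample)
    for organ in focal_organs:
        if organ not in cols_by_organ:
            raise ValueError(f"focal organ {organ!r} has no samples in the matrix")
    if other_organs is None:
        other_organs = [o for o in cols_by_organ if o not in set(focal_organs)]
    if (matrix.values < 0).any():
        raise ValueError("expression values must be non-negative")
    log = np.log2(matrix.astype(float) + 1.0)
    if mode == "pooled":
        pooled_cols = [c for o in other_organs for c in cols_by_organ[o]]
        comparisons = [("pooled_others", pooled_cols)]
    elif mode == "pairwise":
        comparisons = [(o, cols_by_organ[o]) for o in other_organs]
    else:
        raise ValueError("mode must be 'pairwise' or 'pooled'")
    rows = []
    qualify = np.ones(len(matrix), dtype=bool)
    for focal in focal_organs:
        a = log[cols_by_organ[focal]].values
        for other_name, cols in comparisons:
            b = log[cols].values
            res = stats.ttest_ind(a, b, axis=1, equal_var=False, alternative="greater")
            p = np.asarray(res.pvalue)
            if bh_correct:
                from statsmodels.stats.multitest import multipletests
                p = multipletests(p, method="fdr_bh")[1]
            qualify &= p < alpha
            rows.append(pd.DataFrame({
                "gene": matrix.index, "focal": focal, "other": other_name,
                "mean_focal_log2": a.mean(axis=1), "mean_other_log2": b.mean(axis=1),
                "p": p}))
    table = pd.concat(rows, ignore_index=True)
    return set(matrix.index[qualify]), table


def read_blast_tab(path) -> pd.DataFrame:
    """Read 12-column tabular similarity hits (blast outfmt 6 layout)."""
    return pd.read_csv(path, sep="\t", header=None, names=BLAST_TAB_COLUMNS,
                       comment="#")


def reciprocal_best_hits(hits_ab: pd.DataFrame, hits_ba: pd.DataFrame,
                         e_cutoff: float = 1e-5) -> list[tuple[str, str]]:
    """Mutual-top-scoring pairs between two similarity-hit tables.

    Best hit per query = maximum bitscore among hits with
    e_value <= e_cutoff; ties broken by lower e-value then lexicographic
    subject id.  (a, b) is reported iff b is a's best subject in
    ``hits_ab`` and a is b's best subject in ``hits_ba``.
    """
    best_ab = _best_hits(hits_ab, e_cutoff)
    best_ba = _best_hits(hits_ba, e_cutoff)
    pairs = [(a, b) for a, b in best_ab.items() if best_ba.get(b) == a]
    return sorted(pairs)


def _best_hits(hits: pd.DataFrame, e_cutoff: float) -> dict[str, str]:
    if hits.empty:
        return {}
    need = {"query", "subject", "evalue", "bitscore"}
    if not need.issubset(hits.columns):
        raise ValueError(f"hit table needs columns {sorted(need)}")
    if (hits["evalue"] < 0).any():
        raise ValueError("e-values must be non-negative")
    kept = hits[hits["evalue"] <= e_cutoff]
    if kept.empty:
        return {}
    ranked = kept.sort_values(["query", "bitscore", "evalue", "subject"],
                              ascending=[True, False, True, True])
    top = ranked.drop_duplicates("query", keep="first")
    return dict(zip(top["query"], top["subject"]))
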