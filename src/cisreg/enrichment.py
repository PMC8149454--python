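"""Motif over-representation in peak classes versus background.

For a motif and a peak class (e.g. promoters), the unit of counting is
the peak: a peak "contains" the motif if at least one scanned window
passes the FPR-calibrated threshold.  Over-representation relative to a
background sequence set is assessed by a one-sided Fisher exact test
(hypergeometric upper tail), and p-values are Bonferroni-adjusted across
all motif x class tests in a profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .motifs import PWM, BackgroundModel, calibrate_threshold, max_scores


@dataclass(frozen=True)
class EnrichmentResult:
    motif_id: str
    peak_class: str
    hits_in_class: int
    class_size: int
    hits_in_background: int
    background_size: int
    p_raw: float
    p_adjusted: float


def enrichment_test(hits_in_class: int, class_size: int,
                    hits_in_background: int, background_size: int) -> float:
    """One-sided Fisher exact p for the class hit count being this high.

    Equals the hypergeometric upper tail P(X >= hits_in_class) with the
    class/background margins fixed.
    """
    if class_size <= 0:
        raise ValueError("class_size must be positive")
    for label, hits, size in (("class", hits_in_class, class_size),
                              ("background", hits_in_background, background_size)):
        if hits < 0 or size < 0 or hits > size:
            raise ValueError(f"invalid {label} counts: {hits}/{size}")
    table = [[hits_in_class, class_size - hits_in_class],
             [hits_in_background, background_size - hits_in_background]]
    return float(stats.fisher_exact(table, alternative="greater").pvalue)


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Single-step Bonferroni: each p multiplied by the family size, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="bonferroni")[1])


def _n_with_hit(pwm: PWM, sequences: Iterable[str], background: BackgroundModel,
                threshold: float) -> int:
    scores = max_scores(pwm, sequences, background)
    return int((scores >= threshold).sum())


def enrichment_profile(motifs: Sequence[PWM],
                       promoter_seqs: Sequence[str],
                       enhancer_seqs: Sequence[str],
                       background: BackgroundModel,
                       fpr: float = 0.01) -> list[EnrichmentResult]:
    """Per-motif, per-class enrichment with family-wise Bonferroni adjustment.

    For each motif: calibrate the threshold on the background sequences
    at ``fpr``, count sequences containing >= 1 passing window in each
    class and in the background, then Fisher-test each class against the
    background.  Adjustment spans all motif x class tests performed.
    """
    classes = [("promoter", list(promoter_seqs)), ("enhancer", list(enhancer_seqs))]
    partial = []
    for pwm in motifs:
        thr = calibrate_threshold(pwm, background, fpr=fpr)
        bg_hits = _n_with_hit(pwm, background.sequences, background, thr.threshold)
        bg_size = len(background.sequences)
        for cls_name, seqs in classes:
            if not seqs:
                continue
            k = _n_with_hit(pwm, seqs, background, thr.threshold)
            p = enrichment_test(k, len(seqs), bg_hits, bg_size)
            partial.append((pwm.id, cls_name, k, len(seqs), bg_hits, bg_size, p))
    adjusted = bonferroni([row[-1] for row in partial])
    return [EnrichmentResult(motif_id=m, peak_class=c, hits_in_class=k, class_size=n,
                             hits_in_background=bk, background_size=bn,
                             p_raw=p, p_adjusted=pa)
            for (m, c, k, n, bk, bn, p), pa in zip(partial, adjusted)]


def write_enrichment_tsv(path, results: Sequence[EnrichmentResult]) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\tclass\thits_in_class\tclass_size\t"
                 "hits_in_background\tbackground_size\tp_raw\tp_adjusted\n")
        for r in results:
            fh.write(f"{r.motif_id}\t{r.peak_class}\t{r.hits_in_class}\t{r.class_size}\t"
                     f"{r.hits_in_background}\t{r.background_size}\t"
                     f"{r.p_raw:.6g}\t{r.p_adjusted:.6g}\n")
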