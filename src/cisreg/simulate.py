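"""Synthetic data generators with ground truth for every pipeline stage.

Each generator is a pure function of (parameters, seed) and returns its
artifacts together with a truth table sufficient to score the downstream
analysis: planted motif sites, replicate peak structure, organ-enriched
genes, additive/synergistic/null reporter effects, and true ChIP fold
enrichments.  Noise models are Gaussian on the natural measurement
scales (Ct cycles, log2 expression, relative luciferase activity).

Defaults mirror the study designs the analyses were built for: two ATAC
replicates, a digestive-gland + hepatopancreas focal pair against other
organs, luciferase assays with 3 biological x 2 technical replicates,
and small-replicate ChIP-qPCR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import PWM, BackgroundModel, encode_sequence, score_window
from .peaks import GenomicInterval

_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _LUT[codes].tobytes().decode("ascii")


def gen_pwm(consensus: str, consensus_prob: float = 0.85, concentration: float = 60.0,
            seed: int = 0, id: str = "sim_motif") -> PWM:
    """A realistic PWM around a consensus: Dirichlet noise per position.

    Matrices estimated from real binding data carry continuous
    probabilities, which keeps the log-odds score distribution free of
    large ties; ``concentration`` controls how tightly each column
    scatters around the consensus profile.
    """
    rng = np.random.default_rng(seed)
    codes = encode_sequence(consensus.upper())
    if np.any(codes > 3):
        raise ValueError("consensus must contain only A/C/G/T")
    off = (1.0 - consensus_prob) / 3.0
    rows = []
    for c in codes:
        alpha = np.full(4, off)
        alpha[c] = consensus_prob
        rows.append(rng.dirichlet(alpha * concentration))
    return PWM.from_matrix(id, np.vstack(rows))


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def gen_genome(n_chrom: int = 2, length: int = 100_000, gc: float = 0.4,
               seed: int = 0, repeat_density: float = 0.0,
               repeat_length: int = 500) -> tuple[dict[str, str], list[GenomicInterval]]:
    """I.i.d. genome at a given GC content plus a repeat annotation.

    ``repeat_density`` is the expected fraction of each chromosome
    annotated as repeat; repeats of ``repeat_length`` bp are placed
    uniformly (annotation only; the sequence itself is not altered).
    """
    if length < 1000:
        raise ValueError("chromosome length must be >= 1000")
    if not (0 < gc < 1):
        raise ValueError("gc must lie in (0, 1)")
    if not (0 <= repeat_density < 1):
        raise ValueError("repeat_density must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = {}
    repeats: list[GenomicInterval] = []
    for c in range(n_chrom):
        name = f"chr{c + 1}"
        genome[name] = _codes_to_str(rng.choice(4, size=length, p=p))
        n_rep = int(round(repeat_density * length / repeat_length))
        for r in range(n_rep):
            start = int(rng.integers(0, length - repeat_length))
            repeats.append(GenomicInterval(chrom=name, start=start,
                                           end=start + repeat_length,
                                           name=f"rep_{name}_{r}"))
    repeats.sort(key=lambda iv: (iv.chrom, iv.start))
    return genome, repeats


def write_fasta(path, genome: Mapping[str, str]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Replicate peaks with planted motif sites
# ---------------------------------------------------------------------------

def sample_site(pwm: PWM, rng, min_score: float | None = None,
                background: BackgroundModel | None = None,
                max_tries: int = 10_000) -> str:
    """Draw a site from the PWM's own distribution, optionally rejection-
    sampled until its forward score reaches ``min_score``."""
    bg = background if background is not None else BackgroundModel.uniform()
    for _ in range(max_tries):
        codes = np.array([rng.choice(4, p=row) for row in pwm.matrix])
        site = _codes_to_str(codes)
        if min_score is None or score_window(pwm, site, bg) >= min_score:
            return site
    raise RuntimeError(f"could not sample a site scoring >= {min_score} "
                       f"from {pwm.id} in {max_tries} tries")


def gen_peaks_with_motifs(genome: Mapping[str, str], pwm: PWM, n_peaks: int = 200,
                          peak_length: int = 400, planted_fraction: float = 0.5,
                          jitter: int = 20, dropout: float = 0.0, seed: int = 0,
                          min_score: float | None = None,
                          background: BackgroundModel | None = None
                          ) -> tuple[list[GenomicInterval], list[GenomicInterval],
                                     pd.DataFrame, dict[str, str]]:
    """Two replicate peak sets over a genome with motif sites planted.

    Base peaks are placed without overlap (uniformly among non-adjacent
    slots); a ``planted_fraction`` subset receives one motif site
    (sampled from the PWM's distribution, rejection-sampled above
    ``min_score`` when given) written into the genome at the peak
    center.  Each replicate independently jitters both boundaries by
    +/- ``jitter`` bp and drops each peak with probability ``dropout``.

    Returns (rep1, rep2, truth, genome_with_sites).  Truth columns:
    peak_id, chrom, start, end, planted, site_start, site_seq,
    in_rep1, in_rep2.
    """
    if not (0 <= planted_fraction <= 1) or not (0 <= dropout < 1):
        raise ValueError("planted_fraction in [0,1] and dropout in [0,1) required")
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    slot = peak_length + 2 * jitter + 10
    slots = [(c, i) for c in chroms for i in range(len(genome[c]) // slot)]
    if len(slots) < n_peaks:
        raise ValueError(f"cannot pack {n_peaks} peaks of {peak_length} bp "
                         f"into this genome (only {len(slots)} slots)")
    chosen = [slots[i] for i in sorted(rng.choice(len(slots), size=n_peaks, replace=False))]
    seqs = {c: np.array(bytearray(genome[c].encode("ascii")), dtype=np.uint8) for c in chroms}
    n_planted = int(round(planted_fraction * n_peaks))
    planted_idx = set(rng.choice(n_peaks, size=n_planted, replace=False).tolist())
    rows = []
    base: list[GenomicInterval] = []
    for i, (chrom, slot_i) in enumerate(chosen):
        start = slot_i * slot + jitter
        end = start + peak_length
        site_start, site_seq = -1, ""
        if i in planted_idx:
            site_seq = sample_site(pwm, rng, min_score=min_score, background=background)
            site_start = start + (peak_length - len(pwm)) // 2
            seqs[chrom][site_start: site_start + len(pwm)] = \
                np.frombuffer(site_seq.encode("ascii"), dtype=np.uint8)
        base.append(GenomicInterval(chrom=chrom, start=start, end=end, name=f"base_{i:04d}"))
        rows.append({"peak_id": f"base_{i:04d}", "chrom": chrom, "start": start,
                     "end": end, "planted": i in planted_idx,
                     "site_start": site_start, "site_seq": site_seq})
    truth = pd.DataFrame(rows)
    reps = []
    for rep in range(2):
        kept = []
        flags = []
        for iv in base:
            if dropout > 0 and rng.random() < dropout:
                flags.append(False)
                continue
            flags.append(True)
            if jitter > 0:
                ds = int(rng.integers(-jitter, jitter + 1))
                de = int(rng.integers(-jitter, jitter + 1))
            else:
                ds = de = 0
            start = max(0, iv.start + ds)
            end = min(len(genome[iv.chrom]), iv.end + de)
            if end <= start:
                start, end = iv.start, iv.end
            kept.append(GenomicInterval(chrom=iv.chrom, start=start, end=end,
                                        name=f"rep{rep + 1}_{iv.name}"))
        truth[f"in_rep{rep + 1}"] = flags
        reps.append(kept)
    genome_out = {c: seqs[c].tobytes().decode("ascii") for c in chroms}
    return reps[0], reps[1], truth, genome_out


# ---------------------------------------------------------------------------
# Organ expression panel
# ---------------------------------------------------------------------------

def gen_expression(n_genes: int = 2000,
                   organs: Sequence[str] = ("digestive_gland", "hepatopancreas",
                                            "gill", "mantle", "adductor_muscle"),
                   focal_organs: Sequence[str] = ("digestive_gland", "hepatopancreas"),
                   n_enriched: int = 100, effect: float = 3.0, dispersion: float = 0.25,
                   replicates: int = 3, seed: int = 0
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Genes x samples abundance matrix with a planted enriched-gene subset.

    Per-gene log2 baselines are uniform on [3, 9]; samples add Gaussian
    noise with sd ``dispersion`` on the log2 scale; the first
    ``n_enriched`` genes (shuffled) gain ``effect`` log2-fold in every
    focal-organ sample.  Returns (matrix, sample_sheet, truth).
    """
    if n_enriched > n_genes:
        raise ValueError("n_enriched cannot exceed n_genes")
    for organ in focal_organs:
        if organ not in organs:
            raise ValueError(f"focal organ {organ!r} not in organ panel")
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    enriched = set(rng.choice(n_genes, size=n_enriched, replace=False).tolist())
    baseline = rng.uniform(3, 9, size=n_genes)
    cols, organ_of = [], {}
    for organ in organs:
        for r in range(1, replicates + 1):
            s = f"{organ}_r{r}"
            cols.append(s)
            organ_of[s] = organ
    data = np.empty((n_genes, len(cols)))
    focal = set(focal_organs)
    for j, s in enumerate(cols):
        shift = np.where([i in enriched for i in range(n_genes)],
                         effect if organ_of[s] in focal else 0.0, 0.0)
        data[:, j] = 2.0 ** (baseline + shift + rng.normal(0, dispersion, size=n_genes))
    matrix = pd.DataFrame(data, index=genes, columns=cols)
    sheet = pd.DataFrame({"sample": cols, "organ": [organ_of[s] for s in cols]})
    truth = pd.DataFrame({"gene": genes,
                          "enriched": [i in enriched for i in range(n_genes)],
                          "log2_effect": [effect if i in enriched else 0.0
                                          for i in range(n_genes)]})
    return matrix, sheet, truth


# ---------------------------------------------------------------------------
# Dual-luciferase tables
# ---------------------------------------------------------------------------

def gen_luciferase(mode: str = "additive", mean_a: float = 3.0, mean_b: float = 2.0,
                   noise_sd: float = 0.15, n_bio: int = 3, n_tech: int = 2,
                   synergy_factor: float = 2.0, seed: int = 0,
                   n_bio_combined: int | None = None
                   ) -> tuple[pd.DataFrame, dict]:
    """Firefly/Renilla well table under a null, additive or synergistic model.

    Groups: "blank" (control, true relative activity 1), "effector_a",
    "effector_b", and "combined".  Biological replicates draw their true
    activity as group mean + N(0, noise_sd); technical replicates add
    N(0, noise_sd/5) on top.  Under ``additive`` each combined
    biological replicate is an independent A-draw + B-draw (so its mean
    is mean_a + mean_b on the relative-activity scale — exactly the
    quantity the pooled-sum null resamples); under ``synergistic`` that
    sum is multiplied by ``synergy_factor``; under ``null`` every
    effector group sits at the control level 1.
    """
    if mode not in ("null", "additive", "synergistic"):
        raise ValueError("mode must be null, additive or synergistic")
    if synergy_factor <= 0:
        raise ValueError("synergy_factor must be positive")
    rng = np.random.default_rng(seed)
    n_comb = n_bio if n_bio_combined is None else n_bio_combined
    rows = []
    scale = rng.uniform(1.5, 2.5)  # arbitrary plate-level firefly/renilla scale

    def add_group(group: str, activities: np.ndarray):
        for b, act in enumerate(activities, start=1):
            for t in range(1, n_tech + 1):
                well = act + rng.normal(0, noise_sd / 5)
                renilla = rng.normal(100, 5)
                rows.append({"group": group, "bio_replicate": b, "tech_replicate": t,
                             "firefly": max(well, 0.01) * scale * renilla,
                             "renilla": renilla})

    ma, mb = (1.0, 1.0) if mode == "null" else (mean_a, mean_b)
    add_group("blank", 1.0 + rng.normal(0, noise_sd, size=n_bio))
    add_group("effector_a", ma + rng.normal(0, noise_sd, size=n_bio))
    add_group("effector_b", mb + rng.normal(0, noise_sd, size=n_bio))
    comb = (ma + rng.normal(0, noise_sd, size=n_comb)) + \
           (mb + rng.normal(0, noise_sd, size=n_comb))
    if mode == "synergistic":
        comb = comb * synergy_factor
    add_group("combined", comb)
    truth = {"mode": mode, "mean_a": ma, "mean_b": mb,
             "expected_combined_mean": (ma + mb) * (synergy_factor if mode == "synergistic" else 1.0),
             "synergy_factor": synergy_factor if mode == "synergistic" else 1.0,
             "noise_sd": noise_sd, "seed": seed}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# ChIP-qPCR tables
# ---------------------------------------------------------------------------

def gen_chip(true_fe: float = 2.2, ct_base: float = 28.0, noise_sd: float = 0.15,
             replicates: int = 4, seed: int = 0, site: str = "site_1",
             input_ct: float = 24.0) -> tuple[pd.DataFrame, dict]:
    """ChIP Ct table with a known true fold enrichment.

    Mock (IgG) IP Cts sit at ``ct_base``; specific-antibody IP Cts at
    ct_base - log2(true_fe); both get N(0, noise_sd) cycle noise.  Input
    Cts are shared (noise-free) so the realized fold enrichment is
    true_fe * 2^(mock noise - specific noise).
    """
    if true_fe <= 0:
        raise ValueError("true_fe must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, replicates + 1):
        for antibody, ct_ip in (("specific", ct_base - np.log2(true_fe) + rng.normal(0, noise_sd)),
                                ("mock_igg", ct_base + rng.normal(0, noise_sd))):
            rows.append({"target_site": site, "antibody": antibody, "fraction": "ip",
                         "replicate": rep, "ct": float(ct_ip)})
            rows.append({"target_site": site, "antibody": antibody, "fraction": "input",
                         "replicate": rep, "ct": float(input_ct)})
    truth = {"site": site, "true_fe": true_fe, "noise_sd": noise_sd,
             "replicates": replicates, "seed": seed}
    return pd.DataFrame(rows), truth
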