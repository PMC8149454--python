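"""Position weight matrix models: I/O, similarity, clustering, scoring and scanning.

A PWM here is a per-position nucleotide probability matrix (columns in
A, C, G, T order).  Scores are log-odds in bits against a background
nucleotide model.  Scan thresholds are calibrated empirically: the score
cutoff is set so that a chosen fraction (the false-positive rate, FPR) of
background sequences would contain at least one passing window.  This is
the standard construction used to define "statistically significant"
motif occurrences in open-chromatin scans.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

ALPHABET = "ACGT"

#: byte translation: A/a->0, C/c->1, G/g->2, T/t->3, everything else (incl. N)->4
_ENCODE_TABLE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE_TABLE[_b] = _i
    _ENCODE_TABLE[_b + 32] = _i  # lowercase

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """A position probability matrix with pseudocount regularization.

    Parameters
    ----------
    id:
        Motif identifier.
    matrix:
        Array of shape (L, 4); row i holds P(A), P(C), P(G), P(T) at
        position i.  Use :meth:`from_matrix` to build a regularized
        instance from raw (possibly zero-containing) probabilities.
    source_ids:
        Identifiers of the motifs this one was derived from (e.g. the
        members averaged into a cluster consensus).
    pseudocount:
        Probability mass added to every cell before renormalization.
    """

    id: str
    matrix: np.ndarray
    source_ids: tuple[str, ...] = ()
    pseudocount: float = 1e-3

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError(f"PWM {self.id!r}: matrix must have shape (L, 4)")
        if m.shape[0] < 4:
            raise ValueError(f"PWM {self.id!r}: motif length must be >= 4")
        if not np.all(m > 0):
            raise ValueError(f"PWM {self.id!r}: entries must be strictly positive after regularization")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.id!r}: columns must sum to 1 within 1e-6")

    @classmethod
    def from_matrix(cls, id: str, matrix, source_ids: Sequence[str] = (),
                    pseudocount: float = 1e-3) -> "PWM":
        """Regularize raw probabilities (add pseudocount, renormalize rows)."""
        m = np.asarray(matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError(f"PWM {id!r}: matrix must have shape (L, 4)")
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError(f"PWM {id!r}: probabilities must lie in [0, 1]")
        row_sums = m.sum(axis=1)
        if np.any(row_sums <= 0):
            bad = int(np.flatnonzero(row_sums <= 0)[0])
            raise ValueError(f"PWM {id!r}: position {bad} sums to 0")
        m = (m + pseudocount) / (row_sums + 4 * pseudocount)[:, None]
        return cls(id=id, matrix=m, source_ids=tuple(source_ids), pseudocount=pseudocount)

    @classmethod
    def from_consensus(cls, id: str, consensus: str, consensus_prob: float = 0.85,
                       pseudocount: float = 1e-3) -> "PWM":
        """Build a PWM placing ``consensus_prob`` on each consensus base."""
        off = (1.0 - consensus_prob) / 3.0
        m = np.full((len(consensus), 4), off)
        codes = encode_sequence(consensus.upper())
        if np.any(codes > 3):
            raise ValueError("consensus must contain only A/C/G/T")
        m[np.arange(len(consensus)), codes] = consensus_prob
        return cls.from_matrix(id, m, pseudocount=pseudocount)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "PWM":
        # reversing both axes maps A<->T and C<->G in ACGT column order
        return PWM(id=self.id, matrix=self.matrix[::-1, ::-1].copy(),
                   source_ids=self.source_ids, pseudocount=self.pseudocount)

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class BackgroundModel:
    """Background nucleotide model: genome-wide frequencies plus sequences.

    ``origin`` records how the sequences were obtained: drawn from a
    genome ("random_genomic"), simulated i.i.d. ("iid_uniform"), or
    user-supplied ("supplied").
    """

    freqs: np.ndarray
    sequences: tuple[str, ...] = ()
    origin: str = "supplied"

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", f)
        if f.shape != (4,) or not np.isclose(f.sum(), 1.0, atol=1e-6) or np.any(f <= 0):
            raise ValueError("background frequencies must be 4 positive values summing to 1")
        for s in self.sequences:
            if not s:
                raise ValueError("background sequences must be non-empty")
            if re.search("[^ACGTNacgtn]", s):
                raise ValueError("background sequence alphabet must be within {A,C,G,T,N}")

    @classmethod
    def uniform(cls, sequences: Sequence[str] = (), origin: str = "iid_uniform") -> "BackgroundModel":
        return cls(freqs=np.full(4, 0.25), sequences=tuple(sequences), origin=origin)

    @classmethod
    def from_sequences(cls, sequences: Sequence[str], origin: str = "supplied") -> "BackgroundModel":
        """Estimate frequencies from the sequences themselves (N ignored)."""
        counts = np.zeros(4)
        for s in sequences:
            codes = encode_sequence(s)
            counts += np.bincount(codes[codes < 4], minlength=4)
        if counts.sum() == 0:
            raise ValueError("cannot estimate frequencies: no A/C/G/T bases")
        return cls(freqs=counts / counts.sum(), sequences=tuple(sequences), origin=origin)

    @classmethod
    def iid(cls, n_sequences: int, length: int, freqs=None, rng=None,
            origin: str = "iid_uniform") -> "BackgroundModel":
        """Simulate i.i.d. background sequences at the given frequencies."""
        rng = np.random.default_rng(rng)
        f = np.full(4, 0.25) if freqs is None else np.asarray(freqs, dtype=float)
        codes = rng.choice(4, size=(n_sequences, length), p=f / f.sum())
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        seqs = tuple(lut[row].tobytes().decode("ascii") for row in codes)
        return cls(freqs=f / f.sum(), sequences=seqs, origin=origin)


@dataclass(frozen=True)
class ScanThreshold:
    """FPR-calibrated score cutoff for one PWM."""

    pwm_id: str
    fpr: float
    threshold: float
    n_background: int

    def __post_init__(self):
        if not (0 < self.fpr <= 1):
            raise ValueError("fpr must lie in (0, 1]")
        if self.n_background < 1:
            raise ValueError("n_background must be >= 1")


@dataclass(frozen=True)
class MotifHit:
    """Placement of a PWM on a region."""

    pwm_id: str
    region_id: str
    offset: int
    strand: str
    score: float
    passed: bool


# ---------------------------------------------------------------------------
# Motif I/O
# ---------------------------------------------------------------------------

def read_pwms(path, format: str = "meme", pseudocount: float = 1e-3) -> list[PWM]:
    """Read motifs from MEME-minimal or plain probability-table files.

    The probability-table dialect is one ``# <id>`` header line per motif
    followed by one row per position with four whitespace-separated
    probabilities (A, C, G, T).  Returned PWMs are regularized.
    """
    with open(path) as fh:
        text = fh.read()
    if format == "meme":
        records = _parse_meme(text, path)
    elif format == "probability_table":
        records = _parse_probability_table(text, path)
    else:
        raise ValueError(f"unknown motif format: {format!r}")
    return [PWM.from_matrix(mid, rows, pseudocount=pseudocount) for mid, rows in records]


def _parse_meme(text: str, path) -> list[tuple[str, list[list[float]]]]:
    records: list[tuple[str, list[list[float]]]] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {i + 1}: MOTIF line lacks an identifier")
            motif_id = parts[1]
            # find the letter-probability header
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith("letter-probability"):
                if lines[j].strip().startswith("MOTIF"):
                    raise ValueError(f"{path}: motif {motif_id!r} has no letter-probability matrix")
                j += 1
            if j == len(lines):
                raise ValueError(f"{path}: motif {motif_id!r} has no letter-probability matrix")
            header = lines[j].strip()
            m = re.search(r"w=\s*(\d+)", header)
            width = int(m.group(1)) if m else None
            rows = []
            j += 1
            while j < len(lines):
                s = lines[j].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                vals = s.split()
                if len(vals) != 4:
                    raise ValueError(f"{path}: line {j + 1}: expected 4 probabilities, got {len(vals)}")
                try:
                    rows.append([float(v) for v in vals])
                except ValueError as exc:
                    raise ValueError(f"{path}: line {j + 1}: malformed matrix row") from exc
                j += 1
            if width is not None and len(rows) != width:
                raise ValueError(f"{path}: motif {motif_id!r}: declared width {width}, found {len(rows)} rows")
            records.append((motif_id, rows))
            i = j
        else:
            i += 1
    if not records:
        raise ValueError(f"{path}: no MOTIF records found")
    return records


def _parse_probability_table(text: str, path) -> list[tuple[str, list[list[float]]]]:
    records: list[tuple[str, list[list[float]]]] = []
    current_id = None
    rows: list[list[float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if current_id is not None:
                records.append((current_id, rows))
            current_id = line.lstrip("#").strip()
            rows = []
            continue
        if current_id is None:
            raise ValueError(f"{path}: line {lineno}: matrix row before any '# id' header")
        vals = line.split()
        if len(vals) != 4:
            raise ValueError(f"{path}: line {lineno}: expected 4 probabilities, got {len(vals)}")
        try:
            rows.append([float(v) for v in vals])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: malformed matrix row") from exc
    if current_id is not None:
        records.append((current_id, rows))
    if not records:
        raise ValueError(f"{path}: no motifs found")
    return records


def write_pwms(path, pwms: Iterable[PWM], format: str = "meme") -> None:
    """Write motifs in MEME-minimal or probability-table format."""
    pwms = list(pwms)
    with open(path, "w") as fh:
        if format == "meme":
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
            fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
            for pwm in pwms:
                fh.write(f"MOTIF {pwm.id}\n")
                fh.write(f"letter-probability matrix: alength= 4 w= {len(pwm)} nsites= 20 E= 0\n")
                for row in pwm.matrix:
                    fh.write(" ".join(f"{v:.9f}" for v in row) + "\n")
                fh.write("\n")
        elif format == "probability_table":
            for pwm in pwms:
                fh.write(f"# {pwm.id}\n")
                for row in pwm.matrix:
                    fh.write("\t".join(f"{v:.9f}" for v in row) + "\n")
        else:
            raise ValueError(f"unknown motif format: {format!r}")


# ---------------------------------------------------------------------------
# Similarity and clustering
# ---------------------------------------------------------------------------

MIN_OVERLAP = 6


def _pearson_flat(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of flattened matrix blocks, with a degenerate-input guard."""
    x = x.ravel()
    y = y.ravel()
    sx, sy = x.std(), y.std()
    if sx < 1e-12 or sy < 1e-12:
        return 1.0 if np.allclose(x, y, atol=1e-9) else 0.0
    return float(np.corrcoef(x, y)[0, 1])


def pwm_similarity(a: PWM, b: PWM, min_overlap: int = MIN_OVERLAP) -> tuple[float, int, str]:
    """Best alignment similarity between two PWMs.

    Slides ``b`` (forward and reverse-complemented) along ``a`` over every
    relative offset with at least ``min_overlap`` overlapping columns and
    returns the maximum Pearson correlation of the overlapping probability
    entries, together with the best offset (position of b's first column
    relative to a's first column) and orientation ("+" or "-").
    """
    la, lb = len(a), len(b)
    if min(la, lb) < min_overlap:
        raise ValueError(f"motifs too short for min_overlap={min_overlap}")
    best = (-np.inf, 0, "+")
    for orient, bmat in (("+", b.matrix), ("-", b.reverse_complement().matrix)):
        for offset in range(-(lb - min_overlap), la - min_overlap + 1):
            a_lo, a_hi = max(0, offset), min(la, offset + lb)
            b_lo = a_lo - offset
            b_hi = b_lo + (a_hi - a_lo)
            if a_hi - a_lo < min_overlap:
                continue
            r = _pearson_flat(a.matrix[a_lo:a_hi], bmat[b_lo:b_hi])
            if r > best[0] + 1e-12:
                best = (r, offset, orient)
    return best


def cluster_pwms(pwms: Sequence[PWM], sim_threshold: float = 0.8,
                 min_overlap: int = MIN_OVERLAP) -> tuple[list[PWM], dict[str, int]]:
    """Greedy agglomerative motif clustering with averaged consensus motifs.

    Motifs are considered in input order; each joins the best-matching
    existing cluster whose current average it matches at similarity >=
    ``sim_threshold``, otherwise it seeds a new cluster.  A cluster's
    consensus is the column-wise mean of its members aligned at their
    best offsets/orientations (positions outside a member's extent
    contribute a uniform column), renormalized.  Singleton clusters pass
    the input motif through unchanged.

    Returns the list of cluster motifs and a mapping from input motif id
    to cluster index.
    """
    if not pwms:
        raise ValueError("need at least one PWM")
    clusters: list[dict] = []  # each: {"frames": [(matrix, offset)], "ids": [...], "avg": PWM}
    membership: dict[str, int] = {}
    for pwm in pwms:
        best_idx, best_sim, best_off, best_orient = -1, -np.inf, 0, "+"
        for idx, cl in enumerate(clusters):
            sim, off, orient = pwm_similarity(cl["avg"], pwm, min_overlap=min_overlap)
            if sim > best_sim:
                best_idx, best_sim, best_off, best_orient = idx, sim, off, orient
        if best_idx >= 0 and best_sim >= sim_threshold:
            cl = clusters[best_idx]
            mat = pwm.matrix if best_orient == "+" else pwm.reverse_complement().matrix
            cl["frames"].append((mat, best_off))
            cl["ids"].append(pwm.id)
            cl["avg"] = _average_frames(cl["frames"], cl["ids"])
            membership[pwm.id] = best_idx
        else:
            clusters.append({"frames": [(pwm.matrix, 0)], "ids": [pwm.id],
                             "avg": pwm, "seed": pwm})
            membership[pwm.id] = len(clusters) - 1
    out: list[PWM] = []
    for cl in clusters:
        if len(cl["ids"]) == 1:
            out.append(cl["seed"])
        else:
            out.append(cl["avg"])
    return out, membership


def _average_frames(frames: list[tuple[np.ndarray, int]], ids: list[str]) -> PWM:
    """Average member matrices placed at their offsets; pad with uniform columns."""
    lo = min(off for _, off in frames)
    hi = max(off + mat.shape[0] for mat, off in frames)
    stack = np.full((len(frames), hi - lo, 4), 0.25)
    for k, (mat, off) in enumerate(frames):
        stack[k, off - lo: off - lo + mat.shape[0]] = mat
    avg = stack.mean(axis=0)
    # members are already regularized; renormalize without a fresh pseudocount
    avg /= avg.sum(axis=1, keepdims=True)
    return PWM(id=f"avg({','.join(ids)})", matrix=avg, source_ids=tuple(ids))


# ---------------------------------------------------------------------------
# Scoring, calibration and scanning
# ---------------------------------------------------------------------------

def _score_table(pwm: PWM, background: BackgroundModel) -> np.ndarray:
    """(L, 5) per-position log2-odds lookup; column 4 (N/other) scores 0."""
    table = np.zeros((len(pwm), 5))
    table[:, :4] = np.log2(pwm.matrix / background.freqs[None, :])
    return table


def score_window(pwm: PWM, window: str, background: BackgroundModel) -> float:
    """Log-odds score (bits) of one window of exactly the PWM's length.

    Each position contributes log2(P_pwm(base) / P_bg(base)); N bases
    contribute 0 bits.
    """
    if len(window) != len(pwm):
        raise ValueError(f"window length {len(window)} != motif length {len(pwm)}")
    table = _score_table(pwm, background)
    codes = encode_sequence(window)
    return float(table[np.arange(len(pwm)), codes].sum())


def _strand_scores(codes: np.ndarray, fwd_table: np.ndarray, rev_table: np.ndarray):
    """Score every offset of an encoded sequence on both strands.

    Returns (fwd, rev) arrays of length len(seq) - L + 1; the reverse
    score at offset i is the forward score of the reverse-complemented
    window starting at i.
    """
    L = fwd_table.shape[0]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0), np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    idx = np.arange(L)
    fwd = fwd_table[idx, windows].sum(axis=1)
    rev = rev_table[idx, windows].sum(axis=1)
    return fwd, rev


def _rev_table(pwm: PWM, background: BackgroundModel) -> np.ndarray:
    """Lookup table scoring a forward-strand window against the minus strand."""
    table = np.zeros((len(pwm), 5))
    # scoring the reverse complement of the window with the forward PWM is
    # the same as scoring the window with the reverse-complement PWM
    table[:, :4] = np.log2(pwm.matrix[::-1, ::-1] / background.freqs[None, :])
    return table


def max_scores(pwm: PWM, sequences: Iterable[str], background: BackgroundModel) -> np.ndarray:
    """Per-sequence maximum log-odds score over both strands and all offsets."""
    fwd_t = _score_table(pwm, background)
    rev_t = _rev_table(pwm, background)
    out = []
    for seq in sequences:
        if len(seq) < len(pwm):
            raise ValueError(f"sequence shorter than motif length {len(pwm)}")
        fwd, rev = _strand_scores(encode_sequence(seq), fwd_t, rev_t)
        out.append(max(fwd.max(), rev.max()))
    return np.asarray(out)


def calibrate_threshold(pwm: PWM, background: BackgroundModel, fpr: float = 0.01) -> ScanThreshold:
    """Empirical FPR calibration of the scan threshold.

    Computes every background sequence's maximum score (both strands, all
    offsets) and returns the inclusive lower empirical (1 - fpr) quantile
    of that distribution: sorted ascending, index ceil((1-fpr)*n) - 1.
    A sequence passes a subsequent scan iff its best window scores >= the
    threshold, so the expected fraction of background-like sequences
    passing is ~fpr.
    """
    if not (0 < fpr <= 1):
        raise ValueError("fpr must lie in (0, 1]")
    if not background.sequences:
        raise ValueError("background model has no sequences to calibrate on")
    maxima = np.sort(max_scores(pwm, background.sequences, background))
    n = maxima.size
    idx = max(int(np.ceil((1 - fpr) * n)) - 1, 0)
    return ScanThreshold(pwm_id=pwm.id, fpr=fpr, threshold=float(maxima[idx]), n_background=n)


def scan_regions(pwm: PWM, regions: Iterable[tuple[str, str]], threshold: ScanThreshold,
                 background: BackgroundModel | None = None,
                 passing_only: bool = False) -> list[MotifHit]:
    """Scan regions with a PWM at a calibrated threshold.

    Every offset is evaluated on both strands; at each offset the
    better-scoring strand is reported (ties go to "+").  Hits are
    returned in (region, offset) order.  Regions shorter than the motif
    yield no hits.  When ``background`` is omitted a uniform model is
    used for the log-odds denominators.
    """
    if threshold.pwm_id != pwm.id:
        raise ValueError(f"threshold was calibrated for {threshold.pwm_id!r}, not {pwm.id!r}")
    bg = background if background is not None else BackgroundModel.uniform()
    fwd_t = _score_table(pwm, bg)
    rev_t = _rev_table(pwm, bg)
    hits: list[MotifHit] = []
    for region_id, seq in regions:
        codes = encode_sequence(seq)
        fwd, rev = _strand_scores(codes, fwd_t, rev_t)
        for off in range(fwd.size):
            if fwd[off] >= rev[off]:
                strand, score = "+", float(fwd[off])
            else:
                strand, score = "-", float(rev[off])
            passed = score >= threshold.threshold
            if passing_only and not passed:
                continue
            hits.append(MotifHit(pwm_id=pwm.id, region_id=region_id, offset=off,
                                 strand=strand, score=score, passed=passed))
    return hits


def write_hits_tsv(path, hits: Iterable[MotifHit]) -> None:
    with open(path, "w") as fh:
        fh.write("region_id\toffset\tstrand\tscore\tpassed\n")
        for h in hits:
            fh.write(f"{h.region_id}\t{h.offset}\t{h.strand}\t{h.score:.6f}\t{h.passed}\n")
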