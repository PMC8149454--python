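# Methods

This note documents the statistical models behind `cisreg`, the
parameter defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical conventions that
make results reproducible.

## Motif models and FPR-calibrated scanning

A motif is a position probability matrix (PPM) over A, C, G, T.  On
construction a pseudocount (default 1e-3) is added to every cell and
rows are renormalized, which keeps log-odds finite while perturbing
scores negligibly.  A window of the motif's length scores
`Σᵢ log₂(P_pwm(bᵢ)/P_bg(bᵢ))` bits against a background nucleotide
model; `N` bases contribute 0 bits (neutral: they can neither create
nor destroy a pass).  Both strands are evaluated at every offset; at an
exactly tied offset the forward strand is reported, which keeps output
deterministic.

**Threshold calibration.**  Significance of motif occurrences is defined
empirically: the per-sequence maximum score is computed over a
background sequence set, and the threshold is the inclusive lower
(1 − FPR) empirical quantile (sorted ascending, index
`ceil((1−fpr)·n) − 1`).  A background-like sequence then passes a scan
with probability ≈ FPR (default 0.01).  The inclusive-lower convention
is conservative and reproducible; at `fpr = 1` it degenerates to the
minimum, so every background sequence passes.

One subtlety surfaced by testing: if the matrix is heavily quantized
(e.g. a two-valued "0.85 consensus / 0.05 other" matrix), the max-score
distribution carries large point masses and *no* cutoff can achieve the
nominal FPR — the empirical rate jumps past it.  Matrices estimated
from real binding data have continuous entries, for which ties are
measure-zero and calibration is clean.  The simulator therefore
provides `gen_pwm`, which draws each column from a Dirichlet centred on
the consensus profile (concentration 60 ≈ a motif estimated from tens
of sites); calibration tests and the acceptance script use such
matrices.

**Similarity and clustering.**  Motif similarity is the maximum Pearson
correlation of overlapping probability entries over all relative
offsets with at least 6 overlapping columns, considering the second
motif forward and reverse-complemented.  Clustering is greedy
agglomeration in input order: a motif joins the best-matching cluster
whose running average it matches at ≥ 0.8, else it seeds a new cluster;
the cluster motif is the column-wise mean of members at their best
alignments (uniform columns pad non-overlapping positions),
renormalized.  Singletons pass through unchanged.  These defaults are
conventional for motif-library condensation and are configurable; the
method makes no claim to reproduce any particular tool's clustering.

**Background.**  The default background emulates "random genomic"
sampling as i.i.d. sequences at the genome's nucleotide frequencies.
Calibrating on a background whose composition does not match the
scanned sequences biases the realized FPR (an AT-rich motif scanned
over an AT-rich genome against a uniform background passes far too
often); the peak-recovery tests match the background to the simulated
genome's GC for exactly this reason.

## Consensus peaks and annotation

Coordinates are 0-based half-open throughout; GFF3 is converted on
read.  A consensus peak is the intersection (≥ 1 bp) of a replicate-1
and a replicate-2 peak; intersections from multiply-matched peaks are
merged; merged regions shorter than `min_length` (default 100 bp) are
dropped; regions whose repeat-overlap fraction exceeds
`max_repeat_fraction` (default 0: any overlap removes) are dropped.
Intersection-then-merge is the literal, deterministic reading of
"recovered in both replicates"; union or reciprocal-overlap rules would
also be defensible and the thresholds are exposed.

Annotation assigns exactly one category per peak from its midpoint,
with priority promoter > exon > intron > intergenic.  The promoter
window is [TSS − 1000, TSS + 100) in transcription orientation — a
standard default; no oyster-specific promoter definition exists.  The
nearest gene minimizes |midpoint − TSS| and the reported distance is
signed in the gene's orientation (negative = upstream).  Midpoint
assignment is one of several possible conventions (any-overlap and
tool-internal priorities are others) and category fractions shift
slightly between them.

## Enrichment statistics

Motif over-representation in a peak class versus background uses the
peak as the counting unit (a peak either contains ≥ 1 passing window or
not), which removes the confounding of hit counts with region length.
The test is the one-sided Fisher exact / hypergeometric upper tail;
Bonferroni correction spans all motif × class tests in a profile call.
Exact conditional tests are discrete and never anti-conservative: under
the null the rejection rate approaches α from below as expected counts
grow, which is how the null-calibration test evaluates it.

## qPCR quantification

2^−ΔΔCt with the reference-gene subtraction per replicate.  The 95% CI
is a t-interval (df = n − 1) on the tissue's mean ΔCt, transformed
through `2^−x` with ends swapped — CIs are positive and asymmetric on
the fold scale.  Uncertainty in the calibrator tissue's own mean is not
propagated (the calibrator anchors the scale, matching common
practice), so simulated coverage of a planted fold sits somewhat below
the nominal level; the recovery test asserts ≥ 80% at nominal 95%.
Panel normalization divides every RQ and CI bound by the maximum
tissue RQ, preserving all between-tissue ratios.

## Organ-enriched genes

A gene is focal-enriched iff for *every* other organ, *both* focal
samples (digestive gland and hepatopancreas) show higher mean
expression with one-sided p < α (default 0.05, uncorrected by default
since the rule is a conjunction of many tests; a BH option exists).
The internal test is Welch's t on log2(x+1) abundances — a deliberately
simple stand-in whose role is to feed the conjunction rule; externally
computed per-comparison tables from a dedicated DE framework can be
substituted.  "Compared to other organs" is read as each organ
pairwise; a pooled-others mode is provided.

## Reporter synergy: the pooled-sum bootstrap

Relative activity is firefly/Renilla per well divided by the blank
control's mean ratio (control ≡ 1.00 exactly).  Technical replicates
are averaged into their biological replicate before testing.  The
synergy null object is the pool of all n_A × n_B sums of the two
single-effector groups' relative activities; its central percentile
interval (linear-interpolation quantiles, default 95%) describes the
additive expectation, and the test draws `|combined|`-sized resamples
with replacement from the pool, with
`p = (1 + #{boot mean ≥ observed}) / (n_boot + 1)` — one-sided because
the scientific claim is an *excess* over additivity, add-one-corrected
so p never underflows the resampling resolution.  Fixed seeds give
bit-identical p-values.

Two properties of this test are worth stating plainly:

- The additive null it embodies is "combined = A-activity + B-activity"
  *including both baselines*.  The simulator's additive mode therefore
  draws each combined biological replicate as an independent A-draw +
  B-draw, making the generator exactly the test's null.
- The bootstrap treats the pool as fixed, ignoring the sampling noise
  of the pool's own mean.  With effector groups of size n_e and a
  combined group of size n_c, the null z-statistic has variance
  ≈ 1 + n_c/n_e, so the test is calibrated only when n_c ≪ n_e: at
  n_e = 200, n_c = 5 the type-I error is ≈ α, while at a bench-scale
  3/3 design it is anti-conservative (≈ 0.12 at α = 0.05).  The
  calibration test uses the large-group regime; the small-sample
  behaviour is an inherent property of the method, relevant when
  interpreting borderline p-values from 3-replicate designs.

Dose-response comparisons use the two-sided pooled-variance Student t
between adjacent dose groups (pooled rather than Welch by design,
configurable) with Holm step-down correction; a pair with zero variance
in both groups is flagged rather than tested.

## ChIP-qPCR fold enrichment

Per replicate, `signal = eff^−(Ct_IP − Ct_input_adj)` for the specific
antibody and the mock IgG, with the input Ct adjusted by
log_eff(dilution); FE is their ratio.  Amplification efficiency is
fixed at 2 (perfect doubling) by default and exposed as a parameter.
Specific and mock wells pair by replicate index.  Significance is a
one-sided one-sample t of mean FE against 1.  Because FE is a ratio of
exponentials of Gaussian Ct noise it is log-normal: under a true FE of
1 its mean sits slightly above 1 (≈ 1.01 at 0.15-cycle noise), which
nudges the t-test's type-I rate just above α — the calibration test
carries a matching 1-point slack, and the 2.2-fold recovery test's 5%
band absorbs the same bias.

## Synthetic-data generators

All generators are pure functions of (parameters, seed) using one
`numpy` Generator, emit complete truth tables, and write standard
formats (FASTA/BED/TSV) that round-trip through the package readers.
Defaults encode the study designs the statistics serve: two ATAC
replicates with boundary jitter (±20 bp) and dropout; peaks of 400 bp;
planted sites drawn from the PWM's own distribution and
rejection-sampled above the calibrated threshold so recall targets are
well-defined; five-organ expression panels with 3 replicates, log2
baselines on [3, 9] and 0.25 log2 dispersion; luciferase assays with 3
biological × 2 technical replicates and 0.15 activity noise; ChIP with
4 replicates and 0.15-cycle noise.  Noise is Gaussian on each natural
measurement scale — the simplest model supporting calibration tests.

What they do *not* emulate: read-level sequencing artifacts, Tn5
insertion or fragment-length structure, peak-caller signal profiles,
correlated tissue composition, plate/batch effects, or PCR efficiency
drift.  Passing tests on these generators demonstrates that the
*statistical machinery* is correct and calibrated under its stated
assumptions, not that real oyster data would satisfy those assumptions.

## Problem sizes

Test and acceptance computations run at desk scale chosen to make the
Monte-Carlo error bars meaningful: 10,000 + 10,000 background sequences
of 500 nt for FPR calibration, 200-element effector groups with 10,000
fresh sums for interval coverage, 500 simulated datasets for bootstrap
type-I error, 1000 for the ChIP t-test and fold recovery, and
150-peak/150-kb genomes for planted-site recall.  Tolerances are three
binomial standard errors at those sizes (plus explicitly stated,
pre-registered slack where a statistic is known to sit off-center, as
described above).
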