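"""Consensus open-chromatin peaks: replicate intersection, repeat filtering,
and annotation against gene models.

Coordinates are BED-style 0-based half-open throughout; GFF3 input
(1-based closed) is converted on read.  A consensus peak is a region
recovered in both ATAC replicates (>= 1 bp overlap, retained region =
intersection, overlapping intersections merged), passing a minimum
length and a maximum repeat-overlap fraction.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .motifs import MotifHit

CATEGORIES = ("promoter", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("interval chromosome must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
                f"{' (' + self.name + ')' if self.name else ''}: need 0 <= start < end")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class ConsensusPeak:
    interval: GenomicInterval
    support: int = 2
    repeat_overlap_fraction: float = 0.0
    category: str | None = None
    nearest_gene: str = ""
    tss_distance: int | None = None

    @property
    def region_id(self) -> str:
        return self.interval.name


@dataclass(frozen=True)
class GeneModel:
    """Gene with TSS and exon structure.

    ``tss`` is the 0-based position of the first transcribed base: the
    interval start on the + strand, end - 1 on the - strand.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        prev_end = -1
        for s, e in exons:
            if s >= e:
                raise ValueError(f"gene {self.gene_id}: invalid exon {s}-{e}")
            if s < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        if not self.exons:
            return (self.tss, self.tss + 1)
        return (self.exons[0][0], self.exons[-1][1])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ / narrowPeak (extra columns beyond strand are ignored)."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 and f[5] in "+-." else "."
            out.append(GenomicInterval(chrom=f[0], start=start, end=end, name=name, strand=strand))
    return out


def write_bed(path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")


def write_consensus_bed(path, peaks: Iterable[ConsensusPeak]) -> None:
    """BED6 with replicate support in the score field and the repeat
    fraction appended to the name."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            name = f"{iv.name or 'peak'}|rep={p.repeat_overlap_fraction:.3f}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{p.support}\t{iv.strand}\n")


def read_gff3_genes(path) -> list[GeneModel]:
    """Read gene models (gene/mRNA/exon features) from GFF3.

    GFF3 1-based closed coordinates become 0-based half-open.  Exons are
    collected across all transcripts of a gene and merged if overlapping.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for g in db.features_of_type("gene"):
        exons = []
        for e in db.children(g, featuretype="exon"):
            exons.append((e.start - 1, e.end))
        merged = _merge_intervals(exons)
        start0, end0 = g.start - 1, g.end
        tss = start0 if g.strand != "-" else end0 - 1
        genes.append(GeneModel(gene_id=g.id, chrom=g.seqid, strand=g.strand or "+",
                               tss=tss, exons=tuple(merged) or ((start0, end0),)))
    return genes


def _merge_intervals(pairs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    if not pairs:
        return []
    pairs = sorted(pairs)
    merged = [list(pairs[0])]
    for s, e in pairs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(p) for p in merged]


# ---------------------------------------------------------------------------
# Consensus construction
# ---------------------------------------------------------------------------

def consensus_peaks(rep1: Sequence[GenomicInterval], rep2: Sequence[GenomicInterval],
                    min_length: int = 100, repeats: Sequence[GenomicInterval] = (),
                    max_repeat_fraction: float = 0.0) -> list[ConsensusPeak]:
    """Peaks recovered in both replicates, length- and repeat-filtered.

    Each rep1/rep2 overlap (>= 1 bp) contributes its intersection;
    overlapping intersections are merged; merged regions shorter than
    ``min_length`` are dropped; regions whose repeat-overlap fraction
    exceeds ``max_repeat_fraction`` are dropped.  Output is sorted by
    (chrom, start) and named peak_00001, peak_00002, ...
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in rep2:
        trees[iv.chrom].addi(iv.start, iv.end)
    pieces: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for iv in rep1:
        for hit in trees[iv.chrom].overlap(iv.start, iv.end):
            pieces[iv.chrom].append((max(iv.start, hit.begin), min(iv.end, hit.end)))
    repeat_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for r in repeats:
        repeat_trees[r.chrom].addi(r.start, r.end)
    out: list[ConsensusPeak] = []
    for chrom in sorted(pieces):
        for start, end in _merge_intervals(pieces[chrom]):
            if end - start < min_length:
                continue
            frac = _overlap_fraction(repeat_trees[chrom], start, end)
            if frac > max_repeat_fraction:
                continue
            out.append(ConsensusPeak(
                interval=GenomicInterval(chrom=chrom, start=start, end=end),
                support=2, repeat_overlap_fraction=frac))
    for i, p in enumerate(out, start=1):
        p.interval = replace(p.interval, name=f"peak_{i:05d}")
    return out


def _overlap_fraction(tree: IntervalTree, start: int, end: int) -> float:
    covered = _merge_intervals([(max(start, h.begin), min(end, h.end))
                                for h in tree.overlap(start, end)])
    bp = sum(e - s for s, e in covered)
    return bp / (end - start)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def annotate_peak(peak: GenomicInterval, genes: Sequence[GeneModel],
                  promoter_up: int = 1000, promoter_down: int = 100
                  ) -> tuple[str, str, int | None]:
    """Assign a peak to promoter/exon/intron/intergenic by its midpoint.

    The promoter window is [tss - promoter_up, tss + promoter_down) in
    transcription orientation; category priority is promoter > exon >
    intron > intergenic, evaluated against all genes on the chromosome.
    The nearest gene minimizes |midpoint - tss| (ties broken by gene id)
    and the returned distance is signed in its transcription orientation
    (negative = upstream).
    """
    mid = peak.midpoint
    local = [g for g in genes if g.chrom == peak.chrom]
    if not local:
        return ("intergenic", "", None)
    nearest = min(local, key=lambda g: (abs(mid - g.tss), g.gene_id))
    tss_distance = _signed_distance(mid, nearest)
    category = "intergenic"
    for g in local:
        d = _signed_distance(mid, g)
        if -promoter_up <= d < promoter_down:
            category = "promoter"
            break
    if category != "promoter":
        in_exon = any(s <= mid < e for g in local for s, e in g.exons)
        if in_exon:
            category = "exon"
        else:
            in_body = any(g.span[0] <= mid < g.span[1] for g in local)
            category = "intron" if in_body else "intergenic"
    return (category, nearest.gene_id, tss_distance)


def _signed_distance(pos: int, gene: GeneModel) -> int:
    return pos - gene.tss if gene.strand != "-" else gene.tss - pos


def annotate_peaks(peaks: Sequence[ConsensusPeak], genes: Sequence[GeneModel],
                   promoter_up: int = 1000, promoter_down: int = 100) -> list[ConsensusPeak]:
    """Annotate peaks in place (category, nearest gene, TSS distance)."""
    for p in peaks:
        cat, gene, dist = annotate_peak(p.interval, genes, promoter_up, promoter_down)
        p.category, p.nearest_gene, p.tss_distance = cat, gene, dist
    return list(peaks)


def category_fractions(peaks: Sequence[ConsensusPeak]) -> dict[str, float]:
    counts = {c: 0 for c in CATEGORIES}
    for p in peaks:
        if p.category is None:
            raise ValueError("peaks must be annotated first")
        counts[p.category] += 1
    total = max(sum(counts.values()), 1)
    return {c: counts[c] / total for c in CATEGORIES}


def peaks_near_genes(hits: Iterable[MotifHit], peaks: Sequence[ConsensusPeak]
                     ) -> dict[str, int]:
    """Count passing motif hits per gene via each peak's nearest gene.

    Peaks must be annotated.  Genes with zero passing hits are omitted.
    A hit referencing an unknown region_id raises ``KeyError``.
    """
    by_id = {p.region_id: p for p in peaks}
    counts: dict[str, int] = defaultdict(int)
    for h in hits:
        if h.region_id not in by_id:
            raise KeyError(f"hit references unknown region_id {h.region_id!r}")
        if not h.passed:
            continue
        gene = by_id[h.region_id].nearest_gene
        if gene:
            counts[gene] += 1
    return dict(counts)


def write_annotation_tsv(path, peaks: Sequence[ConsensusPeak]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tname\tcategory\tnearest_gene\ttss_distance\n")
        for p in peaks:
            iv = p.interval
            dist = "" if p.tss_distance is None else p.tss_distance
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                     f"{p.category}\t{p.nearest_gene}\t{dist}\n")
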