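"""TE-lncRNA classification, coverage statistics and family enrichment.

A lncRNA whose locus overlaps at least one annotated TE by >= 1 bp is a
TE-lncRNA.  Overlap is computed strand-agnostically on the locus span
(introns included) by default, because intronic TE insertions are part of
the phenomenon being measured; exon-only and strand-aware modes are
available.  Coverage is the union of clipped TE spans (overlapping TEs are
never double-counted), and the coverage rate is union bp over locus length.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .genomic_io import GenomicInterval, TEInsertion, TranscriptModel

__all__ = [
    "TELncRNAStats",
    "FamilyComposition",
    "ContingencyResult",
    "MultiplicitySummary",
    "union_coverage",
    "merge_intervals",
    "classify_te_lncrnas",
    "multiplicity_summary",
    "proportion_report",
    "family_composition",
    "fisher_exact",
    "coverage_rate_bins",
    "te_spans_by_transcript",
    "build_te_index",
    "DEFAULT_RATE_EDGES",
]

DEFAULT_RATE_EDGES = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class TELncRNAStats:
    """Per-lncRNA TE overlap statistics."""

    transcript_id: str
    is_te_lncrna: bool
    te_count: int
    covered_bp: int
    coverage_rate: float
    families: Counter = field(default_factory=Counter)
    locus_length: int = 0
    overlapping: list[TEInsertion] = field(default_factory=list)


@dataclass
class FamilyComposition:
    """Per-family TE incidence counts and proportions for one region class."""

    region_class: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict[str, float]:
        t = self.total
        return {fam: n / t for fam, n in self.counts.items()} if t else {}


@dataclass
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float


@dataclass
class MultiplicitySummary:
    histogram: dict[int, int]
    fraction_multi: float | None
    mean_tes: float | None
    n_te_lncrnas: int
    total_incidences: int


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge (start, end) half-open intervals into their disjoint union."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def union_coverage(intervals: Iterable[tuple[int, int] | GenomicInterval]) -> int:
    """Total bp covered by the union of intervals on one chromosome."""
    pairs = [
        (iv.start, iv.end) if isinstance(iv, GenomicInterval) else tuple(iv)
        for iv in intervals
    ]
    return sum(e - s for s, e in merge_intervals(pairs))


def build_te_index(tes: Sequence[TEInsertion]) -> dict[str, IntervalTree]:
    """Per-chromosome interval tree over TE insertions for fast overlap lookup."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for te in tes:
        iv = te.interval
        trees[iv.chrom].addi(iv.start, iv.end, te)
    return dict(trees)


def classify_te_lncrnas(
    lncrnas: Sequence[TranscriptModel],
    tes: Sequence[TEInsertion],
    exon_only: bool = False,
    strand_aware: bool = False,
) -> list[TELncRNAStats]:
    """Classify each lncRNA as TE-lncRNA or Non-TE-lncRNA with coverage stats.

    ``te_count`` is the number of TEs overlapping the locus (>= 1 bp);
    ``covered_bp`` is the union of the TE spans clipped to the locus (or to
    the exons, in exon-only mode); ``coverage_rate`` divides by the locus
    length (mature length in exon-only mode).
    """
    index = build_te_index(tes)
    out = []
    for m in lncrnas:
        locus = m.locus
        tree = index.get(locus.chrom)
        hits: list[TEInsertion] = []
        if tree is not None:
            for node in tree.overlap(locus.start, locus.end):
                te: TEInsertion = node.data
                if strand_aware and te.interval.strand != m.strand:
                    continue
                if exon_only and not any(
                    te.interval.overlap_bp(e) > 0 for e in m.exons
                ):
                    continue
                hits.append(te)
        targets = m.exons if exon_only else [locus]
        clipped = []
        for te in hits:
            for t in targets:
                bp = te.interval.overlap_bp(t)
                if bp > 0:
                    clipped.append(
                        (max(te.interval.start, t.start), min(te.interval.end, t.end))
                    )
        covered = union_coverage(clipped)
        denom = m.mature_length if exon_only else m.locus_length
        hits.sort(key=lambda te: (te.interval.start, te.interval.end, te.te_id))
        out.append(
            TELncRNAStats(
                transcript_id=m.transcript_id,
                is_te_lncrna=bool(hits),
                te_count=len(hits),
                covered_bp=covered,
                coverage_rate=covered / denom,
                families=Counter(te.family for te in hits),
                locus_length=denom,
                overlapping=hits,
            )
        )
    return out


def te_spans_by_transcript(
    stats: Sequence[TELncRNAStats],
    lncrnas: Sequence[TranscriptModel],
) -> dict[str, list[GenomicInterval]]:
    """Union of overlapping TE spans, clipped to each host locus."""
    loci = {m.transcript_id: m.locus for m in lncrnas}
    spans: dict[str, list[GenomicInterval]] = {}
    for st in stats:
        locus = loci[st.transcript_id]
        clipped = [
            (max(te.interval.start, locus.start), min(te.interval.end, locus.end))
            for te in st.overlapping
        ]
        spans[st.transcript_id] = [
            GenomicInterval(locus.chrom, s, e) for s, e in merge_intervals(clipped)
        ]
    return spans


def multiplicity_summary(stats: Sequence[TELncRNAStats]) -> MultiplicitySummary:
    """Histogram of TEs per TE-lncRNA, fraction with > 1 TE, and the mean.

    The mean is total overlapping TE incidences divided by the number of
    TE-lncRNAs; with zero TE-lncRNAs the summary is empty rather than an
    error.
    """
    te_counts = [s.te_count for s in stats if s.is_te_lncrna]
    n = len(te_counts)
    if n == 0:
        return MultiplicitySummary({}, None, None, 0, 0)
    total = sum(te_counts)
    hist = dict(sorted(Counter(te_counts).items()))
    return MultiplicitySummary(
        histogram=hist,
        fraction_multi=sum(1 for c in te_counts if c > 1) / n,
        mean_tes=total / n,
        n_te_lncrnas=n,
        total_incidences=total,
    )


def proportion_report(k: int, n: int) -> float:
    """Percentage 100*k/n rounded half-up to 2 decimals, as papers print it."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    pct = Decimal(k) / Decimal(n) * 100
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def family_composition(
    tes: Sequence[TEInsertion],
    region_class: str = "genome",
    region: Sequence[GenomicInterval] | None = None,
) -> FamilyComposition:
    """Per-family TE counts and proportions for a region class.

    With ``region=None`` every TE counts once (genome-wide composition).
    Otherwise TE *incidences* are counted: each (TE, region interval) pair
    overlapping by >= 1 bp contributes one count, so a TE inside two lncRNA
    loci contributes twice — matching incidence-based overlap totals.
    """
    counts: Counter = Counter()
    if region is None:
        for te in tes:
            counts[te.family] += 1
    else:
        trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for i, iv in enumerate(region):
            trees[iv.chrom].addi(iv.start, iv.end, i)  # data keeps duplicates distinct
        for te in tes:
            tree = trees.get(te.interval.chrom)
            if tree is not None:
                n_hits = len(tree.overlap(te.interval.start, te.interval.end))
                if n_hits:
                    counts[te.family] += n_hits
    return FamilyComposition(region_class=region_class, counts=dict(counts))


def fisher_exact(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    The odds ratio is the sample odds ratio (a*d)/(b*c), with ``inf`` when
    b*c = 0 and a*d > 0, and ``nan`` for the degenerate 0/0 case.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("contingency cells must be non-negative")
    if all(x == 0 for x in cells):
        raise ValueError("all-zero contingency table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return ContingencyResult(
        table=((a, b), (c, d)), odds_ratio=odds, p_value=float(p)
    )


def coverage_rate_bins(
    stats: Sequence[TELncRNAStats],
    edges: Sequence[float] = DEFAULT_RATE_EDGES,
    te_only: bool = True,
) -> list[int]:
    """Coverage-rate histogram over right-open bins (last bin closed at 100%).

    A rate exactly on an interior edge falls into the bin to its right, so
    0.25 lands in the second bin; 1.0 lands in the last.
    """
    rates = [s.coverage_rate for s in stats if s.is_te_lncrna or not te_only]
    counts, _ = np.histogram(rates, bins=np.asarray(edges, dtype=float))
    return [int(c) for c in counts]
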