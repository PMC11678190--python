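"""Genomic context of TE insertions: positional labels, TSS contribution,
chromosomal insertion hotspots and conservation summaries.

Each TE receives exactly one context label chosen by overlap in the fixed
priority order promoter > exon > intron > downstream > intergenic, in the
style of single-label peak annotators.  The promoter window defaults to
(-2000, +200) around the strand-aware TSS and the downstream window to
1000 bp past the locus end; both are configurable and should be recorded in
any output header.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genomic_io import (
    ConservationTrack,
    GenomicInterval,
    TEInsertion,
    TranscriptModel,
)
from .te_overlap import TELncRNAStats

__all__ = [
    "ContextAnnotation",
    "HotspotResult",
    "ConservationSummary",
    "CONTEXT_LABELS",
    "promoter_window",
    "tss_window",
    "annotate_context",
    "annotate_context_all",
    "tss_contribution",
    "detect_hotspots",
    "summarize_conservation",
]

CONTEXT_LABELS = ("promoter", "exon", "intron", "downstream", "intergenic")

DEFAULT_PROMOTER_WINDOW = (-2000, 200)
DEFAULT_DOWNSTREAM_WINDOW = 1000
DEFAULT_TSS_HALF_WINDOW = 50


@dataclass
class ContextAnnotation:
    te_id: str
    label: str
    nearest_transcript_id: str | None
    distance_to_tss: int | None  # signed bp from TE midpoint; negative = upstream


@dataclass
class HotspotResult:
    chrom: str
    bin_size: int
    counts: np.ndarray
    z_scores: np.ndarray
    flags: np.ndarray  # boolean, z >= threshold
    z_threshold: float

    @property
    def hotspot_bins(self) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.flags)]

    def bin_interval(self, i: int, chrom_size: int) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, i * self.bin_size, min((i + 1) * self.bin_size, chrom_size)
        )


@dataclass
class ConservationSummary:
    feature_class: str
    mean_score: float
    fraction_zero: float
    covered_bp: int


def promoter_window(
    model: TranscriptModel, window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW
) -> GenomicInterval | None:
    """Strand-aware promoter interval around the TSS; None if off-chromosome."""
    up, down = window
    tss = model.tss
    if model.strand == "-":
        start, end = tss - down + 1, tss - up + 1
    else:
        start, end = tss + up, tss + down
    start = max(0, start)
    if start >= end:
        return None
    return GenomicInterval(model.chrom, start, end, model.strand)


def tss_window(
    model: TranscriptModel, half_window: int = DEFAULT_TSS_HALF_WINDOW
) -> GenomicInterval:
    tss = model.tss
    return GenomicInterval(
        model.chrom, max(0, tss - half_window), tss + half_window + 1, model.strand
    )


def _downstream_interval(
    model: TranscriptModel, length: int
) -> GenomicInterval | None:
    locus = model.locus
    if model.strand == "-":
        start, end = max(0, locus.start - length), locus.start
    else:
        start, end = locus.end, locus.end + length
    if start >= end:
        return None
    return GenomicInterval(model.chrom, start, end, model.strand)


def _signed_tss_distance(model: TranscriptModel, pos: int) -> int:
    """Distance of ``pos`` from the TSS, negative upstream of transcription."""
    d = pos - model.tss
    return -d if model.strand == "-" else d


def annotate_context(
    te: TEInsertion,
    transcripts: Sequence[TranscriptModel],
    promoter: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
    downstream: int = DEFAULT_DOWNSTREAM_WINDOW,
) -> ContextAnnotation:
    """Assign one genomic-context label to a TE insertion.

    Regions are tested in priority order promoter > exon > intron >
    downstream; a TE overlapping none of them is intergenic.  When several
    transcripts qualify at the winning priority, the one whose TSS is
    nearest the TE midpoint wins.
    """
    mid = te.interval.midpoint
    same_chrom = [t for t in transcripts if t.chrom == te.interval.chrom]

    def nearest(cands: list[TranscriptModel]) -> TranscriptModel:
        return min(cands, key=lambda t: (abs(mid - t.tss), t.transcript_id))

    for label in ("promoter", "exon", "intron", "downstream"):
        cands = []
        for t in same_chrom:
            if label == "promoter":
                w = promoter_window(t, promoter)
                hit = w is not None and te.interval.overlap_bp(w) > 0
            elif label == "exon":
                hit = any(te.interval.overlap_bp(e) > 0 for e in t.exons)
            elif label == "intron":
                hit = any(te.interval.overlap_bp(i) > 0 for i in t.introns)
            else:
                w = _downstream_interval(t, downstream)
                hit = w is not None and te.interval.overlap_bp(w) > 0
            if hit:
                cands.append(t)
        if cands:
            t = nearest(cands)
            return ContextAnnotation(
                te_id=te.te_id,
                label=label,
                nearest_transcript_id=t.transcript_id,
                distance_to_tss=_signed_tss_distance(t, mid),
            )
    if same_chrom:
        t = nearest(same_chrom)
        return ContextAnnotation(
            te_id=te.te_id,
            label="intergenic",
            nearest_transcript_id=t.transcript_id,
            distance_to_tss=_signed_tss_distance(t, mid),
        )
    return ContextAnnotation(te.te_id, "intergenic", None, None)


def annotate_context_all(
    tes: Sequence[TEInsertion],
    transcripts: Sequence[TranscriptModel],
    promoter: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
    downstream: int = DEFAULT_DOWNSTREAM_WINDOW,
) -> list[ContextAnnotation]:
    """Vector form of :func:`annotate_context` with a per-chromosome index."""
    by_chrom: dict[str, list[TranscriptModel]] = defaultdict(list)
    for t in transcripts:
        by_chrom[t.chrom].append(t)
    return [
        annotate_context(te, by_chrom.get(te.interval.chrom, []), promoter, downstream)
        for te in tes
    ]


def context_label_counts(annotations: Iterable[ContextAnnotation]) -> dict[str, int]:
    counts = Counter(a.label for a in annotations)
    return {label: counts.get(label, 0) for label in CONTEXT_LABELS}


def tss_contribution(
    lncrnas: Sequence[TranscriptModel],
    stats: Sequence[TELncRNAStats],
    half_window: int = DEFAULT_TSS_HALF_WINDOW,
) -> dict[str, bool]:
    """Flag lncRNAs whose TSS +/- ``half_window`` is touched by an overlapping TE.

    Only TEs already overlapping the lncRNA (from classify_te_lncrnas) are
    considered; the flag is true when any of them overlaps the TSS window by
    >= 1 bp.
    """
    by_id = {s.transcript_id: s for s in stats}
    flags = {}
    for m in lncrnas:
        st = by_id.get(m.transcript_id)
        if st is None or not st.is_te_lncrna:
            flags[m.transcript_id] = False
            continue
        w = tss_window(m, half_window)
        flags[m.transcript_id] = any(
            te.interval.overlap_bp(w) > 0 for te in st.overlapping
        )
    return flags


def detect_hotspots(
    tes: Sequence[TEInsertion],
    chrom_sizes: Mapping[str, int],
    bin_size: int = 100_000,
    z_threshold: float = 3.0,
) -> dict[str, HotspotResult]:
    """Binned TE insertion density per chromosome with z-score outlier flags.

    Each TE is assigned to the bin containing its midpoint; a bin is a
    hotspot when its count is at least ``z_threshold`` standard deviations
    (population sd over that chromosome's bins) above the chromosome mean.
    A chromosome with a single bin, or zero bin-count variance, yields no
    hotspots.
    """
    mids: dict[str, list[int]] = defaultdict(list)
    for te in tes:
        mids[te.interval.chrom].append(te.interval.midpoint)
    results = {}
    for chrom, size in chrom_sizes.items():
        n_bins = max(1, -(-size // bin_size))  # ceil
        counts = np.zeros(n_bins, dtype=int)
        for m in mids.get(chrom, []):
            counts[min(m // bin_size, n_bins - 1)] += 1
        sd = counts.std()
        if n_bins == 1 or sd == 0:
            z = np.zeros(n_bins)
            flags = np.zeros(n_bins, dtype=bool)
        else:
            z = (counts - counts.mean()) / sd
            flags = z >= z_threshold
        results[chrom] = HotspotResult(
            chrom=chrom,
            bin_size=bin_size,
            counts=counts,
            z_scores=z,
            flags=flags,
            z_threshold=z_threshold,
        )
    return results


def detect_hotspots_poisson(
    tes: Sequence[TEInsertion],
    chrom_sizes: Mapping[str, int],
    bin_size: int = 100_000,
    alpha: float = 1e-3,
) -> dict[str, HotspotResult]:
    """Poisson-test alternative: flag bins whose count exceeds the upper
    ``alpha`` tail of Poisson(chromosome mean), Bonferroni-corrected."""
    from scipy import stats as _st

    base = detect_hotspots(tes, chrom_sizes, bin_size, z_threshold=np.inf)
    for chrom, res in base.items():
        lam = res.counts.mean()
        n = len(res.counts)
        if n == 1 or lam == 0:
            continue
        p = _st.poisson.sf(res.counts - 1, lam)
        res.flags = p < alpha / n
        res.z_threshold = float("nan")
    return base


def summarize_conservation(
    features_by_class: Mapping[str, Sequence[GenomicInterval]],
    track: ConservationTrack,
) -> dict[str, ConservationSummary]:
    """Mean score and fraction of zero-score bases per feature class.

    Both statistics are computed only over bases present in the track;
    classes with no covered bases are absent from the result.  Features are
    weighted by covered bp, so duplicating every feature leaves the means
    unchanged.
    """
    out = {}
    for cls, features in features_by_class.items():
        total_bp = 0
        score_sum = 0.0
        zero_bp = 0
        for iv in features:
            for bp, score in track.scores_in(iv):
                total_bp += bp
                score_sum += bp * score
                if score == 0.0:
                    zero_bp += bp
        if total_bp == 0:
            continue
        out[cls] = ConservationSummary(
            feature_class=cls,
            mean_score=score_sum / total_bp,
            fraction_zero=zero_bp / total_bp,
            covered_bp=total_bp,
        )
    return out
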