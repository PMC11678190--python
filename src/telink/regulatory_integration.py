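"""Joining TE spans with regulatory tracks and the expression matrix.

Covers per-lncRNA feature counting with group tests (ATAC peaks, m6A sites),
TE-derived feature attribution (TFBS / m6A / ATAC / ORF intervals whose
bases are mostly contributed by TE spans), promoter TFBS density across
lncRNA promoter classes, pairwise correlations, and the tau expression
specificity index.

Defaults: a feature is assigned to a lncRNA on >= 1 bp locus overlap (a
feature overlapping two loci counts for both); a feature is TE-derived when
>= 50% of its bases within the host locus are covered by TE spans; the
default two-group test is the two-sided Mann-Whitney U (count and length
distributions are heavy-tailed) with Welch's t-test available; correlations
are Spearman by default.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .genomic_io import ExpressionMatrix, FeatureTrack, GenomicInterval, TranscriptModel
from .genomic_context import DEFAULT_PROMOTER_WINDOW, promoter_window
from .te_overlap import TELncRNAStats, merge_intervals

__all__ = [
    "AttributionResult",
    "CorrelationResult",
    "GroupTestResult",
    "TauResult",
    "count_features_per_lncrna",
    "compare_groups",
    "attribute_te_features",
    "promoter_tfbs_density",
    "correlate",
    "tau",
    "m6a_abundance_compare",
    "bh_adjust",
    "DEFAULT_ATTRIBUTION_FRACTION",
]

DEFAULT_ATTRIBUTION_FRACTION = 0.5


@dataclass
class AttributionResult:
    feature_id: str
    feature_kind: str
    host_transcript_id: str
    te_derived: bool
    overlap_fraction: float
    contributing_families: tuple[str, ...] = ()


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    method: str
    coefficient: float | None
    p_value: float | None
    n: int


@dataclass
class GroupTestResult:
    test: str
    statistic: float | None
    p_value: float | None
    group_sizes: dict[str, int]
    group_medians: dict[str, float]


@dataclass
class TauResult:
    feature_id: str
    tau: float
    argmax_sample: str


def _locus_tree(lncrnas: Sequence[TranscriptModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for m in lncrnas:
        locus = m.locus
        trees[locus.chrom].addi(locus.start, locus.end, m.transcript_id)
    return dict(trees)


def count_features_per_lncrna(
    lncrnas: Sequence[TranscriptModel], track: FeatureTrack
) -> dict[str, int]:
    """Number of track features overlapping each lncRNA locus by >= 1 bp.

    A feature overlapping several loci is counted for each of them.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, (iv, _label) in enumerate(track):
        trees[iv.chrom].addi(iv.start, iv.end, i)  # data keeps duplicates distinct
    counts = {}
    for m in lncrnas:
        locus = m.locus
        tree = trees.get(locus.chrom)
        counts[m.transcript_id] = (
            len(tree.overlap(locus.start, locus.end)) if tree is not None else 0
        )
    return counts


def compare_groups(
    values: Mapping[str, float] | Sequence[float],
    labels: Mapping[str, str] | Sequence[str],
    test: str = "mannwhitney",
) -> GroupTestResult:
    """Two-sided two-group test on per-lncRNA values.

    ``test`` is 'mannwhitney' (default; rank test with tie handling) or
    'welch'.  A group with fewer than 2 members yields no test (statistic
    and p are None) while sizes and medians are still reported.
    """
    if isinstance(values, Mapping):
        keys = list(values)
        vals = np.asarray([values[k] for k in keys], dtype=float)
        labs = [labels[k] for k in keys]
    else:
        vals = np.asarray(values, dtype=float)
        labs = list(labels)
    groups: dict[str, list[float]] = defaultdict(list)
    for v, l in zip(vals, labs):
        groups[l].append(v)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 group labels, got {sorted(groups)}")
    (la, ga), (lb, gb) = sorted(groups.items())
    sizes = {la: len(ga), lb: len(gb)}
    medians = {
        la: float(np.median(ga)) if ga else float("nan"),
        lb: float(np.median(gb)) if gb else float("nan"),
    }
    if min(sizes.values()) < 2:
        return GroupTestResult(test, None, None, sizes, medians)
    if test == "mannwhitney":
        res = stats.mannwhitneyu(ga, gb, alternative="two-sided")
    elif test == "welch":
        res = stats.ttest_ind(ga, gb, equal_var=False)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupTestResult(
        test, float(res.statistic), float(res.pvalue), sizes, medians
    )


def attribute_te_features(
    te_spans: Mapping[str, Sequence[GenomicInterval]],
    lncrnas: Sequence[TranscriptModel],
    track: FeatureTrack,
    min_fraction: float = DEFAULT_ATTRIBUTION_FRACTION,
    families_by_span: Mapping[str, Sequence[str]] | None = None,
) -> tuple[list[AttributionResult], list[tuple[str, str]]]:
    """Attribute track features to TE origin within their host lncRNA.

    ``te_spans`` maps transcript_id to the union of TE spans clipped to that
    locus (see :func:`telink.te_overlap.te_spans_by_transcript`).  Each
    feature is assigned to the overlapping lncRNA with the largest overlap;
    ``overlap_fraction`` is the fraction of the feature's length covered by
    the host's TE spans, and the feature is TE-derived when the fraction
    reaches ``min_fraction``.  Features outside every lncRNA are returned
    separately as (feature_id, reason) exclusions.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    by_id = {m.transcript_id: m for m in lncrnas}
    trees = _locus_tree(lncrnas)
    results: list[AttributionResult] = []
    excluded: list[tuple[str, str]] = []
    fams = families_by_span or {}
    for iv, label in track:
        tree = trees.get(iv.chrom)
        hits = list(tree.overlap(iv.start, iv.end)) if tree is not None else []
        if not hits:
            excluded.append((label, "outside_all_lncrnas"))
            continue

        def ov(node) -> int:
            return min(node.end, iv.end) - max(node.begin, iv.start)

        host_id = max(hits, key=lambda n: (ov(n), n.data)).data
        spans = te_spans.get(host_id, [])
        clipped = [
            (max(s.start, iv.start), min(s.end, iv.end))
            for s in spans
            if s.overlap_bp(iv) > 0
        ]
        covered = sum(e - s for s, e in merge_intervals(clipped))
        frac = covered / len(iv)
        results.append(
            AttributionResult(
                feature_id=label,
                feature_kind=track.kind,
                host_transcript_id=host_id,
                te_derived=frac >= min_fraction,
                overlap_fraction=frac,
                contributing_families=tuple(sorted(set(fams.get(host_id, ()))))
                if clipped
                else (),
            )
        )
    return results, excluded


def promoter_tfbs_density(
    lncrnas: Sequence[TranscriptModel],
    stats_by_id: Mapping[str, TELncRNAStats],
    tfbs: FeatureTrack,
    promoter: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
) -> tuple[dict[str, float], dict[str, list[float]], GroupTestResult | None]:
    """TFBS density (hits per kb of promoter) across lncRNA promoter classes.

    Classes: 'TE-pro-lncRNA' (TE-lncRNA with >= 1 overlapping TE in its
    promoter window), 'Non-TE-pro-lncRNA' (TE-lncRNA without), and
    'Non-TE-lncRNA'.  Returns per-lncRNA densities grouped by class, the
    class means, and a Kruskal-Wallis rank test across the classes (None
    when fewer than two classes have >= 2 members or all densities are 0).
    """
    tfbs_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, (iv, _) in enumerate(tfbs):
        tfbs_trees[iv.chrom].addi(iv.start, iv.end, i)
    densities: dict[str, list[float]] = {
        "TE-pro-lncRNA": [],
        "Non-TE-pro-lncRNA": [],
        "Non-TE-lncRNA": [],
    }
    for m in lncrnas:
        w = promoter_window(m, promoter)
        if w is None:
            continue
        tree = tfbs_trees.get(w.chrom)
        n_hits = len(tree.overlap(w.start, w.end)) if tree is not None else 0
        density = n_hits / (len(w) / 1000.0)
        st = stats_by_id.get(m.transcript_id)
        if st is None or not st.is_te_lncrna:
            cls = "Non-TE-lncRNA"
        else:
            has_pro_te = any(te.interval.overlap_bp(w) > 0 for te in st.overlapping)
            cls = "TE-pro-lncRNA" if has_pro_te else "Non-TE-pro-lncRNA"
        densities[cls].append(density)
    means = {
        cls: float(np.mean(v)) if v else float("nan") for cls, v in densities.items()
    }
    testable = [v for v in densities.values() if len(v) >= 2]
    test: GroupTestResult | None = None
    if len(testable) >= 2 and any(x > 0 for v in densities.values() for x in v):
        res = stats.kruskal(*testable)
        test = GroupTestResult(
            "kruskal",
            float(res.statistic),
            float(res.pvalue),
            {cls: len(v) for cls, v in densities.items()},
            {cls: float(np.median(v)) if v else float("nan")
             for cls, v in densities.items()},
        )
    return means, densities, test


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "rank",
    pair: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Correlation between two per-lncRNA variables.

    'rank' (Spearman, default) or 'linear' (Pearson); two-sided p.  A
    constant vector makes the coefficient undefined, reported as None.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise ValueError("x and y must be finite")
    n = len(xa)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return CorrelationResult(pair, method, None, None, n)
    if method == "rank":
        r, p = stats.spearmanr(xa, ya)
    elif method == "linear":
        r, p = stats.pearsonr(xa, ya)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(pair, method, float(r), float(p), n)


def tau(
    matrix: ExpressionMatrix, log_transform: bool = True
) -> dict[str, TauResult]:
    """Expression specificity index per feature.

    tau = sum_i (1 - x_i) / (N - 1) over N samples, where x_i is the
    (optionally log2(FPKM+1)-transformed) expression divided by the row
    maximum.  tau is 0 for uniform rows, 1 for single-sample expression;
    all-zero rows are skipped (tau undefined).
    """
    if matrix.n_samples < 2:
        raise ValueError("tau requires at least 2 samples")
    vals = matrix.values.to_numpy(dtype=float)
    if log_transform:
        vals = np.log2(vals + 1.0)
    out: dict[str, TauResult] = {}
    samples = matrix.sample_ids
    n = vals.shape[1]
    for fid, row in zip(matrix.feature_ids, vals):
        mx = row.max()
        if mx <= 0:
            continue
        xhat = row / mx
        t = float((1.0 - xhat).sum() / (n - 1))
        out[fid] = TauResult(
            feature_id=fid, tau=t, argmax_sample=samples[int(row.argmax())]
        )
    return out


def m6a_abundance_compare(
    lncrnas: Sequence[TranscriptModel],
    stats_by_id: Mapping[str, TELncRNAStats],
    m6a: FeatureTrack,
    test: str = "mannwhitney",
) -> tuple[dict[str, int], GroupTestResult | None]:
    """Compare per-lncRNA m6A site counts between TE- and Non-TE-lncRNAs.

    Returns the per-lncRNA counts and the group test; with an empty m6A
    track all counts are 0 and no test is run.
    """
    counts = count_features_per_lncrna(lncrnas, m6a)
    if len(m6a) == 0 or all(v == 0 for v in counts.values()):
        return counts, None
    labels = {
        tid: "TE-lncRNA"
        if (tid in stats_by_id and stats_by_id[tid].is_te_lncrna)
        else "Non-TE-lncRNA"
        for tid in counts
    }
    if len(set(labels.values())) < 2:
        return counts, None
    return counts, compare_groups(counts, labels, test=test)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (for per-motif enrichment scans)."""
    return stats.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")
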