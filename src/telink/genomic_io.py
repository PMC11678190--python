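"""Readers and writers for the genomic file formats the pipeline touches.

Every coordinate inside the package is 0-based half-open (``[start, end)``),
the BED convention.  GTF (1-based closed) and RepeatMasker ``.out`` query
coordinates (1-based closed) are converted at the boundary, in both
directions, so that conversion is an involution on valid files.

Formats handled here:

* GTF transcript annotations (exon features carrying ``transcript_id`` /
  ``gene_id`` and optionally ``class_code`` / ``biotype`` attributes)
* RepeatMasker ``.out`` repeat annotations
* BED3/BED4/BED6 feature tracks (ATAC peaks, TFBS hits, m6A peaks, ORFs)
* TSV expression matrices (features x samples, FPKM)
* bedGraph-style per-base conservation runs
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "TEInsertion",
    "FeatureTrack",
    "ExpressionMatrix",
    "ConservationTrack",
    "read_transcripts",
    "write_transcripts",
    "read_repeatmasker",
    "write_repeatmasker",
    "read_features",
    "write_features",
    "read_expression",
    "write_expression",
    "read_conservation",
    "write_conservation",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "transcript_sequence",
    "project_to_genome",
]

FEATURE_KINDS = ("atac_peak", "tfbs", "m6a_peak", "orf")

# RepeatMasker classes that are masking artifacts, not transposable elements
NON_TE_CLASSES = frozenset({"Simple_repeat", "Low_complexity"})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript.

    ``locus`` spans min exon start to max exon end; ``exons`` are sorted,
    pairwise non-overlapping and lie on the locus chromosome/strand.
    ``class_code`` is the GffCompare-style single-character relation to the
    reference annotation (``None`` when the annotation lacks it).
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    class_code: str | None = None
    biotype: str = "candidate"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"transcript {self.transcript_id}: exons span multiple "
                "chromosomes or strands"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )

    @property
    def locus(self) -> GenomicInterval:
        return GenomicInterval(
            self.exons[0].chrom,
            self.exons[0].start,
            self.exons[-1].end,
            self.exons[0].strand,
        )

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def mature_length(self) -> int:
        """Spliced (mature RNA) length: sum of exon lengths."""
        return sum(len(e) for e in self.exons)

    @property
    def locus_length(self) -> int:
        return len(self.locus)

    @property
    def tss(self) -> int:
        """Transcription start site: locus start on '+', locus end - 1 on '-'."""
        return self.locus.start if self.strand != "-" else self.locus.end - 1

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out


@dataclass
class TEInsertion:
    """A located repeat with its RepeatMasker class/family label."""

    interval: GenomicInterval
    te_class: str
    family: str
    name: str = ""
    score: float = 0.0
    te_id: str = ""

    def __post_init__(self) -> None:
        if not self.te_class or not self.family:
            raise ValueError("te_class and family must be non-empty")

    @property
    def label(self) -> str:
        """Class/family label as RepeatMasker prints it, e.g. ``LTR/Gypsy``."""
        if self.family == self.te_class:
            return self.te_class
        return f"{self.te_class}/{self.family}"


@dataclass
class FeatureTrack:
    """A typed interval set: ATAC peaks, TFBS hits, m6A peaks or ORFs."""

    kind: str
    features: list[GenomicInterval] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")
        if self.labels and len(self.labels) != len(self.features):
            raise ValueError("labels length must match features length")
        if not self.labels:
            self.labels = [f"{self.kind}_{i}" for i in range(len(self.features))]

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(zip(self.features, self.labels))


class ExpressionMatrix:
    """FPKM expression values, features x samples, backed by a DataFrame."""

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("expression matrix contains missing values")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        self.values = values.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row(self, feature_id: str) -> np.ndarray | None:
        """Return the FPKM row for ``feature_id`` or ``None`` if absent."""
        if feature_id not in self.values.index:
            return None
        return self.values.loc[feature_id].to_numpy(dtype=float)

    def row_sum(self, feature_id: str) -> float:
        """Total FPKM across samples; absent features count as unexpressed."""
        r = self.row(feature_id)
        return 0.0 if r is None else float(r.sum())


class ConservationTrack:
    """Per-base conservation scores stored as non-overlapping (interval, score) runs.

    Bases not covered by any run have no score (they are absent, not zero).
    """

    def __init__(self, runs: Iterable[tuple[GenomicInterval, float]]):
        by_chrom: dict[str, list[tuple[int, int, float]]] = defaultdict(list)
        for iv, score in runs:
            by_chrom[iv.chrom].append((iv.start, iv.end, float(score)))
        for chrom, rr in by_chrom.items():
            rr.sort()
            for (s1, e1, _), (s2, _, _) in zip(rr, rr[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping conservation runs on {chrom}")
        self._runs = dict(by_chrom)

    def runs(self, chrom: str) -> list[tuple[int, int, float]]:
        return self._runs.get(chrom, [])

    @property
    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def scores_in(self, iv: GenomicInterval) -> list[tuple[int, float]]:
        """(covered bp, score) pairs for the runs intersecting ``iv``."""
        out = []
        for s, e, score in self.runs(iv.chrom):
            bp = min(e, iv.end) - max(s, iv.start)
            if bp > 0:
                out.append((bp, score))
        return out


# ---------------------------------------------------------------------------
# GTF

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_transcripts(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a GTF file (exon features only).

    GTF 1-based closed coordinates are converted to 0-based half-open.
    Transcripts are returned sorted by transcript_id with exons grouped and
    sorted; a missing ``class_code`` attribute is stored as ``None``.
    """
    exons: dict[str, list[GenomicInterval]] = defaultdict(list)
    meta: dict[str, dict[str, str | None]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF line "
                                 f"({len(parts)} columns, expected 9)")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable coordinates") from exc
            attr = dict(_GTF_ATTR.findall(attrs))
            tid = attr.get("transcript_id")
            if not tid:
                raise ValueError(f"{path}:{lineno}: exon without transcript_id")
            try:
                iv = GenomicInterval(chrom, start_i - 1, end_i, strand)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            exons[tid].append(iv)
            if tid not in meta:
                meta[tid] = {
                    "gene_id": attr.get("gene_id", tid),
                    "class_code": attr.get("class_code"),
                    "biotype": attr.get("biotype", "candidate"),
                }
    models = []
    for tid in sorted(exons):
        m = meta[tid]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=m["gene_id"] or tid,
                exons=exons[tid],
                class_code=m["class_code"],
                biotype=m["biotype"] or "candidate",
            )
        )
    return models


def write_transcripts(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GTF exon features (inverse of read_transcripts)."""
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda t: t.transcript_id):
            for ex in m.exons:
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                if m.class_code is not None:
                    attrs += f' class_code "{m.class_code}";'
                attrs += f' biotype "{m.biotype}";'
                fh.write(
                    f"{ex.chrom}\ttelink\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# RepeatMasker .out


def read_repeatmasker(path: str | Path, keep_non_te: bool = False) -> list[TEInsertion]:
    """Parse a RepeatMasker ``.out`` file into TE insertions.

    The standard layout has 3 header lines followed by whitespace-separated
    columns; query begin/end are 1-based closed and strand 'C' means minus.
    Simple_repeat and Low_complexity records are dropped (they are masking
    artifacts, not transposons) unless ``keep_non_te`` is set.  The
    class/family column is split on the first '/'; when there is no '/',
    the family equals the whole class string.
    """
    tes: list[TEInsertion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            first = stripped.split()[0]
            try:
                score = int(first)
            except ValueError:
                # header line ("SW score ..." / "score div ...")
                continue
            cols = stripped.split()
            if len(cols) < 14:
                raise ValueError(
                    f"{path}:{lineno}: truncated RepeatMasker row "
                    f"({len(cols)} columns, expected >= 14)"
                )
            try:
                qstart, qend = int(cols[5]), int(cols[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable positions") from exc
            chrom = cols[4]
            strand = "-" if cols[8] == "C" else "+"
            name = cols[9]
            class_family = cols[10]
            te_class, _, family = class_family.partition("/")
            if not family:
                family = te_class
            if not keep_non_te and te_class in NON_TE_CLASSES:
                continue
            try:
                iv = GenomicInterval(chrom, qstart - 1, qend, strand)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            tes.append(
                TEInsertion(
                    interval=iv,
                    te_class=te_class,
                    family=family,
                    name=name,
                    score=float(score),
                    te_id=cols[14] if len(cols) > 14 else f"te_{lineno}",
                )
            )
    return tes


_RM_HEADER = (
    "   SW  perc perc perc  query     position in query    matching"
    "  repeat        position in repeat\n"
    "score  div. del. ins.  sequence  begin end   (left)   repeat"
    "  class/family  begin end (left)  ID\n"
    "\n"
)


def write_repeatmasker(tes: Iterable[TEInsertion], path: str | Path) -> None:
    """Write TE insertions in RepeatMasker ``.out`` layout."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, te in enumerate(tes):
            iv = te.interval
            strand = "C" if iv.strand == "-" else "+"
            te_id = te.te_id or f"te_{i}"
            fh.write(
                f"{int(te.score):5d}  0.0  0.0  0.0  {iv.chrom}  "
                f"{iv.start + 1} {iv.end} (0)  {strand}  {te.name or te.family}  "
                f"{te.label}  1 {len(iv)} (0)  {te_id}\n"
            )


# ---------------------------------------------------------------------------
# BED


def read_features(path: str | Path, kind: str) -> FeatureTrack:
    """Read a BED3+ file into a feature track of the stated kind."""
    features: list[GenomicInterval] = []
    labels: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: BED line with < 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable coordinates") from exc
            strand = cols[5] if len(cols) >= 6 and cols[5] in ("+", "-") else "."
            try:
                iv = GenomicInterval(cols[0], start, end, strand)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            features.append(iv)
            labels.append(cols[3] if len(cols) >= 4 else f"{kind}_{len(features) - 1}")
    return FeatureTrack(kind=kind, features=features, labels=labels)


def write_features(track: FeatureTrack, path: str | Path) -> None:
    """Write a feature track as BED4 (BED6 when any feature is stranded)."""
    stranded = any(f.strand != "." for f in track.features)
    with open(path, "w") as fh:
        for iv, label in track:
            if stranded:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")


# ---------------------------------------------------------------------------
# Expression TSV


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a features x samples FPKM table (TSV, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.size == 0:
        raise ValueError(f"{path}: expression table has no sample columns")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value") from exc
    if df.isna().to_numpy().any():
        raise ValueError(f"{path}: ragged or missing expression values")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression value")
    df.index = df.index.astype(str)
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     precision: int = 6) -> None:
    """Write an expression matrix as TSV at fixed decimal precision."""
    matrix.values.to_csv(path, sep="\t", float_format=f"%.{precision}f",
                         index_label="feature_id")


# ---------------------------------------------------------------------------
# bedGraph conservation runs


def read_conservation(path: str | Path) -> ConservationTrack:
    """Read a bedGraph file of per-base conservation score runs."""
    runs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ValueError(f"{path}:{lineno}: bedGraph line with < 4 columns")
            try:
                iv = GenomicInterval(cols[0], int(cols[1]), int(cols[2]))
                score = float(cols[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            runs.append((iv, score))
    return ConservationTrack(runs)


def write_conservation(track: ConservationTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            for s, e, score in track.runs(chrom):
                fh.write(f"{chrom}\t{s}\t{e}\t{score:g}\n")


# ---------------------------------------------------------------------------
# chrom sizes


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# sequence helpers

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def transcript_sequence(model: TranscriptModel, genome) -> str:
    """Spliced sense-strand sequence of a transcript.

    ``genome`` is any mapping of chromosome name to an indexable sequence
    (e.g. a ``pyfaidx.Fasta`` or a plain dict of strings).
    """
    parts = [str(genome[model.chrom][e.start:e.end]) for e in model.exons]
    seq = "".join(parts).upper()
    return _revcomp(seq) if model.strand == "-" else seq


def project_to_genome(model: TranscriptModel, t_start: int,
                      t_end: int) -> list[GenomicInterval]:
    """Project a transcript-coordinate interval through the exon chain.

    Transcript coordinate 0 is the 5' end of the mature RNA, so on the minus
    strand it maps to the highest genomic position.  Returns the genomic
    blocks (sorted by genomic start) covering ``[t_start, t_end)``.
    """
    if not (0 <= t_start < t_end <= model.mature_length):
        raise ValueError("transcript interval out of range")
    # exon chain in transcript (5'->3') order
    exons = model.exons if model.strand != "-" else list(reversed(model.exons))
    blocks: list[GenomicInterval] = []
    offset = 0
    for ex in exons:
        ex_len = len(ex)
        lo = max(t_start, offset)
        hi = min(t_end, offset + ex_len)
        if lo < hi:
            if model.strand == "-":
                g_start = ex.end - (hi - offset)
                g_end = ex.end - (lo - offset)
            else:
                g_start = ex.start + (lo - offset)
                g_end = ex.start + (hi - offset)
            blocks.append(GenomicInterval(model.chrom, g_start, g_end, model.strand))
        offset += ex_len
    return sorted(blocks, key=lambda b: b.start)
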