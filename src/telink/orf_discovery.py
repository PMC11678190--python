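"""Candidate ORF annotation on lncRNA transcripts and TE-derived ORF calls.

ORFs are scanned on the sense strand of the spliced transcript in all three
reading frames.  The default rule is longest-per-stop: each in-frame stop
codon is paired with the most 5' in-frame ATG after the previous in-frame
stop, so nested starts sharing a stop yield one (maximal) ORF.  An ORF must
have at least ``min_codons`` codons including the stop.  Codons containing
N never act as a start or a stop.  An all-ATG mode (one ORF per start
codon) is available for exploratory scans.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .genomic_io import GenomicInterval, TranscriptModel, project_to_genome
from .regulatory_integration import (
    DEFAULT_ATTRIBUTION_FRACTION,
    GroupTestResult,
    compare_groups,
)
from .te_overlap import merge_intervals

__all__ = [
    "OpenReadingFrame",
    "find_orfs",
    "find_orfs_spliced",
    "classify_te_orfs",
    "orf_prevalence_compare",
    "STOP_CODONS",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
DEFAULT_MIN_CODONS = 10


@dataclass
class OpenReadingFrame:
    """An ORF in transcript coordinates (0-based half-open, stop included)."""

    transcript_id: str
    start: int
    end: int
    frame: int
    peptide: str
    genomic_blocks: list[GenomicInterval] | None = None
    te_derived: bool | None = None

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")

    @property
    def n_codons(self) -> int:
        return (self.end - self.start) // 3

    @property
    def genomic_length(self) -> int:
        return self.end - self.start


def find_orfs(
    sequence: str,
    min_codons: int = DEFAULT_MIN_CODONS,
    transcript_id: str = "",
    all_starts: bool = False,
) -> list[OpenReadingFrame]:
    """Scan a spliced sense-strand transcript sequence for candidate ORFs.

    Returns ORFs sorted by (start, end).  ``min_codons`` counts codons
    including the stop; sequences shorter than ``3 * min_codons`` yield an
    empty set.  With ``all_starts`` every in-frame ATG opens its own ORF to
    the next stop instead of only the most 5' one.
    """
    seq = sequence.upper()
    n = len(seq)
    orfs: list[OpenReadingFrame] = []
    if n < 3 * min_codons:
        return orfs
    for frame in range(3):
        starts: list[int] = []  # nt offsets of candidate ATGs since last stop
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if "N" in codon:
                continue
            if codon == START_CODON:
                starts.append(pos)
            elif codon in STOP_CODONS:
                chosen = starts if all_starts else starts[:1]
                for s in chosen:
                    end = pos + 3
                    if (end - s) // 3 >= min_codons:
                        pep = str(Seq(seq[s : pos]).translate())
                        orfs.append(
                            OpenReadingFrame(
                                transcript_id=transcript_id,
                                start=s,
                                end=end,
                                frame=frame,
                                peptide=pep,
                            )
                        )
                starts = []
    orfs.sort(key=lambda o: (o.start, o.end))
    return orfs


def find_orfs_spliced(
    model: TranscriptModel,
    genome,
    min_codons: int = DEFAULT_MIN_CODONS,
    all_starts: bool = False,
) -> list[OpenReadingFrame]:
    """Find ORFs on a transcript model and project them through the exon chain.

    ``genome`` maps chromosome name to an indexable sequence (pyfaidx Fasta
    or dict of strings).
    """
    from .genomic_io import transcript_sequence

    seq = transcript_sequence(model, genome)
    orfs = find_orfs(
        seq, min_codons=min_codons, transcript_id=model.transcript_id,
        all_starts=all_starts,
    )
    for o in orfs:
        o.genomic_blocks = project_to_genome(model, o.start, o.end)
    return orfs


def classify_te_orfs(
    orfs: Sequence[OpenReadingFrame],
    te_spans: Mapping[str, Sequence[GenomicInterval]],
    min_fraction: float = DEFAULT_ATTRIBUTION_FRACTION,
) -> list[OpenReadingFrame]:
    """Flag ORFs as TE-derived when >= ``min_fraction`` of their genomic
    bases (across the exon chain) lie inside the host lncRNA's TE spans.

    ``te_spans`` maps transcript_id to merged TE spans clipped to the locus.
    ORFs are mutated in place (``te_derived`` set) and returned.
    """
    for o in orfs:
        if o.genomic_blocks is None:
            raise ValueError(
                f"ORF on {o.transcript_id}: genomic projection required"
            )
        spans = te_spans.get(o.transcript_id, [])
        clipped = []
        for block in o.genomic_blocks:
            for s in spans:
                bp = s.overlap_bp(block)
                if bp > 0:
                    clipped.append(
                        (max(s.start, block.start), min(s.end, block.end))
                    )
        covered = sum(e - s for s, e in merge_intervals(clipped))
        total = sum(len(b) for b in o.genomic_blocks)
        o.te_derived = covered / total >= min_fraction
    return list(orfs)


def orf_prevalence_compare(
    orf_counts: Mapping[str, int],
    class_labels: Mapping[str, str],
    lengths: Mapping[str, int] | None = None,
    per_kb: bool = False,
    test: str = "mannwhitney",
) -> tuple[dict[str, float], GroupTestResult | None]:
    """Compare per-lncRNA ORF counts between classes (e.g. TE vs Non-TE).

    With ``per_kb`` the counts are divided by transcript length in kb
    (``lengths`` required), exposing the length confounder in raw-count
    comparisons.  Returns the per-class means and the rank test (None when
    no lncRNA has any ORF).
    """
    values: dict[str, float] = {}
    for tid, c in orf_counts.items():
        if per_kb:
            if lengths is None:
                raise ValueError("per_kb mode requires transcript lengths")
            values[tid] = c / (lengths[tid] / 1000.0)
        else:
            values[tid] = float(c)
    by_class: dict[str, list[float]] = defaultdict(list)
    for tid, v in values.items():
        by_class[class_labels[tid]].append(v)
    means = {cls: sum(v) / len(v) if v else float("nan") for cls, v in by_class.items()}
    if len(by_class) < 2 or all(v == 0 for v in values.values()):
        return means, None
    result = compare_groups(values, {t: class_labels[t] for t in values}, test=test)
    return means, result
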