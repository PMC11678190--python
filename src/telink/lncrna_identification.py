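"""Three-stage filter cascade turning assembled candidate transcripts into lncRNAs.

Stage 1 (structure): keep transcripts with a novel-class relation to the
reference annotation (class codes u, x, i, j, o), mature length >= 200 bp
and at least one exon.  Stage 2 (noncoding): keep transcripts that both
coding-potential predictors call noncoding and that have no protein homology
hit; the predictor calls and the homology flag are consumed inputs.  Stage 3
(expressed): keep transcripts whose total FPKM across all samples is greater
than zero.

The ``length`` used by the 200 bp rule is the mature (spliced) transcript
length; switch to the genomic locus span with ``length_mode="locus"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genomic_io import ExpressionMatrix, TranscriptModel

__all__ = [
    "LNCRNA_CLASS_CODES",
    "MIN_LNCRNA_LENGTH",
    "Candidate",
    "FilterReport",
    "candidates_from_models",
    "read_calls",
    "write_calls",
    "filter_structure",
    "filter_noncoding",
    "filter_expressed",
    "run_identification",
]

LNCRNA_CLASS_CODES = frozenset("uxijo")
MIN_LNCRNA_LENGTH = 200
STAGES = ("input", "structure", "noncoding", "expressed")


@dataclass
class Candidate:
    """Per-transcript annotations entering the cascade.

    ``cpc_call`` / ``cnci_call`` are 'coding' or 'noncoding' predictions from
    the two coding-potential tools; ``protein_hit`` flags a protein homology
    match.  Any of the three may be ``None`` for transcripts that never reach
    stage 2 (e.g. in unit fixtures), but a ``None`` reaching stage 2 is an
    error.
    """

    transcript_id: str
    class_code: str | None
    length: int
    exon_count: int
    cpc_call: str | None = None
    cnci_call: str | None = None
    protein_hit: bool | None = None
    model: TranscriptModel | None = None


@dataclass
class FilterReport:
    """Per-stage accounting of the cascade: counts and rejection reasons."""

    stage_names: tuple[str, ...] = STAGES
    counts: list[int] = field(default_factory=list)
    rejections: dict[str, str] = field(default_factory=dict)

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": list(self.stage_names), "surviving": self.counts}
        )


def candidates_from_models(
    models: Iterable[TranscriptModel],
    calls: pd.DataFrame | None = None,
    length_mode: str = "mature",
) -> list[Candidate]:
    """Build cascade candidates from transcript models plus a calls table.

    ``calls`` is indexed by transcript_id with columns cpc_call, cnci_call,
    protein_hit (as written by :func:`write_calls`).
    """
    out = []
    for m in models:
        length = m.mature_length if length_mode == "mature" else m.locus_length
        cpc = cnci = None
        hit: bool | None = None
        if calls is not None and m.transcript_id in calls.index:
            row = calls.loc[m.transcript_id]
            cpc, cnci = str(row["cpc_call"]), str(row["cnci_call"])
            hit = bool(row["protein_hit"])
        out.append(
            Candidate(
                transcript_id=m.transcript_id,
                class_code=m.class_code,
                length=length,
                exon_count=len(m.exons),
                cpc_call=cpc,
                cnci_call=cnci,
                protein_hit=hit,
                model=m,
            )
        )
    return out


def read_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    required = {"transcript_id", "cpc_call", "cnci_call", "protein_hit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: calls table missing columns {sorted(missing)}")
    df["protein_hit"] = df["protein_hit"].astype(bool)
    return df.set_index("transcript_id")


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index_label="transcript_id")


# ---------------------------------------------------------------------------
# the three predicates


def _passes_structure(c: Candidate) -> str | None:
    """Return None if the candidate passes, else the first failing rule."""
    if c.class_code is None or c.class_code not in LNCRNA_CLASS_CODES:
        return "class_code"
    if c.length < MIN_LNCRNA_LENGTH:
        return "length"
    if c.exon_count < 1:
        return "exon_count"
    return None


def _passes_noncoding(c: Candidate) -> str | None:
    for attr in ("cpc_call", "cnci_call", "protein_hit"):
        if getattr(c, attr) is None:
            raise ValueError(
                f"candidate {c.transcript_id}: missing {attr} at noncoding stage"
            )
    if c.cpc_call != "noncoding":
        return "cpc_coding"
    if c.cnci_call != "noncoding":
        return "cnci_coding"
    if c.protein_hit:
        return "protein_hit"
    return None


def _passes_expressed(c: Candidate, matrix: ExpressionMatrix) -> str | None:
    if matrix.row_sum(c.transcript_id) > 0:
        return None
    return "not_expressed"


def filter_structure(
    candidates: Sequence[Candidate], report: FilterReport | None = None
) -> list[Candidate]:
    """Keep candidates with class code in {u,x,i,j,o}, length >= 200, >= 1 exon."""
    survivors = []
    for c in candidates:
        reason = _passes_structure(c)
        if reason is None:
            survivors.append(c)
        elif report is not None:
            report.rejections.setdefault(c.transcript_id, reason)
    return survivors


def filter_noncoding(
    candidates: Sequence[Candidate], report: FilterReport | None = None
) -> list[Candidate]:
    """Keep candidates both predictors call noncoding and without protein hits."""
    survivors = []
    for c in candidates:
        reason = _passes_noncoding(c)
        if reason is None:
            survivors.append(c)
        elif report is not None:
            report.rejections.setdefault(c.transcript_id, reason)
    return survivors


def filter_expressed(
    candidates: Sequence[Candidate],
    matrix: ExpressionMatrix,
    report: FilterReport | None = None,
) -> list[Candidate]:
    """Keep candidates whose FPKM row-sum is > 0 (absent rows are all-zero)."""
    survivors = []
    for c in candidates:
        reason = _passes_expressed(c, matrix)
        if reason is None:
            survivors.append(c)
        elif report is not None:
            report.rejections.setdefault(c.transcript_id, reason)
    return survivors


def run_identification(
    candidates: Sequence[Candidate], matrix: ExpressionMatrix
) -> tuple[list[Candidate], FilterReport]:
    """Apply the cascade structure -> noncoding -> expressed.

    Returns the surviving lncRNA set (models, when present, are re-labelled
    with biotype 'lncRNA') and the per-stage :class:`FilterReport`.
    """
    report = FilterReport()
    report.counts.append(len(candidates))
    s1 = filter_structure(candidates, report)
    report.counts.append(len(s1))
    s2 = filter_noncoding(s1, report)
    report.counts.append(len(s2))
    s3 = filter_expressed(s2, matrix, report)
    report.counts.append(len(s3))
    for c in s3:
        if c.model is not None:
            c.model.biotype = "lncRNA"
    return s3, report
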