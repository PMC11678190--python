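"""Seed-reproducible synthetic dataset generator with ground-truth bookkeeping.

The generator emits a complete toy study — genome FASTA, transcript GTF
(coding genes plus lncRNA candidates, including candidates built to fail
each identification filter), RepeatMasker-style TE annotations, ATAC / TFBS
/ m6A BED tracks, an FPKM expression matrix, coding-potential calls and a
conservation bedGraph — carrying the statistical structure the analysis
modules measure:

* a Gypsy-dominated TE family mixture;
* a planted fraction of TE-lncRNAs with bimodal TE coverage rates
  (mass in the 0-25% and 75-100% intervals);
* intronic/promoter positional bias of hosted TE insertions, with a planted
  subset of TEs crossing lncRNA TSSs;
* uniform intergenic background TEs plus boosted terminal chromosome bins
  (insertion hotspots);
* ATAC peak counts coupled to TE coverage (Poisson(alpha + beta * rate));
* TFBSs planted inside vs outside TE spans, and denser promoter TFBSs for
  lncRNAs with a TE in the promoter;
* m6A site counts drawn identically for TE- and Non-TE-lncRNAs (a true
  null);
* an expression matrix with heavy-metal condition labels, planted
  condition-specific (high tau) features, and planted lowest-expression
  TE-lncRNAs;
* explicit ORF cassettes written into designated lncRNA exons.

Placement geometry guarantees that planted quantities are *exact*: lncRNA
and gene loci are disjoint with >= ``min_gap`` spacing and stay out of the
terminal hotspot zones; TEs hosted by a locus keep 250 bp clearance from
its edges (so their context label is decided by the host alone); background
TEs never touch any locus (so per-lncRNA TE counts, coverage, TSS flags and
promoter classes equal the planted values).  Everything derives from one
``numpy`` Generator, so equal seeds give byte-identical output trees.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .genomic_io import (
    ConservationTrack,
    ExpressionMatrix,
    FeatureTrack,
    GenomicInterval,
    TEInsertion,
    TranscriptModel,
    project_to_genome,
    write_chrom_sizes,
    write_conservation,
    write_expression,
    write_features,
    write_repeatmasker,
    write_transcripts,
)
from .lncrna_identification import Candidate
from .te_overlap import merge_intervals

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "simulate",
    "plant_filter_failures",
]

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.frombuffer(b"ACGT", dtype="S1")
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

DEFAULT_FAMILY_MIXTURE = {
    "LTR/Gypsy": 0.40,
    "LTR/Pao": 0.11,
    "LINE/I-Jockey": 0.08,
    "RC/Helitron": 0.07,
    "LTR/Copia": 0.10,
    "LINE/Jockey": 0.09,
    "DNA/P": 0.08,
    "LINE/R1": 0.07,
}

CONDITIONS = ("control", "Cd", "Cu", "Pb", "Zn")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 1
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "chr2L": 2_000_000,
            "chr2R": 2_000_000,
            "chr3L": 2_000_000,
        }
    )
    n_coding: int = 200
    n_lncrna: int = 1000
    te_lncrna_fraction: float = 0.40
    family_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_MIXTURE)
    )
    # bimodal coverage-rate mixture (Beta params, equal weights)
    coverage_beta_low: tuple[float, float] = (1.2, 6.0)
    coverage_beta_high: tuple[float, float] = (6.0, 1.2)
    # TE geometry
    n_te_intergenic: int = 4500
    te_length_median: float = 1000.0
    te_length_sigma: float = 0.7
    te_length_cap: int = 15_000
    te_length_min: int = 80
    te_body_length_median: float = 400.0  # TEs hosted inside lncRNA loci
    te_body_length_sigma: float = 0.6
    n_simple_repeats: int = 150  # decoy records dropped by the .out reader
    # hotspots: terminal bins at both ends of every chromosome
    hotspot_multiplier: float = 5.0
    hotspot_bin_size: int = 50_000
    # planted regulatory structure
    tss_te_fraction: float = 0.30  # of TE-lncRNAs; these TEs cross the TSS
    atac_alpha: float = 1.0
    atac_beta: float = 6.0
    n_tfbs_body: int = 600
    tfbs_in_te_fraction: float = 0.80
    tfbs_promoter_lambda_te_pro: float = 4.0
    tfbs_promoter_lambda_other: float = 0.5
    m6a_lambda: float = 1.0
    coding_exon_te_fraction: float = 0.05
    # expression
    n_replicates: int = 3
    tau_specific_fraction: float = 0.20
    induced_fold: float = 8.0
    # ORF cassettes
    orf_cassette_count: int = 100
    orf_cassette_codons: int = 60  # including the stop codon
    # identification-filter failure plants
    n_fail_class: int = 25
    n_fail_length: int = 25
    n_fail_coding: int = 25
    n_fail_expression: int = 25
    # geometry
    min_gap: int = 2300
    locus_edge_clearance: int = 250

    def __post_init__(self) -> None:
        if abs(sum(self.family_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("family mixture must sum to 1")
        for name in ("n_coding", "n_lncrna", "n_te_intergenic"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("te_lncrna_fraction", "tss_te_fraction",
                     "tfbs_in_te_fraction", "tau_specific_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{c}_{r + 1}" for c in CONDITIONS for r in range(self.n_replicates)]

    @property
    def condition_of_sample(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.sample_ids}


@dataclass
class GroundTruth:
    """Planted quantities, exact by construction."""

    te_lncrna_ids: list[str]
    non_te_lncrna_ids: list[str]
    coverage: dict[str, dict]  # tid -> {te_count, covered_bp, coverage_rate}
    tss_flagged_ids: list[str]
    te_promoter_ids: list[str]
    hotspot_bins: dict[str, list[int]]
    hotspot_bin_size: int
    tfbs_te_derived_ids: list[str]
    tfbs_non_derived_ids: list[str]
    atac_counts: dict[str, int]
    m6a_counts: dict[str, int]
    tau_specific_ids: list[str]
    tau_uniform_ids: list[str]
    orf_cassettes: list[dict]
    planted_context: dict[str, str]  # te_id -> label, for determinate plants
    expected_filter_report: tuple[int, int, int, int]
    conservation_order: tuple[str, ...] = (
        "coding", "Non-TE-lncRNA", "TE-lncRNA"
    )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["expected_filter_report"] = tuple(d["expected_filter_report"])
        d["conservation_order"] = tuple(d["conservation_order"])
        return cls(**d)


@dataclass
class SimulatedDataset:
    """In-memory synthetic study plus its ground truth."""

    config: SimulationConfig
    chrom_sizes: dict[str, int]
    genome: dict[str, str]
    transcripts: list[TranscriptModel]  # coding + every lncRNA candidate
    tes: list[TEInsertion]
    atac: FeatureTrack
    tfbs: FeatureTrack
    m6a: FeatureTrack
    expression: ExpressionMatrix
    calls: pd.DataFrame
    conservation: ConservationTrack
    truth: GroundTruth
    simple_repeats: list[TEInsertion] = field(default_factory=list)

    @property
    def candidate_models(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.biotype != "coding"]

    @property
    def coding_models(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.biotype == "coding"]

    @property
    def lncrna_models(self) -> list[TranscriptModel]:
        """The clean planted lncRNA set (what the cascade should emit)."""
        clean = set(self.truth.te_lncrna_ids) | set(self.truth.non_te_lncrna_ids)
        return [t for t in self.transcripts if t.transcript_id in clean]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "gtf": out / "annotation.gtf",
            "te": out / "te.out",
            "atac": out / "atac.bed",
            "tfbs": out / "tfbs.bed",
            "m6a": out / "m6a.bed",
            "expression": out / "expression.tsv",
            "calls": out / "calls.tsv",
            "conservation": out / "conservation.bedgraph",
            "chrom_sizes": out / "chrom.sizes",
            "truth": out / "ground_truth.json",
        }
        with open(paths["genome"], "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        write_transcripts(self.transcripts, paths["gtf"])
        # decoy low-complexity records go in the .out; readers drop them
        write_repeatmasker(self.tes + self.simple_repeats, paths["te"])
        write_features(self.atac, paths["atac"])
        write_features(self.tfbs, paths["tfbs"])
        write_features(self.m6a, paths["m6a"])
        write_expression(self.expression, paths["expression"])
        self.calls.to_csv(paths["calls"], sep="\t", index_label="transcript_id")
        write_conservation(self.conservation, paths["conservation"])
        write_chrom_sizes(self.chrom_sizes, paths["chrom_sizes"])
        self.truth.to_json(paths["truth"])
        return paths


# ---------------------------------------------------------------------------
# helpers


def _lognormal_lengths(rng, n, median, sigma, lo, hi) -> np.ndarray:
    x = rng.lognormal(mean=math.log(median), sigma=sigma, size=n)
    return np.clip(np.round(x), lo, hi).astype(int)


def _split_locus(rng, length: int, n_exons: int) -> list[tuple[int, int]]:
    """Exon offsets (relative to locus start) for an exon/intron chain."""
    exon_min, intron_min = 100, 400
    while n_exons > 1 and length < n_exons * exon_min + (n_exons - 1) * intron_min:
        n_exons -= 1
    if n_exons == 1:
        return [(0, length)]
    k = 2 * n_exons - 1
    mins = np.array([exon_min if i % 2 == 0 else intron_min for i in range(k)])
    extra = rng.multinomial(length - mins.sum(), np.full(k, 1.0 / k))
    segs = mins + extra
    # tails of a locus are exonic by definition: first/last segments are exons
    offsets = np.concatenate([[0], np.cumsum(segs)])
    return [
        (int(offsets[i]), int(offsets[i + 1])) for i in range(0, k, 2)
    ]


def _place_in_free_simple(rng, free: list[tuple[int, int]], length: int) -> int | None:
    """Pick a start for a ``length`` interval inside disjoint free segments,
    weighted by available room; updates ``free`` in place."""
    rooms = [(i, e - s - length) for i, (s, e) in enumerate(free) if e - s >= length]
    if not rooms:
        return None
    weights = np.array([r + 1 for _, r in rooms], dtype=float)
    idx = rng.choice(len(rooms), p=weights / weights.sum())
    i, room = rooms[idx]
    s, e = free[i]
    start = s + int(rng.integers(0, room + 1))
    free.pop(i)
    if start > s:
        free.insert(i, (s, start))
        i += 1
    if start + length < e:
        free.insert(i, (start + length, e))
    return start


def _random_seq(rng, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


# ---------------------------------------------------------------------------
# the generator


def simulate(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate the full synthetic study for ``config`` (defaults if None).

    Raises ``ValueError`` before any output is produced when the requested
    loci or TEs cannot fit the genome.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    clearance = cfg.locus_edge_clearance

    # ---- 1. locus specs ---------------------------------------------------
    n_te_l = round(cfg.te_lncrna_fraction * cfg.n_lncrna)
    n_non_te = cfg.n_lncrna - n_te_l

    specs: list[dict] = []
    for i in range(cfg.n_coding):
        specs.append({"id": f"gene_{i:04d}", "kind": "coding",
                      "length": None, "n_exons": int(rng.integers(2, 6))})
    for i in range(n_te_l):
        specs.append({"id": f"lnc_te_{i:04d}", "kind": "lnc_te",
                      "length": None, "n_exons": int(rng.integers(2, 4))})
    for i in range(n_non_te):
        specs.append({"id": f"lnc_nt_{i:04d}", "kind": "lnc_nt",
                      "length": None, "n_exons": int(rng.integers(1, 4))})
    fails = (
        [("fail_class", cfg.n_fail_class), ("fail_length", cfg.n_fail_length),
         ("fail_coding", cfg.n_fail_coding), ("fail_expr", cfg.n_fail_expression)]
    )
    for kind, n in fails:
        for i in range(n):
            specs.append({"id": f"{kind}_{i:03d}", "kind": kind,
                          "length": None,
                          "n_exons": 1 if kind == "fail_length"
                          else int(rng.integers(1, 4))})

    def draw_length(kind: str) -> int:
        if kind == "coding":
            return int(_lognormal_lengths(rng, 1, 2000, 0.4, 600, 6000)[0])
        if kind == "lnc_te":
            return int(_lognormal_lengths(rng, 1, 2200, 0.55, 800, 8000)[0])
        if kind == "fail_length":
            return 150
        return int(_lognormal_lengths(rng, 1, 1200, 0.5, 300, 5000)[0])

    for s in specs:
        s["length"] = draw_length(s["kind"])

    # ---- 2. assign loci to chromosomes and place them ---------------------
    chroms = sorted(cfg.chrom_lengths)
    margin = cfg.hotspot_bin_size  # keep loci out of the terminal hotspot zones
    usable = {c: cfg.chrom_lengths[c] - 2 * margin for c in chroms}
    if min(usable.values()) <= 0:
        raise ValueError("chromosomes shorter than two hotspot bins")
    order = rng.permutation(len(specs))
    per_chrom: dict[str, list[dict]] = {c: [] for c in chroms}
    loads = {c: 0 for c in chroms}
    for idx in order:
        s = specs[idx]
        # greedily balance by current load fraction
        c = min(chroms, key=lambda ch: (loads[ch] + s["length"]) / usable[ch])
        per_chrom[c].append(s)
        loads[c] += s["length"] + cfg.min_gap

    models: list[TranscriptModel] = []
    loci_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for c in chroms:
        group = per_chrom[c]
        total = sum(s["length"] for s in group)
        slack = usable[c] - total - cfg.min_gap * (len(group) + 1)
        if slack < 0:
            raise ValueError(
                f"infeasible placement: loci exceed capacity on {c} "
                f"(short by {-slack} bp)"
            )
        extra = rng.multinomial(slack, np.full(len(group) + 1, 1.0 / (len(group) + 1)))
        cursor = margin
        for j, s in enumerate(group):
            cursor += cfg.min_gap + int(extra[j])
            start = cursor
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            exon_offsets = _split_locus(rng, s["length"], s["n_exons"])
            exons = [
                GenomicInterval(c, start + a, start + b, strand)
                for a, b in exon_offsets
            ]
            biotype = "coding" if s["kind"] == "coding" else "candidate"
            if s["kind"] == "coding":
                class_code = "="
            elif s["kind"] == "fail_class":
                class_code = "="
            else:
                class_code = str(rng.choice(list("uxijo")))
            models.append(
                TranscriptModel(
                    transcript_id=s["id"], gene_id=s["id"].replace("lnc", "g", 1),
                    exons=exons, class_code=class_code, biotype=biotype,
                )
            )
            s["start"], s["chrom"], s["strand"] = start, c, strand
            loci_by_chrom[c].append((start, start + s["length"]))
            cursor = start + s["length"]
    by_id = {m.transcript_id: m for m in models}
    for c in chroms:
        loci_by_chrom[c].sort()

    # ---- 3. TEs hosted by TE-lncRNAs --------------------------------------
    families = sorted(cfg.family_mixture)
    fam_p = np.array([cfg.family_mixture[f] for f in families])
    te_list: list[TEInsertion] = []
    planted_context: dict[str, str] = {}
    coverage_truth: dict[str, dict] = {}
    te_ids_by_host: dict[str, list[str]] = {}
    te_spans_by_host: dict[str, list[tuple[int, int]]] = {}

    def new_te(chrom, start, end, label_hint=None) -> TEInsertion:
        te_id = f"te_{len(te_list):05d}"
        fam_label = families[rng.choice(len(families), p=fam_p)]
        te_class, _, family = fam_label.partition("/")
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        te = TEInsertion(
            interval=GenomicInterval(chrom, start, end, strand),
            te_class=te_class, family=family or te_class,
            name=family or te_class, score=float(rng.integers(200, 5000)),
            te_id=te_id,
        )
        te_list.append(te)
        if label_hint is not None:
            planted_context[te_id] = label_hint
        return te

    te_lnc_ids = [s["id"] for s in specs if s["kind"] == "lnc_te"]
    non_te_ids = [s["id"] for s in specs if s["kind"] == "lnc_nt"]
    n_tss = round(cfg.tss_te_fraction * len(te_lnc_ids))
    tss_hosts = set(
        np.array(te_lnc_ids)[rng.choice(len(te_lnc_ids), size=n_tss, replace=False)]
    )

    low_a, low_b = cfg.coverage_beta_low
    high_a, high_b = cfg.coverage_beta_high
    for tid in te_lnc_ids:
        m = by_id[tid]
        locus = m.locus
        L = len(locus)
        # the 5' end needs clearance for the TSS window and the in-locus part
        # of the promoter window; the 3' end only needs a token margin
        if m.strand == "-":
            body_lo, body_hi = locus.start + 10, locus.end - clearance
        else:
            body_lo, body_hi = locus.start + clearance, locus.end - 10
        body_len = body_hi - body_lo
        if rng.random() < 0.5:
            target_rate = rng.beta(low_a, low_b)
        else:
            target_rate = rng.beta(high_a, high_b)
        target_bp = min(int(target_rate * L), int(body_len * 0.95))
        free = [(body_lo, body_hi)]
        placed: list[tuple[int, int]] = []
        covered = 0
        host_te_ids = []
        # the TSS-crossing plant counts toward coverage and te_count
        if tid in tss_hosts:
            if m.strand == "-":
                s_, e_ = m.tss - 89, m.tss + 61
            else:
                s_, e_ = m.tss - 60, m.tss + 90
            te = new_te(locus.chrom, s_, e_, label_hint="promoter")
            host_te_ids.append(te.te_id)
            clip = (max(s_, locus.start), min(e_, locus.end))
            placed.append(clip)
            covered += clip[1] - clip[0]
        attempts = 0
        while covered < max(target_bp, 1) and attempts < 200:
            attempts += 1
            want = int(
                _lognormal_lengths(rng, 1, cfg.te_body_length_median,
                                   cfg.te_body_length_sigma,
                                   cfg.te_length_min, cfg.te_length_cap)[0]
            )
            want = min(want, max(target_bp - covered, cfg.te_length_min))
            start = _place_in_free_simple(rng, free, want)
            if start is None:
                # fragmented body: shrink to the biggest remaining free segment
                biggest = max((e - s for s, e in free), default=0)
                if biggest < cfg.te_length_min:
                    break
                want = min(biggest, max(target_bp - covered, cfg.te_length_min))
                start = _place_in_free_simple(rng, free, want)
                if start is None:
                    break
            te = new_te(locus.chrom, start, start + want)
            host_te_ids.append(te.te_id)
            placed.append((start, start + want))
            covered += want
            # planted label: inside an intron -> intron, touching an exon -> exon
            iv = te.interval
            if any(iv.start >= i.start and iv.end <= i.end for i in m.introns):
                planted_context[te.te_id] = "intron"
            else:
                planted_context[te.te_id] = "exon"
        te_ids_by_host[tid] = host_te_ids
        te_spans_by_host[tid] = merge_intervals(placed)
        coverage_truth[tid] = {
            "te_count": len(host_te_ids),
            "covered_bp": covered,
            "coverage_rate": covered / L,
        }
    for tid in non_te_ids:
        coverage_truth[tid] = {"te_count": 0, "covered_bp": 0, "coverage_rate": 0.0}
        te_ids_by_host[tid] = []
        te_spans_by_host[tid] = []

    # a few coding genes carry an exonic TE (CDS-overlapping composition)
    coding_ids = [s["id"] for s in specs if s["kind"] == "coding"]
    n_cds_te = round(cfg.coding_exon_te_fraction * len(coding_ids))
    for tid in np.array(coding_ids)[
        rng.choice(len(coding_ids), size=n_cds_te, replace=False)
    ]:
        m = by_id[str(tid)]
        locus = m.locus
        # stay clear of the gene's own promoter window (5' end) too
        if m.strand == "-":
            b_lo, b_hi = locus.start + 10, locus.end - clearance
        else:
            b_lo, b_hi = locus.start + clearance, locus.end - 10
        ex = max(m.exons, key=lambda e: min(e.end, b_hi) - max(e.start, b_lo))
        lo, hi = max(ex.start, b_lo), min(ex.end, b_hi)
        room = hi - lo
        if room < cfg.te_length_min:
            continue
        want = int(rng.integers(cfg.te_length_min, min(room, 600) + 1))
        start = lo + int(rng.integers(0, room - want + 1))
        new_te(m.chrom, start, start + want, label_hint="exon")

    # ---- 4. background and hotspot TEs ------------------------------------
    genome_bp = sum(cfg.chrom_lengths.values())
    if cfg.n_te_intergenic * cfg.te_length_median > 10 * genome_bp:
        raise ValueError("infeasible placement: TE count exceeds genome capacity")
    n_bg_per_chrom = {
        c: cfg.n_te_intergenic // len(chroms) for c in chroms
    }
    for i, c in enumerate(chroms[: cfg.n_te_intergenic % len(chroms)]):
        n_bg_per_chrom[c] += 1
    hotspot_bins: dict[str, list[int]] = {}
    for c in chroms:
        size = cfg.chrom_lengths[c]
        n_bins = -(-size // cfg.hotspot_bin_size)
        hot = [0, n_bins - 1]
        hotspot_bins[c] = hot
        # free space = complement of loci
        free_iv: list[tuple[int, int]] = []
        cursor = 0
        for s, e in loci_by_chrom[c]:
            if s > cursor:
                free_iv.append((cursor, s))
            cursor = e
        if cursor < size:
            free_iv.append((cursor, size))
        free_bp = sum(e - s for s, e in free_iv)
        lens = _lognormal_lengths(
            rng, n_bg_per_chrom[c], cfg.te_length_median, cfg.te_length_sigma,
            cfg.te_length_min, cfg.te_length_cap,
        )
        starts_bg = []
        weights = np.array([e - s for s, e in free_iv], dtype=float)
        weights /= weights.sum()
        for ln in lens:
            # draw a free segment, clip the TE to it (TEs may overlap each other)
            i_seg = rng.choice(len(free_iv), p=weights)
            s, e = free_iv[i_seg]
            ln = min(int(ln), e - s)
            start = s + int(rng.integers(0, e - s - ln + 1))
            starts_bg.append((start, start + ln))
        # terminal hotspot boosts: extra TEs confined to the hot bins
        exp_per_bin = n_bg_per_chrom[c] * (cfg.hotspot_bin_size / free_bp)
        n_extra = int(round((cfg.hotspot_multiplier - 1.0) * exp_per_bin))
        for b in hot:
            lo = b * cfg.hotspot_bin_size
            hi = min(lo + cfg.hotspot_bin_size, size)
            for _ in range(n_extra):
                ln = int(
                    _lognormal_lengths(rng, 1, cfg.te_length_median,
                                       cfg.te_length_sigma, cfg.te_length_min,
                                       cfg.te_length_cap)[0]
                )
                # confined to the bin so hot TEs never reach locus territory
                half = ln // 2
                mid = int(rng.integers(lo + 1, hi - 1))
                start = max(lo, mid - half)
                end = min(hi, start + ln)
                starts_bg.append((start, end))
        for s, e in starts_bg:
            new_te(c, s, e)

    # decoy simple/low-complexity repeats (excluded from every TE analysis)
    simple_repeats: list[TEInsertion] = []
    for i in range(cfg.n_simple_repeats):
        c = chroms[int(rng.integers(0, len(chroms)))]
        ln = int(rng.integers(50, 301))
        start = int(rng.integers(0, cfg.chrom_lengths[c] - ln))
        cls = "Simple_repeat" if i % 2 == 0 else "Low_complexity"
        simple_repeats.append(
            TEInsertion(
                interval=GenomicInterval(c, start, start + ln, "+"),
                te_class=cls, family=cls,
                name="(AT)n" if cls == "Simple_repeat" else "A-rich",
                score=float(rng.integers(10, 100)),
                te_id=f"sr_{i:04d}",
            )
        )

    # ---- 5. ATAC / TFBS / m6A tracks --------------------------------------
    lnc_ids = te_lnc_ids + non_te_ids
    atac_features, atac_labels = [], []
    atac_counts: dict[str, int] = {}
    m6a_features, m6a_labels = [], []
    m6a_counts: dict[str, int] = {}
    for tid in lnc_ids:
        m = by_id[tid]
        locus = m.locus
        rate = coverage_truth[tid]["coverage_rate"]
        k = int(rng.poisson(cfg.atac_alpha + cfg.atac_beta * rate))
        atac_counts[tid] = k
        for _ in range(k):
            ln = min(int(rng.integers(200, 801)), len(locus))
            start = locus.start + int(rng.integers(0, len(locus) - ln + 1))
            atac_features.append(GenomicInterval(locus.chrom, start, start + ln))
            atac_labels.append(f"peak_{len(atac_labels):06d}")
        km = int(rng.poisson(cfg.m6a_lambda))
        m6a_counts[tid] = km
        for _ in range(km):
            ln = min(int(rng.integers(50, 201)), len(locus))
            start = locus.start + int(rng.integers(0, len(locus) - ln + 1))
            m6a_features.append(GenomicInterval(locus.chrom, start, start + ln))
            m6a_labels.append(f"m6a_{len(m6a_labels):05d}")

    tfbs_features, tfbs_labels = [], []
    tfbs_te_ids, tfbs_out_ids = [], []
    n_in_te = round(cfg.tfbs_in_te_fraction * cfg.n_tfbs_body)
    hosts_with_spans = [t for t in te_lnc_ids if te_spans_by_host[t]]
    for i in range(cfg.n_tfbs_body):
        label = f"tfbs_{i:05d}"
        ln = int(rng.integers(8, 16))
        if i < n_in_te:
            tid = hosts_with_spans[int(rng.integers(0, len(hosts_with_spans)))]
            spans = [
                (s, e) for s, e in te_spans_by_host[tid] if e - s >= ln + 2
            ]
            if not spans:
                spans = [max(te_spans_by_host[tid], key=lambda p: p[1] - p[0])]
                ln = min(ln, spans[0][1] - spans[0][0])
            s, e = spans[int(rng.integers(0, len(spans)))]
            start = s + int(rng.integers(0, e - s - ln + 1))
            chrom = by_id[tid].chrom
            tfbs_te_ids.append(label)
        else:
            # fully outside any TE span: use a Non-TE-lncRNA body
            tid = non_te_ids[int(rng.integers(0, len(non_te_ids)))]
            m = by_id[tid]
            locus = m.locus
            lo, hi = locus.start + clearance, locus.end - clearance
            if hi - lo < ln:
                lo, hi = locus.start, locus.end
            start = lo + int(rng.integers(0, hi - lo - ln + 1))
            chrom = locus.chrom
            tfbs_out_ids.append(label)
        tfbs_features.append(GenomicInterval(chrom, start, start + ln))
        tfbs_labels.append(label)
    # promoter TFBSs: denser for lncRNAs whose promoter holds one of their TEs
    for tid in lnc_ids:
        m = by_id[tid]
        lam = (
            cfg.tfbs_promoter_lambda_te_pro
            if tid in tss_hosts
            else cfg.tfbs_promoter_lambda_other
        )
        k = int(rng.poisson(lam))
        for _ in range(k):
            ln = int(rng.integers(8, 16))
            # strictly upstream part of the promoter window, outside the locus
            if m.strand == "-":
                lo, hi = m.tss + 150, m.tss + 1900
            else:
                lo, hi = m.tss - 1900, m.tss - 150
            if lo < 0 or hi - lo < ln:
                continue
            start = lo + int(rng.integers(0, hi - lo - ln + 1))
            label = f"tfbs_pro_{len(tfbs_labels):05d}"
            tfbs_features.append(GenomicInterval(m.chrom, start, start + ln))
            tfbs_labels.append(label)

    # ---- 6. expression matrix ---------------------------------------------
    samples = cfg.sample_ids
    n_s = len(samples)
    n_spec = round(cfg.tau_specific_fraction * len(lnc_ids))
    spec_ids = set(
        np.array(lnc_ids)[rng.choice(len(lnc_ids), size=n_spec, replace=False)]
    )
    metals = [c for c in CONDITIONS if c != "control"]
    cond_of = cfg.condition_of_sample
    rows: dict[str, np.ndarray] = {}
    for s in specs:
        tid = s["id"]
        kind = s["kind"]
        if kind == "fail_expr":
            rows[tid] = np.zeros(n_s)
            continue
        if kind == "coding":
            base = max(rng.gamma(3.0, 20.0), 1.0)
        elif kind == "lnc_te":
            base = max(rng.gamma(2.0, 2.5), 0.5)
        else:
            base = max(rng.gamma(2.0, 5.0), 0.5)
        noise = rng.lognormal(0.0, 0.25, size=n_s)
        if tid in spec_ids:
            metal = metals[int(rng.integers(0, len(metals)))]
            vals = np.zeros(n_s)
            on = [i for i, smp in enumerate(samples) if cond_of[smp] == metal]
            for i in on:
                vals[i] = base * cfg.induced_fold * noise[i]
            rows[tid] = vals
        else:
            rows[tid] = base * noise
    expr = pd.DataFrame(
        {smp: [rows[s["id"]][j] for s in specs] for j, smp in enumerate(samples)},
        index=pd.Index([s["id"] for s in specs], name="feature_id"),
    ).round(6)
    matrix = ExpressionMatrix(expr)
    tau_uniform = [
        t for t in lnc_ids if t not in spec_ids
    ]

    # ---- 7. calls table -----------------------------------------------------
    call_rows = []
    for j, s in enumerate(specs):
        if s["kind"] == "coding":
            continue
        cpc = cnci = "noncoding"
        hit = False
        if s["kind"] == "fail_coding":
            mode = j % 3
            if mode == 0:
                cpc = "coding"
            elif mode == 1:
                cnci = "coding"
            else:
                hit = True
        call_rows.append((s["id"], cpc, cnci, hit))
    calls = pd.DataFrame(
        call_rows, columns=["transcript_id", "cpc_call", "cnci_call", "protein_hit"]
    ).set_index("transcript_id")

    # ---- 8. genome sequence with ORF cassettes ------------------------------
    genome_arr = {c: _random_seq(rng, cfg.chrom_lengths[c]) for c in chroms}
    cassettes: list[dict] = []
    cass_nt = 3 * cfg.orf_cassette_codons
    eligible = []
    for tid in lnc_ids:
        m = by_id[tid]
        best = max(m.exons, key=len)
        if len(best) >= cass_nt + 60:
            eligible.append(tid)
    n_cass = min(cfg.orf_cassette_count, len(eligible))
    chosen = np.array(eligible)[
        rng.choice(len(eligible), size=n_cass, replace=False)
    ]
    comp = str.maketrans("ACGT", "TGCA")
    for tid in chosen:
        m = by_id[str(tid)]
        # transcript offset of the largest exon
        exons_5to3 = m.exons if m.strand != "-" else list(reversed(m.exons))
        off = 0
        best_off, best_len = 0, 0
        for ex in exons_5to3:
            if len(ex) > best_len:
                best_off, best_len = off, len(ex)
            off += len(ex)
        t_start = best_off + 30 + int(rng.integers(0, best_len - cass_nt - 60 + 1))
        t_end = t_start + cass_nt
        interior = "".join(
            _NONSTOP_CODONS[i]
            for i in rng.integers(0, len(_NONSTOP_CODONS),
                                  size=cfg.orf_cassette_codons - 2)
        )
        cassette = "ATG" + interior + "TAA"
        blocks = project_to_genome(m, t_start, t_end)
        # single exon host: one block; write sense-strand bases
        pos = 0
        if m.strand == "-":
            rc = cassette.translate(comp)[::-1]
            for b in blocks:
                seg = rc[pos : pos + len(b)]  # blocks sorted by genomic start
                genome_arr[b.chrom][b.start : b.end] = np.frombuffer(
                    seg.encode(), dtype="S1"
                )
                pos += len(b)
        else:
            for b in blocks:
                seg = cassette[pos : pos + len(b)]
                genome_arr[b.chrom][b.start : b.end] = np.frombuffer(
                    seg.encode(), dtype="S1"
                )
                pos += len(b)
        in_te = any(
            s <= blocks[0].start and blocks[-1].end <= e
            for s, e in te_spans_by_host[str(tid)]
        )
        cassettes.append(
            {"transcript_id": str(tid), "t_start": int(t_start),
             "t_end": int(t_end), "n_codons": cfg.orf_cassette_codons,
             "planted_in_te": bool(in_te)}
        )
    genome = {c: genome_arr[c].tobytes().decode() for c in chroms}

    # ---- 9. conservation track ----------------------------------------------
    runs: list[tuple[GenomicInterval, float]] = []
    te_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for te in te_list:
        te_by_chrom[te.interval.chrom].append((te.interval.start, te.interval.end))
    for s in specs:
        m = by_id[s["id"]]
        locus = m.locus
        if s["kind"] == "coding":
            base = 0.8
        elif s["kind"] == "lnc_te":
            base = 0.45
        else:
            base = 0.45
        spans = te_spans_by_host.get(s["id"], [])
        cursor = locus.start
        pieces: list[tuple[int, int, bool]] = []
        for ts, te_e in spans:
            if ts > cursor:
                pieces.append((cursor, ts, False))
            pieces.append((ts, te_e, True))
            cursor = te_e
        if cursor < locus.end:
            pieces.append((cursor, locus.end, False))
        for ps, pe, is_te in pieces:
            if is_te:
                score = 0.0 if rng.random() < 0.7 else round(rng.uniform(0.0, 0.1), 3)
            else:
                score = round(max(0.0, rng.normal(base, 0.05)), 3)
            runs.append((GenomicInterval(locus.chrom, ps, pe), score))
    # merged TE spans outside any locus
    for c in chroms:
        merged = merge_intervals(te_by_chrom[c])
        loci = loci_by_chrom[c]
        for s, e in merged:
            # clip out locus overlaps
            cursor = s
            for ls, le in loci:
                if le <= cursor:
                    continue
                if ls >= e:
                    break
                if ls > cursor:
                    score = 0.0 if rng.random() < 0.7 else round(
                        rng.uniform(0.0, 0.1), 3)
                    runs.append((GenomicInterval(c, cursor, ls), score))
                cursor = max(cursor, le)
            if cursor < e:
                score = 0.0 if rng.random() < 0.7 else round(rng.uniform(0.0, 0.1), 3)
                runs.append((GenomicInterval(c, cursor, e), score))
    conservation = ConservationTrack(runs)

    # ---- 10. ground truth and dataset ---------------------------------------
    n_cands = sum(1 for s in specs if s["kind"] != "coding")
    n_f1 = cfg.n_fail_class + cfg.n_fail_length
    truth = GroundTruth(
        te_lncrna_ids=sorted(te_lnc_ids),
        non_te_lncrna_ids=sorted(non_te_ids),
        coverage=coverage_truth,
        tss_flagged_ids=sorted(tss_hosts),
        te_promoter_ids=sorted(tss_hosts),
        hotspot_bins=hotspot_bins,
        hotspot_bin_size=cfg.hotspot_bin_size,
        tfbs_te_derived_ids=sorted(tfbs_te_ids),
        tfbs_non_derived_ids=sorted(tfbs_out_ids),
        atac_counts=atac_counts,
        m6a_counts=m6a_counts,
        tau_specific_ids=sorted(spec_ids),
        tau_uniform_ids=sorted(tau_uniform),
        orf_cassettes=cassettes,
        planted_context=planted_context,
        expected_filter_report=(
            n_cands,
            n_cands - n_f1,
            n_cands - n_f1 - cfg.n_fail_coding,
            cfg.n_lncrna,
        ),
    )
    return SimulatedDataset(
        config=cfg,
        chrom_sizes=dict(cfg.chrom_lengths),
        genome=genome,
        transcripts=models,
        tes=te_list,
        atac=FeatureTrack("atac_peak", atac_features, atac_labels),
        tfbs=FeatureTrack("tfbs", tfbs_features, tfbs_labels),
        m6a=FeatureTrack("m6a_peak", m6a_features, m6a_labels),
        expression=matrix,
        calls=calls,
        conservation=conservation,
        truth=truth,
        simple_repeats=simple_repeats,
    )


def plant_filter_failures(
    n_clean: int = 10,
    n_fail_class: int = 5,
    n_fail_length: int = 5,
    n_fail_coding: int = 5,
    n_fail_expression: int = 5,
    seed: int = 0,
) -> tuple[list[Candidate], ExpressionMatrix, tuple[int, int, int, int]]:
    """Candidate annotations failing exactly one named cascade rule each.

    Returns (candidates, expression matrix, expected FilterReport counts).
    Clean candidates pass every stage; each failure candidate violates only
    its designated rule (class code '=', mature length 150, a coding call /
    protein hit, or an all-zero expression row).
    """
    rng = np.random.default_rng(seed)
    cands: list[Candidate] = []
    samples = [f"s{i}" for i in range(3)]
    expr_rows: dict[str, list[float]] = {}

    def add(tid, class_code, length, cpc, cnci, hit, expressed):
        cands.append(
            Candidate(
                transcript_id=tid, class_code=class_code, length=length,
                exon_count=int(rng.integers(1, 4)), cpc_call=cpc, cnci_call=cnci,
                protein_hit=hit,
            )
        )
        expr_rows[tid] = (
            [round(float(rng.gamma(2.0, 5.0)), 4) for _ in samples]
            if expressed
            else [0.0, 0.0, 0.0]
        )

    for i in range(n_clean):
        add(f"clean_{i:03d}", str(rng.choice(list("uxijo"))),
            int(rng.integers(300, 3000)), "noncoding", "noncoding", False, True)
    for i in range(n_fail_class):
        add(f"fclass_{i:03d}", "=", int(rng.integers(300, 3000)),
            "noncoding", "noncoding", False, True)
    for i in range(n_fail_length):
        add(f"flen_{i:03d}", str(rng.choice(list("uxijo"))), 150,
            "noncoding", "noncoding", False, True)
    for i in range(n_fail_coding):
        mode = i % 3
        add(f"fcode_{i:03d}", str(rng.choice(list("uxijo"))),
            int(rng.integers(300, 3000)),
            "coding" if mode == 0 else "noncoding",
            "coding" if mode == 1 else "noncoding",
            mode == 2, True)
    for i in range(n_fail_expression):
        add(f"fexpr_{i:03d}", str(rng.choice(list("uxijo"))),
            int(rng.integers(300, 3000)), "noncoding", "noncoding", False, False)
    matrix = ExpressionMatrix(
        pd.DataFrame.from_dict(expr_rows, orient="index", columns=samples)
    )
    total = len(cands)
    expected = (
        total,
        total - n_fail_class - n_fail_length,
        total - n_fail_class - n_fail_length - n_fail_coding,
        n_clean,
    )
    return cands, matrix, expected
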