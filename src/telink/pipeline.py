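"""End-to-end orchestration: identify -> characterize -> context -> integrate -> orfs.

``run_all`` reads the input files named in a :class:`RunConfig`, executes
every analysis stage, writes per-stage TSV/BED outputs plus a flat
machine-readable report (``report.tsv``) and a human summary
(``summary.txt``), and returns the report as a dict.  Every threshold in
the configuration is recorded once in the report header, so a report is a
pure function of inputs + flags and re-running with the same inputs is
byte-identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import pandas as pd

from . import genomic_io as gio
from . import genomic_context as ctx
from . import lncrna_identification as ident
from . import orf_discovery as orf
from . import regulatory_integration as reg
from . import te_overlap as ovl

__all__ = ["RunConfig", "PipelineError", "run_all"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Input paths and every tunable threshold of the pipeline."""

    gtf: str
    te_out: str
    calls: str
    expression: str
    outdir: str
    chrom_sizes: str | None = None
    atac: str | None = None
    tfbs: str | None = None
    m6a: str | None = None
    genome_fasta: str | None = None
    conservation: str | None = None
    seed: int = 0
    # thresholds (all recorded in the report header)
    length_mode: str = "mature"
    promoter_upstream: int = -2000
    promoter_downstream: int = 200
    downstream_window: int = 1000
    tss_half_window: int = 50
    hotspot_bin_size: int = 100_000
    hotspot_z_threshold: float = 3.0
    attribution_min_fraction: float = 0.5
    orf_min_codons: int = 10
    correlation_method: str = "rank"
    group_test: str = "mannwhitney"
    tau_log_transform: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def thresholds(self) -> dict:
        skip = {
            "gtf", "te_out", "calls", "expression", "outdir", "chrom_sizes",
            "atac", "tfbs", "m6a", "genome_fasta", "conservation",
        }
        return {k: v for k, v in asdict(self).items() if k not in skip}


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the flat report dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, object] = {}
    promoter = (config.promoter_upstream, config.promoter_downstream)

    # ---- stage: identify ---------------------------------------------------
    try:
        transcripts = gio.read_transcripts(config.gtf)
        coding = [t for t in transcripts if t.biotype == "coding"]
        candidates_m = [t for t in transcripts if t.biotype != "coding"]
        calls = ident.read_calls(config.calls)
        matrix = gio.read_expression(config.expression)
        candidates = ident.candidates_from_models(
            candidates_m, calls, length_mode=config.length_mode
        )
        lnc_cands, filt = ident.run_identification(candidates, matrix)
        lncrnas = [c.model for c in lnc_cands if c.model is not None]
        filt.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
        gio.write_transcripts(lncrnas, out / "lncrna.gtf")
        for stage, n in zip(filt.stage_names, filt.counts):
            report[f"filter_{stage}"] = n
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError("identify", exc) from exc

    # ---- stage: characterize ----------------------------------------------
    try:
        tes = gio.read_repeatmasker(config.te_out)
        stats = ovl.classify_te_lncrnas(lncrnas, tes)
        stats_by_id = {s.transcript_id: s for s in stats}
        n_te = sum(1 for s in stats if s.is_te_lncrna)
        report["n_lncrnas"] = len(stats)
        report["n_te_lncrnas"] = n_te
        report["n_non_te_lncrnas"] = len(stats) - n_te
        if stats:
            report["te_lncrna_percent"] = ovl.proportion_report(n_te, len(stats))
            report["non_te_lncrna_percent"] = ovl.proportion_report(
                len(stats) - n_te, len(stats)
            )
        mult = ovl.multiplicity_summary(stats)
        report["te_incidences_in_lncrnas"] = mult.total_incidences
        report["mean_tes_per_te_lncrna"] = (
            round(mult.mean_tes, 1) if mult.mean_tes is not None else "NA"
        )
        report["fraction_te_lncrnas_multi_te"] = (
            round(mult.fraction_multi, 4) if mult.fraction_multi is not None else "NA"
        )
        bins = ovl.coverage_rate_bins(stats)
        report["coverage_rate_bins_0_25_50_75_100"] = ",".join(map(str, bins))
        comp_genome = ovl.family_composition(tes, "genome")
        comp_lnc = ovl.family_composition(
            tes, "lncRNA", [m.locus for m in lncrnas]
        )
        cds = [e for t in coding for e in t.exons]
        comp_cds = ovl.family_composition(tes, "CDS", cds)
        rows = []
        for comp in (comp_genome, comp_lnc, comp_cds):
            for fam, n in sorted(comp.counts.items()):
                rows.append((comp.region_class, fam, n,
                             round(comp.proportions[fam] * 100, 2)))
        pd.DataFrame(
            rows, columns=["region_class", "family", "count", "percent"]
        ).to_csv(out / "family_composition.tsv", sep="\t", index=False)
        if comp_lnc.total and comp_genome.total:
            top_fam = max(comp_lnc.counts, key=comp_lnc.counts.get)
            report["top_lncrna_family"] = top_fam
            report["top_lncrna_family_percent"] = ovl.proportion_report(
                comp_lnc.counts[top_fam], comp_lnc.total
            )
        n_genomic = len(tes)
        if n_genomic and mult.total_incidences:
            in_cds = comp_cds.total
            fisher = ovl.fisher_exact(
                mult.total_incidences, n_genomic - mult.total_incidences,
                in_cds, n_genomic - in_cds,
            )
            report["lncrna_vs_cds_fisher_p"] = fisher.p_value
            report["lncrna_vs_cds_odds_ratio"] = (
                round(fisher.odds_ratio, 4)
                if fisher.odds_ratio == fisher.odds_ratio else "NA"
            )
        with open(out / "stats.tsv", "w") as fh:
            fh.write(
                "transcript_id\tis_te_lncrna\tte_count\tcovered_bp\t"
                "coverage_rate\ttop_family\n"
            )
            for s in stats:
                top = (
                    s.families.most_common(1)[0][0] if s.families else "NA"
                )
                fh.write(
                    f"{s.transcript_id}\t{int(s.is_te_lncrna)}\t{s.te_count}\t"
                    f"{s.covered_bp}\t{s.coverage_rate:.6f}\t{top}\n"
                )
    except Exception as exc:
        raise PipelineError("characterize", exc) from exc

    # ---- stage: context ----------------------------------------------------
    try:
        annos = ctx.annotate_context_all(
            tes, transcripts, promoter=promoter,
            downstream=config.downstream_window,
        )
        label_counts = ctx.context_label_counts(annos)
        for label, n in label_counts.items():
            report[f"context_{label}"] = n
        with open(out / "context.tsv", "w") as fh:
            fh.write("te_id\tlabel\tnearest_transcript\tdistance_to_tss\n")
            for a in annos:
                fh.write(
                    f"{a.te_id}\t{a.label}\t{a.nearest_transcript_id or 'NA'}\t"
                    f"{a.distance_to_tss if a.distance_to_tss is not None else 'NA'}\n"
                )
        flags = ctx.tss_contribution(lncrnas, stats, config.tss_half_window)
        report["n_tss_te_lncrnas"] = sum(flags.values())
        if config.chrom_sizes:
            sizes = gio.read_chrom_sizes(config.chrom_sizes)
            hotspots = ctx.detect_hotspots(
                tes, sizes, config.hotspot_bin_size, config.hotspot_z_threshold
            )
            n_hot = 0
            with open(out / "hotspots.bed", "w") as fh:
                for chrom in sorted(hotspots):
                    res = hotspots[chrom]
                    for b in res.hotspot_bins:
                        iv = res.bin_interval(b, sizes[chrom])
                        fh.write(
                            f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                            f"hotspot_z={res.z_scores[b]:.2f}\n"
                        )
                        n_hot += 1
            report["n_hotspot_bins"] = n_hot
        if config.conservation:
            track = gio.read_conservation(config.conservation)
            classes = {
                "coding": [t.locus for t in coding],
                "Non-TE-lncRNA": [
                    m.locus for m in lncrnas
                    if not stats_by_id[m.transcript_id].is_te_lncrna
                ],
                "TE-lncRNA": [
                    m.locus for m in lncrnas
                    if stats_by_id[m.transcript_id].is_te_lncrna
                ],
                "TE": [te.interval for te in tes],
            }
            cons = ctx.summarize_conservation(classes, track)
            for cls, summ in cons.items():
                key = cls.replace("-", "_").lower()
                report[f"conservation_mean_{key}"] = round(summ.mean_score, 4)
                report[f"conservation_zero_frac_{key}"] = round(
                    summ.fraction_zero, 4
                )
    except Exception as exc:
        raise PipelineError("context", exc) from exc

    # ---- stage: integrate --------------------------------------------------
    try:
        spans = ovl.te_spans_by_transcript(stats, lncrnas)
        fams = {
            s.transcript_id: sorted(s.families) for s in stats
        }
        group = {
            s.transcript_id: "TE-lncRNA" if s.is_te_lncrna else "Non-TE-lncRNA"
            for s in stats
        }
        count_tables = {}
        if config.atac:
            atac = gio.read_features(config.atac, "atac_peak")
            counts = reg.count_features_per_lncrna(lncrnas, atac)
            count_tables["atac"] = counts
            report["atac_peaks_in_lncrnas"] = sum(counts.values())
            report["atac_peaks_in_te_lncrnas"] = sum(
                c for t, c in counts.items() if group[t] == "TE-lncRNA"
            )
            report["atac_peaks_in_non_te_lncrnas"] = sum(
                c for t, c in counts.items() if group[t] == "Non-TE-lncRNA"
            )
            if len(set(group.values())) == 2:
                gt = reg.compare_groups(counts, group, test=config.group_test)
                report["atac_group_test_p"] = (
                    gt.p_value if gt.p_value is not None else "NA"
                )
            rates = [stats_by_id[m.transcript_id].coverage_rate for m in lncrnas]
            cvals = [counts[m.transcript_id] for m in lncrnas]
            if len(rates) >= 3:
                cor = reg.correlate(
                    rates, cvals, method=config.correlation_method,
                    pair=("coverage_rate", "atac_peaks"),
                )
                report["coverage_atac_correlation"] = (
                    round(cor.coefficient, 4)
                    if cor.coefficient is not None else "NA"
                )
                report["coverage_atac_correlation_p"] = (
                    cor.p_value if cor.p_value is not None else "NA"
                )
        if config.tfbs:
            tfbs = gio.read_features(config.tfbs, "tfbs")
            count_tables["tfbs"] = reg.count_features_per_lncrna(lncrnas, tfbs)
            attr, _excl = reg.attribute_te_features(
                spans, lncrnas, tfbs,
                min_fraction=config.attribution_min_fraction,
                families_by_span=fams,
            )
            n_derived = sum(1 for a in attr if a.te_derived)
            report["n_te_derived_tfbs"] = n_derived
            report["n_te_tfbs_lncrnas"] = len(
                {a.host_transcript_id for a in attr if a.te_derived}
            )
            with open(out / "attribution.tsv", "w") as fh:
                fh.write(
                    f"# attribution_min_fraction={config.attribution_min_fraction}\n"
                    "feature_id\tkind\thost\tte_derived\toverlap_fraction\t"
                    "families\n"
                )
                for a in attr:
                    fh.write(
                        f"{a.feature_id}\t{a.feature_kind}\t{a.host_transcript_id}"
                        f"\t{int(a.te_derived)}\t{a.overlap_fraction:.4f}\t"
                        f"{','.join(a.contributing_families) or 'NA'}\n"
                    )
            means, _dens, dtest = reg.promoter_tfbs_density(
                lncrnas, stats_by_id, tfbs, promoter=promoter
            )
            for cls, v in means.items():
                key = cls.replace("-", "_").lower()
                report[f"promoter_tfbs_density_{key}"] = (
                    round(v, 4) if v == v else "NA"
                )
            report["promoter_tfbs_density_p"] = (
                dtest.p_value if dtest is not None else "NA"
            )
        if config.m6a:
            m6a = gio.read_features(config.m6a, "m6a_peak")
            m6a_counts, mtest = reg.m6a_abundance_compare(
                lncrnas, stats_by_id, m6a, test=config.group_test
            )
            count_tables["m6a"] = m6a_counts
            report["m6a_sites_in_lncrnas"] = sum(m6a_counts.values())
            report["m6a_group_test_p"] = (
                mtest.p_value if mtest is not None and mtest.p_value is not None
                else "NA"
            )
        if "atac" in count_tables and "tfbs" in count_tables:
            a = [count_tables["atac"][m.transcript_id] for m in lncrnas]
            b = [count_tables["tfbs"][m.transcript_id] for m in lncrnas]
            if len(a) >= 3:
                cor = reg.correlate(
                    a, b, method=config.correlation_method,
                    pair=("atac_peaks", "tfbs"),
                )
                report["atac_tfbs_correlation"] = (
                    round(cor.coefficient, 4)
                    if cor.coefficient is not None else "NA"
                )
        if count_tables:
            df = pd.DataFrame(
                {k: pd.Series(v) for k, v in count_tables.items()}
            ).fillna(0).astype(int)
            df.to_csv(out / "counts.tsv", sep="\t", index_label="transcript_id")
        taus = reg.tau(matrix, log_transform=config.tau_log_transform)
        lnc_taus = [taus[m.transcript_id].tau for m in lncrnas
                    if m.transcript_id in taus]
        if lnc_taus:
            s = pd.Series(lnc_taus)
            report["tau_lncrna_median"] = round(float(s.median()), 4)
            report["tau_lncrna_mean"] = round(float(s.mean()), 4)
        with open(out / "tau.tsv", "w") as fh:
            fh.write("feature_id\ttau\targmax_sample\n")
            for fid in sorted(taus):
                t = taus[fid]
                fh.write(f"{fid}\t{t.tau:.6f}\t{t.argmax_sample}\n")
    except Exception as exc:
        raise PipelineError("integrate", exc) from exc

    # ---- stage: orfs -------------------------------------------------------
    try:
        if config.genome_fasta:
            from pyfaidx import Fasta

            genome = Fasta(str(config.genome_fasta))
            orf_counts: dict[str, int] = {}
            all_orfs: list[orf.OpenReadingFrame] = []
            for m in lncrnas:
                orfs = orf.find_orfs_spliced(
                    m, genome, min_codons=config.orf_min_codons
                )
                orf.classify_te_orfs(
                    orfs, spans, min_fraction=config.attribution_min_fraction
                )
                orf_counts[m.transcript_id] = len(orfs)
                all_orfs.extend(orfs)
            report["n_candidate_orfs"] = len(all_orfs)
            report["n_te_derived_orfs"] = sum(
                1 for o in all_orfs if o.te_derived
            )
            report["n_te_orf_lncrnas"] = len(
                {o.transcript_id for o in all_orfs if o.te_derived}
            )
            means, ptest = orf.orf_prevalence_compare(orf_counts, group)
            for cls, v in means.items():
                key = cls.replace("-", "_").lower()
                report[f"orfs_per_lncrna_{key}"] = round(v, 4)
            report["orf_prevalence_p"] = (
                ptest.p_value
                if ptest is not None and ptest.p_value is not None
                else "NA"
            )
            with open(out / "orfs.tsv", "w") as fh:
                fh.write(
                    f"# orf_min_codons={config.orf_min_codons}\n"
                    "transcript_id\tstart\tend\tframe\tte_derived\tpeptide\n"
                )
                for o in all_orfs:
                    fh.write(
                        f"{o.transcript_id}\t{o.start}\t{o.end}\t{o.frame}\t"
                        f"{int(bool(o.te_derived))}\t{o.peptide}\n"
                    )
    except Exception as exc:
        raise PipelineError("orfs", exc) from exc

    # ---- report ------------------------------------------------------------
    with open(out / "report.tsv", "w") as fh:
        for k, v in sorted(config.thresholds().items()):
            fh.write(f"# {k}\t{_fmt(v)}\n")
        fh.write("quantity\tvalue\n")
        for k, v in report.items():
            fh.write(f"{k}\t{_fmt(v)}\n")
    with open(out / "summary.txt", "w") as fh:
        fh.write("TE-lncRNA analysis summary\n")
        fh.write("==========================\n\n")
        fh.write("Thresholds: " + ", ".join(
            f"{k}={_fmt(v)}" for k, v in sorted(config.thresholds().items())
        ) + "\n\n")
        for k, v in report.items():
            fh.write(f"{k:40s} {_fmt(v)}\n")
    return report
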