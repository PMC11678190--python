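"""Feature counting, TE attribution, promoter densities, correlation, tau."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from telink.genomic_io import ExpressionMatrix, FeatureTrack, GenomicInterval
from telink.regulatory_integration import (
    attribute_te_features,
    compare_groups,
    correlate,
    count_features_per_lncrna,
    m6a_abundance_compare,
    promoter_tfbs_density,
    tau,
)
from telink.te_overlap import classify_te_lncrnas, te_spans_by_transcript
from conftest import make_te, make_transcript


def track_of(kind, spans, chrom="chr2L"):
    return FeatureTrack(
        kind, [GenomicInterval(chrom, s, e) for s, e in spans],
        [f"f{i}" for i in range(len(spans))],
    )


def per_base_fraction(feature, spans):
    """Brute-force overlap fraction of a feature interval with TE spans."""
    mask = np.zeros(feature[1] - feature[0], dtype=bool)
    for s, e in spans:
        lo, hi = max(s, feature[0]), min(e, feature[1])
        if lo < hi:
            mask[lo - feature[0] : hi - feature[0]] = True
    return mask.mean()


class TestCounting:
    def test_enclosed_peaks_counted(self):
        m = make_transcript(exons=((0, 10_000),))
        track = track_of("atac_peak", [(100, 300), (400, 600), (900, 1200)])
        assert count_features_per_lncrna([m], track)["t1"] == 3

    def test_feature_counts_for_every_overlapping_locus(self):
        a = make_transcript("a", exons=((0, 1000),))
        b = make_transcript("b", exons=((900, 2000),))
        track = track_of("atac_peak", [(950, 980)])
        counts = count_features_per_lncrna([a, b], track)
        assert counts == {"a": 1, "b": 1}

    def test_identical_distributions_give_p_one(self):
        values = {f"x{i}": v for i, v in enumerate([1, 2, 3, 1, 2, 3])}
        labels = {f"x{i}": ("A" if i < 3 else "B") for i in range(6)}
        res = compare_groups(values, labels)
        assert res.p_value == pytest.approx(1.0)

    def test_tiny_group_reports_no_test(self):
        res = compare_groups([1, 2, 3], ["A", "B", "B"])
        assert res.p_value is None and res.group_sizes == {"A": 1, "B": 2}

    def test_planted_group_difference_detected(self, rng):
        te = rng.poisson(4.0, 500)
        non = rng.poisson(2.0, 500)
        res = compare_groups(
            np.concatenate([te, non]), ["TE"] * 500 + ["Non"] * 500
        )
        assert res.p_value < 1e-6
        assert res.group_medians["TE"] > res.group_medians["Non"]


class TestAttribution:
    def _setup(self, te_spans_rel, feature_rel, locus=(0, 10_000)):
        m = make_transcript(exons=(locus,))
        tes = [make_te(start=s, end=e, te_id=f"te{i}")
               for i, (s, e) in enumerate(te_spans_rel)]
        stats = classify_te_lncrnas([m], tes)
        spans = te_spans_by_transcript(stats, [m])
        track = track_of("tfbs", [feature_rel])
        return spans, [m], track

    def test_feature_inside_te_fully_derived(self):
        spans, lnc, track = self._setup([(100, 500)], (200, 300))
        results, _ = attribute_te_features(spans, lnc, track)
        assert results[0].te_derived and results[0].overlap_fraction == 1.0

    def test_forty_percent_not_derived_at_half_threshold(self):
        spans, lnc, track = self._setup([(200, 240)], (200, 300))
        results, _ = attribute_te_features(spans, lnc, track, min_fraction=0.5)
        assert not results[0].te_derived
        assert results[0].overlap_fraction == pytest.approx(0.4)

    def test_abutting_tes_union_counts_once(self):
        # two abutting TEs jointly cover 60% of an m6A peak
        spans, lnc, track = self._setup([(100, 130), (130, 160)], (100, 200))
        track.kind = "m6a_peak"
        results, _ = attribute_te_features(spans, lnc, track)
        assert results[0].overlap_fraction == pytest.approx(0.6)
        assert results[0].te_derived

    def test_outside_every_lncrna_excluded(self):
        spans, lnc, _ = self._setup([(100, 500)], (200, 300))
        track = track_of("tfbs", [(50_000, 50_100)])
        results, excluded = attribute_te_features(spans, lnc, track)
        assert results == [] and excluded == [("f0", "outside_all_lncrnas")]

    def test_monotone_in_threshold(self, rng):
        for _ in range(30):
            n_te = int(rng.integers(1, 5))
            te_spans = []
            for _ in range(n_te):
                s = int(rng.integers(0, 9000))
                te_spans.append((s, s + int(rng.integers(50, 800))))
            fs = int(rng.integers(0, 9500))
            feat = (fs, fs + int(rng.integers(20, 500)))
            spans, lnc, track = self._setup(te_spans, feat)
            flags = []
            for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
                res, _ = attribute_te_features(spans, lnc, track,
                                               min_fraction=thr)
                flags.append(res[0].te_derived)
            assert flags == sorted(flags, reverse=True)
            # and the fraction matches the per-base oracle
            assert res[0].overlap_fraction == pytest.approx(
                per_base_fraction(feat, [(max(0, s), min(e, 10_000))
                                         for s, e in te_spans])
            )

    def test_planted_flags_perfect_precision_recall(self, sim, sim_stats):
        lnc, stats, _ = sim_stats
        spans = te_spans_by_transcript(stats, lnc)
        results, _ = attribute_te_features(spans, lnc, sim.tfbs,
                                           min_fraction=0.5)
        predicted = {r.feature_id for r in results if r.te_derived}
        planted = set(sim.truth.tfbs_te_derived_ids)
        assert predicted == planted  # precision = recall = 1.0
        negatives = {r.feature_id for r in results if not r.te_derived}
        assert set(sim.truth.tfbs_non_derived_ids) <= negatives


class TestPromoterDensity:
    def test_eleven_hits_in_2200bp_is_five_per_kb(self):
        m = make_transcript(exons=((10_000, 12_000),))
        hits = [(8_100 + 150 * i, 8_110 + 150 * i) for i in range(11)]
        track = track_of("tfbs", hits)
        means, dens, _ = promoter_tfbs_density([m], {}, track)
        assert dens["Non-TE-lncRNA"] == [pytest.approx(5.0)]

    def test_no_tfbs_anywhere_no_test(self):
        m = make_transcript(exons=((10_000, 12_000),))
        means, _, test = promoter_tfbs_density([m], {}, track_of("tfbs", []))
        assert test is None and means["Non-TE-lncRNA"] == 0.0

    def test_planted_te_promoter_group_has_highest_density(self, sim, sim_stats):
        lnc, _, by_id = sim_stats
        means, dens, test = promoter_tfbs_density(lnc, by_id, sim.tfbs)
        assert means["TE-pro-lncRNA"] > means["Non-TE-pro-lncRNA"]
        assert means["TE-pro-lncRNA"] > means["Non-TE-lncRNA"]
        assert test is not None and test.p_value < 0.01


class TestCorrelate:
    def test_perfect_monotone(self):
        x = list(range(10))
        res = correlate(x, [2 * v for v in x])
        assert res.coefficient == pytest.approx(1.0)

    def test_independent_uniforms_near_zero(self, rng):
        res = correlate(rng.uniform(size=1000), rng.uniform(size=1000))
        assert abs(res.coefficient) < 0.1

    def test_constant_vector_undefined(self):
        res = correlate([1.0, 1.0, 1.0], [1, 2, 3])
        assert res.coefficient is None and res.p_value is None

    def test_poisson_coupling_recovered(self, rng):
        cov = rng.uniform(0, 1, 1000)
        peaks = rng.poisson(1 + 6 * cov)
        res = correlate(cov, peaks)
        assert res.coefficient > 0.3 and res.p_value < 1e-6

    def test_planted_atac_coupling(self, sim, sim_stats):
        lnc, _, by_id = sim_stats
        counts = count_features_per_lncrna(lnc, sim.atac)
        assert all(
            counts[t] == sim.truth.atac_counts[t] for t in counts
        )  # generator bookkeeping is exact
        res = correlate(
            [by_id[m.transcript_id].coverage_rate for m in lnc],
            [counts[m.transcript_id] for m in lnc],
        )
        assert res.coefficient > 0.3 and res.p_value < 1e-6


class TestTau:
    def _m(self, rows):
        return ExpressionMatrix(
            pd.DataFrame.from_dict(
                rows, orient="index",
                columns=[f"s{i}" for i in range(len(next(iter(rows.values()))))],
            )
        )

    def test_uniform_row_is_zero(self):
        out = tau(self._m({"a": [5, 5, 5]}))
        assert out["a"].tau == pytest.approx(0.0)

    def test_single_sample_expression_is_one(self):
        out = tau(self._m({"a": [10, 0, 0]}))
        assert out["a"].tau == pytest.approx(1.0)
        assert out["a"].argmax_sample == "s0"

    def test_worked_example_without_log(self):
        out = tau(self._m({"a": [1, 0.5, 0]}), log_transform=False)
        assert out["a"].tau == pytest.approx(0.75)

    def test_all_zero_rows_skipped_single_sample_errors(self):
        out = tau(self._m({"a": [0, 0, 0], "b": [1, 1, 1]}))
        assert "a" not in out and "b" in out
        with pytest.raises(ValueError):
            tau(self._m({"a": [1.0]}))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        arrays(
            float, (10, 6),
            elements=st.floats(0, 1e4, allow_nan=False),
        )
    )
    def test_bounded_on_random_matrices(self, vals):
        df = pd.DataFrame(
            vals, index=[f"f{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(6)],
        )
        for res in tau(ExpressionMatrix(df)).values():
            assert -1e-12 <= res.tau <= 1 + 1e-12

    def test_scale_invariance_without_log(self, rng):
        row = rng.gamma(2.0, 5.0, 8)
        a = tau(self._m({"r": list(row)}), log_transform=False)["r"].tau
        b = tau(self._m({"r": list(row * 37.5)}), log_transform=False)["r"].tau
        assert a == pytest.approx(b)

    def test_ten_thousand_random_rows_in_range(self, rng):
        vals = rng.gamma(1.5, 8.0, size=(10_000, 15))
        df = pd.DataFrame(vals, index=[f"f{i}" for i in range(10_000)],
                          columns=[f"s{i}" for i in range(15)])
        taus = np.array([r.tau for r in tau(ExpressionMatrix(df)).values()])
        assert ((taus >= 0) & (taus <= 1)).all()

    def test_planted_specific_features_rank_above_uniform(self, sim):
        out = tau(sim.expression)
        spec = [out[t].tau for t in sim.truth.tau_specific_ids]
        unif = [out[t].tau for t in sim.truth.tau_uniform_ids if t in out]
        assert min(spec) > max(unif)  # AUROC = 1.0


class TestM6A:
    def _lnc_pair(self, rng, n=500):
        lnc, tes = [], []
        for i in range(n):
            start = 20_000 * i
            lnc.append(make_transcript(f"te{i}", exons=((start, start + 5000),)))
            tes.append(make_te(start=start + 100, end=start + 600,
                               te_id=f"t{i}"))
        for i in range(n):
            start = 20_000 * (n + i)
            lnc.append(make_transcript(f"nt{i}", exons=((start, start + 5000),)))
        return lnc, tes

    def test_same_poisson_null_not_significant(self, rng):
        lnc, tes = self._lnc_pair(rng)
        spans = []
        for m in lnc:
            k = rng.poisson(1.0)
            for _ in range(k):
                s = m.locus.start + int(rng.integers(0, 4800))
                spans.append((s, s + 100))
        track = track_of("m6a_peak", spans)
        stats = classify_te_lncrnas(lnc, tes)
        by_id = {s.transcript_id: s for s in stats}
        _, res = m6a_abundance_compare(lnc, by_id, track)
        assert res.p_value > 0.05

    def test_zero_vs_poisson3_significant(self, rng):
        lnc, tes = self._lnc_pair(rng)
        spans = []
        for m in lnc:
            if m.transcript_id.startswith("te"):
                for _ in range(int(rng.poisson(3.0))):
                    s = m.locus.start + int(rng.integers(0, 4800))
                    spans.append((s, s + 100))
        track = track_of("m6a_peak", spans)
        stats = classify_te_lncrnas(lnc, tes)
        by_id = {s.transcript_id: s for s in stats}
        _, res = m6a_abundance_compare(lnc, by_id, track)
        assert res.p_value < 1e-6

    def test_empty_track_no_test(self):
        m = make_transcript(exons=((0, 1000),))
        stats = classify_te_lncrnas([m], [])
        counts, res = m6a_abundance_compare(
            [m], {s.transcript_id: s for s in stats}, track_of("m6a_peak", [])
        )
        assert counts == {"t1": 0} and res is None

    def test_planted_null_in_simulation(self, sim, sim_stats):
        lnc, _, by_id = sim_stats
        _, res = m6a_abundance_compare(lnc, by_id, sim.m6a)
        assert res is not None and res.p_value > 0.05
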