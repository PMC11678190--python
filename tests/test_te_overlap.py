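"""Overlap statistics: union coverage, classification, proportions, Fisher."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telink.te_overlap import (
    TELncRNAStats,
    classify_te_lncrnas,
    coverage_rate_bins,
    family_composition,
    fisher_exact,
    multiplicity_summary,
    proportion_report,
    union_coverage,
)
from conftest import make_te, make_transcript


# ---------------------------------------------------------------------------
# independent oracles


def per_base_union(intervals, span=None) -> int:
    """Boolean-array union coverage; the brute-force reference."""
    if not intervals:
        return 0
    lo = min(s for s, _ in intervals)
    hi = max(e for _, e in intervals)
    mask = np.zeros(hi - lo, dtype=bool)
    for s, e in intervals:
        mask[s - lo : e - lo] = True
    return int(mask.sum())


def fisher_two_sided_exact(a, b, c, d) -> Fraction:
    """Two-sided Fisher p by full enumeration of fixed-margin tables.

    Sums the point probabilities of every table with the observed margins
    whose probability does not exceed the observed table's (exact rational
    arithmetic; independent of any library routine).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x) -> Fraction:
        return Fraction(
            math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1)
        )

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs or abs(px - p_obs) < Fraction(1, 10**12):
            total += px
    return total


# ---------------------------------------------------------------------------


class TestUnionCoverage:
    def test_overlapping_pair(self):
        assert union_coverage([(0, 10), (5, 15)]) == 15

    def test_empty(self):
        assert union_coverage([]) == 0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 5000), st.integers(1, 400)),
            max_size=200,
        )
    )
    def test_matches_per_base_oracle(self, raw):
        intervals = [(s, s + l) for s, l in raw]
        assert union_coverage(intervals) == per_base_union(intervals)

    def test_200_random_intervals(self, rng):
        for _ in range(25):
            ivs = [
                (int(s), int(s) + int(l))
                for s, l in zip(
                    rng.integers(0, 10_000, 200), rng.integers(1, 500, 200)
                )
            ]
            assert union_coverage(ivs) == per_base_union(ivs)


class TestClassification:
    def test_single_te(self):
        m = make_transcript(exons=((0, 1000),))
        (s,) = classify_te_lncrnas([m], [make_te(start=500, end=600)])
        assert s.is_te_lncrna and s.te_count == 1
        assert s.covered_bp == 100 and s.coverage_rate == pytest.approx(0.1)

    def test_no_overlap_is_non_te(self):
        m = make_transcript(exons=((0, 1000),))
        (s,) = classify_te_lncrnas([m], [make_te(start=5000, end=6000)])
        assert not s.is_te_lncrna and s.te_count == 0 and s.covered_bp == 0

    def test_overlapping_tes_not_double_counted(self):
        m = make_transcript(exons=((0, 100),))
        tes = [make_te(start=10, end=60, te_id="a"),
               make_te(start=40, end=90, te_id="b")]
        (s,) = classify_te_lncrnas([m], tes)
        assert s.te_count == 2
        assert s.covered_bp == per_base_union([(10, 60), (40, 90)]) == 80
        assert s.coverage_rate == pytest.approx(0.8)

    def test_partition_te_plus_non_te(self, sim_stats):
        _, stats, _ = sim_stats
        n_te = sum(s.is_te_lncrna for s in stats)
        assert n_te + sum(not s.is_te_lncrna for s in stats) == len(stats)
        for s in stats:
            assert (s.te_count >= 1) == s.is_te_lncrna
            assert 0 <= s.coverage_rate <= 1
            assert s.covered_bp <= s.locus_length

    def test_random_instances_match_per_base_oracle(self, rng):
        for _ in range(40):
            L = int(rng.integers(200, 2000))
            m = make_transcript(exons=((0, L),))
            tes, spans = [], []
            for j in range(int(rng.integers(0, 8))):
                s = int(rng.integers(-300, L))
                e = s + int(rng.integers(20, 600))
                if e <= 0 or s >= L:
                    continue
                tes.append(make_te(start=max(0, s), end=e, te_id=f"t{j}"))
                spans.append((max(0, max(0, s)), min(e, L)))
            (st_,) = classify_te_lncrnas([m], tes)
            assert st_.covered_bp == per_base_union(spans)
            assert st_.te_count == len(tes)


class TestMultiplicity:
    def test_paper_scale_mean(self):
        # 16,118 TE incidences across 2,119 TE-lncRNAs average 7.6 per lncRNA
        stats = []
        counts = [7] * (2119 - 1) + [16118 - 7 * 2118]
        for i, c in enumerate(counts):
            stats.append(TELncRNAStats(f"t{i}", True, c, 0, 0.0))
        m = multiplicity_summary(stats)
        assert m.total_incidences == 16118 and m.n_te_lncrnas == 2119
        assert round(m.mean_tes, 1) == 7.6

    def test_all_single_te(self):
        stats = [TELncRNAStats(f"t{i}", True, 1, 0, 0.0) for i in range(3)]
        assert multiplicity_summary(stats).fraction_multi == 0.0

    def test_planted_counts(self):
        stats = [
            TELncRNAStats(f"t{i}", True, c, 0, 0.0)
            for i, c in enumerate([1, 2, 3, 20])
        ]
        m = multiplicity_summary(stats)
        assert m.mean_tes == pytest.approx(6.5)
        assert m.fraction_multi == pytest.approx(0.75)
        assert m.histogram == {1: 1, 2: 1, 3: 1, 20: 1}

    def test_empty_is_not_an_error(self):
        m = multiplicity_summary(
            [TELncRNAStats("t", False, 0, 0, 0.0)]
        )
        assert m.mean_tes is None and m.histogram == {}


class TestProportions:
    @pytest.mark.parametrize(
        "k,n,expected",
        [(2119, 5246, 40.39), (16118, 39051, 41.27), (2071, 39051, 5.30),
         (6505, 16118, 40.36), (0, 10, 0.00)],
    )
    def test_printed_examples(self, k, n, expected):
        assert proportion_report(k, n) == expected

    def test_zero_n_errors(self):
        with pytest.raises(ValueError):
            proportion_report(0, 0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(1, 10**6), st.integers(0, 10**6))
    def test_complement_sums_to_100(self, n, k):
        k = k % (n + 1)
        assert proportion_report(k, n) + proportion_report(n - k, n) == (
            pytest.approx(100.0, abs=0.011)
        )


class TestFamilyComposition:
    def test_single_family(self):
        comp = family_composition([make_te(family="Gypsy")])
        assert comp.proportions == {"Gypsy": 1.0}

    def test_three_family_mixture_matches_counting(self, rng):
        fams = [str(f) for f in rng.choice(["Gypsy", "Pao", "Helitron"], 300)]
        tes = [make_te(family=f, te_id=f"te{i}") for i, f in enumerate(fams)]
        comp = family_composition(tes)
        for f in set(fams):
            assert comp.counts[f] == fams.count(f)
        assert sum(comp.proportions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_incidence_counting_in_regions(self):
        # one TE overlapping two loci contributes two incidences
        te = make_te(start=100, end=200)
        loci = [
            make_transcript("a", exons=((50, 150),)).locus,
            make_transcript("b", exons=((150, 400),)).locus,
        ]
        comp = family_composition([te], "lncRNA", loci)
        assert comp.counts["Gypsy"] == 2

    def test_empty_region(self):
        comp = family_composition([make_te()], "CDS", [])
        assert comp.total == 0 and comp.proportions == {}


class TestFisher:
    def test_symmetric_table(self):
        res = fisher_exact(10, 10, 10, 10)
        assert res.odds_ratio == 1.0 and res.p_value == pytest.approx(1.0)

    def test_diagonal_table_known_p(self):
        # 2/252 by direct enumeration over tables with margins (5,5,5,5)
        res = fisher_exact(5, 0, 0, 5)
        assert res.p_value == pytest.approx(2 / 252, rel=1e-9)
        assert res.odds_ratio == math.inf

    def test_paper_scale_direction(self):
        # lncRNA vs CDS TE incidences over the 39,051-TE universe
        res = fisher_exact(16118, 22933, 2071, 36980)
        assert res.p_value < 1e-10
        assert res.odds_ratio > 1

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            fisher_exact(0, 0, 0, 0)

    def test_matches_enumeration_for_small_margins(self, rng):
        """Exact agreement with full fixed-margin enumeration (>= 200 tables)."""
        checked = 0
        for _ in range(250):
            a, b, c, d = (int(x) for x in rng.integers(0, 21, size=4))
            if (a + b + c + d) == 0 or max(a + b, c + d, a + c, b + d) > 40:
                continue
            res = fisher_exact(a, b, c, d)
            oracle = float(fisher_two_sided_exact(a, b, c, d))
            assert res.p_value == pytest.approx(oracle, rel=1e-7, abs=1e-12)
            checked += 1
        assert checked >= 200


class TestCoverageBins:
    def _stats(self, rates):
        return [
            TELncRNAStats(f"t{i}", True, 1, 0, r) for i, r in enumerate(rates)
        ]

    def test_basic_binning(self):
        assert coverage_rate_bins(self._stats([0.1, 0.2, 0.8])) == [2, 0, 0, 1]

    def test_boundary_goes_right(self):
        assert coverage_rate_bins(self._stats([0.25])) == [0, 1, 0, 0]
        assert coverage_rate_bins(self._stats([1.0])) == [0, 0, 0, 1]

    def test_bimodal_beta_mixture_concentrates_at_edges(self, rng):
        rates = np.concatenate(
            [rng.beta(1.2, 6.0, 500), rng.beta(6.0, 1.2, 500)]
        )
        bins = coverage_rate_bins(self._stats(rates))
        assert bins[0] + bins[3] >= bins[1] + bins[2]
        assert sum(bins) == 1000
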