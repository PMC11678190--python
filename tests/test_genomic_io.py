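"""Format readers/writers: coordinate conventions, round trips, validation."""

import numpy as np
import pandas as pd
import pytest

from telink.genomic_io import (
    ExpressionMatrix,
    FeatureTrack,
    GenomicInterval,
    project_to_genome,
    read_expression,
    read_features,
    read_repeatmasker,
    read_transcripts,
    transcript_sequence,
    write_expression,
    write_features,
    write_repeatmasker,
    write_transcripts,
)
from conftest import make_te, make_transcript


class TestGenomicInterval:
    def test_rejects_inverted_and_empty(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr2L", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr2L", 20, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)

    def test_overlap_arithmetic(self):
        a = GenomicInterval("chr2L", 0, 10)
        assert a.overlap_bp(GenomicInterval("chr2L", 5, 15)) == 5
        assert a.overlap_bp(GenomicInterval("chr2L", 10, 15)) == 0
        assert a.overlap_bp(GenomicInterval("chr3L", 5, 15)) == 0


class TestGTF:
    def test_one_based_closed_converted(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chr2L\t.\texon\t101\t200\t.\t+\t.\ttranscript_id "t1"; gene_id "g1";\n'
        )
        (m,) = read_transcripts(p)
        assert (m.exons[0].start, m.exons[0].end) == (100, 200)
        assert m.class_code is None  # stored as unknown, not an error

    def test_locus_spans_exons(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chr2L\t.\texon\t101\t200\t.\t+\t.\ttranscript_id "t1";\n'
            'chr2L\t.\texon\t301\t400\t.\t+\t.\ttranscript_id "t1";\n'
        )
        (m,) = read_transcripts(p)
        assert (m.locus.start, m.locus.end) == (100, 400)
        assert len(m.exons) == 2
        assert m.mature_length == 200

    def test_roundtrip_identity(self, tmp_path, rng):
        models = []
        for i in range(50):
            start = int(rng.integers(0, 100_000))
            n_ex = int(rng.integers(1, 4))
            exons, cursor = [], start
            for _ in range(n_ex):
                ln = int(rng.integers(100, 500))
                exons.append((cursor, cursor + ln))
                cursor += ln + int(rng.integers(50, 300))
            models.append(
                make_transcript(
                    f"t{i:03d}", exons=tuple(exons),
                    strand="+" if i % 2 else "-",
                    class_code=str(rng.choice(list("uxijo"))),
                )
            )
        p = tmp_path / "rt.gtf"
        write_transcripts(models, p)
        back = read_transcripts(p)
        assert len(back) == 50
        for a, b in zip(sorted(models, key=lambda m: m.transcript_id), back):
            assert a.transcript_id == b.transcript_id
            assert a.exons == b.exons
            assert a.class_code == b.class_code

    def test_errors_carry_line_numbers(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text("chr2L\texon\t101\n")
        with pytest.raises(ValueError, match=":1"):
            read_transcripts(p)
        p.write_text('chr2L\t.\texon\t101\t200\t.\t+\t.\tgene_id "g1";\n')
        with pytest.raises(ValueError, match="transcript_id"):
            read_transcripts(p)


class TestRepeatMasker:
    HEADER = "   SW ...\nscore ...\n\n"

    def _row(self, chrom, start1, end1, strand, name, classfam, te_id="1"):
        return (
            f"  500  1.0  0.1  0.2  {chrom}  {start1} {end1} (0)  {strand}"
            f"  {name}  {classfam}  1 100 (0)  {te_id}\n"
        )

    def test_parse_class_family_and_coords(self, tmp_path):
        p = tmp_path / "te.out"
        p.write_text(self.HEADER + self._row("chr2L", 1001, 2000, "+", "gypsy1",
                                             "LTR/Gypsy"))
        (te,) = read_repeatmasker(p)
        assert (te.te_class, te.family) == ("LTR", "Gypsy")
        assert (te.interval.start, te.interval.end) == (1000, 2000)

    def test_simple_and_low_complexity_dropped(self, tmp_path):
        p = tmp_path / "te.out"
        p.write_text(
            self.HEADER
            + self._row("chr2L", 1, 50, "+", "(AT)n", "Simple_repeat")
            + self._row("chr2L", 100, 150, "+", "A-rich", "Low_complexity")
            + self._row("chr2L", 200, 900, "C", "helitron1", "RC/Helitron")
        )
        tes = read_repeatmasker(p)
        assert len(tes) == 1
        assert tes[0].te_class == "RC"
        assert tes[0].interval.strand == "-"  # C means minus
        assert not any(
            te.te_class in ("Simple_repeat", "Low_complexity") for te in tes
        )

    def test_family_defaults_to_class_without_slash(self, tmp_path):
        p = tmp_path / "te.out"
        p.write_text(self.HEADER + self._row("chr2L", 1, 50, "+", "x", "Unknown"))
        (te,) = read_repeatmasker(p)
        assert te.family == te.te_class == "Unknown"

    def test_truncated_row_errors(self, tmp_path):
        p = tmp_path / "te.out"
        p.write_text(self.HEADER + "  500  1.0  0.1  0.2  chr2L  1 100\n")
        with pytest.raises(ValueError, match="truncated"):
            read_repeatmasker(p)

    def test_roundtrip(self, tmp_path, rng):
        tes = [
            make_te(start=int(s), end=int(s) + int(l), te_id=f"te_{i}",
                    strand="-" if i % 3 == 0 else "+")
            for i, (s, l) in enumerate(
                zip(rng.integers(0, 10**6, 100), rng.integers(80, 5000, 100))
            )
        ]
        p = tmp_path / "rt.out"
        write_repeatmasker(tes, p)
        back = read_repeatmasker(p)
        assert [(t.interval, t.te_class, t.family) for t in back] == [
            (t.interval, t.te_class, t.family) for t in tes
        ]


class TestBED:
    def test_basic_and_empty(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr2L\t100\t200\tpeak1\n")
        track = read_features(p, "atac_peak")
        assert len(track) == 1 and track.labels == ["peak1"]
        p.write_text("")
        assert len(read_features(p, "atac_peak")) == 0

    def test_invalid_interval_names_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr2L\t100\t200\tok\nchr2L\t300\t300\tbad\n")
        with pytest.raises(ValueError, match=":2"):
            read_features(p, "tfbs")

    def test_roundtrip_1000_random_peaks(self, tmp_path, rng):
        starts = rng.integers(0, 10**6, 1000)
        track = FeatureTrack(
            "atac_peak",
            [GenomicInterval("chr2L", int(s), int(s) + int(l))
             for s, l in zip(starts, rng.integers(1, 900, 1000))],
            [f"p{i}" for i in range(1000)],
        )
        p = tmp_path / "rt.bed"
        write_features(track, p)
        back = read_features(p, "atac_peak")
        assert back.features == track.features
        assert back.labels == track.labels


class TestExpression:
    def test_dims_and_values(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("feature_id\ts1\ts2\nf1\t1.5\t0\nf2\t0\t2\n")
        m = read_expression(p)
        assert m.feature_ids == ["f1", "f2"] and m.sample_ids == ["s1", "s2"]
        assert m.row_sum("f1") == 1.5
        assert m.row_sum("absent") == 0.0

    def test_negative_and_ragged_rejected(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("feature_id\ts1\ts2\nf1\t-1.0\t0\n")
        with pytest.raises(ValueError, match="negative"):
            read_expression(p)
        p.write_text("feature_id\ts1\ts2\nf1\t1.0\n")
        with pytest.raises(ValueError):
            read_expression(p)

    def test_roundtrip_fixed_precision(self, tmp_path, rng):
        df = pd.DataFrame(
            np.round(rng.gamma(2.0, 5.0, size=(100, 15)), 6),
            index=[f"f{i}" for i in range(100)],
            columns=[f"s{i}" for i in range(15)],
        )
        m = ExpressionMatrix(df)
        p = tmp_path / "rt.tsv"
        write_expression(m, p)
        back = read_expression(p)
        assert (back.values.to_numpy() == m.values.to_numpy()).all()
        write_expression(back, tmp_path / "rt2.tsv")
        assert (tmp_path / "rt.tsv").read_bytes() == (tmp_path / "rt2.tsv").read_bytes()


class TestSequenceHelpers:
    def test_spliced_sequence_and_projection_plus(self):
        genome = {"chr2L": "AAACGTACGTAAATTTGGG"}
        m = make_transcript(exons=((3, 7), (12, 16)), strand="+")
        assert transcript_sequence(m, genome) == "CGTAATTT"
        blocks = project_to_genome(m, 2, 6)
        assert [(b.start, b.end) for b in blocks] == [(5, 7), (12, 14)]

    def test_minus_strand_reverse_complement(self):
        genome = {"chr2L": "AAACGTACGTAAATTTGGG"}
        m = make_transcript(exons=((3, 7), (12, 16)), strand="-")
        # reverse complement of the spliced plus-strand sequence CGTAATTT
        assert transcript_sequence(m, genome) == "AAATTACG"
        # first 3 transcript bases map to the 3'-most genomic positions
        blocks = project_to_genome(m, 0, 3)
        assert [(b.start, b.end) for b in blocks] == [(13, 16)]

    def test_readers_emit_valid_intervals_from_sim(self, sim_small, tmp_path):
        paths = sim_small.write(tmp_path / "d")
        for te in read_repeatmasker(paths["te"]):
            assert te.interval.start < te.interval.end
        for m in read_transcripts(paths["gtf"]):
            for e in m.exons:
                assert 0 <= e.start < e.end
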