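import numpy as np
import pytest

from telink.genomic_io import GenomicInterval, TEInsertion, TranscriptModel
from telink.synthetic_data import SimulationConfig, simulate


def make_transcript(
    transcript_id="t1",
    chrom="chr2L",
    exons=((100, 400),),
    strand="+",
    class_code="u",
    biotype="candidate",
):
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=f"g_{transcript_id}",
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
        class_code=class_code,
        biotype=biotype,
    )


def make_te(chrom="chr2L", start=0, end=100, family="Gypsy", te_class="LTR",
            strand="+", te_id="te"):
    return TEInsertion(
        interval=GenomicInterval(chrom, start, end, strand),
        te_class=te_class,
        family=family,
        name=family,
        te_id=te_id,
    )


@pytest.fixture(scope="session")
def sim():
    """Default-condition synthetic study (seed 1, 1000 lncRNAs)."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def sim_small():
    """A fast, reduced synthetic study for I/O and pipeline plumbing tests."""
    return simulate(
        SimulationConfig(
            seed=11,
            n_lncrna=150,
            n_coding=40,
            n_te_intergenic=900,
            n_tfbs_body=120,
            orf_cassette_count=20,
            n_fail_class=5,
            n_fail_length=5,
            n_fail_coding=5,
            n_fail_expression=5,
        )
    )


@pytest.fixture(scope="session")
def sim_stats(sim):
    """TE-lncRNA stats for the default study, computed once."""
    from telink.te_overlap import classify_te_lncrnas

    lnc = sim.lncrna_models
    stats = classify_te_lncrnas(lnc, sim.tes)
    return lnc, stats, {s.transcript_id: s for s in stats}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
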