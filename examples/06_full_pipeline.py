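"""Run the whole pipeline end to end on a written synthetic dataset.

Equivalent to `telink simulate` followed by `telink run`; prints a selection
of the report quantities.
"""

import tempfile
from pathlib import Path

from telink.pipeline import RunConfig, run_all
from telink.synthetic_data import SimulationConfig, simulate

workdir = Path(tempfile.mkdtemp())
ds = simulate(SimulationConfig(seed=1, n_lncrna=200, n_coding=40,
                               n_te_intergenic=900))
paths = ds.write(workdir / "sim")

report = run_all(RunConfig(
    gtf=str(paths["gtf"]), te_out=str(paths["te"]), calls=str(paths["calls"]),
    expression=str(paths["expression"]), outdir=str(workdir / "out"),
    chrom_sizes=str(paths["chrom_sizes"]), atac=str(paths["atac"]),
    tfbs=str(paths["tfbs"]), m6a=str(paths["m6a"]),
    genome_fasta=str(paths["genome"]),
    conservation=str(paths["conservation"]), hotspot_bin_size=50_000,
))

for key in ("filter_input", "filter_expressed", "n_te_lncrnas",
            "te_lncrna_percent", "mean_tes_per_te_lncrna",
            "coverage_atac_correlation", "n_te_derived_tfbs",
            "n_hotspot_bins", "m6a_group_test_p", "n_candidate_orfs"):
    print(f"{key:30s} {report[key]}")
print(f"\nfull report and per-stage tables written to {workdir / 'out'}")
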