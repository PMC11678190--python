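"""Genomic context of TE insertions and chromosome-end insertion hotspots.

Labels every TE (promoter > exon > intron > downstream > intergenic), flags
lncRNAs whose TSS is covered by a TE, and detects binned insertion hotspots
as z-score outliers per chromosome.
"""

from telink.genomic_context import (
    annotate_context_all,
    context_label_counts,
    detect_hotspots,
    tss_contribution,
)
from telink.synthetic_data import SimulationConfig, simulate
from telink.te_overlap import classify_te_lncrnas

ds = simulate(SimulationConfig(seed=1))
annos = annotate_context_all(ds.tes, ds.transcripts)
print("context label counts:", context_label_counts(annos))

lnc = ds.lncrna_models
stats = classify_te_lncrnas(lnc, ds.tes)
flags = tss_contribution(lnc, stats)
print(f"lncRNAs with a TE covering the TSS window: {sum(flags.values())}")

hotspots = detect_hotspots(ds.tes, ds.chrom_sizes, bin_size=50_000)
for chrom, res in sorted(hotspots.items()):
    bins = res.hotspot_bins
    print(f"{chrom}: hotspot bins {bins} "
          f"(z = {[round(float(res.z_scores[b]), 2) for b in bins]}) — "
          "terminal bins, i.e. a bias towards chromosome ends")
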