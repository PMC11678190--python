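"""Chromatin, TFBS and m6A integration plus the tau specificity index.

Counts ATAC peaks per lncRNA and tests TE- vs Non-TE-lncRNAs, correlates
TE coverage with peak counts, attributes TFBSs to TE origin, and scores
expression specificity (tau: 0 = uniform, 1 = single-condition).
"""

from telink.regulatory_integration import (
    attribute_te_features,
    compare_groups,
    correlate,
    count_features_per_lncrna,
    m6a_abundance_compare,
    tau,
)
from telink.synthetic_data import SimulationConfig, simulate
from telink.te_overlap import classify_te_lncrnas, te_spans_by_transcript

ds = simulate(SimulationConfig(seed=1))
lnc = ds.lncrna_models
stats = classify_te_lncrnas(lnc, ds.tes)
by_id = {s.transcript_id: s for s in stats}

counts = count_features_per_lncrna(lnc, ds.atac)
labels = {s.transcript_id: ("TE-lncRNA" if s.is_te_lncrna else "Non-TE-lncRNA")
          for s in stats}
test = compare_groups(counts, labels)
print(f"ATAC peaks, median per lncRNA: {test.group_medians} (p={test.p_value:.2e})")

cor = correlate([by_id[m.transcript_id].coverage_rate for m in lnc],
                [counts[m.transcript_id] for m in lnc])
print(f"Spearman(TE coverage rate, ATAC peaks) = {cor.coefficient:.3f} "
      f"(p={cor.p_value:.1e}) — open chromatin tracks TE content")

spans = te_spans_by_transcript(stats, lnc)
attr, excluded = attribute_te_features(spans, lnc, ds.tfbs, min_fraction=0.5)
n_derived = sum(a.te_derived for a in attr)
print(f"TFBSs inside lncRNAs: {len(attr)} ({n_derived} TE-derived at >=50% "
      f"TE coverage; {len(excluded)} hits outside any lncRNA)")

_, m6a_test = m6a_abundance_compare(lnc, by_id, ds.m6a)
print(f"m6A site abundance TE vs Non-TE: p={m6a_test.p_value:.3f} "
      "(no difference — a true null in this dataset)")

taus = tau(ds.expression)
spec = [taus[t].tau for t in ds.truth.tau_specific_ids]
print(f"tau of condition-specific features: min {min(spec):.3f} "
      "(close to 1 = expressed in one heavy-metal condition only)")
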