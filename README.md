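# telink

Identification and multi-omic characterization of transposable-element-derived
long noncoding RNAs (TE-lncRNAs).

## The problem

A large fraction of lncRNAs overlap transposable element (TE) insertions, and
those insertions appear to supply functional parts — promoters, transcription
factor binding sites (TFBSs), open-chromatin regions, even small open reading
frames (sORFs).  Studying this requires a chain of genomic bookkeeping that is
easy to get subtly wrong: filtering assembled transcripts down to expressed
lncRNAs, computing union TE coverage without double-counting overlapping
repeats, assigning single genomic-context labels, detecting insertion
hotspots, and attributing interval features (ATAC peaks, TFBS hits, m6A
sites, ORFs) to the TE spans inside each host locus.

`telink` packages that chain as a tested Python library for people analysing
TE–lncRNA interplay in *Drosophila*-scale genomes, plus a seed-reproducible
synthetic-data generator whose ground-truth bookkeeping makes every step
verifiable end to end.

## The core quantities

* **lncRNA identification** — a three-stage cascade over assembled
  transcripts: (1) class code ∈ {u, x, i, j, o}, mature length ≥ 200 bp,
  ≥ 1 exon; (2) both coding-potential predictors call noncoding *and* no
  protein homology hit (the calls are consumed inputs); (3) total FPKM over
  all samples > 0.
* **TE-lncRNA classification** — a lncRNA overlapping ≥ 1 TE by ≥ 1 bp on
  its locus span.  Per lncRNA: TE count, union-covered bp, and coverage rate
  = covered bp / locus length ∈ [0, 1].
* **Family enrichment** — per-family incidence proportions by region class
  (genome / lncRNA / CDS) with two-sided Fisher exact tests on 2×2 tables,
  odds ratio (a·d)/(b·c).
* **Context and hotspots** — one label per TE by priority
  promoter > exon > intron > downstream > intergenic (promoter window
  −2000/+200 around the strand-aware TSS); hotspot bins with
  z = (count − mean)/sd ≥ 3 over each chromosome's fixed-width bins.
* **Feature attribution** — a feature is TE-derived when ≥ 50% of its bases
  (union logic, spliced for ORFs) fall inside the host's TE spans.
* **Expression specificity** — τ = Σᵢ(1 − x̂ᵢ)/(N − 1) over N samples, with
  x̂ᵢ the log2(FPKM+1)-transformed value divided by the row maximum; τ = 0
  for uniform rows, 1 for single-condition expression.

## Worked example

```bash
python examples/02_te_overlap.py
```

prints (seed 1, default synthetic study of 1000 lncRNAs on a 3 × 2 Mb genome):

```
TE-lncRNAs: 400/1000 (40.0% of lncRNAs)
TE incidences in lncRNAs: 1497; mean 3.7 TEs per TE-lncRNA; 72.0% carry more than one TE
coverage-rate histogram (0-25 / 25-50 / 50-75 / 75-100%): [155, 42, 84, 119]
most common family in lncRNAs: Gypsy (40.95%)
lncRNA vs CDS insertion: OR=186.8, p=0.00e+00 (noncoding loci tolerate far more insertions than coding exons)
```

40% of the synthetic lncRNAs were planted as TE-lncRNAs and are recovered
exactly; the coverage-rate histogram is bimodal (most TE-lncRNAs are either
lightly or almost fully covered); Gypsy dominates the family mixture; and TE
incidences concentrate overwhelmingly in noncoding loci rather than coding
exons.  The other scripts in `examples/` demonstrate identification, context
labels and hotspots, the chromatin/TFBS/m6A/τ integration, and ORF discovery;
`examples/06_full_pipeline.py` runs everything end to end.

The same pipeline is scriptable from a shell:

```bash
telink simulate --out simdir --seed 1
telink run --gtf simdir/annotation.gtf --te simdir/te.out \
    --calls simdir/calls.tsv --expr simdir/expression.tsv \
    --chrom-sizes simdir/chrom.sizes --atac simdir/atac.bed \
    --tfbs simdir/tfbs.bed --m6a simdir/m6a.bed \
    --genome simdir/genome.fa --out outdir
```

`outdir/report.tsv` holds every computed quantity with all thresholds
recorded in its header; re-running with the same inputs is byte-identical.

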