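# Methods

This note documents the models, conventions and design choices behind
`telink`, and what the synthetic-data generator does and does not emulate.

## Coordinates and formats

All internal coordinates are 0-based half-open (`[start, end)`).  GTF
(1-based closed) and RepeatMasker `.out` query coordinates (1-based closed,
strand `C` = minus) are converted at the I/O boundary in both directions, so
write-then-read round trips are exact.  RepeatMasker `Simple_repeat` and
`Low_complexity` records are masking artifacts, not transposons, and are
dropped on read.  The repeat class/family column splits on the first `/`;
a label without `/` uses the whole string as both class and family — family
names are treated as opaque labels throughout (no repeat-library
normalization is attempted).  A GTF exon lacking a `class_code` attribute
yields `None`, which fails the identification whitelist rather than
erroring: the filter is a whitelist and unknown provenance is not evidence
of novelty.

## lncRNA identification

The cascade applies three predicates in order — structure (class code ∈
{u, x, i, j, o}, length ≥ 200 bp, ≥ 1 exon), noncoding (both predictor
calls noncoding and no protein hit; these calls are consumed inputs, since
coding-potential models and homology search are upstream tools), expressed
(row sum of FPKM > 0, with transcripts absent from the matrix counted as
unexpressed for robustness to partial matrices).  The three predicates
commute; the order only shapes the per-stage accounting in the
`FilterReport`.  **Length** means the mature (spliced) transcript length:
the 200 bp convention in the lncRNA literature refers to the RNA molecule,
not the genomic span.  `length_mode="locus"` switches to the genomic span.

## TE overlap and enrichment

Overlap is computed strand-agnostically on the locus span (introns
included) with a ≥ 1 bp threshold: intronic insertions are part of the
phenomenon being measured, and TE annotations are not meaningfully stranded
relative to transcription of the host.  Exon-only and strand-aware modes
exist as flags.  Union coverage merges clipped TE spans so nested or
overlapping repeats are counted once; coverage rate divides by locus
length.  TE counting is incidence-based: a TE overlapping two lncRNAs
contributes one count to each, which is the convention that makes
"TEs in lncRNAs / TEs in genome" ratios well defined.  Fisher tests use
scipy's exact two-sided hypergeometric p-value with the sample odds ratio
(a·d)/(b·c) (∞ representable); the test suite checks the p-value against a
full fixed-margin enumeration in exact rational arithmetic.  Percentages
are printed at two decimals with half-up rounding (`proportion_report`), so
complementary percentages sum to 100.00 within rounding.  Coverage-rate
bins are right-open except the last (a rate of exactly 25% falls in the
25–50% bin; 100% falls in the last).

## Genomic context, hotspots, conservation

Each TE gets exactly one label by priority promoter > exon > intron >
downstream > intergenic, resolving multi-region overlaps deterministically
the way single-label peak annotators do; ties across transcripts go to the
TSS nearest the TE midpoint.  The promoter window defaults to (−2000, +200)
around the strand-aware TSS — a common convention, recorded in every output
header because no single default is canonical; the downstream window is
1000 bp.  TSS contribution flags a lncRNA when one of *its own* overlapping
TEs touches the ±50 bp TSS window by ≥ 1 bp.

Hotspots: TEs are binned by midpoint into fixed-width bins (default
100 kb) per chromosome; a bin is flagged when z = (count − mean)/sd ≥ 3,
with mean and population sd taken over that chromosome's bins.  A z-score
on fixed bins is transparent and directly testable; a Poisson-tail variant
(`detect_hotspots_poisson`) is provided behind a separate function.  Note
an intrinsic ceiling of this statistic: with k hot bins among n, z cannot
exceed √((n−k)/k) however intense the hotspot, so detection resolution must
match the expected hotspot width (the synthetic study plants 50 kb terminal
hotspots and recovery is run at 50 kb bins for that reason).

Conservation summaries weight by covered base: mean score and
fraction-of-zero-score bases are computed only over bases present in the
track (missing bases are absent, not zero), so duplicating features leaves
means unchanged and classes with no covered bases are simply absent.

## Regulatory integration

Features are assigned to a lncRNA on ≥ 1 bp locus overlap (a feature may
count for several lncRNAs — the BEDTools-intersect convention).  A feature
is TE-derived when ≥ 50% of its bases are covered by the union of the host
locus's TE spans; 1 bp assignment plus 50% attribution keeps assignment
permissive while guarding against crediting long peaks to incidental TE
touches.  Both thresholds are arguments and appear in output headers.
Attribution is monotone in the threshold by construction.  The default
two-group test is the two-sided Mann–Whitney U because count and length
distributions here are heavy-tailed; Welch's t-test is available where a
mean-based test is wanted.  Correlations default to Spearman (the coupling
of interest is monotone, not linear), Pearson behind a flag; constant
vectors yield an explicitly undefined coefficient rather than NaN
arithmetic.  Promoter TFBS density is hits per kb of promoter window,
compared across the three promoter classes (TE-pro-lncRNA = a TE-lncRNA
one of whose overlapping TEs reaches its promoter window;
Non-TE-pro-lncRNA; Non-TE-lncRNA) with a Kruskal–Wallis rank test.
Multiple-testing correction for per-motif scans uses Benjamini–Hochberg
(`bh_adjust`).  m6A abundance is site count per lncRNA; a length-normalized
variant would be a caller-side division and is not baked in.

τ uses log2(FPKM+1) followed by max-normalization by default: the index
requires x̂ᵢ ∈ [0, 1], max-normalization is the canonical construction, and
the log tames FPKM dynamic range; raw mode is a flag.  All-zero rows have
no defined τ and are skipped; single-sample matrices are an error.

## ORF discovery

ORFs are scanned on the spliced sense strand in three frames — a lncRNA is
a stranded molecule; an antisense ORF belongs to a different transcript
(a 6-frame mode exists for exploration).  The default rule is
longest-per-stop: each in-frame stop pairs with the most 5' ATG after the
previous in-frame stop, minimum 10 codons including the stop, matching
common sORF-annotation practice; an all-starts mode reports every nested
ORF.  Codons containing N never start or stop an ORF.  ORF spans are
projected through the exon chain for genomic TE attribution, which uses
the same union/threshold rule as other features.  Raw ORF counts per
lncRNA confound with transcript length; `orf_prevalence_compare` therefore
offers a per-kb mode, and the test suite demonstrates the confounder
(longer transcripts, more raw ORFs, equal per-kb rates).

## The synthetic study

The generator emits a complete toy study — genome FASTA, GTF, `.out`,
ATAC/TFBS/m6A BED, FPKM matrix, coding-potential calls, conservation
bedGraph, chromosome sizes — from one seeded numpy Generator, plus a
`GroundTruth` record that is exact by construction.  Default conditions:

* 3 chromosomes × 2 Mb; 200 coding genes; 1000 lncRNAs of which 40% are
  TE-lncRNAs; 100 extra candidates each failing exactly one identification
  rule (25 per rule).
* TE family mixture dominated by LTR/Gypsy (0.40), with LTR/Pao 0.11,
  LINE/I-Jockey 0.08, RC/Helitron 0.07 and four minor families making up
  the rest — proportions of the Gypsy-dominated mixtures reported for fly
  lncRNA repeats.
* Intergenic TE lengths log-normal (median 1 kb, σ = 0.7, capped at 15 kb,
  the observed repeat-length range); TEs hosted inside lncRNA loci use a
  smaller scale (median 400 bp) so multi-TE hosts and fine-grained coverage
  targets are achievable.
* Per-TE-lncRNA coverage targets from an equal mixture of Beta(1.2, 6) and
  Beta(6, 1.2) — the bimodal 0–25% / 75–100% concentration.
* 4500 uniform intergenic background TEs plus 5× planted intensity in the
  terminal 50 kb bin at both ends of every chromosome (the chromosome-end
  hotspot bias).  The planted bin size is recorded in the ground truth.
* 30% of TE-lncRNAs get a TE crossing the TSS (these are simultaneously the
  TE-promoter class); planting TSS-covering TEs on Non-TE-lncRNAs would
  contradict the planted TE-lncRNA fraction, so the fraction applies within
  TE-lncRNAs.
* ATAC peaks per lncRNA ~ Poisson(1 + 6·coverage_rate); m6A sites ~
  Poisson(1) identically in both classes (a true null); 600 body TFBSs of
  which 80% are placed fully inside a TE span and 20% fully outside any
  (attribution ground truth), plus promoter TFBSs at λ = 4 for the
  TE-promoter class vs 0.5 otherwise.
* Expression: 15 samples (control + Cd/Cu/Pb/Zn × 3 replicates); gamma
  baselines with coding > Non-TE-lncRNA > TE-lncRNA means and log-normal
  per-sample noise; 20% of lncRNAs are condition-specific (expressed only
  in one metal's replicates, 8-fold induced) — the planted high-τ set.
* 100 explicit 60-codon ORF cassettes (ATG + 58 non-stop codons + TAA)
  written into designated lncRNA exons of an otherwise i.i.d. ACGT genome.
* 150 Simple_repeat/Low_complexity decoy records are written to the `.out`
  to exercise reader filtering; they are excluded from all TE analyses.

Placement geometry makes planted quantities exact rather than approximate:
loci are disjoint with ≥ 2.3 kb gaps and stay out of the terminal hotspot
bins; hosted TEs keep 250 bp clearance from the 5' locus end (so no body TE
strays into the TSS window or the in-locus promoter segment) and 10 bp from
the 3' end; background TEs never touch a locus.  Consequently per-lncRNA TE
counts, union coverage, TSS flags, promoter classes, ATAC counts and TFBS
attribution flags all equal their planted values, and recovery tests can
assert equality, not approximation.

What the generator does **not** emulate: nested/fragmented repeats,
sequence homology between TE copies, realistic base composition or codon
usage, transcriptional noise structure beyond log-normal scatter, or
read-level artifacts (no FASTQ).  Passing recovery tests therefore
demonstrates the correctness of the interval arithmetic, the statistics and
the plumbing under the stated statistical structure — not robustness to
alignment or assembly error in real data.

## Problem sizes and numerics

The default study (1000 lncRNAs, ~7000 TEs, 6 Mb genome) was chosen so the
full suite, including two end-to-end pipeline runs and a 500-instance
brute-force oracle comparison for each overlap primitive, completes in
about a minute on one core; the dataset-level counts of the motivating
study (thousands of external sequencing runs) are inputs to the reporting
arithmetic, not regeneration targets.  Ties, degenerate inputs and edge
cases are fixed deterministically: interior bin edges are right-open, the
hotspot sd uses the population formula with sd = 0 meaning no hotspots,
attribution host ties go to the larger overlap then the lexicographically
later id, and all randomness flows from explicit integer seeds.
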