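# Methods

## The problem

Antibody-directed tagmentation assays (CUT&Tag and relatives) release
paired-end DNA fragments wherever the targeted factor sits on chromatin.
For a histone such as H2A.Z, the *length* of each fragment carries
information beyond its position: DNA still wrapped around an intact
nucleosome protects ~150 bp or more, a partially unwrapped nucleosome
protects an intermediate stretch, and sub-nucleosomal or free DNA yields
short fragments. `wrapstate` quantifies how the mixture of these three
states changes at gene promoters between biological conditions (e.g. wild
type versus a chaperone knockout), alongside the supporting analyses such
a study needs: peak co-occupancy of two factors, coverage tracks,
reference-point meta-profiles, differential promoter binding, and
pulldown-MS interactor calling.

## Wrapping-state model

Fragment lengths are partitioned into three classes at fixed boundaries:

| class      | length (bp) | interpretation            |
|------------|-------------|---------------------------|
| unwrapped  | < 100       | sub-nucleosomal / free DNA|
| partial    | 100–150     | partially unwrapped       |
| full       | > 150       | fully wrapped nucleosome  |

Lengths of exactly 100 and 150 bp fall in the partial class: the middle
band is read inclusively and the outer bands strictly, the only convention
that makes the three ranges a partition. Boundaries are parameters
(`boundaries=(100, 150)`) for assays with different protection footprints.

The pipeline (`wrapping_pipeline`) compares a test condition against a
reference in a fixed order: pool replicates; restrict fragments to
promoter windows (TSS ± `flank`, default 1 kb); **depth-match** by exact
subsampling without replacement to the smallest promoter-restricted count;
partition by class; build raw binned coverage per class per condition
(bin 10 bp); and summarise. Depth matching is the load-bearing step — it
guarantees the per-condition totals are identical, so any per-class
difference downstream is a change in *composition*, not sequencing depth.
Subsampling is an exact count, not a Bernoulli fraction, precisely so this
equality is testable (`WrappingCounts` grand totals equal the matched
depth).

### Profile construction: average, then log

The per-class fold-change profile around the TSS is computed as

    log2( (mean_test(x) + pc) / (mean_ref(x) + pc) ),   pc = 0.001,

where `mean_cond(x)` is the promoter-averaged class coverage at offset
`x` (strand-aware, minus-strand promoters flipped). The alternative —
per-bin log2 tracks averaged across promoters — is the right object at
very deep sequencing, but at the depths this package targets a 10 bp bin
holds only a handful of fragments, and `log2((k+1)/(k'+1))` with k ≈ 1–5
is dominated by the pseudocount: a true two-fold composition change
reads out near +0.6 instead of +1.0. Averaging first estimates per-class
coverage over thousands of promoters before the ratio is taken, so the
expected profile value is `log2(w_test / w_ref)` wherever both classes are
observed. The pseudocount 0.001 only guards against empty columns; it is
deliberately far below typical promoter coverage (~0.1–5 fragments/bin)
so it contributes < 0.1 of bias even at profile edges. The per-bin log2
tracks are still produced (pseudocount 1) as browser outputs.

Per-promoter, per-class, per-condition counts assign each fragment to the
leftmost promoter it overlaps, so counts conserve the matched depth
exactly even when promoter windows touch.

### Boxplot statistics

Region-level log2 fold changes use `log2((test + 1) / (ref + 1))` on
per-promoter counts (pseudocount 1: zero counts are common at these
depths). Significance uses a one-sided Wilcoxon rank-sum test comparing
the per-region count vectors of the two conditions as two samples, with
the asterisk key `* p < 0.01, ** p < 0.001, *** p < 0.0001`. The rank-sum
p-value is exact (full permutation distribution) when the pooled sample
size is ≤ 16 with no ties, otherwise a normal approximation with
tie-corrected variance and 0.5 continuity correction; both paths are
`scipy.stats.mannwhitneyu` under the hood and are checked against a full
enumeration oracle in the test suite. A one-sided pooled-variance t
(`welch_t_one_sided` companion) is available where a t-test is preferred
for region-level log2FC comparisons.

## Co-occupancy and Fisher association

Coordinates are 0-based half-open throughout; book-ended intervals do not
overlap; strand is ignored in all overlap computations (tagmentation is
unstranded). Two peak sets are classified into A-only / shared / B-only,
where **shared is the union-merge of every A and B peak overlapping the
other set, counted once as merged regions**. Peak-level pair counting
would double-count chains of mutually overlapping peaks; merged-region
counting is unambiguous, at the cost that shared counts are not comparable
one-to-one with pair-counted Venn diagrams.

Association of a peak set with a reference set (e.g. promoters) uses a
2×2 Fisher exact test against a matched random null: `n_random` regions
(default 55,000) of fixed length (default 250 bp) placed uniformly over
the genome, chromosomes weighted by their number of valid start positions.
Rows are (query, random), columns (overlaps reference, does not). This
matched-null table is simpler than genome-fraction constructions and has
the same directional reading: positive log2 odds ratio = association.
P-values are computed with exact integer arithmetic (hypergeometric
weights via binomial coefficients; the two-sided tail sums all tables
whose integer weight is ≤ the observed weight, so ties are resolved
exactly rather than by floating-point tolerance). The odds ratio applies
a Haldane 0.5 correction to all cells when any cell is zero, keeping the
log2 finite. Both one- and two-sided p-values are reported, since
published figures rarely state which tail was used.

Genomic-distribution annotation is deliberately coarse: each peak's
midpoint is assigned one category with priority promoter > gene body >
intergenic. Counts always partition the peak set.

## Coverage tracks

Raw coverage counts, per fixed-width bin (default 10 bp), the number of
fragments overlapping the bin by ≥ 1 bp — whole-fragment counting, the
fragment-level analogue of extending reads to the template length. RPKM is
`raw × 1e9 / (total_fragments × bin_size)`. Wrapping-state class tracks
are kept raw (depth matching already normalised them); factor-enrichment
tracks use RPKM; the normalization is always an explicit tag, never
inferred. bedGraph is the canonical on-disk format, written as one line
per maximal run of equal-valued bins with zero runs omitted and values in
shortest round-trip `repr` — write→read round-trips are bit-exact and are
tested as such.

The peak caller applies three rules on a binned track: maximal runs of
bins ≥ cutoff; merge runs separated by ≤ max_gap bp; drop merged regions
shorter than min_length bp. Summits are the leftmost bin reaching the
peak maximum (deterministic ties). Cutoff, length, and gap have no
defaults at the CLI: they are data-dependent choices the user must own.

## Meta-profiles

Reference-point matrices hold one row per region, anchored at the TSS
(genes) or the interval midpoint (peaks), covering upstream/downstream
extents in `bin_width` windows (bp-weighted means of the underlying
track, so matrix bins need not align with track bins). Minus-strand rows
are orientation-flipped so downstream always means downstream of
transcription — without this the up/downstream asymmetry analysis would
be meaningless. Windows off the chromosome are missing (NaN) and excluded
from means rather than zero-filled, avoiding artifactual edge decay.
Quantile partitioning splits regions into k near-equal groups by
ascending score (lower groups take the remainder; ties keep input order).
Replicate correlation (Pearson or Spearman) runs over concatenated bin
vectors, with zero-variance tracks reported missing rather than silently
correlated.

## Differential promoter binding

Per promoter per sample: fragment count (a fragment spanning two
promoters counts in both), CPM with the sample's whole fragment total as
library size, `log2(cpm + 0.5)`. The region test is a pooled-variance
two-sample Student t across replicates with Benjamini–Hochberg
correction; classes are SigUp (log2FC > 0.5, padj < 0.05), SigDown
(mirrored), NS. The pooled t was chosen over Welch's unequal-variance t
after measurement: with 3 replicates per group, the Welch–Satterthwaite
degrees of freedom collapse whenever the two sample variances differ by
chance, which at a planted log2FC of 1.5 and replicate noise sd 0.2 costs
roughly a third of the achievable sensitivity (~64% versus ~96% of
planted regions recovered at BH < 0.05), while the generator's — and the
assay's — replicate variances are genuinely comparable. Under the null
the pooled t is exact for Gaussian log-intensities, and FDR control is
verified by simulation in the acceptance suite. This classifier is a
transparent stand-in for dispersion-modelling count packages; its
SigUp/SigDown counts are not expected to match results derived from other
statistical machinery.

## ChIP-MS interactor flagging

Per protein: log2FC = mean log2 intensity (bait) − mean log2 intensity
(control); p from a two-sample Welch t on log2 intensities (here group
variances can genuinely differ — bait pulldowns concentrate real
interactors while controls sit at background); enriched requires
log2FC > 0.5 and p < 0.05. Missing intensities are never imputed: a
protein with fewer than two observations in either group is untestable
(no p, never enriched). Complex heatmap tables are pure configuration —
an ordered subunit list per complex, rendered without clustering; an
editable example for the H2A.Z remodeler complexes (p400-TIP60, SRCAP,
INO80) ships with the package with subunit spellings transcribed from the
source material.

## Synthetic data generator

The generator defines the study conditions the tests and acceptance runs
measure under; its defaults were chosen once to resemble a desk-scale
promoter-profiling experiment and are not tuned per test:

* genome: 2 chromosomes × 5 Mb; 2000 genes, TSS ≥ 2.5 kb apart with
  jittered placement, strands Bernoulli(0.5);
* promoters: TSS ± 1 kb (so promoters cover 40% of this compact genome —
  far denser than a real genome, which keeps desk-scale runs informative);
* per condition: 3 replicates × 66,667 fragments (~200k per condition);
* promoter enrichment multiplier 8 (odds of a promoter fragment relative
  to the promoter share of the genome), positional spread sd 300 bp
  around the TSS — a peaked, promoter-centric signal typical of H2A.Z;
* class mixing weights (unwrapped, partial, full) = (0.2, 0.3, 0.5) at
  baseline; preset variants shift them (`wrap-shift`: reference
  (0.15, 0.35, 0.50) vs test (0.30, 0.35, 0.35), i.e. a doubling of the
  unwrapped fraction at the expense of fully wrapped — the signature of
  nucleosome destabilisation) or displace unwrapped fragments +250 bp
  downstream of the TSS (`asym`), emulating preferential unwrapping over
  early gene bodies;
* class-conditional lengths: unwrapped = round Normal(70, 15) truncated
  to [30, 99]; partial = uniform integer [100, 150]; full = round
  Normal(185, 20) truncated to [151, 400]. Truncation is strict, so every
  emitted fragment classifies back to the class it was drawn from — the
  property that makes mixing-weight recovery exactly checkable;
* fragments are clamped to lie wholly on-chromosome preserving their
  drawn length (gene placement keeps a margin, so clamping is rare);
* ChIP-MS tables: log2 intensities Normal(20, sd) with planted proteins
  gaining +log2(fold) in the bait group; count matrices: log2 CPM
  uniform(4, 8) plus Normal replicate noise, planted regions gaining the
  requested log2FC in the test condition.

Every stochastic stream is seeded by a blake2b hash of
`(master_seed | condition | replicate)` reduced to 31 bits, recorded in
the truth manifest (JSON) from which the entire dataset regenerates
byte-identically.

What the generator does **not** emulate: mappability and GC structure,
PCR duplicates, copy-number variation, chromatin-state heterogeneity
across promoters (all occupied promoters are exchangeable), overdispersed
count noise beyond the log-normal replicate model, and missing-value
structure in proteomics (intensities are complete unless the user masks
them). Passing tests therefore demonstrate that the *algorithms* recover
planted structure under their stated assumptions — not that real
libraries satisfy those assumptions.

## Numerical and design choices

* Exact Fisher p-values use integer-weight comparisons for the two-sided
  tail; sums are converted to float only at the final division
  (agreement with brute-force enumeration to < 1e-12 on every table with
  grand total ≤ 60 is part of the acceptance suite).
* The rank-sum exact path requires ≤ 16 pooled observations and no ties;
  the asymptotic path applies tie correction and continuity correction.
* quantile groups put remainder elements in the lower groups; argsort is
  stable so ties resolve by input order.
* Subsampled fragment indices are sorted, keeping output files
  coordinate-ordered per input order.
* Degenerate differential rows (zero variance in both groups) get p = 1
  when the group means agree and p = 0 otherwise, rather than NaN.
* Out-of-genome fragments are clipped (coverage) or errors (interval
  validation) depending on whether the operation is aggregate or
  record-level; both paths warn or raise explicitly.
* The run-config hash excludes the output directory, so identical
  analyses written to different locations share a hash and reproduce
  byte-identically; no timestamps enter numeric outputs.

## Problem sizes

Default analysis runs use the generator's native scale (2000 promoters,
~200k fragments per condition, 1 M coverage bins), which a laptop core
handles in seconds per pipeline stage; the simulation-based checks
(50-seed FDR null, six-point weight-recovery grid) complete in about a
minute total. These sizes were chosen as the smallest at which the
binomial/delta-method error bounds of the recovery analyses are several
times tighter than the tolerances being checked.

## Known limitations

* The wrapping profile assumes symmetric promoter windows; the TSS is
  recovered as the window midpoint.
* Depth matching subsamples once per run; bootstrap uncertainty on the
  profiles is not computed.
* The differential classifier models log-CPM noise as Gaussian with a
  shared within-region variance; strongly overdispersed data would need a
  count model.
* The shared-peak convention (merged regions) means Venn counts are not
  directly comparable to pair-counted published figures.
* bedGraph reading requires bin-aligned intervals by design; arbitrary
  interval tracks should be rasterised upstream.
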