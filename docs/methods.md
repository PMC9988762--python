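# Methods

## Scope and model

`peakrank` implements a two-condition cistrome–transcriptome integration:
replicate consensus peaks, midpoint genomic annotation with Fisher-exact
region enrichment, count-based differential binding with a PCA noise
filter, regulatory-potential (RP) gene scoring with rank-product
aggregation against differential expression, and a three-way
direction-concordance filter against active histone marks.  Conditions are
labelled TIL/TNIL (in labor / not in labor) throughout but are arbitrary
group labels.

Assumptions: peak calling, read alignment and counting happen upstream;
inputs are replicate BED peak files, a gene model TSV, a per-site count
matrix over consensus sites, a DESeq2-style per-gene DE table, and
per-mark histone differential-site tables.  All coordinates are 0-based
half-open (BED frame) everywhere; chromosome names are matched exactly.
ChIP peaks are unstranded; strand enters only through the gene model.

## Consensus sites

Replicate peaks of one condition are pooled and merged (intervals whose
gap ≤ `min_gap`, default 0, join; touching intervals join).  A merged
interval is retained when peaks from ≥ `min_overlap` distinct replicates
(default: all) overlap it by ≥ 1 bp — the DiffBind-style construction.  No
fractional-overlap rule is applied and no summit re-centering is done;
sites are full merged intervals.  Differential analysis runs on the merged
union of the two condition consensus sets.

## Annotation

Sites are classified by their integer midpoint into exactly one category
with precedence Promoter > FiveUTR > ThreeUTR > Exon > Intron > Downstream
> DistalIntergenic, mirroring the hierarchy of the common ChIP annotators.
The promoter window is −3000/+3000 bp around the TSS (strand-aware,
inclusive at both edges); Downstream is the 3000 bp window past the
transcript end, symmetric with the promoter convention.  UTR calls require
a CDS; the gene-model TSV therefore carries optional `cdsStart`/`cdsEnd`
columns, and genes without a CDS yield plain Exon.  The nearest gene
minimizes |midpoint − TSS| with ties broken by lexicographic gene id;
signed distances are negative upstream of the TSS in gene orientation.
Reports provide both the raw categories and a pooled "distal" rollup
(DistalIntergenic + Downstream), since published summaries often pool
non-genic classes.

Per-category enrichment of differential sites uses the conventional
two-sided Fisher exact test (sum of hypergeometric probabilities ≤ the
observed table's) on the 2×2 table (differential vs not × in-category vs
not), BH-adjusted across categories; categories absent from both groups
are omitted.

## Differential binding stand-in

Counts are normalized to counts-per-million per sample and transformed as
log2(CPM + 0.5).  Each site is tested with a two-sample t-test on log2
CPM.  This is a deliberate stand-in for the DiffBind consensus of DESeq2
and edgeR: re-implementing two negative-binomial frameworks is out of
scope, and everything downstream consumes only the per-site fold change,
p-value and direction.

Two choices here were genuinely open:

* **Variance model.**  The default is the pooled (Student) statistic.  At
  3 replicates per group the Welch–Satterthwaite approximation is
  measurably conservative even for ideal normal data, which would bias
  every downstream funnel count; the pooled test is calibrated at the
  nominal level under the null count model (the acceptance script
  recomputes this rejection rate), and shared variance is also closer in
  spirit to the shrunken-dispersion NB tests being replaced.
  `variance="welch"` is available for designs with genuinely
  heteroskedastic groups.
* **Significance rule.**  `mode="raw"` (P < α, default α = 0.05) mirrors
  the common DiffBind usage; `mode="adjusted"` applies BH.  Both are
  exposed because published descriptions are frequently ambiguous on this
  point.

Sites with zero within-group variance in both groups are degenerate: they
get p = 1 when the group means agree, p = 0 otherwise, and are flagged.

## PC2 noise filter and its scale sensitivity

The filter computes a PCA of the samples × differential-sites matrix
(sites as variables, columns mean-centered, unscaled, via SVD).  A site's
loading is its entry in the **unit-norm** second right singular vector —
the only normalization under which a fixed per-site threshold is
comparable across runs — and sites with |loading| > `pc2` (default 0.005)
are removed.  Only magnitudes are used, so the filter is invariant to the
sign indeterminacy of singular vectors.  With fewer than 3 sites, fewer
than 3 samples, or fewer than two nonzero singular values the filter is
skipped with a warning.

A fixed absolute cutoff on unit-norm loadings is inherently
scale-sensitive: over m sites the loading vector has root-mean-square
entry m^(−1/2), so at m ≈ 2000 a typical entry is ≈ 0.022 and at m ≈ 150
it is ≈ 0.08.  A 0.005 cutoff therefore only retains an appreciable
fraction of sites when m is in the tens of thousands, or when PC2 is
strongly concentrated on a few artifact-driven sites (the regime the
filter is meant for in genome-scale data).  At the desk-scale site counts
of the synthetic scenario the cutoff removes nearly all differential
sites, planted signal included — the acceptance script reports end-to-end
sensitivity both with the default threshold and with the filter disabled
to make this visible.  Recommendation: keep 0.005 only for genome-scale
site sets; for small site sets disable the filter (`pc2: null`) or choose
a threshold relative to m^(−1/2).  The convention in force (unit-norm
loadings, absolute threshold) is echoed in the run metadata.

## Regulatory potential and ranking

RP of gene g: s_g = Σ_{i=1..k} 2^(−d_i/d0) over peaks whose center lies
within `rp_window` of the TSS; d_i = |peak center − TSS| in bp.

* `d0` (half-decay distance) defaults to 1000 bp, the promoter-type
  transcription-factor setting of the upstream tool ecosystem; it is
  configurable and echoed in all output headers.
* `rp_window` defaults to 10·d0: terms beyond it contribute < 2^(−10) ≈
  0.001 each, bounding both truncation error and compute.
* The RP score entering criterion (2) is computed from the differential
  sites only (gained and lost subsets separately), matching an "occupancy
  changes at the consensus sites" reading; scoring from all consensus
  sites is available through the same function.

R_DE ranks genes by de_score = log2FC × (−log10 padj) (base-10 by
convention of the DESeq2 ecosystem; configurable), signed **within each
expression-direction stratum** so that the most up-regulated gene and the
most down-regulated gene each rank first in their stratum — up- and
down-regulation are analyzed separately downstream, which this mirrors.
Zero adjusted p-values are clipped to the smallest positive float.
Undefined scores rank last and are flagged.  R_RP ranks RP scores
descending.  Ranks use average ties; the aggregated rank is the product
R_DE × R_RP, ascending, ties broken by gene id.

## Three-way integration

Candidates are the criteria-(1,2) genes with ≥ 1 differential histone
site assigned to them whose direction matches the gene's expression
direction.  "Within the gene" is operationalized as transcript span ±
`assignment_window` (default 3000 bp, the promoter window) around the site
midpoint; multi-assignment to overlapping genes is allowed.  A gene's
histone (and, where needed, PGR) direction is the sign of the mean log2FC
of its assigned significant sites; an exact zero mean is
direction-ambiguous and excluded with a log note.  A gene contributed by
both the gained and the lost PGR subset takes its PGR direction from the
same mean-sign rule.  Per-mark tables carry the (histone, PGR, expression)
triples; the union summary counts distinct genes across marks.

## Synthetic data generator

The generator emulates the study design the pipeline targets: two
conditions × 3 replicates, a 90 Mb three-chromosome pseudo-genome with
1000 non-overlapping genes (2–8 exons, CDS for UTR annotation), 2000
background peaks (~400 bp) shared across replicates with Gaussian boundary
jitter (σ = 25 bp) and 10% per-replicate dropout, and planted signal:

* 30 target genes and 30 decoy genes, each with one differential PGR site
  within ±500 bp of the TSS (so RP clears 0.1), gained sites present in
  every TIL replicate and no TNIL replicate (conversely for lost);
* negative-binomial site counts (gamma–Poisson, Var = μ + αμ², α = 0.05),
  background means lognormal around 100, planted sites with group mean
  ratio 2^2 = 4 (log2FC 2, base mean 200 in the low group) — a strong but
  realistic differential-occupancy effect;
* a DE table with |log2FC| = 2 and strongly shifted test statistics for
  planted genes (uniform-p nulls elsewhere), BH-adjusted;
* per-mark histone differential sites inside the gene body: concordant
  with the expression direction for targets, flipped for decoys, plus 200
  null background sites per mark.

One global seed drives independent substreams per generator (model, truth,
peaks, counts, DE, histone), making fixture bundles byte-identical across
runs.  What the generator does **not** emulate: read-level data and
mappability artifacts, peak-width/shape differences between factors and
marks, correlated biological replicates, batch effects or coherent
artifact axes (hence no realistic target for the PC2 filter, see above),
GC/copy-number biases, and isoform-level expression.  Passing tests
therefore demonstrate the correctness of the integration logic and its
statistical calibration under this idealized model, not performance on
real sequencing data.

## Numerical and degenerate-input choices

* Merging is deterministic: inputs are sorted by (chrom, start, end);
  touching intervals merge at `min_gap = 0` (gap ≤ 0 rule).
* An empty query in overlap statistics raises instead of returning 0.
* BED scores are clamped to [0, 1000] on write, with a logged warning.
* DE tables with padj = 0 are clipped to the smallest positive float.
* Fisher tables for categories absent from both groups are omitted.
* The DE/RP gene reconciliation is an inner join; dropped genes are
  logged, and an empty intersection is an error.
* All thresholds live once in the pipeline config and are echoed in
  `run_metadata.json`; outputs contain no timestamps, so identical config
  and inputs yield byte-identical output files (checksummed in the
  metadata).

## Problem sizes

The default synthetic scenario (1000 genes, ~2000 background peaks, ~1900
union sites, 6 samples) runs the full pipeline in about a second; the test
suite repeats it across 20 seeds for the recovery checks, and the
calibration checks use 20 seeds × 2000 null sites.  These sizes were
chosen to make the statistical assertions (rejection rates within ±0.01,
sensitivity ≥ 0.9) tight enough to be meaningful while keeping the whole
suite fast enough to run on every change.

## Known limitations

* The differential-binding test is a t-based stand-in, not an NB model;
  with very low counts or unequal library sizes its calibration degrades
  sooner than DESeq2/edgeR's would.
* The absolute PC2 loading threshold is only meaningful relative to the
  number of differential sites (see above).
* Annotation is midpoint-based; wide sites spanning multiple features get
  a single category by design.
* Histone data enter as pre-computed differential-site tables; the package
  does not itself run the histone count analysis.
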