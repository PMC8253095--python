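# Methods

This note documents the statistical procedures implemented in
`multicistrome`, the design of the synthetic study that validates them, the
defaults and why they were chosen, and what the validation does and does not
demonstrate about real data.

## Coordinate conventions and interval algebra

All coordinates are 0-based half-open (BED convention); abutting intervals do
not overlap, and overlap requires ≥ 1 shared base unless a larger minimum is
requested. Chromosome names are matched as exact strings — no `chr` aliasing
— and a validation pass reports names absent from the declared assembly, so
input mix-ups fail loudly rather than silently dropping data. Merging,
overlap queries and fragment counting are sorted-sweep / binary-search
implementations whose results are checked against all-pairs brute-force scans
in the test suite.

## Consensus peaks and QC

A sample's working peak set for a factor is the set of caller-1 peaks that
overlap at least one caller-2 peak. Caller-1 coordinates are retained — the
intersection filters peaks rather than clipping them — because clipping to
the geometric intersection would destroy peak-width information that the
signal matrices and motif scans use downstream. No summit extension or width
capping is applied before intersection.

QC works per factor over samples: a sample is excluded when its consensus
peak count falls below Q1 − 1.5·IQR (quantiles by linear interpolation
between order statistics) or below a hard floor of 10 000 peaks. The floor is
meaningful for genome-scale data; the synthetic study configures it to 0 and
relies on the fence. With tight peak-count distributions the fence is
aggressive — a sample whose dual-caller dropout dipped a little can be
excluded — and the pipeline treats that as a legitimate QC decision,
propagating the exclusion to every downstream stage.

## Membership decomposition

Consensus regions are the gap-0 merge of all samples' working peaks; a sample
occupies a region when at least one of its peaks overlaps it by ≥ 1 bp.
Regions are classed `shared_all` (all samples), `sample_specific` (exactly
one) or `partial` (in between). Partial regions are carried and reported but
excluded from shared-vs-specific contrasts: at toy scale they are mostly
caller-dropout artifacts, and including them would make the "shared
fraction" depend on the number of samples rather than on per-sample biology.
Accordingly, the recovered shared fraction is defined per sample as
shared_all / (shared_all + that sample's specific count), averaged over
samples — the quantity directly comparable to the planted per-sample core
fraction.

## Matched shuffle null

For each factor, all called peaks are concatenated (unmerged) and each
interval is re-drawn uniformly over the genome: a chromosome is chosen with
probability proportional to its length, then a start uniform over positions
where the interval fits, accepted only if it shares zero bases with the
exclusion set (default: the concatenation itself). Placements may overlap one
another — deduplication would distort the length-matched null. Each interval
gets up to 1 000 attempts; exhaustion is a hard error naming the interval,
not a silent shrinkage of the null. Seeds are mandatory; two runs with the
same seed are identical. The null is not GC- or mappability-matched.

## Signal quantification and rank-sum tests

Fragments are counted per region by any-overlap, so one fragment can
increment several regions. CPM = count × 10⁶ / library size, with library
size equal to the fragment count unless the caller supplies a larger value.
Signal matrices hold mean per-bp CPM coverage in 25-bp bins (configurable)
across ±flank around each region midpoint (floor((start+end)/2)); flanks of
2 000 and 5 000 bp are produced. Windows truncated by a chromosome edge keep
their row with missing bins. Heatmap exports order rows by descending row
sum. Single-end fragments are used at their aligned length, no extension.

Count comparisons use ln(count + 1) and a two-sided Mann–Whitney/Wilcoxon
rank-sum test: exact by full enumeration of the C(n₁+n₂, n₁) group
assignments (midranks for ties) when n₁·n₂ ≤ 64, otherwise the normal
approximation with tie and continuity corrections. Fully tied inputs return
p = 1 with a degeneracy flag.

## Active-site stratification

The H3K27ac signal matrix over a sample's TF-specific sites is clustered with
Lloyd's k-means (Euclidean, k-means++ init, 10 restarts keeping the lowest
within-cluster sum of squares; missing bins imputed to 0). Rows are clustered
in a canonical lexicographic order and labels mapped back, making the result
invariant to input row permutation at a fixed seed (default 1729, always
logged). Clusters are ranked by mean signal in the central ±10 bins — active
sites are defined by signal at the site center, so a whole-row mean would
reward broad flanking noise — and the top two clusters are selected.

k defaults to 3. The choice is structural: k-means on raw binned coverage
splits whatever population has the largest amplitude spread, which is always
the marked (signal-carrying) population, never the near-zero unmarked one.
With a marked/unmarked site structure and a fixed top-two selection rule,
k = 4 therefore splits the marked population three ways and the selection
loses its lowest-signal tier, whereas k = 3 resolves the natural
strong-active / moderate-active / unmarked structure and the top-two rule
selects exactly the marked sites. k remains a logged configuration value.

## Annotation, linkage, enrichment

Genomic context classifies each region by its midpoint with precedence
promoter > exon > intron > downstream > distal intergenic; promoter =
[TSS − 1 000, TSS + 1 000) and downstream extends the same distance past the
strand-aware gene end. Without exon annotation the gene body counts as
intron.

Peak-to-gene linkage assigns each region to the gene whose TSS is nearest the
region midpoint, provided the distance is ≤ 20 kb; equidistant TSSs all
receive the link, and the gene list is deduplicated afterwards. The same
nearest-within-window rule serves both the per-site gene assignment and the
essential-gene test (a single-set enrichment).

Over-representation is the upper-tail hypergeometric probability of the
observed overlap between the (deduplicated) query gene set and each gene set,
both intersected with the universe — by default all genes in the annotation,
logged in every report. Benjamini–Hochberg correction is applied across the
tested sets; the top 12 sets are reported.

## Motif enrichment

PWMs are JASPAR-style count matrices normalized on load with pseudocount
0.01. A window scores Σᵢ log₂(pᵢ(base)/bg(base)); a hit requires
score ≥ 0.8 × the maximum attainable score, both strands scanned (reverse via
reverse complement, positions reported on the forward strand), windows
containing N skipped, and a PWM whose maximum score is not positive can match
nothing. Per motif, enrichment is a two-proportion z-score of the fraction of
foreground regions with ≥ 1 hit against the same fraction in a matched-
shuffle background of identical length multiset, with the background
fraction clamped to [1/(2n_bg), 1 − 1/(2n_bg)]. This statistic is a fully
specified ranking score for motif enrichment, not an emulation of any
external tool's Z score; no numeric agreement with externally published
motif scores is claimed, only the ranking semantics (the biologically planted
motif rises to the top).

## Transcriptome

Size factors are median-of-ratios: per sample, the median over reference
genes (nonzero in every sample) of count/geometric-mean. A poscounts-style
fallback (`pseudo_reference=True`) takes geometric means over nonzero entries
and per-sample medians over observed genes, for datasets with no all-nonzero
gene. The estimator is cross-checked against an independent reference
implementation in the test suite. Note the absolute factors are only defined
up to the geometric-mean normalization; the invariant property is that factor
*ratios* are scale-equivariant.

Filtering removes genes whose normalized count is below 4 in **every**
sample ("never expressed"); a stricter any-sample rule is available by flag.
Retained values are log₂(x + 1).

Differential expression is a deliberately simple negative-binomial Wald test,
not a reimplementation of a full DE framework: per gene, normalized group
means μ_a, μ_b; log₂FC = log₂((μ_b + 0.5)/(μ_a + 0.5)); method-of-moments
dispersion from the pooled within-group variance, clipped to [10⁻⁸, 10],
shrunk 50/50 toward a least-squares trend α(μ) = a₀ + a₁/μ fitted over
informative genes; delta-method variance of the log₂ group means using
Var(K/sf) = μ/sf + αμ²; BH across genes; a gene passes at FDR ≤ 0.05 and
|log₂FC| ≥ 2. Genes with zero counts in both groups are excluded. Under a
null 2v2 NB simulation (2 000 genes, dispersion 0.05) the test's p < 0.05
fraction sits near 0.05–0.06 — acceptably calibrated for an approximate test
with two replicates per group. At some seeds a single null outlier gene can
pass both thresholds; with n = 2 per group that residual false-positive risk
is inherent to the design and is reported, not suppressed.

## Concordance

Pearson correlations are computed between sample columns (log1p CPM of reads
in consensus regions, or filtered log expression); zero-variance columns
yield missing values, never 0. Hierarchical clustering is complete-linkage
agglomeration on d = 1 − r; labels are sorted lexicographically before
agglomeration, which is the documented deterministic tie-break. Dendrograms
export as Newick and merge tables; complete linkage guarantees monotone merge
heights.

## Synthetic study design

The generator emulates a four-sample, five-factor (AR, FOXA1, CTCF, H3K27ac,
H3K27me3) study on a 3 × 1 Mb genome with uniform random sequence, driven by
one seed through named substreams (genome, regions, genes, fragments,
expression, motifs, callers, gene sets, intensity) so streams regenerate
independently.

* **Regions.** 500 core sites plus 100 specific sites per sample, widths
  log-normal (median 300 bp, σ = 0.15, clipped to [150, 600]), placed
  disjointly with ≥ 2 kb separation so that ±2 kb signal windows never
  contain a neighboring planted site. Regions occupy the first 72% of each
  chromosome; the remainder is a deliberate gene desert. The specific-site
  scaffold is shared by AR, FOXA1 and CTCF (pioneer-factor co-binding at the
  same enhancers), but FOXA1 and CTCF each occupy only a ~60% random
  repertoire of the scaffold, constant across samples, and every TF has its
  own per-site log-normal (σ = 0.5) binding-strength multiplier shared across
  samples — this is what makes read-count correlation structure factor-driven
  rather than sample-driven.
* **Fragments.** 65-bp single-end fragments: Poisson background at
  0.003 fragments/bp plus, at each enriched site, exactly its planted
  intensity in fragments (core = 3 × the specific intensity of 40), placed
  with a triangular center distribution for a peaked profile. Deterministic
  per-site counts make the truth table exact (region → intensity) and keep
  the planted signal tiers compact; the stochastic parts are placement and
  background.
* **Histone mark.** H3K27ac covers all core sites and the planted "active"
  half of every sample's AR-specific sites — in every sample, independent of
  AR occupancy (the enhancer stays active where the factor is absent). Active
  enhancers come in two tiers (strong = core-level, moderate =
  specific-level), a coarse emulation of the mark's wide dynamic range.
  H3K27me3 is background-only coverage and never gets peak calls.
* **Callers.** Caller-1 emits the planted peaks; caller-2 is the same set
  shifted uniformly within ±50 bp with 5% dropout, so the dual-caller
  intersection is non-trivial without modeling caller internals.
* **Motifs.** A 15-bp steroid-response-like consensus is written into core
  sites with probability 0.8 and specific sites with 0.3; the emitted JASPAR
  library holds the planted PWM plus nine random decoys.
* **Genes.** 40% of genes anchor their TSS 0.5–1.5 kb from a core site, 20%
  from a specific site, 40% sit in the desert — so nearest-TSS linkage is
  informative (a dense uniform gene layout would put ~80% of genes in every
  query and no planted overlap could reach significance). The hallmark-like
  and essential-gene sets draw 85% of their members from core-linked genes;
  six random sets are controls.
* **Expression.** Negative-binomial counts (dispersion 0.05), gene means
  log-normal (median 100, σ = 1.5), per-sample library factors uniform in
  [0.7, 1.4]; exactly two genes differ between samples {S1,S2} and {S3,S4}
  at |log₂FC| = 3 (one up, one down), from a base mean of 60.

What passing the recovery suite shows: the pipeline's operations compose
correctly and recover planted structure of realistic shape at toy scale. What
it does not show: robustness to GC and mappability bias, copy-number-driven
coverage (the generator is copy-number-flat), fragment-length artifacts,
caller disagreement beyond jitter/dropout, or genome-scale multiple-testing
behavior. The noise null is length-matched but not composition-matched, as
in the real analysis.

## Problem sizes and determinism

Default synthetic scale (3 Mb genome, ~900 regions, ~20 fragment tracks of
roughly 10⁵ fragments, 200 genes) was chosen so the full pipeline runs in
tens of seconds on one CPU while keeping every test statistic far from its
decision boundary. All randomness flows from explicit seeds; reruns with an
unchanged configuration are byte-identical, and the acceptance script derives
every substream from its single `--seed`.
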