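# Methods

This note documents the statistical procedures, their assumptions, the
parameters that matter, and the design decisions taken where the design
was genuinely open. The package analyses synovial B cells from early
rheumatoid arthritis: index-sorted Smart-seq2 single-cell transcriptomes,
Visium-style spatial sections from paired tissue, and reconstructed paired
BCR chains.

## Synthetic study (`synth`)

Real data of this kind is controlled-access, so the generator is a
first-class module producing inputs with the statistical structure each
downstream stage assumes, along with the planted truth needed to score
recovery exactly. What it emulates — and what it does not — bounds what
green tests prove: passing shows the algorithms recover planted structure
of the modeled kind at realistic noise levels, not that they are robust to
everything real tissue adds (ambient RNA, doublets, segmentation error,
spatially smooth gradients, isotype-dependent expression).

**Single cells.** Endogenous counts are negative binomial with per-gene
dispersion drawn from a log-normal prior (this gives the spike-in trend a
nontrivial mean–variance shape to fit) and a per-cell log-normal capture
efficiency (sd 0.25). Three transcriptional programs — naive, memory,
plasma — multiply their genes' means by a fold change (6, 6, 8). Each
program spans its canonical markers (e.g. XBP1/SDC1/PRDM1/SLAMF7/JCHAIN
for plasma cells) plus 40 co-regulated auxiliary genes: real
transcriptional programs span dozens of genes, and that breadth is what
makes clusters separable and type profiles identifiable. Program genes
draw their baseline means from a tighter, higher prior than filler genes
because lineage markers are well-expressed in their lineage; with the
long-tailed shared prior an entire program occasionally landed near zero
and the type became unidentifiable. ERCC spike-in rows share fixed
abundances scaled only by efficiency. Dropout zeroes endogenous entries
with probability 0.10. Empty control wells (and a planted 5% of
low-quality cells) carry ~1% background signal; their QC metrics draw from
the same degradation distribution (reads ×~0.01, detected genes ×~0.02)
— that resemblance is the premise of the QC filter, so the planted bad
cells *define* what the filter must catch. Defaults: 2000 genes, 50
spike-ins, 150/300/100 cells per cluster, 8 empty wells — an order of
magnitude below the real study's 3468 cells × ~20k genes, chosen so the
full pipeline runs in well under a minute while every statistical
structure is preserved.

**Index sort.** Log-normal IgD/CD27/CD19/CD138 intensities with
subset-specific means (naive IgD-high CD27-low; memory IgD-low CD27-mid;
plasma CD27-very-high CD138-high), sd 0.22 on the log10 scale — wide
enough to overlap, separated enough that KDE valley gating is
well-defined.

**Spatial sections.** Two sections (one per donor/serostatus) of 24×24
spots in three rectangular regions — lymphocyte infiltrate, plasma-cell
niche, stroma. Spot counts are Poisson around depth × (mixture-weighted
sum of normalized cell-type profiles) × a per-section gene-wise batch
factor (log-sd 0.1). Every cell type has three distinct abundance levels
across the regions: a type confined to a single region of three caps the
achievable truth-vs-score Spearman at √(3pq) ≈ 0.82 purely through ties,
which would make score recovery ill-posed by construction. Spot depth is
8000 expected UMIs with log-sd 0.3 spot-to-spot variation, as in real
Visium where local tissue density drives severalfold depth differences;
this variation also identifies the per-gene depth slopes of the NB
normalization (with constant expected depth those slopes are fitted on a
~1% depth range and amplify Poisson noise into dominant pseudo-structure).
The niche region's CXCL12 mean is elevated 10-fold, mimicking the
CXCL12–CXCR4 plasma-cell survival axis.

**BCR repertoire.** Germline V/J segments are synthetic stand-ins for IMGT
alleles (fixed stop-free random codons, 294/48 nt; labelled synthetic in
code). Each planted clone family shares heavy and light V/J calls; member
sequences are germline V+J with exactly n point substitutions confined to
the V segment, byte-identical within a "sequence group" (identical
siblings) and at distinct positions otherwise. The default repertoire
mirrors the study's clone-size spectrum: families of 21 (16 identical), 5,
4, 3, 2, 2 with memory/plasma splits, isotypes along the class-switch
order, plus 30 singleton background cells on distinct V/J combinations.
One family reproduces the structure of an autoreactive clonotype: two
identical plasma siblings plus one similar memory member, 39/27 heavy/light
mutations.

## QC filter (`scqc`)

Count-valued metrics are log1p-transformed, all metrics z-scored, PC1
computed by SVD and sign-oriented so the control-well mean is at the low
end (fallback without controls: positive loading on detected genes). The
threshold is mean(control scores) + k·SD (default k = 3, exposed as a
margin parameter); how the original analysis placed its cut along PC1 is
not recorded, so tying it to the empty-well distribution is our explicit,
overridable rule. Ties at the threshold are excluded (conservative). The
kept/excluded partition is invariant to row order and to affine rescaling
of any metric (z-scoring), and a cell cannot be excluded by increasing its
detected-gene count in practice, because PC1 is oriented toward quality.

## Normalization and variable genes (`scnorm`)

Technical factors: per-cell spike totals rescaled to mean 1. Biological
factors: cells ordered by library size on a ring; each contiguous pool
(sizes 21–101, clipped to n) contributes one equation
Σ_pool f = median ratio of pooled profile to the average pseudo-cell; the
stacked system is solved by least squares with low-weight library-size
anchors for identifiability, negative solutions replaced by library-size
factors. With fewer cells than the smallest pool the method falls back to
library-size factors outright. Expression is log2(x/f + 1); endogenous
rows use biological factors, spike rows technical ones.

The technical trend is a tricube-weighted local linear smooth (span 0.6)
through the spike-ins' (mean, variance) of log-expression, clipped at
zero, with the tail above the variance peak projected to be monotone
decreasing (isotonic); evaluation outside the spike domain returns the
boundary value. A parametric family a·m/(mⁿ + b) is available when fewer
than five distinct spike means exist. Per endogenous gene, technical
variance is trend(mean) and biological variance the remainder — an
identity, so they always sum to the total.

The significance test treats the smoothed trend as the true technical
variance: (n−1)·total/tech is referred to chi-squared(n−1), one-sided.
This is the infinite-denominator-df limit of the variance-ratio F test and
is exactly calibrated when the trend is accurate (the trend averages many
spike-ins, so its estimation error is negligible next to a single gene's);
an F(n−1, n−1) reference would be conservative by an order of magnitude
here. At the null, a variance ratio of exactly 1 gives p ≈ 0.47 at n = 40
rather than exactly 0.5 — the price of calibration. FDR is
Benjamini–Hochberg; the selection rule is bio > 0.5 (strict) and
FDR ≤ 0.05.

## Clustering and gates (`sccluster`)

The clustering space is the top-10 PCs of HVG log-expression (UMAP is kept
for display; clustering a 2-D embedding is metrically worse, though a
`cluster_on="umap"` option exists). k-means uses k = 5 with 10 restarts
and a fixed seed. The original 5→3 merge was decided visually; our stated
surrogate assigns each k-means cluster the program with the highest mean
z-scored signature score (defaults: naive IGHD/IL4R/FCER2; memory
ITGAM/GPR183/CD27/TNFRSF13B; plasma XBP1/SDC1/PRDM1/SLAMF7/JCHAIN) and
merges clusters sharing a program, erroring loudly if a program wins no
cluster. Top-20 DEGs rank genes by the average of the two pairwise
log2-mean differences, ties broken lexicographically, reported with
per-cluster detection fractions.

Flow gates partition cells on IgD/CD27 with a CD27++ stratum that takes
precedence over the 2×2 quadrants (plasma cells are IgD− CD27++).
Thresholds default to KDE valley detection on log10 intensities (one
valley for IgD, two for CD27), overridable, because the original gates
were manual and unreported.

## Spatial analysis (`spatial`)

Per-section normalization fits, per gene, a Poisson log-linear model
μ = exp(b0 + b1·log10 depth) by vectorized Newton iterations, estimates an
NB dispersion by method of moments, regularizes log-dispersion by a
tricube smooth over log gene mean, and emits Pearson residuals
(y−μ)/√(μ+μ²/θ) clipped to ±√n_spots. All-zero genes are dropped. On a
gene proportional to depth under Poisson noise the residuals have mean ≈ 0
and variance ≈ 1.

Integration concatenates common-gene residuals, takes 30 PCs, removes each
batch's global offset, then iterates a soft k-means (10 clusters,
temperature at the within-cluster scale) whose E-step is multiplied by a
batch-diversity penalty — each batch's responsibility in a cluster is
scaled by (expected/observed)^θ with θ = 1 — followed by per-cluster
per-batch centroid shifts toward the cluster centroid, until the largest
shift is below 1e−4 (≤ 20 iterations). The diversity term is essential:
without it a batch-pure cluster receives a zero shift and twin clusters
from different batches never merge.

Spot clustering builds a k-NN graph (k = 20), reweights edges by the
Jaccard overlap of neighbor sets, prunes below 1/15 and runs multilevel
Louvain at resolution 0.8 (these are the conventional defaults of the
pipeline family used in the original analysis; all exposed). The Louvain
implementation draws from Python's global `random`; the seed is set and
restored locally, so results are reproducible. Cluster markers use
one-vs-rest Wilcoxon rank-sum on log1p depth-scaled counts, BH per
cluster, retaining log2FC > 1 (fold change on expm1 means) and adjusted
p < 0.05 — both strict.

NMF is our own multiplicative-update implementation (Frobenius objective)
because the per-iteration error trace is part of the contract (the
objective is provably non-increasing and asserted as such); it is
cross-checked against scikit-learn's MU solver in the tests. The input is
residuals shifted by their global minimum (how non-negativity was achieved
originally is unstated; a counts-based path is a one-liner via the same
function). ORA is an upper-tail hypergeometric test per GMT term with BH
across terms.

## Integration (`integrate`)

Signature enrichment runs, per gene, Kruskal–Wallis across the included
clusters (targets ∪ comparators; non-listed clusters are excluded
entirely — the alternative reading of the ambiguous original phrasing can
be had by listing them) and Dunn pairwise z-tests of each target against
each comparator, with tie-corrected pooled-rank variance and Bonferroni
adjustment over the full pairwise family. A gene is enriched when its
fold change (ratio of expm1 means) exceeds 1 against every comparator and
the worst adjusted Dunn p is below 0.01. On fully null data ≤ 2% of genes
pass at these cut-offs.

Fisher's exact test on the 2×2 overlap table uses the sample odds ratio
ad/bc (∞ and 0 conventions for zero cells; an error when both products
vanish) and a two-sided p summing all hypergeometric probabilities not
exceeding the observed one (with the standard 1+1e−7 tolerance); it is
verified against exhaustive enumeration for every table with universe
≤ 50.

Spot scoring replaces anchor-based label transfer with non-negative least
squares of each spot's expression (over the signature-gene union) on
cell-type mean profiles, coefficients renormalized to sum to one; this is
a transparent, testable surrogate that produces exactly what the original
transfer was used for — per-spot type scores to correlate.
Rank-deficient profile matrices get a 1e−6 ridge with a warning;
all-zero solutions become uniform scores. Co-localization is Spearman
correlation of the reference type's scores against every type over all
pooled spots (per-section averaging is an option; whether the original
pooled or averaged is unstated). Gene overlays return raw counts keyed by
array position.

## BCR analysis (`bcr`)

Pair filtering keeps productive, full-length chains above an expression
cutoff, takes the highest-expression chain per locus, and emits a pair
only for exactly one surviving heavy and one light, logging every cell's
disposition. Clonotypes group pairs within a donor by gene-level heavy and
light V/J (allele suffixes like \*01 stripped — published clonotype calls
are allele-ambiguous; an allele-level key is available). CDR3 identity is
deliberately not part of the key; clone numbers within a clonotype label
distinct heavy+light nucleotide sequence pairs, ordered by multiplicity
then sequence. An "identical sibling" is a memory member whose heavy+light
nucleotide sequences and heavy constant-gene call match a plasma member
exactly (the strictest reading of "identical variable and constant chain
pair"); other memory members of a plasma-containing clonotype are
"similar". Clonality fractions divide clonotype members by the donor's
memory+plasma total and are also reported as integer percentages.

SHM counts aligned non-gap mismatches within the V-segment interval.
Isotype ranks follow the heavy-locus class-switch order IGHM < IGHD <
IGHG3 < IGHG1 < IGHA1 < IGHG2 < IGHG4 < IGHE < IGHA2. Glycosylation
sequons are overlapping N-X-[S/T] with X ≠ P; introduced sites are sequon
positions absent from the aligned germline. Trees are neighbor-joining on
p-distances of gap-padded concatenated heavy+light sequences (a pairwise
p-distance stands in for a full multiple alignment), negative branch
lengths clamped at zero. The index-hopping check counts member pairs in
8-neighborhood-adjacent wells of the same plate and permutes member
positions over the plate's occupied wells (add-one p-value); the original
check's exact statistic is unpublished, so ours is a stated surrogate.

## Pipeline (`pipeline`)

A single YAML config drives synth → scqc → scnorm → sccluster → spatial →
integrate → bcr; optional stages are skipped and noted. Stages exchange
only serialized artifacts under `out/<stage>/`, and a manifest records
SHA-256 hashes of every artifact — two runs with the same config and seed
are byte-identical (asserted in the tests). The global seed feeds every
stochastic stage through stable CRC-derived sub-seeds.

## Numerical choices and limitations

Tolerances: batch-correction stopping at max shift < 1e−4; NMF relative
objective improvement < 1e−6 (tests use tighter); NNLS ridge 1e−6 only on
rank deficiency. Tie-breaks are lexicographic wherever a ranking is
emitted. Degenerate inputs (no controls, single section, < 5 spikes,
singleton clusters, constant score vectors) warn and fall back or error as
documented per function.

Known limitations: the NB depth regression needs real depth variation to
identify slopes (guaranteed by the generator, true of real Visium, but a
constant-depth matrix will normalize poorly); the marker-score 5→3 merge
presumes the k-means clusters are program-alignable and errors otherwise;
the chi-squared variance test assumes the spike trend is estimated much
more precisely than single-gene variances; NNLS scoring assumes reference
profiles on the same linear scale as the spots' depth-normalized counts;
and none of the biological claims of the original study (autoreactivity,
niche biology) are reproduced here — only the computational procedures
that support them.
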