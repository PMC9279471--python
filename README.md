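# synbcell

Integrated analysis of synovial B cells at the onset of rheumatoid
arthritis: quality control, spike-in-aware normalization and clustering of
index-sorted Smart-seq2 single-cell RNA-seq; clustering and factorization
of Visium-style spatial transcriptomics sections; single-cell/spatial
signature integration with co-localization statistics; and paired
B-cell-receptor (BCR) clonotype and clonality analysis.

The package is aimed at computational immunologists who want the full
multi-stage analysis as reusable, tested library code. Because the study
data of this kind is controlled-access, a first-class synthetic-data
module (`synbcell.synth`) generates inputs with the same statistical
structure — three B-cell transcriptional programs, ERCC spike-ins, empty
control wells, multi-section spot grids with a CXCL12-high plasma niche,
and clonal families spanning the memory and plasma compartments — with
every planted truth returned, so each stage's recovery can be scored
exactly.

## The methods in brief

* **QC** (`scqc`): per-cell quality metrics (reads, Q30, failed-FastQC
  count, mapped reads/genes/length, spike-in reads) are log1p-transformed,
  z-scored and projected on PC1, oriented so empty control wells sit at the
  low end; cells scoring below mean(controls) + k·SD are excluded.
* **Normalization** (`scnorm`): technical size factors from ERCC spike-in
  totals; biological size factors by deconvolution of ring-pooled profiles;
  log2(x/f + 1) expression. A tricube local-regression trend through the
  spike-ins' (mean, variance) estimates each gene's technical variance;
  biological variance is total − trend(mean), with a chi-squared
  variance-ratio test and BH-FDR. Highly variable genes satisfy
  bio > 0.5 and FDR ≤ 0.05.
* **Clustering** (`sccluster`): UMAP for display; k-means (k = 5) in
  top-PC space, each cluster assigned the marker program
  (naive / memory / plasma) with the highest mean scaled signature score
  and same-program clusters merged; top-20 DEGs by average pairwise log2
  fold change; IgD/CD27 flow gates (CD27++ stratum takes precedence) and a
  cluster × gate contingency table.
* **Spatial** (`spatial`): per-section regularized-NB Pearson residuals;
  Harmony-style iterative batch correction in PC space with a
  batch-diversity penalty; shared-nearest-neighbor Jaccard graph + Louvain
  communities; one-vs-rest Wilcoxon cluster markers (log2FC > 1,
  adj. p < 0.05); 20-factor multiplicative-update NMF with hypergeometric
  over-representation analysis of top factor genes against a GMT file.
* **Integration** (`integrate`): Kruskal–Wallis + Dunn post-hoc
  (Bonferroni) cluster signatures (FC > 1, adj. p < 0.01); Fisher's exact
  overlap between signature sets; per-spot cell-type scores by non-negative
  least squares on signature genes; Spearman co-localization; raw-count
  overlays (e.g. CXCL12, VIM).
* **BCR** (`bcr`): pair filtering by completeness/expression; clonotypes
  keyed on gene-level heavy/light V-J usage within donors; numbered clones
  for distinct nucleotide sequences; identical-sibling detection across the
  memory/plasma compartments; per-donor clonality fractions; SHM counting
  over the aligned V segment; class-switch isotype ranks; N-X-[S/T]
  glycosylation sequons; neighbor-joining trees; a permutation test
  against index hopping between neighboring wells.

## Worked example

```python
import numpy as np, pandas as pd
from synbcell import synth, scqc, scnorm, sccluster, bcr

cfg = synth.SynthConfig(seed=1)
cem, qc = synth.generate_sc_counts(cfg)

res = scqc.run_qc(qc)                      # PC1 filter vs. empty wells
keep = res.keep_mask & ~cem.obs["is_control"]
counts = cem.counts[:, keep.to_numpy()]

tech = scnorm.spike_size_factors(counts, cem.is_spike)
bio = scnorm.pooled_size_factors(counts[~cem.is_spike])
expr = scnorm.normalize(counts, bio, cem.is_spike, tech)
spikes = expr[cem.is_spike]
trend = scnorm.fit_technical_trend(spikes.mean(1), spikes.var(1, ddof=1))
dec = scnorm.decompose_variance(expr[~cem.is_spike], trend,
                                np.array(cem.gene_names)[~cem.is_spike])
hvgs = scnorm.select_hvgs(dec)
print(len(hvgs))                           # 794 highly variable genes

chains, truth = synth.generate_bcr(cfg)
pairs, _ = bcr.filter_pairs(chains)
clonotypes = bcr.group_clonotypes(pairs)
largest = max(clonotypes, key=lambda c: c.size)
print(largest.size)                        # 21 members in the largest clone
frac, pct = bcr.clonality_fraction(70, 753)
print(pct)                                 # 9 (percent of memory+plasma cells)
```

The QC step keeps all 522 intact cells and removes every planted
empty-well-like library; the 794 selected genes include all planted
program genes; the largest planted clone family (21 members, 16 sharing an
identical receptor) is recovered exactly, and a clonotype with 70 members
among 753 memory and plasma cells is a 9% clonal fraction.

End-to-end runs are driven by a YAML config:

```
synbcell validate --config run.yaml
synbcell run --config run.yaml --out out/
```

which executes synth → scqc → scnorm → sccluster → spatial → integrate →
bcr, each stage reading only the previous stages' serialized artifacts,
and writes a manifest with SHA-256 hashes (two runs with the same config
and seed are byte-identical).

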