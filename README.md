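# metabolokit

A desk-scale Python library and command-line toolbox for metabolomic data
analysis: data processing, study-design-driven univariate statistics,
knowledge-based and data-driven network construction, high-scoring
subnetwork discovery, and set-level functional analysis. It targets
feature-by-sample intensity tables as produced after peak picking and
compound identification (e.g. GC-TOF-MS profiles), and is equally usable
on proteomic or transcriptomic matrices.

## What it does

**Processing.** Log/power transforms; sample-based normalization (total
signal, sample metadata such as dry mass, per-batch reference medians, and
QC-LOESS drift correction: per feature and batch, a locally weighted
polynomial regression of pooled-QC intensity on injection order, span
chosen by leave-one-out cross-validation, with batch alignment to a common
QC median); feature scaling (auto, Pareto, range); PCA overview.

**Statistics.** A declared study design (two-group / multi-group /
two-way, independent / paired / mixed) selects the appropriate tests
automatically — Welch-family parametric defaults with non-parametric
alternatives (Mann-Whitney, Kruskal-Wallis + Dunn-Bonferroni, Friedman +
Wilcoxon-Bonferroni), Games-Howell/Tukey post hocs, Greenhouse-Geisser
correction for repeated measures, Type II two-way ANOVA with an optional
20%-trimmed robust variant and simple-main-effect follow-ups. P-values
are Benjamini-Hochberg adjusted across features (pFDR); bootstrap testing
and noncentral-distribution power analysis (a priori n / post hoc power)
are included.

**Networks.** Pairwise correlation networks (Pearson/Spearman/Kendall,
|r| > 0.7 default threshold), full-order shrinkage partial correlations,
and Tanimoto chemical-similarity networks from substructure fingerprints
(`T(a,b) = |a∩b| / |a∪b|`). A flat-file property graph (genes, proteins,
compounds, microRNAs, pathways with typed relations such as CATALYSIS,
CONVERSION, CONTROL, ANNOTATION) supports single- and mixed-relation
neighbourhood queries, e.g. gene → enzyme → compound paths.

**Subnetwork scoring.** Per-entity p-values are modelled as a
beta-uniform mixture `f(p) = λ + (1−λ)·a·p^(a−1)`; the FDR-controlled
threshold `τ` yields additive node scores `s(p) = (a−1)(ln p − ln τ)`,
and a prize-collecting heuristic finds a connected subgraph of maximal
total score (the active module).

**Enrichment.** Functional class scoring (Fisher, Stouffer, Reporter
with background standardization, median, mean) with entity-permutation
significance, hypergeometric overrepresentation analysis with Fisher
combination across node types, and term-frequency summaries.

## Worked example

Simulate a paired two-group study (100 features, 20 subjects measured in
both conditions, 10 features carrying a standardized effect of d = 2),
log-transform, and test with the design-appropriate paired procedure:

```sh
metabolokit simulate dataset --seed 7 --out data --n-features 100 --n-samples 20
metabolokit process --in data/intensities.tsv --sample-meta data/sample_meta.tsv \
    --out norm.tsv --transform log2
metabolokit stats --in norm.tsv --sample-meta data/sample_meta.tsv \
    --out stats.tsv --design two_paired --group group
```

which prints

```
11 significant feature(s) at pFDR < 0.05
```

— the paired Welch t test on within-subject differences recovered the
10 planted effect features (plus one false positive at the 5% FDR level;
`data/truth.tsv` holds the ground truth). Asking the engine what it would
run for this design:

```
$ metabolokit stats --design two_paired --group group --suggest
Welch's t test on difference [parametric] (default)
Mann-Whitney U test on difference [nonparametric]
t test on difference [parametric]
- P-values adjusted for FDR correction using Benjamini-Hochberg procedure
```

`stats.tsv` is a per-feature table (statistic, df, p, pFDR, mean
difference, log2FC). From there, `metabolokit network corr --threshold
0.7` builds the correlation network, `metabolokit network subnet` scores
its nodes from the p-values and extracts the high-scoring subnetwork, and
`metabolokit enrich fcs --method reporter` tests pathway sets. Multi-stage
runs can be described in one YAML config for `metabolokit run`.

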