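# Methods

This note documents the models and procedures implemented in
metabolokit, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the numerical choices that
matter for reproducibility.

## Data model

The central object is a feature × sample intensity matrix of
non-negative reals with aligned per-sample metadata (group factors,
subject id for pairing, batch label, integer injection order, sample type
∈ {biological, qc, blank}) and per-feature annotations. Missing cells
are preserved as missing and never imputed implicitly; every analysis is
complete-case per feature. This is a deliberate choice where common
practice varies (minimum-value imputation, half-minimum, model-based):
complete-case analysis makes no distributional claim about values below
the detection limit, at the cost of per-feature sample-size variation.
Identifiers are plain strings in a single user-supplied namespace; an
identifier-mapping operation (two-column table, one-to-many expansion
with warning) covers translation between naming systems.

## Processing

**Transforms** are elementwise: log2 / log10 / ln (requiring strictly
positive intensities — a zero is an error naming the offending cell, not
a silent pseudo-count) and power with a positive exponent.

**Sample normalization.** `sum` divides each sample by its total signal
and rescales by the median of all totals, so corrected values stay on
the original intensity scale. `metadata` divides by a positive numeric
per-sample covariate (e.g. dry mass), rescaled by its median.
`batch_median` divides each sample feature-wise by the median vector of
designated reference samples within its batch; "reference" is a
user-chosen sample type (QC by default) because the data alone cannot
say which samples anchor a batch.

**QC-LOESS drift correction.** Instrument response drifts over the
injection sequence; pooled QC samples injected at intervals trace that
drift. Per feature and per batch the QC intensities are regressed on
injection order with a locally weighted polynomial (degree 2, tricube
weights); the span is selected per feature and batch from the grid
{0.3, 0.4, …, 1.0} by leave-one-out cross-validation on the QC points
(minimum squared prediction error). Every sample is divided by the
fitted curve at its injection order and rescaled to the across-batch QC
median, which simultaneously aligns batches to a common level. At least
4 QC samples per batch are required; features with fewer non-missing QC
values pass through uncorrected with a warning. Degree 2 with a
CV-chosen span tracks both monotone and slowly curving drift while the
span floor of 0.3 prevents interpolating QC noise. A fitted curve that
reaches zero or below marks the affected positions missing rather than
producing negative intensities.

**Feature scaling**: auto `(x−m)/s`, Pareto `(x−m)/√s`, range
`(x−m)/(max−min)`, with `s` the n−1 sample standard deviation; constant
features scale to 0 with a warning. The conventional pipeline order is
transform → sample normalization → feature scaling; each stage is
equivariant under feature/sample permutation.

**PCA** operates on centered samples × features (full SVD); it refuses
missing values rather than imputing behind the user's back.

## Statistics

A `DesignSpec` names one of seven study designs; `suggest_methods`
returns the matching ordered method list with the parametric default
first, the non-parametric alternative flagged, and the follow-up
procedures. Welch-family tests are the defaults throughout because
heteroscedasticity across biological groups is the norm in intensity
data, and the Welch statistic coincides with the Student one in the
balanced homoscedastic case anyway. All tests are two-sided.

Specifics worth recording:

- **Mann-Whitney** switches from the exact null distribution to the
  normal approximation (tie-corrected, continuity-corrected) when the
  combined sample size exceeds 20 or ties are present.
- **Paired designs** test the within-subject difference against zero
  (one-sample t; Wilcoxon signed-rank as the rank-based alternative).
- **Welch ANOVA** uses the heteroscedastic F with Welch-Satterthwaite
  denominator degrees of freedom (implemented directly; cross-checked
  against an independent implementation in the test suite).
- **Repeated-measures ANOVA** reports the Greenhouse-Geisser epsilon
  computed from the double-centered condition covariance and the
  epsilon-adjusted p-value; epsilon is exactly 1 for two conditions.
- **Two-way ANOVA** uses Type II sums of squares (an OLS fit), chosen
  over Type I/III because it is order-invariant and sensible without a
  significant interaction; the robust variant applies 20% symmetric
  trimming within each cell before the same fit. Simple main effects of
  the first factor within levels of the second are computed when the
  interaction p < 0.05 (unadjusted), BH-adjusted across levels.
- **Post hocs**: Games-Howell (per-pair Welch df, studentized-range
  reference) or Tukey after parametric multi-group tests; Dunn's
  rank-based z with tie correction and Bonferroni adjustment after
  Kruskal-Wallis; pairwise Welch-Bonferroni or Wilcoxon-Bonferroni for
  repeated measures.
- **BH adjustment** is the step-up procedure applied across features
  (and separately across terms in enrichment).
- **Bootstrap p-values** resample group labels: `p = (1 + #{|stat*| ≥
  |stat|})/(B+1)`, B ≥ 100, seeded.
- **Power analysis** uses noncentral t/F distributions; a-priori mode
  returns the smallest integer per-group n reaching the target power
  (e.g. d = 1, α = 0.05, power 0.8 → n = 17 per group).

Features with too few complete observations are reported as NA rows with
a note, never dropped silently.

## Networks

**Correlation networks** use pairwise-complete observations with a
minimum of 5 shared samples per pair; thresholding is on |r| (default
0.7) and the signed coefficient is kept as the edge weight, so strong
negative associations are retained as edges.

**Partial correlations** are full-order: the sample correlation matrix is
shrunk toward the identity with an analytic intensity (the ratio of the
summed sampling variances of the off-diagonal correlations to their
summed squares, clipped to [0,1] — zero for well-conditioned data, rising
automatically as p approaches n), inverted, and standardized to
`−prec_ij/√(prec_ii·prec_jj)`. A limited-order estimator would scale to
larger panels but is stochastic; the full-order shrinkage estimator is
deterministic and testable against the 3-variable closed form.

**Tanimoto networks** compare binary substructure fingerprints
(881-bit PubChem-style space by default, supplied as explicit bit-position
lists so no live chemistry service is needed); all-zero fingerprints are
excluded with a warning.

**BUM scoring.** P-values from the statistics stage are fitted by
maximum likelihood to `f(p) = λ + (1−λ)·a·p^(a−1)` (L-BFGS-B over a 3×3
grid of starts to avoid local optima; p = 0 clipped to machine epsilon).
With `π = λ + (1−λ)a` (the noise density at p = 1), the p-threshold for a
target FDR is `τ = ((π − FDR·λ)/(FDR·(1−λ)))^(1/(a−1))` and node scores
are `s(p) = (a−1)(ln p − ln τ)`: positive exactly below τ, monotone
decreasing in p. The default FDR feeding τ is 0.05. Identifiability
note: in the weak-signal corner (λ ≥ 0.9 with diffuse a ≥ 0.6) the
likelihood has a ridge along which (λ, a) trade off; single-draw
estimates there scatter more than elsewhere even though the fitted
likelihood matches or exceeds the generating parameters'. Recovery is
therefore assessed on replicate-averaged fits.

**Maximum-scoring subnetwork.** The search is a prize-collecting
expansion: starting from a top-scoring node, repeatedly attach the
positive-score node with the best net gain, where the gain charges the
cheapest chain of negative bridge nodes needed to reach it (multi-source
Dijkstra with node cost max(−s, 0)); then prune negative leaves whose
removal keeps the subgraph connected, and restart from each
positive-score node, keeping the best result. A simpler fixed-depth
lookahead was evaluated first and could not cross multi-node negative
bridges, falling to 72% of the exhaustive optimum on adversarial small
graphs; the path-based expansion attains the optimum on all 50 random
≤10-node test graphs while remaining near-linear per step. If every node
scores negative, the single best node is returned with a warning. Ties
break on sorted node ids, making the result deterministic.

## Knowledge graphs

Nodes are typed (gene, protein, compound, microRNA, pathway) and each
relation constrains its endpoint types (CATALYSIS: protein→compound;
CONVERSION: gene→protein; CONTROL: protein→gene or microRNA→gene;
BIOCHEMICAL_REACTION: compound→compound; MOLECULAR_BINDING:
protein→protein; GENETIC_ASSOCIATION: gene→gene; ANNOTATION: pathway→any
molecular entity). Loading validates the schema and rejects dangling
endpoints. Queries collect edges of the requested relation type(s)
within k hops of the seed entities (k = 1 by default, up to 3),
traversing edges in both directions; mixed-relation queries deliberately
chain different relation types across hops — that is what lets a gene
seed reach the compounds of its enzyme product (gene −CONVERSION→
protein −CATALYSIS→ compound). Pathway ANNOTATION edges can be exported
as annotation sets per entity type for the enrichment module.

## Enrichment

Functional class scoring works from the per-entity statistics table
without any significance cutoff. Set statistics: Fisher `−2Σln p`;
Stouffer `Σ Φ⁻¹(1−p)/√k`; Reporter = Stouffer Z standardized by the mean
and standard deviation of Z over 1000 random same-size entity sets;
median and mean of the entity statistics. Significance is by entity
permutation — random same-size draws from the universe — with
`p = (1 + #{perm ≥ obs})/(n_perm + 1)`, one-sided on the set statistic,
BH-adjusted across terms. Entity permutation (rather than sample
permutation) is used because it operates on the statistics table alone,
keeping enrichment runnable from any externally produced table; the
trade-off is that inter-entity correlation is not preserved under the
null, as with all gene-sampling schemes. ORA is the upper-tail
hypergeometric test `P(X ≥ k)` of a selected list against a universe;
for networks mixing node types, each type is tested against its own
universe and per-term p-values are Fisher-combined across types.

## Synthetic data generator

The generator emulates a GC-TOF-MS-style two-group study: log-normal
intensities (baseline log2 mean 10, SD 0.5), per-observation noise
SD 0.5 on the log2 scale, optional shared subject effects for paired
designs, group effects expressed as standardized shifts d of the
analysed contrast (the within-subject difference for paired designs),
batch structure with multiplicative drift over the injection sequence
(linear decay or smooth sinusoidal wander, 30% relative amplitude by
default — strong enough that successful correction is unambiguous),
pooled QC samples every 5 injections with noise SD 0.125 (pooled
material varies far less than biology), and optional uniform missingness.
Default study conditions: 100 features, 20 samples per group, paired, 10
features carrying d = 2 — a strong, clearly detectable metabolic signal.

It does **not** emulate: intensity-dependent (left-censored)
missingness, correlated feature blocks / pathway co-regulation,
heteroscedasticity across groups, retention-index or spectral structure,
or batch-specific feature dropout. Passing tests on this generator
therefore demonstrate correctness of the procedures under clean
log-normal conditions, not robustness to every artefact of real data.

All generators are deterministic under their seed and return ground
truth sufficient for recovery metrics.

## Problem sizes and runtime choices

The test-suite and acceptance-script simulations use: 2000 null features
per test family for type-I calibration (binomial 99% band around 0.05);
n = 5000 p-values × 3 replicates per point for the 3×3 BUM recovery
grid; 2000 replicates for the empirical-power check; 100 features × 30
QC-anchored injections for drift correction; 50 random ≤10-node graphs
against exhaustive connected-subgraph search. These sizes give Monte
Carlo error comfortably below the assertion tolerances while keeping a
full run in tens of seconds.

## Known limitations

- No multivariate/classification statistics (PLS-DA, clustering) beyond
  the PCA overview.
- The knowledge-graph store is schema plus flat files; no pre-compiled
  organism database ships with the package.
- Mixed and two-way repeated ANOVA delegate to pingouin; unbalanced
  mixed designs inherit its conventions.
- FCS entity permutation ignores inter-entity correlation (see above).
- Complete-case handling can leave low-coverage features underpowered;
  an explicit imputation step is the user's responsibility.
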