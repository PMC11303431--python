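# Methods

`coexmod` re-implements, as a tested and reusable pipeline, the desk-side half of a
candidate-nomination study for regulators of a leaky plaque microvasculature: weighted
co-expression module discovery on a bulk transcriptome, correlation of module summary
profiles with quantitative histology (microvessel density and related traits), hub-gene
ranking inside trait-correlated modules, dual Pearson/MIC ranking of omics features
against a trait, and set-overlap testing. This note records the models, the defaults and
why they are what they are, what the synthetic cohorts do and do not emulate, and the
numerical conventions.

## Weighted co-expression network

Features are correlated across samples (Pearson by default; Spearman available).
Constant features get correlation 0 with everything, which isolates them in the network
instead of propagating NaNs. The correlation matrix is soft-thresholded into a weighted
adjacency

* unsigned (default): `a_ij = |cor(x_i, x_j)|^beta`
* signed: `a_ij = ((1 + cor(x_i, x_j))/2)^beta`

The power `beta` is scanned over {1..10, 12, 14, 16, 18, 20}. For each candidate the
connectivity distribution `k_i = sum_{j != i} a_ij` is tested for scale-free shape:
connectivities are discretized into 10 equal-width bins, `log10` of the bin frequency is
regressed on `log10` of the bin mean connectivity, and the fit R² is reported with the
sign of the slope negated, so a decaying degree distribution scores positively.
`pick_power` takes the smallest power with signed R² ≥ 0.8 (the community convention),
falling back to the argmax with a warning.

**Power cap.** The scale-free fit index is a noisy statistic, and on cohorts where most
features are unstructured it can keep climbing toward extreme powers at which the whole
network disconnects — at which point any fixed clustering threshold downstream collapses
to "everything unassigned". The pipeline therefore caps the applied power at the widely
used sample-size recommendation (unsigned: 9 / 8 / 7 / 6 for n < 20 / 30 / 40 / ≥ 40
samples; signed: doubled). `pick_power` itself is untouched; the cap is applied by
`run_pipeline` and logged when it binds.

Adjacency is converted to the topological overlap matrix

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),   l_ij = sum_{u != i,j} a_iu a_uj

with diagonal 1 and a zero denominator mapped to 0. TOM credits shared neighbours, which
averages away much of the pairwise sampling noise; `1 − TOM` is the clustering
dissimilarity. Matrices are dense with a hard cap of 20,000 features.

## Module detection

Average-linkage hierarchical clustering on `1 − TOM` (scipy), followed by a **static
height cut**: branches below the cut height become clusters, clusters smaller than
`min_module_size` (default 30) are relabelled "grey" (unassigned). A static cut is fully
specifiable and deterministic, which is what makes the module boundary testable; the
adaptive dynamic tree cut is out of scope.

**Cut height default 0.98.** Measured on the default synthetic cohort at the capped
power, within-module mean TOM dissimilarity spans roughly 0.88–0.98 across cohort draws
(a module whose latent factor happens to have low realized variance sits at the top of
that range), while unstructured features only aggregate into clusters of `min_size` near
dissimilarity ~0.995. A cut at 0.95 sits inside the within-module tail and silently
drops whole weak-but-real modules on a noticeable fraction of draws; 0.98 is the highest
round value that still sits below the noise floor. The cost is that a surviving module
occasionally absorbs a few noise features; both effects are visible in the
`analysis/04_recovery_benchmarks.py` output. The height remains a config knob.

Modules are labelled `M1, M2, ...` in decreasing size order (ties: smallest member
feature ID); a WGCNA-style color alias table is emitted for familiarity.

**Eigengenes.** A module's eigengene is the first principal component (SVD) of its
standardized expression submatrix, rescaled to unit sample variance, and sign-oriented
to correlate non-negatively with the module's average standardized profile. If that
average is exactly orthogonal (a two-feature module with mirrored profiles), the
eigengene is oriented positively toward the lexicographically smallest member — a
deterministic tie-break, so reruns are bit-identical. Variance explained is the leading
eigenvalue share. Module membership `kME_{g,m}` is the correlation of gene `g` with
eigengene `m`.

**Merging.** Modules whose eigengenes correlate at ≥ 1 − 0.2 are merged iteratively,
closest pair first, with eigengenes recomputed after every merge (so chains collapse
transitively), then relabelled by size.

## Trait association

Module–trait cells are Pearson correlations of eigengenes with traits (the convention
for eigengene work); per-cell samples with a missing trait value are dropped pairwise
and cells with fewer than 3 complete pairs are reported absent. P-values use the
two-sided Student-t transform `t = r sqrt(n−2)/sqrt(1−r²)` with `n−2` df; `|r| = 1` maps
to p = 0. Raw p-values are reported by default (matching how such heatmaps are usually
read); Benjamini–Hochberg adjustment is available by flag. An `auto` method applies the
Shapiro–Wilk test at alpha = 0.05 to each variable and uses Pearson only when both pass,
Spearman otherwise — the standard convention for correlating qPCR/protein measurements.
Gene significance (GS) is the same machinery applied per feature.

## Candidate ranking

* **Hub ranking** inside a chosen module: members are ranked by `|GS|` (descending) and
  by centrality (descending); the combined score is the mean of the two ranks, with ties
  broken by the better GS rank, then feature ID. Centrality defaults to intramodular
  connectivity kIM computed on the **TOM-weighted** subnetwork (shared-neighbour weights
  are steadier than raw adjacency at cohort-scale n); kME is the alternative.
* **Dual ranking**: every feature is scored by Pearson r (pairwise-complete) and by MIC;
  the top-k lists (default k = 100; k = 10 in the synthetic studies) under `|r|` and
  under MIC are intersected and cross-referenced against annotation gene sets. Features
  with fewer than 8 complete pairs are excluded (MIC needs that much resolution).
  Identifier matching is case-sensitive with an opt-in uppercase normalization.
* **Set overlap**: one-sided hypergeometric upper tail `P(X ≥ k)` for an overlap of `k`
  between sets of size `K` and `n` in a universe of `N`, plus fold enrichment
  `(k/n)/(K/N)`. The upper tail is the standard choice for enrichment-style questions
  (e.g. a differential-expression list against a module's gene set).

## Maximal information coefficient

MIC is implemented from scratch (`coexmod.mic`), since it is the second ranking measure
of the dual procedure. For `n` complete pairs and budget `B(n) = ceil(n^alpha)` (alpha =
0.6), all grid sizes `r × s` with `r, s ≥ 2` and `r·s ≤ B(n)` are considered; the
normalized score is `I*(r, s) / log2(min(r, s))` and MIC is the maximum over sizes.
`I*` is approximated by the published heuristic: equipartition one axis into equal-count
bins (ties kept in one bin), then optimize the other axis exactly by dynamic programming
over clump boundaries (runs of consecutive points sharing a row of the fixed axis),
with the number of candidate clumps capped at `c` times the column budget (c = 15).
The DP is exact over its candidate boundaries because mutual information decomposes as
`H(rows)` plus a per-column-bin sum. The score is symmetrized by taking the maximum over
both axis orientations, making `mic(x, y) == mic(y, x)` exact.

Grids are defined on ranks with the original index as a deterministic tie-break (no
jitter), so MIC is invariant to strictly monotone transformations of either variable to
1e−12, and bit-reproducible. A constant input returns 0 with a warning; fewer than 8
pairs is an error. `mic_oracle` (n ≤ 12) maximizes exhaustively over **all** grids with
boundaries between consecutive rank-ordered points and `r·s ≤ max_cells ≤ 16`; because
its search space is a superset of the heuristic's on these sizes, `oracle ≥ heuristic`
is an invariant the test suite checks on 200 random instances. Note the exact MIC of a
finite sample need not reach 1 on noiseless data when `n` is odd (equal-count rows
cannot be balanced); the exactness check uses even `n`.

Only MIC is implemented from the MINE family; MAS/MEV/MCN are out of scope.

## Synthetic cohorts

The generator (`coexmod.simulate`) draws the statistical shape the analysis assumes,
with ground truth recorded for every draw:

* **Expression**: one standard-normal latent factor per module; feature `g` of module
  `m` is `x_g = beta·f_m + eps`, `eps ~ N(0, noise_sd²)`, then all features are
  standardized. Population within-module correlation is `beta²/(beta² + noise_sd²)`.
  Defaults — 40 samples, 5 modules × 50 features, loading 0.8, noise sd 0.6 (within-
  module correlation 0.64), 750 noise features — mirror the 22–43-patient scale of the
  cohorts this pipeline is meant for while keeping test runs at seconds scale.
  `hub_loading` plants, as the first feature of each module, a higher-fidelity copy of
  the factor with population correlation `hub_loading` exactly
  (`x = beta·f + sqrt(1 − beta²)·eps`); the regular members' factor correlation is
  `loading/sqrt(loading² + noise_sd²)`, so the hub is defined on the same (correlation)
  scale the ranking operates on.
* **Traits**: a linked trait is `rho·f_m + sqrt(1 − rho²)·N(0,1)` (population
  correlation exactly `rho`; `|rho| = 1` returns the factor itself); null traits are
  independent normal; missing-at-random masking is available. Default: MVD linked to M1
  at rho = 0.7 plus 4 null traits.
* **Peptides**: linear (`t`), parabolic (`(t − mean)²`) and sinusoidal (`sin(omega t)`)
  functions of a target trait, each standardized to unit variance before adding
  `N(0, noise_sd²)` noise — so `noise_sd` is signal-relative — among independent-normal
  noise features. Default 5/5/0 planted among 190 noise features at sd 0.3.
* **Symmetric target**: the dual-ranking studies use a target built by mirroring
  uniform(0, √3) draws, which is exactly zero-centered and symmetric (any even function
  of it has exactly zero sample covariance with it) and uniformly spread, the convention
  of functional-relationship benchmarks. A plain normal draw is only symmetric in
  distribution; its sample skew leaks parabolic signal into the Pearson ranking and its
  central clustering starves the parabola's arms.

What the generator does **not** emulate: probe-level microarray artifacts, batch and
background effects, overlapping or nested modules (one factor per module), heavy-tailed
or count-distributed intensities, censored/ordinal traits, and trait–trait correlation
structure. Passing the recovery benchmarks therefore shows the pipeline recovers the
factor-model structure it targets at realistic cohort scale — not that it is robust to
everything real cohorts do.

## Numerical conventions and edge cases

* Variances and standardization use denominator `n − 1` throughout.
* Quantile normalization equalizes each sample's value distribution to the mean sorted
  profile; ties within a sample receive the mean of the reference quantiles they span.
  With ties whose pattern differs across samples, one pass cannot land exactly on a
  fixed point (tie-averaging perturbs the row's value multiset); on tie-free data the
  operation is exactly idempotent, which is what the property test asserts.
* Tables are written as TSV with full (`%.17g`) float precision; reruns of the pipeline
  on identical inputs and config are byte-identical (manifests carry no timestamps).
* Probe collapse (`none` | max-variance probe per gene) is exposed as a config option
  without claiming fidelity to any upstream convention.
* Feature filtering keeps the `top_n = 10,000` most variable features by default (ties
  broken by feature ID); the option can be disabled.

## Study sizes used by the scripted analyses

The numbered drivers under `analysis/` and `scripts/acceptance.py` use: 10 seeds for
module recovery, 20 for trait anchoring and hub recovery, 200 (acceptance) or 50
(driver) for null calibration, 50 null draws at n = 200 for the MIC null level, 200
small instances for the oracle bound, and 10 seeds for dual-ranking discrimination.
These sizes put each study at seconds-to-minutes scale on a single CPU.

## Known limitations

* The static cut has no concept of branch shape; very unbalanced module sizes or
  correlated factors can still mis-partition (the eigengene merge step catches the
  worst of it).
* The hub-recovery benchmark is sensitive to the gene-significance sampling noise at
  n = 40: with the planted hub at factor correlation 0.95 against members at 0.8, the
  hub's population GS edge is ~0.66 vs ~0.56, and its combined top-5 probability per
  cohort is ~0.85 — informative but not saturated.
* MIC's heuristic is an approximation; it can undershoot the exhaustive maximum (never
  overshoot it on matched budgets), and small-n null MIC is substantially above zero
  (median ~0.2 at n = 200, higher at n = 40), which is why rankings compare features at
  a common n rather than thresholding MIC absolutely.
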