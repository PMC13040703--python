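# Methods

`gutliver` implements the statistical core of a cross-compartment
microbiome-metabolome-phenotype integration for 2x2 (genotype x diet) rodent
MASH studies: four groups (WT-ND, WT-WD, KO-ND, KO-WD; default n = 6, 6, 8,
8), feature tables per compartment (liver, small- and large-intestinal
contents, plasma) and omics layer (taxa, predicted enzymes, metabolites),
plus continuous phenotype markers (ALT, hepatic triglyceride, ...).

## Group statistics

The two-way ANOVA for the unbalanced 2x2 design is written in cell-means
form. With cells ordered (WT-ND, WT-WD, KO-ND, KO-WD), each effect is a
contrast `c` over cell means: genotype (1/2, 1/2, -1/2, -1/2), diet
(1/2, -1/2, 1/2, -1/2), interaction (1, -1, -1, 1). Then
`SS = L^2 / sum(c_i^2 / n_i)` with `L = sum(c_i m_i)`, tested against the
pooled within-cell mean square `MSE = sum((n_i - 1) s_i^2) / (N - 4)` on
(1, N-4) df. For a 2x2 these contrasts are exactly Type III sums of squares,
the only convention that is order-free here; the formulation needs only
per-cell (mean, SD, n), so published summary tables can be re-analyzed
without raw data. `anova2_from_raw` simply computes the cell summaries first,
and the two routes agree to 1e-9 (property-tested, plus an effect-coded OLS
Type III oracle from statsmodels).

A caveat for summary-based reconstruction: printed summaries are rounded.
For markers whose interaction contrast `L` is small relative to the rounding
step (e.g. a fold-change marker with L ~ 0.2 printed at 2 decimals), the
reconstructed F carries ~20% input-rounding uncertainty; the test suite
propagates worst-case rounding bounds instead of pretending to more
precision than the print carries.

All-pairs comparisons: Tukey-Kramer (studentized range on the pooled MSE,
unequal n) and Steel-Dwass (per-pair tie-corrected standardized rank sums
referred to the studentized range with df = infinity via `q = |z|*sqrt(2)`;
the large-sample form, standard at n = 6-8). Group flag letters follow the
convention a: p < 0.05 vs WT-ND, b: vs WT-WD, c: vs KO-ND. Both tests are
computed for every marker and disagreements logged, since which test applies
to which marker is a per-marker judgement.

## Differential profiling

Per feature: two-sided Wilcoxon rank-sum (exact by enumeration when there
are no ties and min(n) <= 12, otherwise the tie- and continuity-corrected
normal approximation), Benjamini-Hochberg adjustment within one
(table x comparison) family, and `log2(mean_B / mean_A)` on the original
scale. A zero group mean is replaced by half the smallest positive value in
the table (deterministic, scale-aware); features undetected in both groups
are excluded before BH with a logged count. "Marked" features satisfy
q < 0.05 AND |log2FC| >= 2.5; the two filters commute.

## Diversity and ordination

Alpha: Shannon in bits (base 2; configurable), richness as detected-feature
count, Pielou J = H / log2(richness) (missing when richness <= 1). Group
comparison by tie-corrected Kruskal-Wallis with the chi-square reference
(k-1 df). Note the exact Wilcoxon level at (6, 8) is 0.0426 and the KW
chi-square level at (6,6,8,8) about 0.0415 — both slightly conservative,
as expected for small-sample rank tests at nominal 0.05.

Beta: binary Jaccard, Bray-Curtis, unweighted and weighted UniFrac (the
UniFrac pair via scikit-bio, requiring a rooted tree covering all observed
features; weighted UniFrac unnormalized by default, normalization available).
PCoA is classical scaling: eigendecomposition of the double-centered squared
distance matrix, axes ordered by eigenvalue, negative eigenvalues dropped
from both coordinates and the variance denominator with a logged note. PCA
of metabolite tables is implemented as PCoA on Euclidean distances of
per-feature standardized data, which equals classical PCA up to axis sign
(used as a test oracle both ways). PERMANOVA uses the within/between
squared-distance pseudo-F and a seeded permutation p-value with the add-one
convention, so p >= 1/(n_perm + 1).

## LDA effect-size ranking

A defined two-class variant of the LDA effect-size procedure for
differential taxa: total-sum scaling to 1e6 per sample; Kruskal-Wallis
screen at alpha = 0.05; then `n_boot` (default 30) rounds in which
ceil(2n/3) samples per class are subsampled without replacement, features
constant within the draw receive tiny Gaussian jitter (sd 1e-5 of the data
scale), and a two-class LDA with the pooled covariance shrunk 10% toward its
diagonal gives, per feature, effect = |class-mean difference + coefficient x
projected class difference| / 2. The score is log10(max(1, mean bootstrap
effect)); sub-unit effects floor at 0. The subclass stage of the original
multi-level procedure is omitted because the comparisons here are plain
two-group. Ranking takes the top k = 10 by |score|, ties broken by screen
p then feature id.

## Weighted correlation network

Input features from all compartments/layers are concatenated as rows over
the shared samples (ids prefixed `compartment/layer:` to keep origin).
Stages:

- **Robust Z**: per feature `(x - median) / (1.4826 * MAD)`; if MAD = 0 the
  sample SD is used; still-constant features are excluded with a log entry.
- **Adjacency**: unsigned `A_ij = |rho_ij|^beta` with tie-corrected Spearman
  rho (Pearson of midranks); default beta = 4. Unsigned is chosen because
  the downstream axis step thresholds absolute correlations. A scale-free
  fit report (log-log degree regression R^2 over a beta grid, equal-width
  connectivity bins, R^2 >= 0.8 else curve-stabilization else grid max) is
  available; the configured beta always takes precedence.
- **TOM**: `TOM_ij = (l_ij + A_ij) / (min(k_i, k_j) + 1 - A_ij)`, `TOM_ii = 1`;
  clustering uses dissTOM = 1 - TOM.
- **Module detection** (deterministic): average-linkage dendrogram; the cut
  height is chosen by scanning merge heights (capped at their 0.99 quantile)
  for the cut maximizing first the number of clusters of at least
  `min_module_size` (default 30) and then their feature coverage; branches
  are recursively split where the top internal merge-height gap exceeds the
  spread of the remaining internal heights; undersized clusters become
  background (label 0); finally a cohesion filter dissolves clusters whose
  median within-cluster TOM is less than 3x the median member-to-nonmember
  TOM. The ratio threshold separates by an order of magnitude in practice:
  chance agglomerations of independent features sit near 2, genuine
  one-factor modules at 7+ even at doubled noise. This stand-in for the
  usual dynamic tree-cut heuristic is validated by planted-module recovery,
  not by reproducing any particular empirical module count.
- **Eigengenes**: first principal component of the module's robust-Z rows
  across samples, scaled to unit variance (ddof = 1), sign-oriented so the
  mean correlation with member features is positive.
- **Merging**: iteratively fuse the closest module pair while eigengene
  dissimilarity 1 - cor < `merge_cut_height` (default 0.2), recomputing
  eigengenes after each merge; modules renumbered by decreasing size.

## Axis extraction

Module-phenotype association uses tie-corrected Spearman rho between each
eigengene and each phenotype (reported as absolute values with a >= 0.6
marker, after the usual presentation). A module is *selected* when some
phenotype reaches |rho| >= 0.6 AND its eigengene differs between KO-WD and
WT-ND (Wilcoxon p < 0.05) — both criteria logged per module. *Hepatic hubs*
are liver metabolites with q < 0.05 (strict) and |log2FC| >= 2.5 (inclusive)
that belong to selected modules (a flag lifts the membership restriction).
For each hub and each gut-side feature (SI or LI, any layer) in a selected
module, the Spearman rho across samples is computed; edges with
|rho| >= 0.6 form the SI-liver and LI-liver subnetworks (feature-to-hub
edges, module membership acting as a filter; threshold comparisons carry a
1e-12 epsilon because rho of perfectly monotone data returns 1 minus float
noise). Every emitted edge is re-asserted against all three thresholds.

## Synthetic studies

The generator is a one-factor-per-module latent Gaussian model — exactly
the structure the module/eigengene construct assumes, so recovery is a fair
test. Per sample and module: `f_m = mu_m(group) + N(0,1)` with
`mu_m = genotype_effect + diet_effect + interaction` in latent units.
A feature loaded on module m has log-signal
`baseline + loading * f_m + shift(group) + N(0, noise_sd)`; metabolite and
enzyme intensities are exponentials (log-normal, baseline ~ N(10, 1));
taxa use the same model on log-abundance (baseline ~ N(0, 2), so relative
abundances span realistic orders of magnitude), closed per sample to
relative abundances and optionally multinomially sampled at a sequencing
depth. Phenotypes are noisy linear combinations of the factors.

The planted KO-WD shift is `ln(2)*lfc - loading * (mu_m(KO-WD) - mu_m(WT-ND))`,
which makes the expected log2 ratio of group mean intensities equal the
requested fold change exactly. Two sampling caveats: the empirical fold
change of a *module* feature carries the shared O(1/sqrt(n)) deviation of
that study's factor-mean draw (about 0.19 log2 units at n = 200/group),
common to all members of the module, so convergence checks use background
features; and compositional closure distorts fold changes of taxa, so
planted-effect calibration applies to intensity layers.

Defaults mirror the study design: n = (6, 6, 8, 8), beta = 4, minimum
module size 30, merge cut 0.2, marked filter (2.5, 0.05), axis threshold
0.6, 30 LDA bootstraps, 999 permutations. What the generator does *not*
emulate: sequencing error, chimeras, PCR/batch effects, instrument drift,
heavy-tailed non-Gaussian factors, and compositional coupling between
layers; passing recovery tests therefore demonstrates correctness of the
pipeline's statistics under its own model assumptions, not robustness to
those real-data artifacts.

## Numerical and design choices

- Determinism: every stochastic stage (generator, LDA bootstrap, PERMANOVA)
  is driven by a config seed; repeated pipeline runs are byte-identical.
- File dialect: UTF-8 TSV, "." decimal; floats written via shortest-repr so
  write-read round trips are bitwise exact.
- Sample alignment across tables must be exact (the design has every mouse
  in every compartment); mismatches error with the offending ids rather
  than silently intersecting.
- Problem sizes in the recovery tests (a few hundred features, 25-50 seeds
  or replicates) were chosen as the smallest sizes at which the planted
  effects are comfortably identifiable under the stated noise levels.
- Degenerate inputs: constant features are excluded from the network with a
  log entry; all-zero samples report missing alpha diversity; an all-zero
  distance matrix yields PERMANOVA (F, p) = (0, 1) with a warning.

## Known limitations

- The module detector targets desk-scale inputs (<= ~5,000 features); no
  block-wise approximation for larger networks.
- Steel-Dwass uses the asymptotic studentized-range reference; exact
  enumeration is not implemented.
- No rarefaction or depth normalization; tables are consumed as provided.
- The LDA ranking has no multi-class one-against-all mode and no cladogram
  output.
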