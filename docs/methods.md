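# Methods

This note documents the models, estimators and numerical choices behind
`enterotyper`, what the synthetic cohort generator does and does not
emulate, and the package's known limitations.

## Distances and ordination

Profiles are compositional: each sample's genus (or KEGG-pathway)
abundances are renormalized to sum to one after adding a pseudocount
(default 10⁻⁶) to every entry. The pseudocount exists solely to make
profiles strictly positive for the Kullback–Leibler terms of the
Jensen–Shannon divergence; it perturbs each entry by at most ~3×10⁻⁵ for
a 30-genus profile and is configurable.

The Jensen–Shannon distance is d(p, q) = √JSD(p, q) with
JSD = ½KL(p‖m) + ½KL(q‖m) and m = (p + q)/2. Logarithms are taken in
base 2 by default, which bounds JSD by 1 and hence d by 1; base e is
available (the bound becomes √ln 2). √JSD is a true metric, which the
test suite checks by triangle-inequality sweeps. Bray–Curtis and
Euclidean distances are computed on the same normalized profiles, with no
log or count transform.

Principal coordinate analysis is classical scaling: double-center
−½D², eigendecompose, scale eigenvectors by the square roots of the
eigenvalues. JS and BC matrices need not be Euclidean-embeddable;
negative eigenvalues are clamped to zero and their summed magnitude is
reported, with no Lingoes/Cailliez correction — the ordination is used
for display, not inference.

## PAM clustering and cluster-number selection

PAM is the classical Kaufman–Rousseeuw k-medoids on the precomputed
distance matrix: BUILD greedily seeds medoids (first the sample with the
smallest total distance, then the sample giving the largest cost
reduction), and SWAP repeatedly applies the best strictly improving
(medoid, non-medoid) exchange until none exists. All ties break toward
the lowest sample index, so results are deterministic without a seed.
PAM is a local search: on unstructured point clouds roughly one instance
in ten ends in a local optimum that exhaustive medoid-set search beats
(the R reference implementation behaves identically on such instances);
on data with genuine cluster structure the optimum is reached reliably,
and the oracle tests verify exact agreement with brute-force search on
such instances.

The cluster number k (scanned 2..min(10, n−1) by default) maximizes a
medoid-based Calinski–Harabasz pseudo F-statistic:
W = Σᵢ d(xᵢ, medoid of cluster i)², B = Σⱼ nⱼ·d(medoidⱼ, overall medoid)²
(the overall medoid is the sample minimizing total distance to all
samples), CH = [B/(k−1)]/[W/(n−k)], with +∞ returned when W = 0 (exact
duplicate clusters). CH ties break toward smaller k. The mean silhouette
width is reported alongside with the Kaufman–Rousseeuw support bands
(≤ 0.25 none, ≤ 0.5 weak, ≤ 0.75 reasonable, else strong), but never
overrides the CH choice: two-cluster gut structure is routinely reported
at weak or no silhouette support, so SI is a quality qualifier, not a
veto. Note the tie-breaks make CH formally dependent on sample order in
degenerate configurations with exact total-distance ties (e.g. collinear
even-sized data); generic data are unaffected.

Clusters are relabeled by marker dominance: the cluster with the highest
mean *Bacteroides* abundance becomes enterotype 1, then the highest
remaining *Prevotella* cluster becomes enterotype 2, further clusters by
decreasing size. Absent markers trigger a size-ordered fallback with a
warning.

## LEfSe-style differential abundance

The published LEfSe description is informal, so the effect size used
here is stated exactly. Profiles are scaled to a per-sample sum of 10⁶
(the conventional scale that puts log₁₀ scores in the familiar 2–6
range). Features are screened by a two-sided Wilcoxon rank-sum test at
α = 0.01 — for two classes this is equivalent to the Kruskal–Wallis
test, and the implementation uses exact null enumeration when both
groups have ≤ 10 tie-free observations, the tie-corrected normal
approximation otherwise. The study design has no sub-classes, so the
LEfSe within-class (subclass) stage is a no-op and is omitted.

For surviving features, 30 bootstrap rounds subsample ⅔ of each class
(without replacement, at least two samples). Each round fits a pooled-
covariance linear discriminant w (unit norm); the pooled covariance gets
diagonal loading of 0.1·tr(S)/p whenever fitted (n < p is the norm
here), falling back to an absolute load when the trace is zero. A
feature's effect is

    effect_i = ( |Δμ_i| + |w_i|·|wᵀΔμ| ) / 2

— the mean of its raw class-mean gap and its share of the class
separation along the discriminant axis — and its score is
log₁₀ max(effect_i, 1), averaged over rounds and signed by the direction
of the full-data class-mean difference (negative = enterotype 1,
positive = enterotype 2). Features pass at |score| ≥ 2. Bootstrap
subsampling uses RNG streams keyed by the membership of each class, so
results are invariant to sample reordering and exactly antisymmetric
under class-label swaps.

## Twin statistics

Concordance is counted per paired observation — an (MZ pair, time point)
at which both co-twins were sampled — matching the convention in which a
pair sampled at two time points contributes two observations (a
10-pair/8-longitudinal design yields 18). Persistency is counted per
twice-sampled subject. Percentages are reported half-up to one decimal.

Distance comparisons classify every unordered sample pair into exactly
one of four sets: same subject across times, co-twins at the same time,
co-twins across times, unrelated individuals. The default test is a
two-sample permutation test on the pooled distance values (statistic:
difference of means; add-one estimator p = (1 + #extreme)/(1 + n_perm),
default n_perm = 10 000, default alternative "less" for the directional
question of whether related communities are closer). Distances sharing a
sample are not independent, so the naive pooling is anti-conservative in
principle; a subject-label permutation mode
(`twin_longitudinal.subject_permutation_test`) that permutes the design
labels across samples and rebuilds the sets each round is provided for
sensitivity analysis.

## Host associations

Traits, food-group intakes and nutrient intakes form three separate
multiple-testing families, each BH-adjusted on its own — the analyses
are reported per family, and pooling families would couple unrelated
hypotheses. Nutrients are energy-adjusted by the residual method:
ordinary least squares of each nutrient on total energy intake over
complete cases, residuals standardized to mean 0, sd 1 (sample sd);
residual sds below 10⁻¹⁰ of the data scale are treated as zero variance
and yield an all-zero column with a warning. Missing diet blocks are
never imputed; analyses use complete cases and log the n.

Diet-pattern clustering is UPGMA (average linkage) on Euclidean
distances over the standardized nutrient residuals, cut at two groups (a
fixed-count cut, not a height threshold), and tested against the
enterotype split with the two-sided Fisher exact test
(probability-mass rule). Discordant-twin comparisons use the Wilcoxon
signed-rank test on within-pair differences (enterotype-2 twin minus
enterotype-1 twin), dropping zero differences per the standard
convention, with exact sign-pattern enumeration for ≤ 10 tie-free
differences.

## Synthetic cohort generator

The generator emulates the statistical skeleton of an MZ-twin gut
metagenome study; defaults describe a 10-pair cohort, 8 pairs sampled at
two time points (36 samples):

| parameter | default | meaning |
|---|---|---|
| `n_pairs` | 10 | MZ twin pairs |
| `p_longitudinal` | 0.8 | fraction of pairs sampled at both times (deterministic count) |
| `pi2` | 0.583 | marginal probability of enterotype 2 |
| `rho_conc` | 0.722 | co-twin copies the index twin's enterotype |
| `rho_pers` | 0.813 | subject keeps its enterotype at time 2 |
| Dirichlet total concentration | 50 | within-enterotype dispersion (free parameter; no published estimate exists, this value gives clearly separated but overlapping components) |
| `n_diet_missing` | 4 | samples with the whole diet block missing |

Genus profiles are exact Dirichlet draws over 30 named genera:
enterotype 1 concentrates mass on *Bacteroides* (45%) with elevated
*Catenibacterium*; enterotype 2 on *Prevotella* (45%) with elevated
*Lactobacillus*, *Dorea* and *Coprococcus*; the remainder is uniform
filler. KEGG profiles use 20 pathway ids with five elevated pathways per
component. An optional multinomial read-resampling layer (`read_depth`)
adds count noise; it is off by default because the pipeline consumes
relative abundances.

Traits are Gaussian in original clinical units; only serum uric acid
carries an enterotype-2 shift by default (+1.8 mg/dL on sd 1.2).
Nutrients are linear in energy (energy ~ N(2000, 300) kcal/day) with
Gaussian noise; the nine diet variables the analysis targets (fiber,
potassium, iron, vitamins A/C/E, folate, carotene, retinol) carry a
+2.0·sd enterotype-2 shift. These effect sizes are chosen so the planted
associations are detectable at the default cohort size after BH
correction — i.e. the generator emulates a study in which these
variables *were* the significant ones; rank-based tests make the
Gaussian shape itself non-load-bearing.

The time-2 state is a symmetric two-state Markov step applied
independently per subject (only the marginal persistency is specified,
not direction-specific switch rates). A consequence worth knowing: pair
concordance at time 2 is diluted by the independent flips to
ρ_conc·(ρ_pers² + (1−ρ_pers)²) + (1−ρ_conc)·2ρ_pers(1−ρ_pers) ≈ 0.66 at
the defaults, so estimator-recovery checks measure concordance on
baseline (time-1) paired observations, where `rho_conc` is directly
identified.

What the generator does **not** emulate: phylogenetic or co-occurrence
structure among genera, genus–pathway coupling (genus and KEGG profiles
are drawn independently given the enterotype), longitudinal drift beyond
the one-step flip, diet–microbiome causal structure (nutrient shifts are
attached to the enterotype label, not to the community), or realistic
food-group correlations. Passing tests therefore demonstrate estimator
and pipeline correctness under the assumed two-component model — not
that real gut communities are two discrete clusters.

## Reproducibility

All stochastic stages accept explicit seeds; the pipeline driver fans a
single global seed into per-stage seeds by stable hashing of stage
names, so any stage can be re-run in isolation. The run summary JSON is
byte-identical for identical config + seed. Problem sizes used by the
verification scripts — 40-sample cohorts for clustering recovery,
500-pair cohorts for estimator recovery, 10³ replicates for permutation
calibration — were chosen to make sampling error small relative to the
tolerances being checked while keeping runs interactive.

## Limitations

* Enterotype discreteness is assumed, not tested: no gap statistic,
  Dirichlet-multinomial mixtures or gradient analyses are provided.
* The permutation default treats distances as exchangeable units; use
  the subject-permutation mode when dependence matters.
* CH is the medoid/squared-distance form defined above; other CH
  variants (e.g. on ordination coordinates) can select different k on
  the same data.
* The LEfSe effect size is this package's explicit formalization of an
  informally published procedure; scores are comparable within runs, not
  across tools.
* No phylogeny-aware distances (UniFrac) and no multi-class (>2)
  one-against-all LEfSe mode.
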