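# enterotyper

Enterotype analysis of gut microbial communities for twin cohorts:
cluster genus-level relative-abundance profiles into enterotypes, measure
monozygotic (MZ) twin concordance and longitudinal persistency, and test
associations of enterotypes with host biomarkers and long-term diet.

The package targets the classic study design in which fecal metagenomes
from MZ twin pairs — some sampled at two time points roughly two years
apart — are profiled to genus-level and KEGG-pathway relative abundances,
and the questions are: do the communities fall into *Bacteroides*- vs
*Prevotella*-dominated enterotypes, do co-twins share them, do they persist
over time, and which host traits and nutrient intakes track them?

## Methods at a glance

* **Distances.** Jensen–Shannon distance d(p, q) = √JSD(p, q) with
  JSD = ½KL(p‖m) + ½KL(q‖m), m = (p+q)/2 in log base 2 (so d ∈ [0, 1]),
  plus Bray–Curtis and Euclidean; profiles are pseudocounted (10⁻⁶) and
  renormalized first. Ordination by classical PCoA.
* **Clustering.** Partitioning around medoids (PAM), the deterministic
  Kaufman–Rousseeuw BUILD+SWAP on the distance matrix. The cluster number
  k maximizes a medoid-based Calinski–Harabasz pseudo-F,
  CH = [B/(k−1)] / [W/(n−k)] with W = Σᵢ d(xᵢ, medoidᵢ)² and
  B = Σⱼ nⱼ d(medoidⱼ, overall medoid)²; the mean silhouette width
  s̄ = mean (b−a)/max(a, b) qualifies cluster support. Clusters are
  relabeled so the *Bacteroides*-dominated one is enterotype 1 and the
  *Prevotella*-dominated one enterotype 2.
* **Differential abundance.** A LEfSe-style two-class procedure: a
  Wilcoxon rank-sum screen at α = 0.01 (exact small-sample null), then a
  bootstrapped regularized linear discriminant on profiles scaled to 10⁶
  per sample; features report a signed log₁₀ LDA score (negative =
  enterotype 1, positive = enterotype 2) thresholded at |score| ≥ 2.
* **Twin statistics.** Concordance = % of (pair, time) observations where
  both co-twins share the enterotype; persistency = % of twice-sampled
  subjects keeping theirs. Community distances are split into
  self-over-time / twin-same-time / twin-different-time / unrelated sets
  and compared by two-sample permutation tests (difference of means,
  add-one p-value).
* **Host associations.** Wilcoxon rank-sum per trait / food group /
  energy-adjusted nutrient (standardized OLS residuals of nutrient on
  energy) with Benjamini–Hochberg correction within each family; UPGMA
  clustering of nutrient-residual profiles tested against enterotypes by
  Fisher's exact test; Wilcoxon signed-rank tests within
  enterotype-discordant twin pairs.
* **Synthetic cohorts.** `enterotyper.synthetic_data` generates twin
  cohorts with the full latent structure (two Dirichlet community
  components, pair concordance, time-2 persistence, trait and nutrient
  shifts), so every stage is testable without sequence data.

## Worked example

```bash
enterotyper simulate --out-dir sim --seed 7
```

writes `genus.tsv`, `kegg.tsv`, `design.tsv`, `metadata.tsv` and
`truth.tsv` for a 10-pair cohort (36 samples, 8 pairs sampled twice).
Then, with a config file

```yaml
# run.yaml
genus_path: sim/genus.tsv
kegg_path: sim/kegg.tsv
design_path: sim/design.tsv
metadata_path: sim/metadata.tsv
out_dir: out
seed: 7
```

```bash
enterotyper run-all --config run.yaml
```

prints (numbers from this exact seed):

```
Clustering (js distance):
  enterotype 1: 17/36 (47.2%)
  enterotype 2: 19/36 (52.8%)
  selected k: bc=2, eu=2, js=2
Twin concordance: 13/18 (72.2%)
Persistency over time: 13/16 (81.3%)
  self_over_time_vs_unrelated: mean diff -0.1053, P = 0.0057
  twin_same_time_vs_unrelated: mean diff -0.0989, P = 0.0066
  twin_diff_time_vs_unrelated: mean diff -0.0734, P = 0.0393
Functional clusters (KEGG): k = 2
LEfSe: 6 differential features
  Bacteroides: score -5.51 (enriched in enterotype 1)
  Prevotella: score +5.51 (enriched in enterotype 2)
  Dorea: score +5.01 (enriched in enterotype 2)
  ...
Significant nutrient associations (adj. P < 0.05): nutrient_carotene,
  nutrient_fiber, nutrient_folate, nutrient_iron, nutrient_potassium,
  nutrient_retinol, nutrient_vitamin_a, nutrient_vitamin_c, nutrient_vitamin_e
```

Every distance metric selects two clusters; 13 of the 18 co-twin
observations share an enterotype (72.2%) and 13 of 16 twice-sampled
subjects keep theirs (81.3%); within-subject and within-pair community
distances are shorter than between unrelated individuals; *Bacteroides*
and *Prevotella* are the top discriminating genera with opposite signs;
all nine planted nutrient shifts are recovered after energy adjustment
and BH correction.
`out/summary.json` holds the same numbers machine-readably, and
`out/*.tsv` the per-sample assignments, CH/SI scans, PCoA coordinates and
association tables.

The library API mirrors the stages — see `enterotyper.distances`,
`enterotyper.clustering`, `enterotyper.differential_abundance`,
`enterotyper.twin_longitudinal`, `enterotyper.host_association`.

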