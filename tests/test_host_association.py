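from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

from enterotyper import host_association as ha
from enterotyper.io_core import MetadataTable, ValidationError
from enterotyper.synthetic_data import CohortSpec, generate_twin_cohort
from enterotyper.twin_longitudinal import paired_observations


def exact_ranksum_p(x, y):
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    observed = ranks[:n1].sum()
    sums = np.array([sum(ranks[list(c)]) for c in combinations(range(len(pooled)), n1)])
    return min(1.0, 2 * min(np.mean(sums <= observed), np.mean(sums >= observed)))


def exact_signed_rank_p(diffs):
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    stats = np.array(
        [np.sum(ranks * signs) for signs in product([0, 1], repeat=len(d))]
    )
    return min(1.0, 2 * min(np.mean(stats <= observed), np.mean(stats >= observed)))


def meta_of(frame, **kwargs):
    return MetadataTable(frame, **kwargs)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert ha.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(ha.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_monotone_and_bounded(self, rng):
        p = rng.random(30)
        adj = ha.bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            ha.bh_adjust([0.5, 1.5])


class TestWilcoxonAssociation:
    def _meta(self, values, trait="x"):
        df = pd.DataFrame({trait: values}, index=[f"s{i}" for i in range(len(values))])
        return meta_of(df, trait_cols=[trait])

    def test_identical_groups_p_one(self):
        meta = self._meta([5.0, 5.0, 7.0, 5.0, 5.0, 7.0])
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=meta.sample_ids)
        res = ha.wilcoxon_association(meta, labels, "trait")
        assert res.loc[0, "p"] == 1.0
        assert res.loc[0, "higher_in"] == 0

    def test_separated_groups_match_enumeration_oracle(self):
        meta = self._meta([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=meta.sample_ids)
        res = ha.wilcoxon_association(meta, labels, "trait")
        expected = exact_ranksum_p(np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]))
        assert expected == pytest.approx(0.1)
        assert res.loc[0, "p"] == pytest.approx(expected, abs=1e-12)
        assert res.loc[0, "higher_in"] == 2

    def test_uric_acid_is_top_trait_on_shifted_cohort(self, default_cohort, truth_labels):
        res = ha.wilcoxon_association(default_cohort.metadata, truth_labels, "trait")
        top = res.sort_values("p_adj").iloc[0]
        assert top["variable"] == "uric_acid"
        assert top["p_adj"] < 0.05
        assert top["higher_in"] == 2


class TestEnergyAdjust:
    def _meta(self, energy, nutrients):
        df = pd.DataFrame({"energy": energy, **nutrients},
                          index=[f"s{i}" for i in range(len(energy))])
        return meta_of(df, nutrient_cols=list(nutrients), energy_col="energy")

    def test_exact_linear_nutrient_gives_zero_residuals(self):
        energy = np.array([1500.0, 1800.0, 2000.0, 2400.0])
        meta = self._meta(energy, {"n1": 2 * energy})
        res = ha.energy_adjust(meta)
        np.testing.assert_allclose(res["n1"], 0.0, atol=1e-9)

    def test_residuals_standardized(self, rng):
        energy = rng.normal(2000, 300, 50)
        meta = self._meta(energy, {"n1": 0.01 * energy + rng.normal(0, 1, 50)})
        res = ha.energy_adjust(meta)
        assert res["n1"].mean() == pytest.approx(0.0, abs=1e-9)
        assert res["n1"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_energy_independent_nutrient_residual_tracks_raw(self, rng):
        energy = rng.normal(2000, 300, 500)
        raw = rng.normal(10, 2, 500)
        meta = self._meta(energy, {"n1": raw})
        res = ha.energy_adjust(meta)
        z = (raw - raw.mean()) / raw.std(ddof=1)
        assert np.corrcoef(res["n1"], z)[0, 1] > 0.99

    def test_too_few_complete_cases_rejected(self):
        meta = self._meta(np.array([2000.0, 2100.0]), {"n1": np.array([1.0, 2.0])})
        with pytest.raises(ValidationError, match="complete cases"):
            ha.energy_adjust(meta)


class TestNutrientCluster:
    def test_duplicated_points_split_cleanly(self):
        res = pd.DataFrame(
            [[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]],
            index=list("abcd"), columns=["n1", "n2"],
        )
        groups, _ = ha.nutrient_cluster(res, n_groups=2)
        assert groups["a"] == groups["b"]
        assert groups["c"] == groups["d"]
        assert groups["a"] != groups["c"]

    def test_upgma_merge_heights_match_hand_trace(self):
        # 1-D points 0, 1, 5, 7: merges at 1, 2, then mean(5,7,4,6)=5.5
        res = pd.DataFrame({"n1": [0.0, 1.0, 5.0, 7.0]}, index=list("abcd"))
        _, Z = ha.nutrient_cluster(res, n_groups=2)
        np.testing.assert_allclose(sorted(Z[:, 2]), [1.0, 2.0, 5.5])

    def test_associated_subset_aligns_better_with_enterotype(self):
        spec = CohortSpec(n_pairs=25, p_longitudinal=0.0, n_diet_missing=0, seed=42)
        cohort = generate_twin_cohort(spec)
        truth = cohort.truth.set_index("sample_id")["enterotype"]
        residuals = ha.energy_adjust(cohort.metadata)
        subset = [f"nutrient_{n}" for n in
                  ("fiber", "potassium", "iron", "vitamin_a", "vitamin_c",
                   "vitamin_e", "folate", "carotene", "retinol")]
        g_all, _ = ha.nutrient_cluster(residuals, n_groups=2)
        g_sub, _ = ha.nutrient_cluster(residuals, n_groups=2, subset=subset)
        t = truth.loc[residuals.index]
        assert adjusted_rand_score(t, g_sub) >= adjusted_rand_score(t, g_all)
        assert adjusted_rand_score(t, g_sub) > 0.2

    def test_missing_subset_nutrient_rejected(self):
        res = pd.DataFrame({"n1": [0.0, 1.0, 2.0]}, index=list("abc"))
        with pytest.raises(ValidationError, match="absent"):
            ha.nutrient_cluster(res, subset=["nope"])


class TestFisher:
    def test_balanced_table_p_one(self):
        groups = pd.Series([1, 1, 2, 2], index=list("abcd"))
        enterotypes = pd.Series([1, 2, 1, 2], index=list("abcd"))
        _, p, _ = ha.fisher_association(groups, enterotypes)
        assert p == 1.0

    def test_perfect_association_matches_hypergeometric_enumeration(self):
        idx = [f"s{i}" for i in range(10)]
        groups = pd.Series([1] * 5 + [2] * 5, index=idx)
        enterotypes = pd.Series([1] * 5 + [2] * 5, index=idx)
        _, p, table = ha.fisher_association(groups, enterotypes)
        # all tables with margins (5,5;5,5): only the two perfect ones are
        # as improbable as observed -> p = 2 / C(10,5)
        assert p == pytest.approx(2 / comb(10, 5), abs=1e-12)

    def test_transpose_invariance(self, rng):
        idx = [f"s{i}" for i in range(20)]
        groups = pd.Series(rng.integers(1, 3, 20), index=idx)
        enterotypes = pd.Series(rng.integers(1, 3, 20), index=idx)
        _, p1, _ = ha.fisher_association(groups, enterotypes)
        _, p2, _ = ha.fisher_association(enterotypes, groups)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_non_2x2_rejected(self):
        groups = pd.Series([1, 2, 3], index=list("abc"))
        enterotypes = pd.Series([1, 2, 1], index=list("abc"))
        with pytest.raises(ValidationError, match="2x2"):
            ha.fisher_association(groups, enterotypes)


class TestDiscordantTwins:
    def _cohort_obs(self, cohort):
        truth = cohort.truth.set_index("sample_id")["enterotype"]
        return paired_observations(cohort.design, truth)

    def test_all_positive_differences_match_sign_flip_enumeration(self):
        diffs = [1.0, 2.0, 3.0, 4.0, 5.0]
        from enterotyper._ranktests import signed_rank_p

        p, n = signed_rank_p(diffs)
        assert n == 5
        assert p == pytest.approx(2 / 32)
        assert p == pytest.approx(exact_signed_rank_p(diffs), abs=1e-12)

    def test_antisymmetric_differences_p_one(self):
        from enterotyper._ranktests import signed_rank_p

        p, _ = signed_rank_p([-2.0, -1.0, 1.0, 2.0])
        assert p == 1.0

    def test_null_cohort_rarely_flags_anything(self):
        # under the global null, BH's chance of any rejection is at most the
        # FDR level per family, so >= 90% of runs should come out clean
        clean_runs = 0
        runs = 20
        for seed in range(runs):
            spec = CohortSpec(
                n_pairs=12, p_longitudinal=0.0, rho_conc=0.0, n_diet_missing=0,
                nutrient_effects={"protein": (0.01, 0.0, 1.0), "fat": (0.01, 0.0, 1.0),
                                  "iron": (0.01, 0.0, 1.0)},
                seed=seed,
            )
            cohort = generate_twin_cohort(spec)
            res = ha.discordant_twin_test(
                cohort.metadata, self._cohort_obs(cohort), families=("nutrient",)
            )
            if not (len(res) and res["significant"].any()):
                clean_runs += 1
        assert clean_runs / runs >= 0.9

    def test_too_few_discordant_pairs_rejected(self, default_cohort):
        obs = self._cohort_obs(default_cohort)
        concordant_only = [o for o in obs if o.concordant]
        with pytest.raises(ValidationError, match="discordant"):
            ha.discordant_twin_test(default_cohort.metadata, concordant_only)


def test_parameter_recovery_sensitivity_and_fdp():
    """Variables flagged at adj. p < 0.05 recover the planted shifts
    (uric acid + 9 nutrients) with high sensitivity and controlled FDP."""
    true_set = {"uric_acid"} | {
        f"nutrient_{n}" for n in
        ("fiber", "potassium", "iron", "vitamin_a", "vitamin_c",
         "vitamin_e", "folate", "carotene", "retinol")
    }
    sens, fdp = [], []
    for seed in range(20):
        cohort = generate_twin_cohort(CohortSpec(seed=seed))
        truth = cohort.truth.set_index("sample_id")["enterotype"]
        flagged = set()
        for family in ("trait", "food", "nutrient"):
            res = ha.wilcoxon_association(cohort.metadata, truth, family)
            flagged |= set(res.loc[res["p_adj"] < 0.05, "variable"])
        sens.append(len(flagged & true_set) / len(true_set))
        fdp.append(len(flagged - true_set) / max(1, len(flagged)))
    assert np.mean(sens) >= 0.8
    assert np.mean(fdp) <= 0.2
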