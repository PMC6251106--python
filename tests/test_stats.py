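"""Statistical engines against hand-computed and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sociobiome.metrics import DistanceMatrix, DyadDistanceSet
from sociobiome.stats import (
    band_jsd_anova,
    dyad_mixed_model,
    indicator_analysis,
    mantel_kendall,
    permanova,
)

from conftest import rel_rows


def euclid_dm(values, ids=None):
    values = np.asarray(values, float).reshape(-1, 1)
    ids = ids or [f"s{i}" for i in range(len(values))]
    d = np.abs(values - values.T)
    return DistanceMatrix(ids, d, "euclidean")


ANOVA_VALUES = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
ANOVA_META = pd.DataFrame(
    {"group": list("AAABBB")}, index=[f"s{i}" for i in range(6)]
)


class TestPermanova:
    def test_univariate_euclidean_equals_classic_anova(self):
        # one-way ANOVA by hand: SSB = 121.5, SSW/df = 1 -> F = 121.5
        res = permanova(euclid_dm(ANOVA_VALUES), ANOVA_META, ["group"], n_perm=9, seed=0)
        assert res.table.at["group", "F"] == pytest.approx(121.5)
        assert res.table.at["group", "df"] == 1
        assert res.table.at["Residual", "df"] == 4

    def test_exhaustive_permutation_p(self):
        # 2 of the 20 distinct assignments reach the maximal F -> p = 0.1
        res = permanova(
            euclid_dm(ANOVA_VALUES), ANOVA_META, ["group"], permutations="exhaustive"
        )
        assert res.table.at["group", "p"] == pytest.approx(0.1)

    def test_monte_carlo_agrees_with_exhaustive(self):
        exact = permanova(
            euclid_dm(ANOVA_VALUES), ANOVA_META, ["group"], permutations="exhaustive"
        ).table.at["group", "p"]
        mc = permanova(
            euclid_dm(ANOVA_VALUES), ANOVA_META, ["group"], n_perm=999, seed=1
        ).table.at["group", "p"]
        assert abs(mc - exact) < 0.05

    def test_duplicated_term_gets_zero_sequential_ss(self):
        meta = ANOVA_META.assign(group2=ANOVA_META["group"].values)
        res = permanova(euclid_dm(ANOVA_VALUES), meta, ["group", "group2"], n_perm=9, seed=0)
        assert res.table.at["group2", "SS"] == pytest.approx(0.0, abs=1e-9)

    def test_r2_partition_sums_to_one(self, small_study, small_rel):
        from sociobiome.metrics import bray_curtis

        res = permanova(
            bray_curtis(small_rel), small_study["metadata"],
            ["band", "life_stage", "sex"], n_perm=19, seed=0,
        )
        assert res.table["R2"].drop("Total").sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_level_term_rejected(self):
        meta = ANOVA_META.assign(const="x")
        with pytest.raises(ValueError, match="single level"):
            permanova(euclid_dm(ANOVA_VALUES), meta, ["const"], n_perm=9)


def tau_b_brute_force(x, y):
    """Naive O(n^2) tie-corrected Kendall tau-b pair counting."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / np.sqrt((n0 - tx) * (n0 - ty))


class TestMantelKendall:
    def matrices(self, seed=0, n=5, tied=True):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, size=(n, n)).astype(float) if tied else rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        return a

    def test_perfect_concordance_and_discordance(self):
        a = self.matrices(seed=1, tied=False)
        ids = list("abcde")
        assoc = DistanceMatrix(ids, a, "assoc")
        up = DistanceMatrix(ids, 2 * a + 0.1 * (a > 0), "dist")  # positive affine off-diag
        down_vals = (a.max() + 1.0) - a
        np.fill_diagonal(down_vals, 0)
        down = DistanceMatrix(ids, down_vals, "dist")
        assert mantel_kendall(assoc, up, n_perm=19).tau == pytest.approx(1.0)
        assert mantel_kendall(assoc, down, n_perm=19).tau == pytest.approx(-1.0)

    def test_tau_matches_brute_force_with_ties(self):
        ids = list("abcde")
        a = self.matrices(seed=2)
        b = self.matrices(seed=3)
        res = mantel_kendall(
            DistanceMatrix(ids, a, "assoc"), DistanceMatrix(ids, b, "dist"), n_perm=19
        )
        tril = np.tril_indices(5, k=-1)
        assert res.tau == pytest.approx(tau_b_brute_force(a[tril], b[tril]), abs=1e-12)

    def test_mismatched_ids_rejected(self):
        a = self.matrices()
        with pytest.raises(ValueError, match="share ids"):
            mantel_kendall(
                DistanceMatrix(list("abcde"), a, "x"),
                DistanceMatrix(list("abcdf"), a, "y"),
            )

    def test_permutation_p_detects_planted_signal(self):
        rng = np.random.default_rng(4)
        pts = rng.random((12, 2))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        ids = [f"i{k}" for k in range(12)]
        sim = d.max() - d
        np.fill_diagonal(sim, 0)
        res = mantel_kendall(
            DistanceMatrix(ids, sim, "assoc"), DistanceMatrix(ids, d, "dist"),
            n_perm=199, seed=0,
        )
        assert res.tau == pytest.approx(-1.0)
        assert res.p_perm <= 0.01


def indval_brute_force(rel, labels):
    """Independent loop implementation of the two-group IndVal statistic."""
    groups = sorted(set(labels))
    out = {}
    for taxon in rel.columns:
        best_stat, best_g = -1.0, None
        for g in groups:
            members = [s for s, lab in zip(rel.index, labels) if lab == g]
            others = [s for s in rel.index if s not in members]
            mean_g = np.mean([rel.at[s, taxon] for s in members])
            mean_o = np.mean([rel.at[s, taxon] for s in others])
            a = mean_g / (mean_g + mean_o) if (mean_g + mean_o) > 0 else 0.0
            b = np.mean([rel.at[s, taxon] > 0 for s in members])
            stat = np.sqrt(a * b)
            if stat > best_stat:
                best_stat, best_g = stat, g
        out[taxon] = (best_stat, best_g)
    return out


class TestIndicatorAnalysis:
    labels = pd.Series(
        ["foal"] * 3 + ["sub-adult"] * 3, index=[f"s{i + 1}" for i in range(6)]
    )

    def test_perfect_indicator(self):
        rel = rel_rows([0.4], [0.5], [0.3], [0.0], [0.0], [0.0])
        res = indicator_analysis(rel, self.labels, permutations="exhaustive")
        row = res.table.loc["SV1"]
        assert (row["A"], row["B"], row["stat"]) == (1.0, 1.0, 1.0)
        assert row["group"] == "foal"

    def test_no_specificity_closed_form(self):
        rel = rel_rows([0.2], [0.2], [0.2], [0.2], [0.2], [0.2])
        res = indicator_analysis(rel, self.labels, permutations="exhaustive")
        row = res.table.loc["SV1"]
        assert row["A"] == pytest.approx(0.5)
        assert row["stat"] == pytest.approx(np.sqrt(0.5))

    def test_toy_table_matches_brute_force(self):
        rng = np.random.default_rng(5)
        rel = rel_rows(*rng.dirichlet(np.full(4, 0.6), size=6))
        rel[rel < 0.05] = 0.0
        res = indicator_analysis(rel, self.labels, permutations="exhaustive")
        expected = indval_brute_force(rel, list(self.labels))
        for taxon, (stat, group) in expected.items():
            assert res.table.at[taxon, "stat"] == pytest.approx(stat, abs=1e-12)
            assert res.table.at[taxon, "group"] == group

    def test_exhaustive_p_matches_brute_force(self):
        rng = np.random.default_rng(6)
        rel = rel_rows(*rng.dirichlet(np.full(3, 0.6), size=6))
        res = indicator_analysis(rel, self.labels, permutations="exhaustive")
        labels = list(self.labels)
        for taxon in rel.columns:
            obs = res.table.at[taxon, "stat"]
            exceed = total = 0
            # brute-force p: enumerate distinct relabellings, recompute max stat
            for perm in set(itertools.permutations(labels)):
                stat, _ = indval_brute_force(rel[[taxon]], list(perm))[taxon]
                if stat >= obs - 1e-12:
                    exceed += 1
                total += 1
            assert res.table.at[taxon, "p"] == pytest.approx(exceed / total)

    def test_requires_two_groups(self):
        rel = rel_rows([1.0], [1.0], [1.0])
        labels = pd.Series(["a", "a", "a"], index=rel.index)
        with pytest.raises(ValueError, match="two groups"):
            indicator_analysis(rel, labels)


def make_dyads(categories, distances, focals=None, bands=None, family="test"):
    n = len(distances)
    df = pd.DataFrame(
        {
            "id_a": [f"x{i}" for i in range(n)],
            "id_b": [f"y{i}" for i in range(n)],
            "category": categories,
            "group": categories,
            "distance": distances,
            "focal": focals or [f"f{i % 4}" for i in range(n)],
            "band": bands or ["b1"] * n,
        }
    )
    return DyadDistanceSet(family, df)


class TestDyadMixedModel:
    def test_equal_distances_give_null_result(self):
        dy = make_dyads(["a"] * 5 + ["b"] * 5, [0.3] * 10)
        res = dyad_mixed_model(dy)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_detects_planted_category_shift(self):
        rng = np.random.default_rng(7)
        d = np.concatenate([rng.normal(0.2, 0.02, 30), rng.normal(0.5, 0.02, 30)])
        dy = make_dyads(
            ["a"] * 30 + ["b"] * 30, d,
            focals=[f"f{i % 6}" for i in range(60)],
            bands=[f"band{i % 3}" for i in range(60)],
        )
        res = dyad_mixed_model(dy)
        assert res.p < 1e-6
        assert res.means["a"] < res.means["b"]
        assert res.statistic_name == "chi2" and res.df == 1

    def test_pairwise_contrasts_flag_only_shifted_pair(self):
        rng = np.random.default_rng(8)
        d = np.concatenate(
            [rng.normal(0.2, 0.03, 25), rng.normal(0.2, 0.03, 25), rng.normal(0.6, 0.03, 25)]
        )
        dy = make_dyads(
            ["a"] * 25 + ["b"] * 25 + ["c"] * 25, d,
            focals=[f"f{i % 5}" for i in range(75)],
            bands=[f"band{i % 3}" for i in range(75)],
        )
        res = dyad_mixed_model(dy, pairwise=True)
        pw = res.pairwise.set_index(["cat_a", "cat_b"])
        assert pw.at[("a", "b"), "p_adjusted"] > 0.05
        assert pw.at[("a", "c"), "p_adjusted"] < 0.01
        assert pw.at[("b", "c"), "p_adjusted"] < 0.01


class TestBandAnova:
    def test_zero_f_for_identical_groups(self):
        dy = make_dyads(["g1"] * 4 + ["g2"] * 4, [0.1, 0.2, 0.1, 0.2] * 2)
        res = band_jsd_anova(dy)
        assert res.statistic == pytest.approx(0.0)

    def test_matches_hand_computed_anova_and_tukey(self):
        # groups: (1,2,3), (2,3,4), (10,11,12); hand ANOVA: means 2, 3, 11,
        # grand mean 16/3; SSB = 3*[(10/3)^2 + (7/3)^2 + (17/3)^2] = 146;
        # SSW = 2+2+2 = 6 -> F = (146/2) / (6/6) = 73
        dy = make_dyads(
            ["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3,
            [1, 2, 3, 2, 3, 4, 10, 11, 12],
        )
        res = band_jsd_anova(dy)
        assert res.statistic == pytest.approx(73.0)
        assert res.df == (2, 6)
        pw = res.pairwise.set_index(["group_a", "group_b"])
        assert pw.at[("g1", "g2"), "p_adjusted"] > 0.05
        assert pw.at[("g1", "g3"), "p_adjusted"] < 0.01
        assert pw.at[("g2", "g3"), "p_adjusted"] < 0.01
        assert res.means["g3"] == pytest.approx(11.0)
        assert res.ses["g1"] == pytest.approx(np.std([1, 2, 3], ddof=1) / np.sqrt(3))

    def test_small_group_rejected(self):
        dy = make_dyads(["g1"] * 3 + ["g2"], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="fewer than 2"):
            band_jsd_anova(dy)
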