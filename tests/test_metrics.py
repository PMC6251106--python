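"""Distance metrics against closed forms and brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jensenshannon

from sociobiome.metrics import (
    CoreConfig,
    bray_curtis,
    categorize_dyads_individuals,
    categorize_dyads_samples,
    core_microbiome,
    jensen_shannon,
)
from sociobiome.simulate import build_relationship_map, small_config

from conftest import rel_rows


class TestCoreMicrobiome:
    def test_prevalence_boundary_at_five_samples(self):
        # ceil(0.999 * 5) = 5: an SV must clear detection in all 5 samples
        rows = np.full((5, 2), 0.5)
        rows[4, 1] = 1e-6  # below detection in one sample
        rows[4, 0] = 1 - 1e-6
        rel = rel_rows(*rows)
        kept, _ = core_microbiome(rel, CoreConfig())
        assert kept == ["SV1"]

    def test_kept_when_present_in_all(self):
        rel = rel_rows(*np.full((5, 2), 0.5))
        kept, sub = core_microbiome(rel)
        assert kept == ["SV1", "SV2"]
        pd.testing.assert_frame_equal(sub, rel)

    def test_matches_brute_force_on_random_tables(self):
        cfg = CoreConfig(detection=0.01, prevalence=0.8)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.dirichlet(np.full(50, 0.3), size=20)
            rel = rel_rows(*x)
            kept, _ = core_microbiome(rel, cfg)
            expected = []
            for sv in rel.columns:  # brute-force two-loop scan
                hits = sum(rel.at[s, sv] >= cfg.detection for s in rel.index)
                if hits >= math.ceil(cfg.prevalence * len(rel)):
                    expected.append(sv)
            assert kept == expected

    def test_empty_core_allowed_with_warning(self, caplog):
        rel = rel_rows([1.0, 0.0], [0.0, 1.0])
        with caplog.at_level("WARNING"):
            kept, sub = core_microbiome(rel, CoreConfig(detection=0.5, prevalence=1.0))
        assert kept == [] and sub.shape[1] == 0


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis(rel_rows([0.2, 0.8], [0.2, 0.8]))
        assert d.values[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        d = bray_curtis(rel_rows([1.0, 0.0], [0.0, 1.0]))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_formula_example(self):
        d = bray_curtis(rel_rows([0.5, 0.5, 0.0], [0.2, 0.3, 0.5]))
        assert d.values[0, 1] == pytest.approx(0.5)

    def test_unnormalized_core_subset_accepted(self):
        # a core-filtered table keeps raw retained abundances (rows < 1)
        d = bray_curtis(rel_rows([0.4, 0.4], [0.3, 0.5]))
        assert 0.0 < d.values[0, 1] < 1.0


class TestJensenShannon:
    def test_self_divergence_zero(self):
        d = jensen_shannon(rel_rows([0.3, 0.7], [0.3, 0.7]))
        assert d.values[0, 1] == 0.0

    def test_disjoint_supports_ln2(self):
        d = jensen_shannon(rel_rows([1.0, 0.0], [0.0, 1.0]))
        assert d.values[0, 1] == pytest.approx(math.log(2), abs=1e-12)

    def test_worked_value(self):
        d = jensen_shannon(rel_rows([0.5, 0.5], [0.25, 0.75]))
        assert d.values[0, 1] == pytest.approx(0.0339, abs=1e-4)

    def test_matches_scipy_oracle_on_random_profiles(self):
        rng = np.random.default_rng(0)
        x = rng.dirichlet(np.full(30, 0.4), size=12)
        d = jensen_shannon(rel_rows(*x))
        for i, j in itertools.combinations(range(12), 2):
            # scipy returns sqrt(JSD) with natural log
            expected = jensenshannon(x[i], x[j]) ** 2
            assert d.values[i, j] == pytest.approx(expected, abs=1e-10)


class TestMetricProperties:
    def random_profiles(self, n, k=20, seed=1):
        rng = np.random.default_rng(seed)
        return rng.dirichlet(np.full(k, 0.3), size=n)

    def test_bounds_symmetry_on_random_pairs(self):
        # 1000 random pairs via a 46-point matrix (46*45/2 = 1035 pairs)
        x = self.random_profiles(46)
        for metric, bound in ((bray_curtis, 1.0), (jensen_shannon, math.log(2))):
            d = metric(rel_rows(*x)).values
            assert np.allclose(d, d.T)
            assert np.all(d >= 0) and np.all(d <= bound + 1e-12)
            assert np.allclose(np.diag(d), 0)

    def test_sqrt_jsd_triangle_inequality(self):
        x = self.random_profiles(9, seed=2)
        d = np.sqrt(jensen_shannon(rel_rows(*x)).values)
        triples = list(itertools.permutations(range(9), 3))[:100]
        for i, j, k in triples:
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestDyadCategories:
    def test_within_individual_definition(self):
        meta = pd.DataFrame(
            {"individual_id": ["A", "A"], "band": ["X", "X"]},
            index=["s1", "s2"],
        )
        d = jensen_shannon(rel_rows([0.5, 0.5], [0.4, 0.6]))
        fam = categorize_dyads_samples(d, meta)
        assert list(fam.pairs["category"]) == ["within_individual"]
        assert list(fam.pairs["focal"]) == ["A"]

    def test_cross_band_sample_pairs_excluded(self):
        meta = pd.DataFrame(
            {"individual_id": ["A", "B"], "band": ["X", "Y"]},
            index=["s1", "s2"],
        )
        d = jensen_shannon(rel_rows([0.5, 0.5], [0.4, 0.6]))
        fam = categorize_dyads_samples(d, meta)
        assert len(fam.pairs) == 0

    def test_mother_offspring_category(self):
        cfg = small_config(seed=6)
        relmap = build_relationship_map(cfg)
        juv, mum = next(iter(relmap.mother_of.items()))
        inds = sorted(relmap.individuals)
        rng = np.random.default_rng(0)
        rel = rel_rows(*rng.dirichlet(np.full(15, 0.5), size=len(inds)))
        rel.index = inds
        d = jensen_shannon(rel)
        fams = categorize_dyads_individuals(d, relmap)
        pairs = fams["maternal"].pairs
        row = pairs[(pairs["id_a"].isin([juv, mum])) & (pairs["id_b"].isin([juv, mum]))]
        assert list(row["category"]) == ["mother_offspring"]

    def test_category_counts_match_brute_force(self):
        cfg = small_config(seed=6)
        relmap = build_relationship_map(cfg)
        inds = sorted(relmap.individuals)
        rng = np.random.default_rng(1)
        rel = rel_rows(*rng.dirichlet(np.full(15, 0.5), size=len(inds)))
        rel.index = inds
        fams = categorize_dyads_individuals(jensen_shannon(rel), relmap)

        # independent enumeration over all unordered pairs
        counts = {"within_band": 0, "between_band": 0, "mother_offspring": 0,
                  "nonmaternal_mare_juvenile": 0, "foalless_mare_juvenile": 0,
                  "stallion_mare": 0, "mare_mare": 0}
        mothers = set(relmap.mother_of.values())
        for a, b in itertools.combinations(inds, 2):
            same = relmap.band_of[a] == relmap.band_of[b]
            counts["within_band" if same else "between_band"] += 1
            if not same:
                continue
            roles = {relmap.role_of[a], relmap.role_of[b]}
            if roles == {"mare"}:
                counts["mare_mare"] += 1
            if roles == {"stallion", "mare"}:
                counts["stallion_mare"] += 1
            for x, y in ((a, b), (b, a)):
                if relmap.role_of[x] in ("foal", "sub-adult") and relmap.role_of[y] == "mare":
                    if relmap.mother_of.get(x) == y:
                        counts["mother_offspring"] += 1
                    elif y in mothers:
                        counts["nonmaternal_mare_juvenile"] += 1
                    else:
                        counts["foalless_mare_juvenile"] += 1

        observed = pd.concat([f.pairs for f in fams.values()])["category"].value_counts()
        for cat, expected in counts.items():
            if expected:
                assert observed.get(cat, 0) == expected, cat

    def test_within_individual_less_than_between(self, small_study, small_rel):
        jsd = jensen_shannon(small_rel)
        fam = categorize_dyads_samples(jsd, small_study["metadata"])
        means = fam.mean_by_category()
        assert means["within_individual"] < means["between_individual_within_band"]
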