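"""Composition tables, the selection-index bootstrap, densities, summary
t-tests, Calanus sizing, clustering and habitat comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import rand_score

from aukforage import diet
from aukforage import synthetic_data as sd


def _long(counts_by_sample, **meta):
    rows = []
    for sid, counts in counts_by_sample.items():
        for taxon, c in counts.items():
            rows.append({"sample_id": sid, "taxon": taxon, "count": c,
                         "source": "at_sea", "year": 2014, "stratum": "none",
                         **meta})
    return pd.DataFrame(rows)


class TestCompositionTable:
    def test_single_taxon_sample(self):
        out = diet.composition_table(_long({"s1": {"A": 7}}))
        assert out.ra_mean_pct.iloc[0] == 100.0
        assert out.of_pct.iloc[0] == 100.0

    def test_occurrence_frequency_definition(self):
        samples = {f"s{i}": {"A": 1 if i < 18 else 0, "B": 1} for i in range(20)}
        out = diet.composition_table(_long(samples)).set_index("taxon")
        assert out.loc["A", "of_pct"] == pytest.approx(90.0)

    def test_per_sample_ra_sums_to_100(self, cfg):
        samples = sd.gen_zoo_samples(cfg, "continental_shelf", 10)
        ra = diet._ra_matrix(samples)
        assert np.allclose(ra.sum(axis=1), 100.0, atol=1e-9)

    def test_zero_total_sample_excluded(self):
        df = _long({"s1": {"A": 3}, "s2": {"A": 0}})
        with pytest.warns(UserWarning, match="s2"):
            out = diet.composition_table(df)
        assert set(out.taxon) == {"A"} and out.n_samples.iloc[0] == 1


class TestLfsi:
    def test_point_estimates_from_published_means(self):
        hyp = diet.lfsi(0.470, 0.176, 0.039, 0.027, seed=0)
        gla = diet.lfsi(0.341, 0.128, 0.063, 0.031, seed=0)
        assert round(hyp.point, 2) == 0.43
        assert round(gla.point, 2) == 0.28

    def test_equal_means_centre_on_zero(self):
        r = diet.lfsi(0.3, 0.1, 0.3, 0.05, seed=1)
        assert r.point == 0.0
        assert abs(r.boot_mean) < 4 * r.boot_sd / np.sqrt(r.n_boot)

    def test_boot_sd_matches_closed_form(self):
        # SD of a difference of independent normals: sqrt(0.176^2 + 0.027^2)
        r = diet.lfsi(0.470, 0.176, 0.039, 0.027, n_boot=100_000, seed=2)
        expected = np.sqrt(0.176**2 + 0.027**2)
        mc_se = expected / np.sqrt(2 * (r.n_boot - 1))
        assert r.boot_sd == pytest.approx(expected, abs=3 * mc_se)
        assert round(r.boot_sd, 2) == 0.18

    def test_ci_brackets_boot_mean(self):
        r = diet.lfsi(0.4, 0.2, 0.1, 0.1, seed=3)
        assert r.ci_low <= r.boot_mean <= r.ci_high

    def test_validation(self):
        with pytest.raises(ValueError):
            diet.lfsi(1.2, 0.1, 0.1, 0.1, seed=0)
        with pytest.raises(ValueError):
            diet.lfsi(0.5, 0.1, 0.1, 0.1, n_boot=50, seed=0)
        with pytest.raises(ValueError, match="seed"):
            diet.lfsi(0.5, 0.1, 0.1, 0.1)

    def test_table_points_sum_to_zero_over_shared_universe(self, cfg):
        pouch = sd.gen_pouch_samples(cfg, 2014, 12)
        env = sd.gen_zoo_samples(cfg, "continental_shelf", 11)
        table = diet.lfsi_table(pouch, env, n_boot=200, seed=0)
        assert table.point.sum() == pytest.approx(0.0, abs=1e-9)


class TestDensity:
    def test_arithmetic(self):
        assert diet.density_per_m3(0) == 0.0
        assert diet.density_per_m3(100) == pytest.approx(7.84, abs=0.005)

    def test_halving_depth_doubles_density(self):
        assert diet.density_per_m3(50, haul_depth_m=25) == \
            pytest.approx(2 * diet.density_per_m3(50, haul_depth_m=50))

    def test_bad_geometry(self):
        with pytest.raises(ValueError):
            diet.density_per_m3(10, haul_depth_m=0)


class TestSummaryT:
    @pytest.mark.parametrize("m1,s1,m2,s2,expected_t", [
        (65.3, 28.6, 47.0, 17.6, 2.43),   # larger Arctic copepod, 2012 vs 2014
        (15.5, 9.2, 34.1, 12.8, -5.28),
        (4.2, 4.0, 9.0, 6.7, -2.75),
    ])
    def test_between_year_t_values(self, m1, s1, m2, s2, expected_t):
        res = diet.two_sample_t_summary(m1, s1, 20, m2, s2, 20)
        assert res["df"] == 38
        # inputs are the rounded yearly summaries; allow one ulp of the print
        assert res["t"] == pytest.approx(expected_t, abs=0.01)

    def test_identical_summaries(self):
        res = diet.two_sample_t_summary(5, 2, 10, 5, 2, 10)
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_matches_scipy_on_raw_data(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1.3, 12)
        res = diet.two_sample_t_summary(a.mean(), a.std(ddof=1), len(a),
                                        b.mean(), b.std(ddof=1), len(b))
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert res["t"] == pytest.approx(ref.statistic, rel=1e-10)
        assert res["p"] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            diet.two_sample_t_summary(5, 0, 10, 5, 0, 10)


class TestClassifyCalanus:
    def test_ordering_and_tie_rule(self):
        rule = {"CV": diet.CalanusSizeRule("CV", (2.9, 4.0))}
        assert diet.classify_calanus("CV", 2.0, rule) == "finmarchicus"
        assert diet.classify_calanus("CV", 2.9, rule) == "glacialis"  # boundary up
        assert diet.classify_calanus("CV", 4.0, rule) == "hyperboreus"
        assert diet.classify_calanus("CV", 5.0, rule) == "hyperboreus"

    def test_missing_stage_warns(self):
        with pytest.warns(UserWarning):
            assert diet.classify_calanus("CII", 2.0, {}) == "unclassified"

    def test_mixture_recovery_with_fitted_cutpoints(self, rng):
        truth = np.repeat(diet.CALANUS_SPECIES, 300)
        lengths = np.concatenate([
            rng.normal(2.5, 0.15, 300),   # finmarchicus
            rng.normal(3.4, 0.15, 300),   # glacialis
            rng.normal(4.8, 0.25, 300),   # hyperboreus
        ])
        cuts = diet.suggest_cutpoints(lengths)
        rule = {"CV": diet.CalanusSizeRule("CV", cuts)}
        pred = diet.classify_calanus("CV", lengths, rule)
        assert (pred == truth).mean() >= 0.95


class TestBrayCurtisWard:
    def test_identical_and_disjoint_samples(self):
        df = _long({"s1": {"A": 5, "B": 5}, "s2": {"A": 5, "B": 5},
                    "s3": {"C": 10}})
        dist, _, _ = diet.bray_curtis_ward(df)
        assert dist.loc["s1", "s2"] == 0.0
        assert dist.loc["s1", "s3"] == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=3, max_size=3),
           st.lists(st.integers(0, 50), min_size=3, max_size=3))
    def test_semimetric_properties(self, u, v):
        if sum(u) == 0 or sum(v) == 0:
            return
        df = _long({"u": dict(zip("ABC", u)), "v": dict(zip("ABC", v))})
        dist, _, _ = diet.bray_curtis_ward(df)
        d = dist.loc["u", "v"]
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(dist.loc["v", "u"])
        expect = sum(abs(a - b) for a, b in zip(u, v)) / sum(u + v)
        assert d == pytest.approx(expect)

    def test_two_communities_recovered(self, cfg):
        shelf = sd.gen_zoo_samples(cfg, "continental_shelf", 10)
        ocean = sd.gen_zoo_samples(cfg, "open_ocean", 10)
        df = pd.concat([shelf, ocean], ignore_index=True)
        _, _, labels = diet.bray_curtis_ward(df, k=2)
        truth = [sid.rsplit("_", 1)[0] for sid in labels.index]
        assert rand_score(truth, labels.to_numpy()) >= 0.9

    def test_ward_variants_both_run(self, cfg):
        df = sd.gen_zoo_samples(cfg, "shelf_break", 6)
        for variant in ("ward.D2", "ward.D"):
            _, Z, labels = diet.bray_curtis_ward(df, k=2, variant=variant)
            assert (Z[:, 2] >= 0).all()
        with pytest.raises(ValueError):
            diet.bray_curtis_ward(df, variant="average")

    def test_newick_roundtrips_leaf_names(self, cfg):
        df = sd.gen_zoo_samples(cfg, "open_ocean", 5)
        dist, Z, _ = diet.bray_curtis_ward(df)
        nwk = diet.linkage_to_newick(Z, dist.index)
        assert nwk.endswith(";")
        for name in dist.index:
            assert name in nwk


class TestHabitatCompare:
    def test_identical_constant_convention(self):
        df = pd.DataFrame({"stratum": list("aabbcc"), "density": [2.0] * 6})
        res = diet.habitat_density_compare(df, species_col=None)["all"]
        assert res["H"] == 0.0 and res["p"] == 1.0

    def test_rank_oracle(self):
        df = pd.DataFrame({"stratum": list("aaabbbccc"),
                           "density": [1, 2, 3, 4, 5, 6, 7, 8, 9]})
        res = diet.habitat_density_compare(df, species_col=None)["all"]
        assert res["H"] == pytest.approx(7.2, abs=1e-9)
        assert res["p"] == pytest.approx(0.0273, abs=0.0005)

    def test_separated_strata_distinct_letters(self, rng):
        rows = []
        for stratum, mu in (("shelf", 1.0), ("break", 100.0), ("ocean", 10_000.0)):
            for v in rng.normal(mu, mu * 0.01, 8):
                rows.append({"stratum": stratum, "density": v,
                             "species": "C. finmarchicus"})
        res = diet.habitat_density_compare(pd.DataFrame(rows))["C. finmarchicus"]
        letters = res["letters"]
        assert len(set(letters.values())) == 3
        assert res["p"] < 0.01

    def test_small_stratum_excluded(self):
        df = pd.DataFrame({"stratum": ["a"] * 4 + ["b"] * 4 + ["c"],
                           "density": [1, 2, 3, 4, 8, 9, 10, 11, 100.0]})
        with pytest.warns(UserWarning, match="c"):
            res = diet.habitat_density_compare(df, species_col=None)["all"]
        assert set(res["letters"]) == {"a", "b"}
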