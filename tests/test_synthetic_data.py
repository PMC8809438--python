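"""Tree, clade-table and community simulators that feed every other test."""

import numpy as np
import pytest
from scipy import stats

import floraphylo as fp


class TestSimulateTree:
    def test_two_tip_cherry_is_ultrametric(self):
        t = fp.simulate_tree(2, seed=0)
        assert t.n_tips == 2 and t.is_ultrametric()

    def test_same_seed_same_newick(self):
        a = fp.write_newick(fp.simulate_tree(10, seed=123))
        b = fp.write_newick(fp.simulate_tree(10, seed=123))
        assert a == b

    def test_different_seed_different_tree(self):
        a = fp.write_newick(fp.simulate_tree(10, seed=1))
        b = fp.write_newick(fp.simulate_tree(10, seed=2))
        assert a != b

    @pytest.mark.parametrize(
        "kwargs", [dict(n_tips=1), dict(n_tips=5, birth=0.0),
                   dict(n_tips=5, model="birth-death", birth=1.0, death=1.5),
                   dict(n_tips=5, model="unknown")],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(fp.ValidationError):
            fp.simulate_tree(**kwargs)

    def test_yule_depth_matches_analytic_expectation(self):
        """Crown height of a Yule-n tree has mean Σ_{k=2}^{n-1} 1/(kλ)."""
        n, reps = 8, 400
        depths = np.array([fp.simulate_tree(n, seed=s).max_depth() for s in range(reps)])
        expected = sum(1.0 / k for k in range(2, n))
        se = depths.std(ddof=1) / np.sqrt(reps)
        assert abs(depths.mean() - expected) < 3 * se

    def test_birth_death_tree_is_ultrametric(self):
        t = fp.simulate_tree(20, model="birth-death", birth=1.0, death=0.4, seed=9)
        assert t.is_ultrametric()


class TestSimulateCladeTable:
    def test_constant_age_gives_constant_mdt(self):
        t = fp.simulate_clade_table(
            n_clades=30, age_dist={"name": "constant", "value": 19.4}, seed=0
        )
        sub = t.subset(t.genera[5:15])
        assert fp.mdt(sub).mdt == pytest.approx(19.4)

    def test_uniform_age_law_of_large_numbers(self):
        t = fp.simulate_clade_table(
            n_clades=10_000, age_dist={"name": "uniform", "low": 0.001, "high": 40.0},
            seed=1,
        )
        se = 40.0 / np.sqrt(12 * 10_000)
        assert abs(t.ages.mean() - 20.0) < 3 * se

    def test_default_ages_track_flora_mean_and_median(self):
        t = fp.simulate_clade_table(n_clades=50_000, seed=2)
        assert t.ages.mean() == pytest.approx(19.40, rel=0.05)
        assert np.median(t.ages) == pytest.approx(13.75, rel=0.05)

    def test_degenerate_origin_probs(self):
        t = fp.simulate_clade_table(
            n_clades=20, origin_probs={"Eastern Asia": 1.0}, seed=3
        )
        assert set(t.df["origin"]) == {"Eastern Asia"}

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(fp.ValidationError, match="sum to 1"):
            fp.simulate_clade_table(n_clades=5, origin_probs={"A": 0.4, "B": 0.4})

    def test_counts_at_least_one(self):
        t = fp.simulate_clade_table(
            n_clades=2000, count_dist={"name": "geometric", "mean": 1.2}, seed=4
        )
        assert t.counts.min() >= 1


class TestSimulateCommunities:
    def test_strength_zero_reduces_every_regime_to_neutral(self):
        t = fp.simulate_tree(30, seed=5)
        dm = fp.patristic_matrix(t)
        mats = []
        for regime in ("neutral", "filtering", "repulsion"):
            sc = fp.AssemblyScenario(regime=regime, strength=0.0, n_sites=6,
                                     richness=10, seed=99)
            mats.append(fp.simulate_communities(t, sc, distance_matrix=dm).incidence)
        assert mats[0].equals(mats[1]) and mats[0].equals(mats[2])

    def test_richness_exceeding_tips_rejected(self):
        t = fp.simulate_tree(5, seed=0)
        sc = fp.AssemblyScenario(n_sites=2, richness=9, seed=0)
        with pytest.raises(fp.ValidationError, match="richness"):
            fp.simulate_communities(t, sc)

    def test_unknown_regime_rejected(self):
        with pytest.raises(fp.ValidationError, match="regime"):
            fp.AssemblyScenario(regime="chaos")

    def test_reproducible_under_seed(self):
        t = fp.simulate_tree(20, seed=6)
        sc = fp.AssemblyScenario(regime="filtering", strength=1.0, n_sites=4,
                                 richness=(5, 10), seed=7)
        a = fp.simulate_communities(t, sc)
        b = fp.simulate_communities(t, sc)
        assert a.incidence.equals(b.incidence)
        assert a.species_meta.equals(b.species_meta)

    def test_filtering_strength_monotone_in_mean_nti(self):
        """Mean NTI is nondecreasing along a filtering strength grid."""
        t = fp.simulate_tree(64, seed=7)
        dm = fp.patristic_matrix(t)
        strengths = [0.0, 0.5, 1.0, 2.0, 4.0]
        means = []
        for s in strengths:
            sc = fp.AssemblyScenario(regime="filtering", strength=s, n_sites=200,
                                     richness=12, seed=11)
            occ = fp.simulate_communities(t, sc, distance_matrix=dm)
            rng = np.random.default_rng(13)
            means.append(
                np.mean([
                    fp.nti(occ.species_at(site), dm, n_reps=199, seed=rng).nti
                    for site in occ.sites
                ])
            )
        rho = stats.spearmanr(strengths, means).statistic
        assert rho > 0
        assert means[-1] > means[0]


class TestFixture:
    def test_unknown_profile_rejected(self):
        with pytest.raises(fp.ValidationError, match="profile"):
            fp.make_fixture("atlantis-maxi")

    def test_fixture_shape_and_invariants(self, kunlun_mini):
        tree, clades, occ, region_map = kunlun_mini
        assert tree.n_tips == 60
        assert len(clades) == 20
        assert len(occ.sites) == 8
        assert set(region_map.values()) == {"east", "west", "central-north", "central-south"}
        # every checklist genus has a clade age, with per-site counts aligned
        assert set(occ.species_meta["genus"]) <= set(clades.genera)
        assert set(clades.sites) == set(occ.sites)

    def test_fixture_endemism_near_construction_rate(self, kunlun_mini):
        frac = kunlun_mini.occurrence.species_meta["endemic"].mean()
        assert abs(frac - 0.30) <= 0.05

    def test_fixture_deterministic(self, kunlun_mini):
        again = fp.make_fixture("kunlun-mini")
        assert fp.write_newick(again.phylogeny) == fp.write_newick(kunlun_mini.phylogeny)
        assert again.occurrence.incidence.equals(kunlun_mini.occurrence.incidence)
        assert again.clade_table.df.equals(kunlun_mini.clade_table.df)

    def test_per_site_counts_match_checklist(self, kunlun_mini):
        clades, occ = kunlun_mini.clade_table, kunlun_mini.occurrence
        for site in occ.sites:
            gc = occ.genus_counts_at(site)
            col = clades.df.set_index("genus")[f"count_{site}"]
            for genus, n in gc.items():
                assert col[genus] == n
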