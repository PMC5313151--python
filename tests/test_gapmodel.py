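"""Gap-model allometry, competition mechanics and stochastic demography."""

import numpy as np
import pandas as pd
import pytest

from compsd.gapmodel import (
    GapConfig,
    SiteConditions,
    TreeIndividual,
    aboveground_biomass,
    annual_growth_step,
    establishment_step,
    height_from_dbh,
    light_multiplier,
    mortality_step,
    optimal_increment,
    replicate_mean_biomass,
    simulate_stand,
    stand_from_table,
)
from compsd.params import light_archetype


class G:  # minimal growth-parameter stub for the allometry functions
    d_max = 50.0
    h_max = 3000.0
    g_growth = 170.0
    biomass_a = 0.1
    biomass_b = 2.4


class TestAllometry:
    def test_height_hits_h_max_at_d_max(self):
        assert height_from_dbh(50.0, G) == pytest.approx(3000.0)

    def test_height_example(self):
        # 137 + 114.52*10 - 1.1452*100
        assert height_from_dbh(10.0, G) == pytest.approx(1167.68)

    def test_height_intercept_is_breast_height(self):
        assert height_from_dbh(1e-9, G) == pytest.approx(137.0, abs=1e-5)

    def test_nonpositive_dbh_rejected(self):
        with pytest.raises(ValueError):
            height_from_dbh(0.0, G)

    def test_increment_vanishes_at_d_max(self):
        assert optimal_increment(50.0, G) == pytest.approx(0.0, abs=1e-12)

    def test_increment_example(self):
        assert optimal_increment(10.0, G) == pytest.approx(0.4821, abs=1e-4)

    def test_increment_non_negative_over_range(self):
        for d in np.linspace(0.5, 50.0, 100):
            assert optimal_increment(d, G) >= 0.0

    def test_biomass_power_law(self):
        t = TreeIndividual("x", dbh=10.0)
        assert aboveground_biomass(t, G) == pytest.approx(25.119, abs=1e-3)
        t2 = TreeIndividual("x", dbh=20.0)
        assert aboveground_biomass(t2, G) / aboveground_biomass(t, G) == pytest.approx(
            2**2.4
        )


class TestLightMultiplier:
    def test_open_sky_near_maximum(self):
        assert light_multiplier(0.0, 5) > 0.95

    def test_beer_lambert_attenuation(self):
        # AL = exp(-0.4*2) = 0.4493 through the tolerant curve
        al = np.exp(-0.8)
        c1, c2, cp = light_archetype(5)
        expected = c1 * (1 - np.exp(-c2 * (al - cp)))
        assert light_multiplier(2.0, 5, extinction_k=0.4) == pytest.approx(expected)

    def test_deep_shade_kills_intolerant_response(self):
        # AL below the intolerant compensation point (0.08)
        assert light_multiplier(7.0, 1, extinction_k=0.4) == 0.0

    def test_bad_extinction_rejected(self):
        with pytest.raises(ValueError):
            light_multiplier(1.0, 3, extinction_k=0.0)


class TestGrowthStep:
    def test_unshaded_tree_grows_at_optimum(self, succession_pair):
        site = SiteConditions(gdd=1700, swc=0.5)  # both responses = 1 at these
        sp = succession_pair["tol"]
        assert sp.kernel.psi == 0.5 and (sp.kernel.gdd_min + sp.kernel.gdd_max) / 2 == 1700
        tree = TreeIndividual("tol", dbh=10.0)
        expected = optimal_increment(10.0, sp.growth) * light_multiplier(0.0, 5)
        annual_growth_step([tree], site, succession_pair)
        assert tree.dbh == pytest.approx(10.0 + expected)
        assert tree.age == 1

    def test_gdd_outside_window_stops_growth(self, succession_pair):
        site = SiteConditions(gdd=5000, swc=0.5)
        tree = TreeIndividual("tol", dbh=10.0)
        annual_growth_step([tree], site, succession_pair)
        assert tree.dbh == 10.0
        assert tree.slow_growth_years == 1

    def test_taller_tree_shades_shorter_only(self, succession_pair):
        site = SiteConditions(gdd=1700, swc=0.5)
        cfg = GapConfig()
        tall = TreeIndividual("tol", dbh=30.0)
        short = TreeIndividual("tol", dbh=10.0)
        solo_inc = optimal_increment(30.0, succession_pair["tol"].growth) * light_multiplier(0.0, 5)
        lai_tall = cfg.leaf_area_coeff * 30.0**2 / site.plot_area
        shaded_inc = (
            optimal_increment(10.0, succession_pair["tol"].growth)
            * light_multiplier(lai_tall, 5, cfg.extinction_k)
        )
        annual_growth_step([tall, short], site, succession_pair, cfg)
        assert tall.dbh == pytest.approx(30.0 + solo_inc)
        assert short.dbh == pytest.approx(10.0 + shaded_inc)

    def test_unknown_species_rejected(self, succession_pair):
        with pytest.raises(KeyError, match="mystery"):
            annual_growth_step(
                [TreeIndividual("mystery", dbh=5.0)],
                SiteConditions(gdd=1700, swc=0.5),
                succession_pair,
            )


class TestMortality:
    def test_intrinsic_rate_value(self):
        assert GapConfig().intrinsic_rate / 400.0 == pytest.approx(0.01)

    def test_cohort_survival_to_age_max(self, succession_pair):
        # fraction of an unstressed cohort surviving age_max years is
        # (1 - 4/A)^A ~ e^-4 ~ 0.018
        n = 20_000
        p = 4.0 / succession_pair["tol"].growth.age_max
        stand = [TreeIndividual("tol", dbh=5.0) for _ in range(n)]
        survivors = mortality_step(stand, succession_pair, np.random.default_rng(1))
        observed = len(survivors) / n
        se = np.sqrt(p * (1 - p) / n)
        assert observed == pytest.approx(1 - p, abs=4 * se)

    def test_stressed_trees_die_fast(self, succession_pair):
        # 10-yr survival of a persistently suppressed cohort matches the
        # closed form (1 - p)^10 with p = p_i + (1-p_i)*0.368 (~0.010 for
        # the stress term alone)
        n = 10_000
        stand = [
            TreeIndividual("tol", dbh=5.0, slow_growth_years=2) for _ in range(n)
        ]
        rng = np.random.default_rng(2)
        for _ in range(10):
            for t in stand:
                t.slow_growth_years = 2  # keep the cohort suppressed
            stand = mortality_step(stand, succession_pair, rng)
        p_i = 4.0 / succession_pair["tol"].growth.age_max
        p = p_i + (1 - p_i) * 0.368
        expected = (1 - p) ** 10
        se = np.sqrt(expected * (1 - expected) / n)
        assert len(stand) / n == pytest.approx(expected, abs=4 * se)


class TestEstablishment:
    def test_empty_plot_mean_recruits(self, succession_pair):
        site = SiteConditions(gdd=1700, swc=0.5)
        rng = np.random.default_rng(3)
        n_years = 2000
        total = 0
        for _ in range(n_years):
            stand = establishment_step([], site, succession_pair, rng)
            total += sum(1 for t in stand if t.species_code == "tol")
        rate = succession_pair["tol"].growth.recruit_rate
        se = np.sqrt(rate / n_years)
        assert total / n_years == pytest.approx(rate, abs=3 * se)

    def test_closed_canopy_blocks_intolerant_recruits(self, succession_pair):
        # canopy LAI ~7.3 leaves floor light ~0.055: above the tolerant
        # compensation point (0.05) but below the intolerant one (0.08)
        site = SiteConditions(gdd=1700, swc=0.5)
        canopy = [TreeIndividual("intol", dbh=55.0, age=60) for _ in range(3)]
        rng = np.random.default_rng(4)
        recruits = []
        for _ in range(200):
            new = establishment_step(list(canopy), site, succession_pair, rng)
            recruits.extend(new[len(canopy):])
        assert recruits
        assert all(t.species_code == "tol" for t in recruits)

    def test_no_recruits_outside_gdd_window(self, succession_pair):
        site = SiteConditions(gdd=100, swc=0.5)
        rng = np.random.default_rng(5)
        assert establishment_step([], site, succession_pair, rng) == []

    def test_sapling_size_range(self, succession_pair):
        site = SiteConditions(gdd=1700, swc=0.5)
        rng = np.random.default_rng(6)
        stand = []
        for _ in range(50):
            stand = establishment_step(stand, site, succession_pair, rng)
        saplings = [t.dbh for t in stand if t.age == 0]
        assert saplings and all(0.5 <= d <= 2.5 for d in saplings)


class TestSimulation:
    def test_years_must_be_positive(self, succession_pair):
        with pytest.raises(ValueError):
            simulate_stand([], SiteConditions(gdd=1700, swc=0.5),
                           succession_pair, years=0)

    def test_empty_stand_no_eligible_species_stays_empty(self, succession_pair):
        traj = simulate_stand([], SiteConditions(gdd=100, swc=0.5),
                              succession_pair, years=10)
        assert (traj.frame["agb_kg"] == 0).all()
        assert traj.frame["year"].max() == 10

    def test_state_invariants_over_run(self, succession_pair):
        traj = simulate_stand([], SiteConditions(gdd=1700, swc=0.5),
                              succession_pair, years=60,
                              rng=np.random.default_rng(7))
        f = traj.frame
        assert (f["agb_kg"] >= 0).all() and np.isfinite(f["agb_kg"]).all()
        assert (f["basal_area_m2"] >= 0).all()

    def test_dbh_never_exceeds_d_max(self, succession_pair):
        site = SiteConditions(gdd=1700, swc=0.5)
        stand = [TreeIndividual("intol", dbh=69.5)]
        for _ in range(30):
            annual_growth_step(stand, site, succession_pair)
        assert stand[0].dbh <= succession_pair["intol"].growth.d_max + 1e-9

    def test_replicates_deterministic_given_seed(self, succession_pair):
        site = SiteConditions(gdd=1700, swc=0.5)
        a = replicate_mean_biomass([], site, succession_pair, years=25,
                                   n_reps=3, seed=9)
        b = replicate_mean_biomass([], site, succession_pair, years=25,
                                   n_reps=3, seed=9)
        pd.testing.assert_series_equal(a, b)

    def test_single_replicate_equals_single_run(self, succession_pair):
        site = SiteConditions(gdd=1700, swc=0.5)
        mean = replicate_mean_biomass([], site, succession_pair, years=20,
                                      n_reps=1, seed=5)
        traj = simulate_stand([], site, succession_pair, years=20,
                              rng=np.random.default_rng(5))
        pd.testing.assert_series_equal(mean, traj.final_biomass(), check_names=False)

    def test_stand_table_expansion(self):
        frame = pd.DataFrame(
            {"species_code": ["a", "b"], "dbh_cm": [5.0, 7.0], "count": [2, 1]}
        )
        stand = stand_from_table(frame)
        assert [t.species_code for t in stand] == ["a", "a", "b"]
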