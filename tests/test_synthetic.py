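"""Synthetic experiment generator: pools, sites, climate, growth simulation."""

import numpy as np
import pandas as pd
import pytest

from drydiv import synthetic as syn
from drydiv.climate import water_balance
from drydiv.rings import bai_from_trw, growth_response, response_table


class TestSpeciesPool:
    def test_two_species_get_range_endpoints(self):
        pool = syn.generate_species_pool(2, (0.8, 1.5), seed=1)
        assert sorted(s.hsm for s in pool) == pytest.approx([0.8, 1.5])

    def test_single_species_at_midpoint(self):
        (sp,) = syn.generate_species_pool(1, (0.8, 1.5), seed=1)
        assert sp.hsm == pytest.approx(1.15)

    def test_seed_determinism(self):
        a = syn.generate_species_pool(6, seed=3)
        b = syn.generate_species_pool(6, seed=3)
        assert a == b

    def test_margins_span_range_uniformly(self):
        pool = syn.generate_species_pool(5, (0.5, 2.5), seed=0)
        hsms = [s.hsm for s in pool]
        assert np.diff(hsms) == pytest.approx([0.5] * 4)
        for s in pool:
            assert s.P50 < s.TLP < 0

    @pytest.mark.parametrize("bad", [(1.5, 0.8), (0.0, 1.0), (0.5, 3.5)])
    def test_invalid_range_rejected(self, bad):
        with pytest.raises(ValueError, match="hsm_range"):
            syn.generate_species_pool(3, bad, seed=0)


class TestGenerateSite:
    @staticmethod
    def design(**kw):
        pool = syn.generate_species_pool(3, seed=0)
        codes = [s.species_code for s in pool]
        kw.setdefault("compositions", [(c,) for c in codes] + [tuple(codes)])
        return syn.SiteDesign(site_id="S1", species_pool=pool, plot_rows=6, **kw)

    def test_zero_mortality_all_alive_and_quota_filled(self):
        trees, report = syn.generate_site(self.design(), mortality_rate=0.0, seed=1)
        assert all(t.alive for t in trees)
        # interior candidates exceed the quota for monocultures: exactly 10 focal
        mono = report[report["composition"].str.count("\\+") == 0]
        assert (mono["n_focal"] == 10).all()
        assert (report["n_focal"] <= 10).all()

    def test_high_mortality_reports_empty_compositions(self):
        with pytest.warns(RuntimeWarning, match="no focal trees"):
            trees, report = syn.generate_site(self.design(), mortality_rate=0.9, seed=2)
        assert (report["n_focal"] == 0).any()
        dead = [t for t in trees if not t.alive]
        assert dead, "dead trees stay in the stem map"

    def test_focal_trees_are_interior_with_alive_neighbors(self):
        trees, _ = syn.generate_site(self.design(), mortality_rate=0.3, seed=3)
        sm = syn.stem_map_frame(trees)
        spacing = 1.5
        for _, t in sm[sm["focal"]].iterrows():
            assert t["alive"]
            plot = sm[sm["plot_id"] == t["plot_id"]]
            assert 0 < t["x_m"] < plot["x_m"].max()
            assert 0 < t["y_m"] < plot["y_m"].max()
            first_order = plot[
                (np.hypot(plot["x_m"] - t["x_m"], plot["y_m"] - t["y_m"]) <= spacing + 1e-9)
                & (plot["tree_id"] != t["tree_id"])
            ]
            assert first_order["alive"].all()

    def test_unknown_species_in_composition_rejected(self):
        pool = syn.generate_species_pool(2, seed=0)
        with pytest.raises(ValueError, match="unknown species"):
            syn.SiteDesign(site_id="S1", species_pool=pool, compositions=[("SPXX",)])

    def test_site_determinism(self):
        a, _ = syn.generate_site(self.design(), mortality_rate=0.2, seed=9)
        b, _ = syn.generate_site(self.design(), mortality_rate=0.2, seed=9)
        assert a == b


class TestGenerateClimate:
    def test_scripted_severe_year_is_driest(self):
        clim = syn.generate_climate("s", (1991, 2021), {2018: "severe"}, seed=4)
        annual = water_balance(clim).groupby("year").sum()
        assert annual.idxmin() == 2018

    def test_short_span_warns(self):
        with pytest.warns(RuntimeWarning, match="31-year"):
            syn.generate_climate("s", (2000, 2020), {}, seed=0)

    def test_unknown_severity_rejected(self):
        with pytest.raises(ValueError, match="severity"):
            syn.generate_climate("s", (1991, 2021), {2018: "apocalyptic"}, seed=0)

    def test_determinism(self):
        a = syn.generate_climate("s", (1991, 2021), {2018: "severe"}, seed=5)
        b = syn.generate_climate("s", (1991, 2021), {2018: "severe"}, seed=5)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_multiyear_script_labels_calendar(self, small_scaffold):
        # 2018 severe + 2019-2020 moderate + 2021 wet labels Resp_yr 1..4
        assert small_scaffold.calendar.resp_years == {1: 2018, 2: 2019, 3: 2020, 4: 2021}
        assert small_scaffold.calendar.reference_years == [2017]


class TestSimulateRings:
    def test_null_model_gives_unit_response_ratios(self, small_scaffold):
        sc = small_scaffold
        cfg = syn.EffectConfig().null()
        series = syn.simulate_ring_series(
            sc.stem_map, sc.traits, sc.rew_by_year, {}, cfg,
            resp_label_by_year=sc.resp_label_by_year,
            rng=np.random.default_rng(0),
        )
        for s in series[:20]:
            for rec in growth_response(s, sc.calendar, metric="BIOMinc"):
                assert rec.growth_response == pytest.approx(1.0, rel=1e-9)
                assert rec.log_response == pytest.approx(0.0, abs=1e-9)

    def test_trw_bai_roundtrip_to_1e_9(self, small_scaffold):
        sc = small_scaffold
        cfg = syn.EffectConfig().null()  # deterministic growth: G = exp(mu)
        series = syn.simulate_ring_series(
            sc.stem_map, sc.traits, sc.rew_by_year, {}, cfg,
            resp_label_by_year=sc.resp_label_by_year,
            rng=np.random.default_rng(1),
        )
        g = float(np.exp(cfg.mu_of("x")))
        for s in series[:20]:
            expected_bai = g / (s.density * 1e-6)
            assert bai_from_trw(s.trw) == pytest.approx(expected_bai, rel=1e-9)

    def test_seed_determinism_bit_identical(self, small_scaffold):
        sc = small_scaffold
        cfg = syn.EffectConfig(seed=13)
        runs = []
        for _ in range(2):
            series = syn.simulate_ring_series(
                sc.stem_map, sc.traits, sc.rew_by_year, {}, cfg,
                resp_label_by_year=sc.resp_label_by_year,
            )
            runs.append(series)
        for a, b in zip(*runs):
            assert (a.trw == b.trw).all() and (a.density == b.density).all()

    def test_hsm_gradient_reduces_drought_loss(self, small_scaffold):
        """With a positive trait slope, drought-year growth loss shrinks as HSM rises."""
        sc = small_scaffold
        cfg = syn.EffectConfig(
            theta0=-0.6, theta_hsm=0.3,
            sigma2_site=0.0, sigma2_plot=0.0, sigma2_tree=0.0, sigma2_resid=0.0,
            beta_fd={1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0},
        )
        series = syn.simulate_ring_series(
            sc.stem_map, sc.traits, sc.rew_by_year, {}, cfg,
            resp_label_by_year=sc.resp_label_by_year, rng=np.random.default_rng(2),
        )
        recs = []
        for s in series:
            recs.extend(growth_response(s, sc.calendar, metric="BIOMinc"))
        df = response_table(recs).merge(
            sc.stem_map[["tree_id", "species_code"]], on="tree_id"
        ).merge(sc.traits[["species_code", "HSM_TLP"]], on="species_code")
        yr1 = df[df["resp_yr"] == 1]
        means = yr1.groupby("HSM_TLP")["log_response"].mean()
        assert (np.diff(means.loc[sorted(means.index)].to_numpy()) > 0).all()

    def test_null_noise_geometric_mean_near_one(self, small_scaffold):
        sc = small_scaffold
        cfg = syn.EffectConfig(
            alpha_age=0.0, gamma_ba=0.0, theta0=0.0, theta_hsm=0.0,
            beta_fd={1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0},
            sigma2_site=0.0, sigma2_plot=0.0, sigma2_tree=0.0,
        )
        df = syn.simulate_consecutive_responses(sc, cfg, seed=3)
        n = len(df)
        se = np.sqrt(2 * cfg.sigma2_resid / n)
        assert abs(df["log_response"].mean()) < 4 * se

    def test_fd_effect_recovered_by_regression(self, small_scaffold):
        """A -0.3 diversity effect in year 3 is recovered within 2 SE by OLS."""
        import statsmodels.formula.api as smf

        sc = small_scaffold
        cfg = syn.EffectConfig(beta_fd={1: 0.0, 2: 0.0, 3: -0.3, 4: 0.0}, seed=21)
        df = syn.simulate_consecutive_responses(sc, cfg, seed=21)
        yr3 = df[df["resp_yr"] == 3]
        res = smf.ols("log_response ~ FD_HSM_norm + HSM_TLP", data=yr3).fit()
        est, se = res.params["FD_HSM_norm"], res.bse["FD_HSM_norm"]
        assert est == pytest.approx(-0.3, abs=2 * se)


class TestTruthMapping:
    def test_pre_drought_diversity_effect_is_zero(self, small_scaffold):
        truth = syn.truth_consecutive_coefficients(small_scaffold, syn.EffectConfig())
        assert truth["BA_z"] == 0.0
        assert truth["FD_HSM_norm:center(HSM_TLP)"] == 0.0
        assert truth["C(resp_yr)[3]:FD_HSM_norm"] == -0.3
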