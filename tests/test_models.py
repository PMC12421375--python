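"""Mixed-model layer: fitting, inference, comparison, marginal effects, R2."""

import numpy as np
import pandas as pd
import pytest

from drydiv import synthetic as syn
from drydiv.models import (
    ConsecutiveDroughtModel,
    DegenerateFitError,
    ModelSpec,
    RankDeficientError,
    SingleYearDroughtModel,
    compare_models,
    marginal_effects,
    r2_nakagawa,
)


def synth_single_year(
    seed=0, n_sites=6, trees_per_site=60,
    b_hsm=0.0, b_rew=0.0, b_fd=0.0, sigma_site=0.08, sigma_plot=0.05, sigma=0.2,
):
    """Directly synthesized cross-site single-year dataset with known effects."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sites):
        rew = rng.uniform(-0.05, 0.3)
        prev = rng.uniform(0.1, 0.4)
        u_site = rng.normal(0, sigma_site)
        u_plot = {p: rng.normal(0, sigma_plot) for p in range(4)}
        for t in range(trees_per_site):
            plot = t % 4
            hsm = rng.uniform(0.8, 1.5)
            fd = rng.uniform(0, 1)
            ba_z, hegyi_z, age_z = rng.normal(size=3)
            y = (
                b_hsm * hsm + b_rew * rew + b_fd * fd
                + u_site + u_plot[plot] + rng.normal(0, sigma)
            )
            rows.append(
                {
                    "log_response": y, "site_id": f"S{s}", "plot_id": f"S{s}p{plot}",
                    "tree_id": f"S{s}t{t}", "HSM_TLP": hsm, "FD_HSM_norm": fd, "nSR": 1 + t % 4,
                    "REWmin": rew, "prev_REWmin": prev, "BA_z": ba_z, "Hegyi_z": hegyi_z,
                    "age_z": age_z,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def consecutive_fit(small_scaffold):
    cfg = syn.EffectConfig(seed=5)
    df = syn.simulate_consecutive_responses(small_scaffold, cfg, seed=5)
    return ConsecutiveDroughtModel.from_dataframe(df).fit(), small_scaffold, cfg


class TestConsecutiveModel:
    def test_recovers_truth_within_wald_bands(self, consecutive_fit):
        fit, scaffold, cfg = consecutive_fit
        truth = syn.truth_consecutive_coefficients(scaffold, cfg)
        tab = fit.coefficient_table()
        for term, value in truth.items():
            assert abs(tab.loc[term, "estimate"] - value) < 4 * tab.loc[term, "se"], term

    def test_intercept_suppressed_year_levels_present(self, consecutive_fit):
        fit, _, _ = consecutive_fit
        assert "Intercept" not in fit.fe_names
        assert {f"C(resp_yr)[{r}]" for r in (1, 2, 3, 4)} <= set(fit.fe_names)

    def test_metadata_records_methods(self, consecutive_fit):
        fit, _, _ = consecutive_fit
        meta = fit.metadata
        assert meta["estimation"] == "REML"
        assert meta["aic_basis"] == "ML refit"
        assert "residual" in meta["df_method"]

    def test_missing_year_levels_rejected(self, consecutive_fit):
        _, scaffold, cfg = consecutive_fit
        df = syn.simulate_consecutive_responses(scaffold, cfg, seed=6)
        broken = df[~((df["tree_id"] == df["tree_id"].iloc[0]) & (df["resp_yr"] == 3))]
        with pytest.raises(ValueError, match="missing response-year levels"):
            ConsecutiveDroughtModel.from_dataframe(broken)

    def test_constant_response_is_degenerate(self, consecutive_fit):
        _, scaffold, cfg = consecutive_fit
        df = syn.simulate_consecutive_responses(scaffold, cfg, seed=7)
        df["log_response"] = 0.123
        with pytest.raises(DegenerateFitError):
            ConsecutiveDroughtModel.from_dataframe(df)

    def test_single_species_design_names_inestimable_terms(self, consecutive_fit):
        _, scaffold, cfg = consecutive_fit
        df = syn.simulate_consecutive_responses(scaffold, cfg, seed=8)
        sp = df["species_code"].iloc[0]
        mono = df[df["species_code"] == sp]
        keep = mono.groupby("tree_id")["resp_yr"].nunique() == 4
        mono = mono[mono["tree_id"].isin(keep[keep].index)]
        with pytest.raises(RankDeficientError, match="HSM"):
            ConsecutiveDroughtModel.from_dataframe(mono)


class TestSingleYearModel:
    def test_recovers_trait_and_drought_slopes(self):
        df = synth_single_year(seed=1, b_hsm=0.5, b_rew=1.2, n_sites=8, trees_per_site=80)
        fit = SingleYearDroughtModel.from_dataframe(df, interaction_order=2).fit()
        tab = fit.coefficient_table()
        assert abs(tab.loc["center(HSM_TLP)", "estimate"] - 0.5) < 3 * tab.loc["center(HSM_TLP)", "se"]

    def test_three_way_spec_includes_drought_interaction(self):
        df = synth_single_year(seed=2)
        fit = SingleYearDroughtModel.from_dataframe(df, drought_cov="REWmin").fit()
        assert any("REWmin" in n and ":" in n for n in fit.fe_names)
        assert "prev_REWmin" in fit.fe_names

    def test_type_one_error_controlled_under_null(self):
        """Nominal-level rejections of the diversity main effect under the null."""
        rejections = 0
        n_rep = 20
        for rep in range(n_rep):
            df = synth_single_year(seed=100 + rep)
            fit = SingleYearDroughtModel.from_dataframe(df, interaction_order=2).fit()
            rejections += fit.pvalues["FD_HSM_norm"] < 0.05
        assert rejections <= 4  # ~binomial(20, 0.05) upper tail

    def test_random_structure_is_plot_in_site(self):
        df = synth_single_year(seed=3)
        fit = SingleYearDroughtModel.from_dataframe(df, interaction_order=2).fit()
        vcs = fit.variance_components
        assert "group" in vcs and "residual" in vcs and len(vcs) >= 3


class TestEffectMonotonicity:
    def test_fitted_fd_magnitude_grows_with_true_effect(self, small_scaffold):
        """Larger simulated diversity effects yield larger fitted FD-by-year
        coefficients in expectation (replicated at three effect sizes)."""
        means = []
        for size in (0.0, 0.15, 0.30):
            cfg = syn.EffectConfig(beta_fd={1: 0.0, 2: 0.0, 3: -size, 4: 0.0})
            ests = []
            for rep in range(30):
                df = syn.simulate_consecutive_responses(small_scaffold, cfg, seed=3000 + rep)
                fit = ConsecutiveDroughtModel.from_dataframe(df).fit(ml_refit=False)
                ests.append(abs(fit.params["C(resp_yr)[3]:FD_HSM_norm"]))
            means.append(np.mean(ests))
        assert means[0] < means[1] < means[2]


class TestCompare:
    def test_identical_specs_have_zero_delta(self, consecutive_fit):
        fit, scaffold, cfg = consecutive_fit
        again = ConsecutiveDroughtModel(fit.model.data, fit.model.spec).fit()
        table = compare_models([fit, again])
        assert table["dAIC"].iloc[-1] == pytest.approx(0.0, abs=1e-6)

    def test_mismatched_data_rejected(self, consecutive_fit):
        fit, scaffold, cfg = consecutive_fit
        other = syn.simulate_consecutive_responses(scaffold, cfg, seed=9)
        fit2 = ConsecutiveDroughtModel.from_dataframe(other).fit()
        with pytest.raises(ValueError, match="different response"):
            compare_models([fit, fit2])

    def test_true_moderator_wins_aic(self, consecutive_fit):
        """FD drives the simulated effect, so the FD model should out-rank nSR."""
        fit, scaffold, cfg = consecutive_fit
        m2a = ConsecutiveDroughtModel(fit.model.data, ModelSpec(kind="consecutive", diversity="nSR")).fit()
        table = compare_models([fit, m2a]).set_index("name")
        assert table.loc["m2b", "rank"] == 1


class TestMarginalEffects:
    def test_linearity_in_diversity(self, consecutive_fit):
        fit, scaffold, _ = consecutive_fit
        hsm_mean = float(fit.model.data["HSM_TLP"].mean())
        me = marginal_effects(fit, {"FD_HSM_norm": [0.0, 0.6], "resp_yr": [3], "HSM_TLP": [hsm_mean]})
        diff = me["predicted"].iloc[1] - me["predicted"].iloc[0]
        expected = 0.6 * fit.params["C(resp_yr)[3]:FD_HSM_norm"]
        assert diff == pytest.approx(expected, abs=1e-9)

    def test_extrapolation_flagged(self, consecutive_fit):
        fit, _, _ = consecutive_fit
        with pytest.warns(RuntimeWarning, match="outside"):
            me = marginal_effects(fit, {"FD_HSM_norm": [5.0], "resp_yr": [3], "HSM_TLP": [1.0]})
        assert me["extrapolated"].all()

    def test_bands_widen_away_from_center(self, consecutive_fit):
        fit, _, _ = consecutive_fit
        me = marginal_effects(
            fit, {"FD_HSM_norm": [0.0, 0.3, 0.6], "resp_yr": [3], "HSM_TLP": [1.0]}
        )
        assert (me["ci_upper"] > me["ci_lower"]).all()


class TestR2:
    def test_conditional_at_least_marginal(self, consecutive_fit):
        fit, _, _ = consecutive_fit
        r2m, r2c = r2_nakagawa(fit)
        assert 0 <= r2m <= r2c <= 1

    def test_manual_recompute(self, consecutive_fit):
        fit, _, _ = consecutive_fit
        X = np.asarray(fit._res.model.exog)
        var_f = float(np.var(X @ fit.params.to_numpy()))
        vcs = fit.variance_components
        var_r = sum(v for k, v in vcs.items() if k != "residual")
        total = var_f + var_r + vcs["residual"]
        r2m, r2c = r2_nakagawa(fit)
        assert r2m == pytest.approx(var_f / total)
        assert r2c == pytest.approx((var_f + var_r) / total)

    def test_pure_noise_fixed_effects_give_small_marginal(self, default_scaffold):
        cfg = syn.EffectConfig(
            alpha_age=0.0, gamma_ba=0.0, theta0=0.0, theta_hsm=0.0,
            beta_fd={1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0},
            sigma2_site=0.0, sigma2_plot=0.0, sigma2_tree=0.0,
        )
        df = syn.simulate_consecutive_responses(default_scaffold, cfg, seed=17)
        fit = ConsecutiveDroughtModel.from_dataframe(df).fit()
        r2m, _ = r2_nakagawa(fit)
        assert r2m < 0.02
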