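"""Negative-binomial emergence model: fits, LRT, marginal means, Dunnett."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from weevilstats import EmergenceModel, SimulationConfig, lrt_treatment, simulate_emergence
from weevilstats.emergence import _ordered_levels
from weevilstats.vocab import TREATMENTS


def single_arm(counts, block_per_row=True):
    return pd.DataFrame(
        {
            "block": [f"B{i}" for i in range(len(counts))] if block_per_row else "B1",
            "treatment": "control",
            "emerged": counts,
        }
    )


class TestFitNB:
    def test_intercept_only_mean_equals_sample_mean(self):
        data = single_arm([5, 7, 9, 3])
        res = EmergenceModel(data, include_treatment=False, block_mode="none").fit()
        assert np.exp(res.params["Intercept"]) == pytest.approx(6.0, rel=1e-6)

    def test_fixed_theta_recovers_poisson_coefficients(self):
        cfg = SimulationConfig(seed=23, n_blocks=10)
        data = simulate_emergence(cfg)
        res = EmergenceModel(data, theta=1e8).fit()
        x = EmergenceModel(data)._design()
        pois = sm.GLM(data["emerged"].to_numpy(float), x, family=sm.families.Poisson()).fit()
        assert np.allclose(res.params.to_numpy(), pois.params.to_numpy(), rtol=1e-6)

    def test_parameter_recovery_moderate_scale(self):
        cfg = SimulationConfig(seed=29, n_blocks=100)
        res = EmergenceModel(simulate_emergence(cfg)).fit()
        ratios = res.treatment_ratios()
        for t in ("fungi", "halfmix", "nematodes"):
            assert ratios[t] == pytest.approx(cfg.rate_ratios[t], abs=0.1)
        assert res.converged

    def test_theta_estimate_sane(self):
        cfg = SimulationConfig(seed=31, n_blocks=200, nb_dispersion=5.0)
        res = EmergenceModel(simulate_emergence(cfg)).fit()
        assert 2.5 < res.theta < 10.0

    def test_all_zero_group_warns(self):
        data = pd.DataFrame(
            {
                "block": list("ABAB"),
                "treatment": ["control", "control", "fungi", "fungi"],
                "emerged": [4, 6, 0, 0],
            }
        )
        with pytest.warns(UserWarning, match="all-zero"):
            EmergenceModel(data)

    def test_control_level_required(self):
        data = single_arm([1, 2, 3]).assign(treatment="fungi")
        with pytest.raises(ValueError, match="control"):
            EmergenceModel(data)

    def test_level_ordering_puts_control_first(self):
        assert _ordered_levels(["fungi", "control", "halfmix"], TREATMENTS)[0] == "control"


class TestLRT:
    def test_identical_fits(self):
        data = simulate_emergence(SimulationConfig(seed=37, n_blocks=8))
        res = EmergenceModel(data, include_treatment=False).fit()
        chi2, df, p = lrt_treatment(res, res)
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_nested_loglik_ordering_and_df(self):
        data = simulate_emergence(SimulationConfig(seed=41, n_blocks=10))
        full = EmergenceModel(data).fit()
        null = EmergenceModel(data, include_treatment=False).fit()
        chi2, df, p = lrt_treatment(full, null)
        assert full.llf >= null.llf - 1e-6
        assert df == 3
        assert chi2 >= 0.0 and 0.0 <= p <= 1.0

    def test_block_mode_mismatch_rejected(self):
        data = simulate_emergence(SimulationConfig(seed=43, n_blocks=6))
        full = EmergenceModel(data, block_mode="fixed").fit()
        null = EmergenceModel(data, include_treatment=False, block_mode="none").fit()
        with pytest.raises(ValueError, match="block"):
            lrt_treatment(full, null)

    def test_power_regime_detectable(self):
        """At the trial's effect sizes and 10 blocks/arm the LRT is usually
        in the single-digit-to-teens range: detectable, not overwhelming."""
        chis = []
        for seed in range(40):
            data = simulate_emergence(SimulationConfig(seed=100 + seed, n_blocks=10))
            full = EmergenceModel(data).fit()
            null = EmergenceModel(data, include_treatment=False).fit()
            chis.append(lrt_treatment(full, null)[0])
        median = np.median(chis)
        assert 3.0 < median < 40.0


class TestMarginalMeans:
    def test_one_block_equals_group_sample_means(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(
            {
                "block": "B1",
                "treatment": np.repeat(list(TREATMENTS), 30),
                "emerged": rng.poisson([20, 10, 8, 6], size=(30, 4)).T.ravel(),
            }
        )
        res = EmergenceModel(data, block_mode="none").fit()
        mm = res.marginal_means()
        observed = data.groupby("treatment")["emerged"].mean()
        for t in TREATMENTS:
            assert mm.loc[t, "mean"] == pytest.approx(observed[t], rel=1e-5)

    def test_ratio_of_means_equals_exp_coefficient(self):
        data = simulate_emergence(SimulationConfig(seed=47, n_blocks=10))
        res = EmergenceModel(data).fit()
        mm = res.marginal_means()
        for t in ("fungi", "nematodes"):
            ratio = mm.loc[t, "mean"] / mm.loc["control", "mean"]
            assert ratio == pytest.approx(np.exp(res.params[f"treatment[{t}]"]), rel=1e-9)

    def test_delta_se_matches_parametric_bootstrap(self):
        cfg = SimulationConfig(seed=53, n_blocks=10, block_sd=0.0)
        data = simulate_emergence(cfg)
        res = EmergenceModel(data, block_mode="none").fit()
        mm = res.marginal_means()
        theta = res.theta
        mu_hat = {t: mm.loc[t, "mean"] for t in TREATMENTS}
        rng = np.random.default_rng(99)
        boot = []
        for _ in range(300):
            sim = data.copy()
            mus = sim["treatment"].map(mu_hat).to_numpy(float)
            sim["emerged"] = rng.poisson(rng.gamma(theta, mus / theta))
            bres = EmergenceModel(sim, block_mode="none").fit()
            boot.append(bres.marginal_means()["mean"])
        boot_se = pd.concat(boot, axis=1).std(axis=1)
        for t in TREATMENTS:
            assert mm.loc[t, "se"] == pytest.approx(boot_se[t], rel=0.25)


class TestDunnett:
    def test_single_contrast_matches_unadjusted(self):
        data = simulate_emergence(
            SimulationConfig(
                seed=59, n_blocks=12,
                treatments=("control", "nematodes"),
                outcome_probs={"control": (1, 0, 0, 0), "nematodes": (1, 0, 0, 0)},
                rate_ratios={"control": 1.0, "nematodes": 0.5},
                community_effect={"control": 1.0, "nematodes": 1.0},
            )
        )
        res = EmergenceModel(data).fit()
        (c,) = res.dunnett_contrasts(n_mc=200_000, seed=1)
        assert c.p_adjusted == pytest.approx(c.p_unadjusted, abs=0.01)

    def test_identity_correlation_matches_sidak(self):
        from weevilstats.emergence import EmergenceResults

        # synthetic results object with independent contrasts
        names = ["Intercept", "treatment[a]", "treatment[b]", "treatment[c]"]
        params = pd.Series([1.0, -0.4, -0.6, -0.2], index=names)
        vcov = pd.DataFrame(np.diag([0.01, 0.04, 0.04, 0.04]), index=names, columns=names)
        data = pd.DataFrame(
            {"block": ["B1", "B2"] * 4, "treatment": np.repeat(["control", "a", "b", "c"], 2),
             "emerged": 1}
        )
        model = EmergenceModel(data, block_mode="none")
        res = EmergenceResults(model=model, params=params, theta=5.0, llf=0.0,
                               vcov=vcov, converged=True, k_params=5)
        for c in res.dunnett_contrasts(n_mc=400_000, seed=2):
            sidak = 1 - (1 - c.p_unadjusted) ** 3
            assert c.p_adjusted == pytest.approx(sidak, abs=0.01)

    def test_adjusted_at_least_unadjusted(self):
        data = simulate_emergence(SimulationConfig(seed=61, n_blocks=10))
        res = EmergenceModel(data).fit()
        for c in res.dunnett_contrasts(n_mc=50_000, seed=3):
            assert c.p_adjusted >= c.p_unadjusted
            assert 0.0 < c.ratio
            assert 0.0 <= c.p_adjusted <= 1.0


class TestRandomBlockMode:
    def test_fixed_and_random_agree_on_balanced_data(self):
        cfg = SimulationConfig(seed=67, n_blocks=20, block_sd=0.3)
        data = simulate_emergence(cfg)
        fixed = EmergenceModel(data, block_mode="fixed").fit()
        random = EmergenceModel(data, block_mode="random").fit()
        rf, rr = fixed.treatment_ratios(), random.treatment_ratios()
        for t in ("fungi", "halfmix", "nematodes"):
            assert rr[t] == pytest.approx(rf[t], rel=0.05)
        assert 0.0 < random.sigma_block < 1.0

    def test_random_mode_lrt(self):
        data = simulate_emergence(SimulationConfig(seed=71, n_blocks=12))
        full = EmergenceModel(data, block_mode="random").fit()
        null = EmergenceModel(data, include_treatment=False, block_mode="random").fit()
        chi2, df, p = lrt_treatment(full, null)
        assert df == 3 and chi2 >= 0.0
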