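import numpy as np
import pandas as pd
import pytest

import policytextpanel as ptp
from policytextpanel.estimators import (
    ModelSpec,
    RankError,
    SpecError,
    fit_fe_2sls,
    fit_two_part,
    fit_twoway_fe,
    lincom,
    marginal_effects,
)

from conftest import lsdv_fit, make_small_panel


def spec_fe(outcome, regressors, **kw):
    return ModelSpec(outcome=outcome, regressors=tuple(regressors), cluster="none", **kw)


class TestTwowayFE:
    def test_matches_lsdv_oracle_small_fixture(self, small_panel):
        spec = spec_fe("y", ["x1", "x2"])
        fit = fit_twoway_fe(small_panel, spec)
        oracle = lsdv_fit(small_panel, "y", ["x1", "x2"])
        for name in ("x1", "x2"):
            assert fit.params[name] == pytest.approx(oracle[name], abs=1e-8)

    def test_matches_lsdv_on_larger_fixture(self):
        df = make_small_panel(n_persons=40, n_waves=4, seed=2)
        assert len(df) <= 200
        spec = spec_fe("y", ["x1", "x2"])
        fit = fit_twoway_fe(df, spec)
        oracle = lsdv_fit(df, "y", ["x1", "x2"])
        for name in ("x1", "x2"):
            assert fit.params[name] == pytest.approx(oracle[name], abs=1e-8)

    def test_person_constant_regressor_flagged_unidentified(self, small_panel):
        df = small_panel.copy()
        df["fixed_trait"] = df["person_id"].str.len().astype(float)  # constant per person
        fit = fit_twoway_fe(df, spec_fe("y", ["x1", "fixed_trait"]))
        assert "fixed_trait" in fit.unidentified
        assert "fixed_trait" not in fit.params.index

    def test_collinear_regressors_raise_rank_error(self, small_panel):
        df = small_panel.copy()
        df["x3"] = df["x1"] + df["x2"]
        with pytest.raises(RankError, match="collinear"):
            fit_twoway_fe(df, spec_fe("y", ["x1", "x2", "x3"]))

    def test_outcome_shift_invariance(self, small_panel):
        spec = spec_fe("y", ["x1", "x2"])
        base = fit_twoway_fe(small_panel, spec)
        shifted = small_panel.copy()
        shifted["y"] = shifted["y"] + 100.0
        after = fit_twoway_fe(shifted, spec)
        for name in ("x1", "x2"):
            assert after.params[name] == pytest.approx(base.params[name], abs=1e-10)

    def test_singleton_clusters_reduce_to_hc1(self, small_panel):
        df = small_panel.copy()
        df["prefecture_id"] = [f"solo{i}" for i in range(len(df))]
        hc1 = fit_twoway_fe(df, spec_fe("y", ["x1", "x2"]))
        cr1 = fit_twoway_fe(
            df, ModelSpec(outcome="y", regressors=("x1", "x2"), cluster="prefecture")
        )
        np.testing.assert_allclose(cr1.vcov.to_numpy(), hc1.vcov.to_numpy(), rtol=1e-10)

    def test_cluster_robust_se_nonnegative(self, small_panel):
        fit = fit_twoway_fe(
            small_panel, ModelSpec(outcome="y", regressors=("x1", "x2"), cluster="prefecture")
        )
        assert (np.diag(fit.vcov.to_numpy()) >= 0).all()

    def test_vcov_positive_semidefinite(self, small_panel):
        fit = fit_twoway_fe(small_panel, spec_fe("y", ["x1", "x2"]))
        eigs = np.linalg.eigvalsh(fit.vcov.to_numpy())
        assert (eigs > -1e-12).all()

    def test_r2_within_bounds(self, small_panel):
        fit = fit_twoway_fe(small_panel, spec_fe("y", ["x1", "x2"]))
        assert 0.0 <= fit.r2_within <= 1.0

    def test_endogenous_spec_rejected(self, small_panel):
        spec = ModelSpec(
            outcome="y", regressors=("x1",), endogenous="x2", instruments=("x1",)
        )
        with pytest.raises(SpecError):
            fit_twoway_fe(small_panel, spec)


@pytest.fixture(scope="module")
def synthetic_exposure_table():
    corpus_spec = ptp.CorpusSpec(n_prefectures=20, seed=5)
    _, truth = ptp.generate_corpus(corpus_spec)
    return ptp.rescale(truth.exposure, 100.0)


COVARS = ("days_unable", "severity", "utilization", "age", "log_income")
FULL_REGRESSORS = (
    "uebmi_enrolled",
    "benefit_expansion",
    "cost_containment",
    "uebmi_enrolled:benefit_expansion",
    "uebmi_enrolled:cost_containment",
    "benefit_expansion:cost_containment",
    "uebmi_enrolled:benefit_expansion:cost_containment",
    "service_delivery",
    "pharmaceutical",
    *COVARS,
)


class TestParameterRecovery:
    def test_interaction_recovery_monte_carlo(self, synthetic_exposure_table):
        """Mean of b6-hat across replicates within 3 MC SEs of the planted value
        (the full 200-replicate run lives in the acceptance suite)."""
        spec = ModelSpec(
            outcome="log_oop", regressors=FULL_REGRESSORS, cluster="individual"
        )
        true_b6 = ptp.Beta().b6_expansion_containment
        estimates = []
        for r in range(30):
            pspec = ptp.PanelSpec(
                n_individuals_per_prefecture_wave=25, gamma_confounder=0.0, seed=300 + r
            )
            panel, _ = ptp.generate_panel(pspec, synthetic_exposure_table)
            merged = ptp.merge_exposures(panel, synthetic_exposure_table).data
            fit = fit_twoway_fe(merged, spec)
            estimates.append(fit.params["benefit_expansion:cost_containment"])
        estimates = np.asarray(estimates)
        mc_se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - true_b6) < 3 * mc_se


class TestFE2SLS:
    def test_self_instrument_equals_ols(self, small_panel):
        iv = fit_fe_2sls(
            small_panel,
            ModelSpec(
                outcome="y",
                regressors=("x2",),
                endogenous="x1",
                instruments=("x1",),
                cluster="none",
            ),
        )
        ols = fit_twoway_fe(small_panel, spec_fe("y", ["x1", "x2"]))
        for name in ("x1", "x2"):
            assert iv.params[name] == pytest.approx(ols.params[name], abs=1e-10)

    def test_just_identified_equals_iv_ratio(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(15):
            fe = rng.normal()
            for t in range(3):
                z = rng.normal()
                x = 0.6 * z + rng.normal(0, 0.5)
                y = 2.0 * x + fe + rng.normal(0, 0.3)
                rows.append({"person_id": f"i{i}", "year": 2000 + t, "z": z, "x": x, "y": y})
        df = pd.DataFrame(rows)
        fit = fit_fe_2sls(
            df,
            ModelSpec(
                outcome="y",
                regressors=(),
                endogenous="x",
                instruments=("z",),
                fe=frozenset({"individual"}),
                cluster="none",
            ),
        )
        demean = lambda s: s - s.groupby(df["person_id"]).transform("mean")
        zt, xt, yt = demean(df["z"]), demean(df["x"]), demean(df["y"])
        wald = float((zt * yt).sum() / (zt * xt).sum())
        assert fit.params["x"] == pytest.approx(wald, abs=1e-10)
        assert fit.diagnostics["overid_stat"] is None  # just identified

    def test_endogeneity_correction(self):
        """Confounded DGP: OLS biased away from truth, 2SLS covers it."""
        rng = np.random.default_rng(42)
        rows = []
        for i in range(600):
            fe = rng.normal()
            for t in range(3):
                conf = rng.normal()
                z1, z2 = rng.normal(), rng.normal()
                x = 0.8 * z1 - 0.5 * z2 + 0.9 * conf + rng.normal(0, 0.5)
                y = -1.0 * x + fe + 0.9 * conf + 0.1 * t + rng.normal(0, 0.5)
                rows.append(
                    {"person_id": f"i{i}", "prefecture_id": f"p{i % 10}",
                     "year": 2000 + t, "z1": z1, "z2": z2, "x": x, "y": y}
                )
        df = pd.DataFrame(rows)
        iv_spec = ModelSpec(
            outcome="y", regressors=(), endogenous="x",
            instruments=("z1", "z2"), cluster="none",
        )
        iv = fit_fe_2sls(df, iv_spec)
        ols = fit_twoway_fe(df, spec_fe("y", ["x"]))
        assert abs(iv.params["x"] - (-1.0)) < 3 * iv.se("x")
        assert abs(ols.params["x"] - (-1.0)) > 5 * ols.se("x")  # visibly biased
        assert iv.diagnostics["first_stage_F"] > 50
        assert iv.diagnostics["endogeneity_p"] < 0.01
        assert iv.diagnostics["overid_p"] > 0.01  # valid instruments

    def test_exogenous_regressor_passes_hausman(self):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(300):
            fe = rng.normal()
            for t in range(3):
                z = rng.normal()
                x = 0.8 * z + rng.normal(0, 0.5)
                y = 1.0 * x + fe + rng.normal(0, 0.5)
                rows.append({"person_id": f"i{i}", "year": 2000 + t, "z": z, "x": x, "y": y})
        df = pd.DataFrame(rows)
        fit = fit_fe_2sls(
            df,
            ModelSpec(outcome="y", regressors=(), endogenous="x",
                      instruments=("z",), cluster="none"),
        )
        assert fit.diagnostics["endogeneity_p"] > 0.05

    def test_instrument_overlap_rejected(self, small_panel):
        with pytest.raises(SpecError):
            fit_fe_2sls(
                small_panel,
                ModelSpec(outcome="y", regressors=("x2",), endogenous="x1",
                          instruments=("x2",), cluster="none"),
            )

    def test_duplicate_instruments_rank_deficient(self, small_panel):
        df = small_panel.copy()
        df["z"] = df["x1"] + np.random.default_rng(0).normal(0, 1, len(df))
        df["z_copy"] = df["z"]
        with pytest.raises(RankError):
            fit_fe_2sls(
                df,
                ModelSpec(outcome="y", regressors=("x2",), endogenous="x1",
                          instruments=("z", "z_copy"), cluster="none"),
            )

    def test_forbidden_regression_guard(self, small_panel):
        with pytest.raises(SpecError, match="plug-in"):
            fit_fe_2sls(
                small_panel,
                ModelSpec(outcome="y", regressors=("x2",), endogenous="x1",
                          instruments=("x2", "y"), cluster="none"),
                force_plugin=True,
            )


class TestLincom:
    def test_unit_vector_reproduces_coefficient(self, small_panel):
        fit = fit_twoway_fe(small_panel, spec_fe("y", ["x1", "x2"]))
        lc = lincom(fit, "x1")
        assert lc.estimate == pytest.approx(fit.params["x1"])
        assert lc.se == pytest.approx(fit.se("x1"))
        assert lc.p == pytest.approx(fit.pvalue("x1"))

    def test_weighted_contrast_parsing(self, small_panel):
        fit = fit_twoway_fe(small_panel, spec_fe("y", ["x1", "x2"]))
        lc = lincom(fit, "x1 + 0.5*x2 - 0.5*x2")
        assert lc.estimate == pytest.approx(fit.params["x1"])

    def test_dict_contrast(self, small_panel):
        fit = fit_twoway_fe(small_panel, spec_fe("y", ["x1", "x2"]))
        lc = lincom(fit, {"x1": 1.0, "x2": 2.0})
        expected = fit.params["x1"] + 2 * fit.params["x2"]
        assert lc.estimate == pytest.approx(expected)
        c = np.array([1.0, 2.0])
        V = fit.vcov.loc[["x1", "x2"], ["x1", "x2"]].to_numpy()
        assert lc.se == pytest.approx(float(np.sqrt(c @ V @ c)))

    def test_unknown_coefficient_rejected(self, small_panel):
        fit = fit_twoway_fe(small_panel, spec_fe("y", ["x1", "x2"]))
        with pytest.raises(SpecError, match="nope"):
            lincom(fit, "x1 + nope")

    def test_delta_se_close_to_cluster_bootstrap(self):
        """Delta-method SE vs person-level bootstrap SD on a small fixture."""
        df = make_small_panel(n_persons=30, n_waves=3, seed=4)
        spec = ModelSpec(outcome="y", regressors=("x1", "x2"), cluster="individual")
        fit = fit_twoway_fe(df, spec)
        target = lincom(fit, "x1 + 0.5*x2")

        rng = np.random.default_rng(99)
        persons = df["person_id"].unique()
        estimates = []
        for _ in range(500):
            chosen = rng.choice(persons, size=len(persons), replace=True)
            parts = []
            for j, pid in enumerate(chosen):
                block = df[df["person_id"] == pid].copy()
                block["person_id"] = f"b{j}"
                parts.append(block)
            boot = pd.concat(parts, ignore_index=True)
            bfit = fit_twoway_fe(boot, spec)
            estimates.append(bfit.params["x1"] + 0.5 * bfit.params["x2"])
        boot_se = float(np.std(estimates, ddof=1))
        assert abs(target.se - boot_se) / boot_se < 0.15


@pytest.fixture(scope="module")
def interaction_fit():
    rng = np.random.default_rng(12)
    rows = []
    for i in range(80):
        fe = rng.normal()
        for t in range(3):
            d = float(rng.random() < 0.5)
            e = rng.normal(1.0, 1.0)
            c = rng.normal(0.5, 1.0)
            y = (
                0.8 * d - 0.4 * e + 0.3 * c + 0.5 * d * e - 0.7 * d * c
                + 0.2 * e * c - 0.3 * d * e * c + fe + rng.normal(0, 0.4)
            )
            rows.append({"person_id": f"i{i}", "year": 2000 + t,
                         "d": d, "e": e, "c": c, "y": y})
    df = pd.DataFrame(rows)
    spec = spec_fe("y", ["d", "e", "c", "d:e", "d:c", "e:c", "d:e:c"])
    return fit_twoway_fe(df, spec)


class TestMarginalEffects:

    def test_effect_at_zero_equals_main_coefficient(self, interaction_fit):
        table = marginal_effects(interaction_fit, "d", "e", [0.0], fixed={"c": 0.0})
        assert table["effect"].iloc[0] == pytest.approx(interaction_fit.params["d"])
        assert table["se"].iloc[0] == pytest.approx(interaction_fit.se("d"))

    def test_sign_change_at_ratio(self, interaction_fit):
        beta_d = interaction_fit.params["d"]
        beta_de = interaction_fit.params["d:e"]
        m_star = -beta_d / beta_de
        table = marginal_effects(interaction_fit, "d", "e", [m_star], fixed={"c": 0.0})
        assert table["effect"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_vectorized_agrees_with_per_point_lincom(self, interaction_fit):
        grid = [-1.0, 0.0, 0.5, 2.0]
        c_fix = 0.7
        table = marginal_effects(interaction_fit, "d", "e", grid, fixed={"c": c_fix})
        for m, effect, se in zip(table["moderator_value"], table["effect"], table["se"]):
            lc = lincom(
                interaction_fit,
                {"d": 1.0, "d:e": m, "d:c": c_fix, "d:e:c": m * c_fix},
            )
            assert effect == pytest.approx(lc.estimate, abs=1e-12)
            assert se == pytest.approx(lc.se, abs=1e-12)

    def test_three_way_moderation(self, interaction_fit):
        p = interaction_fit.params
        table = marginal_effects(interaction_fit, "d", "e", [1.5], fixed={"c": 2.0})
        expected = p["d"] + 1.5 * p["d:e"] + 2.0 * p["d:c"] + 3.0 * p["d:e:c"]
        assert table["effect"].iloc[0] == pytest.approx(expected)

    def test_out_of_range_grid_warns(self, interaction_fit):
        with pytest.warns(UserWarning, match="outside observed range"):
            marginal_effects(interaction_fit, "d", "e", [1e6])

    def test_missing_interaction_rejected(self, small_panel):
        fit = fit_twoway_fe(small_panel, spec_fe("y", ["x1", "x2"]))
        with pytest.raises(SpecError, match="interaction"):
            marginal_effects(fit, "x1", "x2", [0.0])

    def test_output_sorted_by_moderator(self, interaction_fit):
        table = marginal_effects(interaction_fit, "d", "e", [2.0, -1.0, 0.5])
        assert list(table["moderator_value"]) == [-1.0, 0.5, 2.0]


class TestTwoPart:
    def _spending_panel(self, p_spend=0.75, seed=0, n_persons=120):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_persons):
            fe = rng.normal(0, 0.5)
            for t in range(3):
                x1 = rng.normal()
                spend = 0.0
                if rng.random() < p_spend:
                    spend = float(np.exp(3.0 + 0.8 * x1 + fe + rng.normal(0, 0.5)))
                rows.append(
                    {"person_id": f"i{i}", "prefecture_id": f"p{i % 5}",
                     "year": 2000 + t, "x1": x1, "spend": spend}
                )
        return pd.DataFrame(rows)

    def test_all_positive_part1_degenerate_part2_equals_fe(self):
        df = self._spending_panel(p_spend=1.0, seed=1)
        spec = spec_fe("spend", ["x1"])
        part1, part2 = fit_two_part(df, spec)
        assert "degenerate_binary_part" in part1.flags
        df_log = df.copy()
        df_log["log_spend"] = np.log(df_log["spend"])
        direct = fit_twoway_fe(df_log, spec_fe("log_spend", ["x1"]))
        assert part2.params["x1"] == pytest.approx(direct.params["x1"], abs=1e-10)

    def test_perfect_separation_flagged(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(40):
            for t in range(2):
                flag = float(i % 2)
                spend = 5.0 + rng.random() if flag else 0.0
                rows.append(
                    {"person_id": f"i{i}", "prefecture_id": "p0",
                     "year": 2000 + t, "flag": flag, "spend": spend}
                )
        df = pd.DataFrame(rows)
        part1, _ = fit_two_part(df, spec_fe("spend", ["flag"]))
        assert "separation" in part1.flags
        assert part1.params.empty

    def test_part1_probit_estimates_reasonable(self):
        df = self._spending_panel(p_spend=0.75, seed=5, n_persons=400)
        part1, _ = fit_two_part(df, spec_fe("spend", ["x1"]))
        assert not part1.flags
        # no dependence of the spending indicator on x1 in this DGP
        assert abs(part1.params["x1"]) < 4 * part1.se("x1")

    def test_part2_positive_subsample_recovery(self):
        df = self._spending_panel(p_spend=0.75, seed=7, n_persons=400)
        _, part2 = fit_two_part(df, spec_fe("spend", ["x1"]))
        assert abs(part2.params["x1"] - 0.8) < 3 * part2.se("x1")

    def test_two_part_recovers_planted_interaction(self, synthetic_exposure_table):
        pspec = ptp.PanelSpec(
            n_individuals_per_prefecture_wave=60,
            p_spend_intercept=0.8,
            gamma_confounder=0.0,
            seed=11,
        )
        panel, _ = ptp.generate_panel(pspec, synthetic_exposure_table)
        merged = ptp.merge_exposures(panel, synthetic_exposure_table).data
        spec = ModelSpec(
            outcome="oop_raw", regressors=FULL_REGRESSORS, cluster="individual"
        )
        part1, part2 = fit_two_part(merged, spec)
        true_b6 = ptp.Beta().b6_expansion_containment
        est = part2.params["benefit_expansion:cost_containment"]
        assert abs(est - true_b6) < 3 * part2.se("benefit_expansion:cost_containment")

    def test_negative_spending_rejected(self, small_panel):
        with pytest.raises(SpecError):
            fit_two_part(small_panel, spec_fe("y", ["x1"]))  # y can be negative
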