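"""Treatment/recovery model family, response magnitudes, and the
non-parametric group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pinetherm.design import TREATMENT_TERMS
from pinetherm.lmm import fit_lmm
from pinetherm.stress_models import simplify_model
from pinetherm.synthetic import ExperimentParams, generate_experiment
from pinetherm.treatment_models import (
    RECOVERY_WINDOW,
    STRESS_WINDOW,
    PeriodWindow,
    build_treatment_model,
    kruskal_dunn,
    response_magnitude,
    treatment_contrasts,
    treatment_effect_reduction,
)

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")


def window_subset(obs, window):
    return obs[obs["day"].isin(window.day_indices)]


class TestWindows:
    def test_stress_and_recovery_are_disjoint_and_cover_4_to_17(self):
        assert not set(STRESS_WINDOW.day_indices) & set(RECOVERY_WINDOW.day_indices)
        assert set(STRESS_WINDOW.day_indices) == set(range(4, 14))
        assert set(RECOVERY_WINDOW.day_indices) == {14, 15, 16, 17}

    def test_every_observation_in_at_most_one_window(self, treatment_obs):
        obs, _ = treatment_obs
        s = window_subset(obs, STRESS_WINDOW).index
        r = window_subset(obs, RECOVERY_WINDOW).index
        assert len(set(s) & set(r)) == 0

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            PeriodWindow("bad", ())
        with pytest.raises(ValueError):
            PeriodWindow("bad", (0, 1))


class TestBuildModel:
    def test_full_term_structure_matches_treatment_equation(self, treatment_obs):
        obs, _ = treatment_obs
        spec = build_treatment_model(obs, STRESS_WINDOW)
        assert set(spec.terms) == set(TREATMENT_TERMS)
        # treatment dummy: drought = 0, control = 1
        from pinetherm.design import build_design

        X, names = build_design(spec, window_subset(obs, STRESS_WINDOW))
        col = X[:, names.index("treatment")]
        sub = window_subset(obs, STRESS_WINDOW)
        assert np.array_equal(col, (sub["treatment"] == "control").astype(float))

    def test_empty_window_rejected(self, treatment_obs):
        obs, _ = treatment_obs
        with pytest.raises(ValueError, match="no observations"):
            build_treatment_model(obs[obs["day"] < 0], STRESS_WINDOW)

    def test_single_treatment_window_rejected(self, treatment_obs):
        obs, _ = treatment_obs
        ctrl = obs[obs["treatment"] == "control"]
        with pytest.raises(ValueError, match="single treatment"):
            build_treatment_model(ctrl, STRESS_WINDOW)

    def test_flipping_treatment_coding_flips_sign_keeps_z(self, treatment_obs):
        obs, _ = treatment_obs
        sub = window_subset(obs, STRESS_WINDOW)
        spec = build_treatment_model(obs, STRESS_WINDOW)
        fit = fit_lmm(spec, sub, method="REML")
        flipped = sub.copy()
        flipped["treatment"] = flipped["treatment"].map(
            {"control": "drought", "drought": "control"}
        )
        spec_f = build_treatment_model(flipped, STRESS_WINDOW)
        fit_f = fit_lmm(spec_f, flipped, method="REML")
        b, b_f = fit.params["treatment"], fit_f.params["treatment"]
        z = b / fit.bse["treatment"]
        z_f = b_f / fit_f.bse["treatment"]
        assert b_f == pytest.approx(-b, abs=1e-8)
        # the flipped dummy is an exact reparameterization; the residual
        # discrepancy in |z| is linear-algebra round-off between the two
        # equivalent design matrices
        assert abs(z_f) == pytest.approx(abs(z), abs=5e-6)

    def test_simplification_drops_null_terms_keeps_active_ones(self):
        # generated with recovery-style structure: treatment, time, airT and
        # radiation active; dimensions and treatment interactions null.
        # Backward AIC deletion retains a pure-noise term with nontrivial
        # probability at a 4-day window, so null terms are judged in
        # aggregate while active terms must always survive.
        coeffs = {"intercept": 0.4, "treatment": -0.11, "t": -0.3,
                  "air_temp": 0.024, "radiation": 0.00086}
        nulls = ("treatment:height", "treatment:diameter", "height",
                 "diameter", "treatment:t", "treatment:rh")
        dropped = 0
        for seed in (404, 405, 406, 407):
            params = ExperimentParams(seed=seed, coefficients=coeffs, residual_sd=0.05)
            obs, _ = generate_experiment(params, model="treatment")
            sub = window_subset(obs, RECOVERY_WINDOW)
            spec = build_treatment_model(obs, RECOVERY_WINDOW)
            spec, _ = simplify_model(spec, sub)
            for active in ("treatment", "t", "air_temp", "radiation"):
                assert active in spec.terms
            dropped += sum(n not in spec.terms for n in nulls)
        assert dropped >= len(nulls) * 4 // 2


class TestTreatmentContrasts:
    @pytest.fixture(scope="class")
    def stress_fit(self):
        obs, truth = generate_experiment(ExperimentParams(seed=43), model="treatment")
        sub = obs[obs["day"].isin(STRESS_WINDOW.day_indices)]
        spec = build_treatment_model(obs, STRESS_WINDOW)
        return fit_lmm(spec, sub, method="REML")

    def test_families_and_sizes(self, stress_fit):
        out = treatment_contrasts(stress_fit)
        assert len(out["treatment_within_provenance"].table) == 6
        assert len(out["provenance_within_drought"].table) == 15
        assert len(out["provenance_within_control"].table) == 15

    def test_strong_treatment_effect_found_per_provenance(self, stress_fit):
        tab = treatment_contrasts(stress_fit)["treatment_within_provenance"].table
        # generating treatment gap is -0.23 with residual SD 0.08
        assert (tab["p_adj"] < 0.01).all()
        assert (tab["estimate"] < 0).all()  # control cooler-indexed than drought

    def test_unresponsive_provenance_stands_out(self):
        # five provenances respond to drought; the sixth does not: its
        # interaction cancels the main treatment effect
        coeffs = {"intercept": 0.45, "treatment": -0.25,
                  "provenance[I4]:treatment": 0.25}
        params = ExperimentParams(seed=507, coefficients=coeffs, residual_sd=0.06)
        obs, _ = generate_experiment(params, model="treatment")
        sub = obs[obs["day"].isin(STRESS_WINDOW.day_indices)]
        fit = fit_lmm(build_treatment_model(obs, STRESS_WINDOW), sub, method="REML")
        tab = treatment_contrasts(fit)["treatment_within_provenance"].table
        tab = tab.set_index(tab["a"].str.split(":").str[0])
        assert tab.loc["I4", "p_adj"] > 0.05
        assert (tab.drop(index="I4")["p_adj"] < 0.05).all()


class TestEffectReduction:
    def test_printed_coefficients_give_about_half(self):
        out = treatment_effect_reduction(-0.23, -0.11)
        assert out["percent"] == pytest.approx(52.17, abs=0.01)
        assert out["rounded_to_ten"] == 50.0

    def test_equal_and_zero_recovery_cases(self):
        assert treatment_effect_reduction(-0.2, -0.2)["percent"] == 0.0
        assert treatment_effect_reduction(-0.2, 0.0)["percent"] == 100.0

    def test_zero_stress_coefficient_rejected(self):
        with pytest.raises(ValueError):
            treatment_effect_reduction(0.0, -0.1)

    def test_accepts_fitted_models(self, treatment_obs):
        obs, _ = treatment_obs
        fits = {}
        for w in (STRESS_WINDOW, RECOVERY_WINDOW):
            sub = obs[obs["day"].isin(w.day_indices)]
            fits[w.name] = fit_lmm(build_treatment_model(obs, w), sub, method="REML")
        out = treatment_effect_reduction(fits["stress"], fits["recovery"])
        assert np.isfinite(out["percent"])


class TestResponseMagnitude:
    def test_combinatorics_within_provenance(self):
        params = ExperimentParams(seed=3)
        obs, _ = generate_experiment(params, model="treatment")
        tab = response_magnitude(obs, "cwsi", STRESS_WINDOW)
        # 4 drought x 4 control per provenance, 6 provenances
        assert len(tab) == 6 * 16
        one = tab[tab["provenance"] == "ES1"]
        assert one["drought_tree_id"].nunique() == 4
        assert one["control_tree_id"].nunique() == 4

    def test_identical_series_give_zero_deltas(self):
        days = list(range(4, 14))
        rows = []
        for prov in ("A", "B"):
            for treat in ("control", "drought"):
                for k in range(2):
                    for d in days:
                        rows.append({"tree_id": f"{prov}{treat}{k}", "provenance": prov,
                                     "treatment": treat, "day": d, "cwsi": 0.4})
        obs = pd.DataFrame(rows)
        tab = response_magnitude(obs, "cwsi", STRESS_WINDOW)
        assert np.allclose(tab["delta_index"], 0.0)

    def test_provenance_missing_a_treatment_excluded_with_warning(self):
        params = ExperimentParams(seed=3)
        obs, _ = generate_experiment(params, model="treatment")
        obs = obs[~((obs["provenance"] == "I4") & (obs["treatment"] == "drought"))]
        with pytest.warns(UserWarning, match="I4"):
            tab = response_magnitude(obs, "cwsi", STRESS_WINDOW)
        assert "I4" not in set(tab["provenance"])

    def test_provenance_specific_effects_separated_by_kruskal_dunn(self):
        # strongest response in ES1, none in I4 (cancelling interaction)
        coeffs = {"intercept": 0.45, "treatment": -0.2,
                  "provenance[ES1]:treatment": -0.25,
                  "provenance[I4]:treatment": 0.2}
        params = ExperimentParams(seed=606, coefficients=coeffs, residual_sd=0.05)
        obs, _ = generate_experiment(params, model="treatment")
        tab = response_magnitude(obs, "cwsi", STRESS_WINDOW)
        groups = {p: g["delta_index"].to_numpy() for p, g in tab.groupby("provenance")}
        res = kruskal_dunn(groups)
        assert res["p_kruskal"] < 0.01
        dunn = res["dunn"]
        extreme = dunn[((dunn["a"] == "ES1") & (dunn["b"] == "I4"))
                       | ((dunn["a"] == "I4") & (dunn["b"] == "ES1"))]
        assert (extreme["p_adj"] < 0.05).all()


class TestKruskalDunn:
    def test_two_groups_equivalent_to_squared_rank_sum(self, rng):
        a, b = rng.normal(0, 1, 18), rng.normal(0.5, 1, 14)
        res = kruskal_dunn({"a": a, "b": b})
        z = stats.ranksums(a, b).statistic
        assert res["H"] == pytest.approx(z**2, rel=1e-9)

    def test_shifted_group_detected_with_direction(self, rng):
        groups = {
            "low": rng.normal(0, 1, 25),
            "mid": rng.normal(0, 1, 25),
            "high": rng.normal(2.5, 1, 25),
        }
        res = kruskal_dunn(groups)
        dunn = res["dunn"].set_index(["a", "b"])
        row = dunn.loc[("low", "high")] if ("low", "high") in dunn.index else dunn.loc[("high", "low")]
        assert row["p_adj"] < 0.01
        assert res["mean_ranks"]["high"] > res["mean_ranks"]["low"]

    def test_rank_statistics_invariant_under_monotone_transform(self, rng):
        groups = {k: rng.normal(m, 1, 20) for k, m in [("a", 0), ("b", 0.8), ("c", 1.6)]}
        res1 = kruskal_dunn(groups)
        res2 = kruskal_dunn({k: np.exp(v) for k, v in groups.items()})
        assert res1["H"] == pytest.approx(res2["H"], rel=1e-12)
        assert np.allclose(res1["dunn"]["stat"], res2["dunn"]["stat"])

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            kruskal_dunn({"a": [1.0], "b": [1.0, 2.0, 3.0]})
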