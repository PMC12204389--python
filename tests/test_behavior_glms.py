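"""Regression battery: registry, recovery of injected effects, contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from foragehmm import task
from foragehmm.behavior_glms import (
    add_state_columns,
    fit_model,
    get_spec,
    lagged_outcome_scan,
    registry,
    tus_contrasts,
)
from foragehmm.features import add_derived_regressors
from foragehmm.glmhmm import GLMHMM, build_design


class TestRegistry:
    def test_thirteen_specs(self):
        specs = registry()
        assert len(specs) == 13
        names = {s.name for s in specs}
        assert {"GLM1.1", "GLM2.5", "GLM4.5"} <= names

    def test_rt_and_pupil_models_have_no_random_intercept(self):
        for name in ("GLM2.3", "GLM2.4"):
            spec = get_spec(name)
            assert not spec.random_intercept
            assert spec.random_slope == "motivation"

    def test_condition_models_use_sham_reference(self):
        for name in ("GLM4.1", "GLM4.2", "GLM4.3", "GLM4.4", "GLM4.5"):
            assert "Treatment('sham')" in get_spec(name).formula

    def test_unknown_model_rejected(self):
        with pytest.raises(KeyError, match="GLM9"):
            get_spec("GLM9.9")


def _synthetic_logit_table(beta_richness=0.5, n=24000, seed=0):
    """Decisions generated directly from a logistic model with known
    coefficients on z-scored predictors (the spec's own generative form)."""
    rng = np.random.default_rng(seed)
    n_subj = 4
    subj = np.repeat([f"m{i}" for i in range(n_subj)], n // n_subj)
    sess = np.char.add(subj.astype(str), np.tile(
        np.repeat([f"_s{j}" for j in range(10)], n // n_subj // 10), n_subj
    ).astype(str))
    z_rich = rng.normal(0, 1, n)
    z_mag = rng.normal(0, 1, n)
    logit = 0.2 + beta_richness * z_rich + 0.6 * z_mag
    table = pd.DataFrame(
        {
            "subject_id": subj,
            "session_id": sess,
            "trial_number": np.tile(np.arange(n // n_subj // 10), n_subj * 10),
            "reward_magnitude": z_mag,
            "reward_probability": rng.normal(0, 1, n),
            "richness": z_rich,
            "stochasticity": rng.normal(0, 1, n),
            "decision": (rng.random(n) < expit(logit)).astype(int),
        }
    )
    return table


class TestFitModel:
    def test_recovers_injected_richness_effect(self):
        table = _synthetic_logit_table(beta_richness=0.5)
        fit = fit_model("GLM1.2", table, method="fixed", zscore=False)
        assert fit.term("richness")["estimate"] == pytest.approx(0.5, abs=0.06)
        assert fit.term("reward_magnitude")["estimate"] == pytest.approx(0.6, abs=0.06)

    def test_mixed_and_fixed_agree_on_homogeneous_data(self):
        table = _synthetic_logit_table(n=8000, seed=1)
        fx = fit_model("GLM1.2", table, method="fixed", zscore=False)
        mx = fit_model("GLM1.2", table, method="mixed", zscore=False)
        assert mx.term("richness")["estimate"] == pytest.approx(
            fx.term("richness")["estimate"], abs=0.08
        )

    def test_constant_response_rejected(self):
        table = _synthetic_logit_table(n=2000, seed=2)
        table["decision"] = 1
        with pytest.raises(ValueError, match="variation"):
            fit_model("GLM1.2", table, method="fixed", zscore=False)

    def test_gaussian_family_recovers_state_shift_sign(self, single_animal_table):
        X, y, sess = build_design(single_animal_table)
        model = GLMHMM(n_states=2, n_restarts=3, random_state=0).fit(X, y, sess)
        der = add_state_columns(add_derived_regressors(single_animal_table), model)
        fit = fit_model("GLM2.3", der, method="fixed")
        # high-motivation state has faster pursue RTs by construction
        assert fit.term("motivation")["estimate"] < 0
        assert fit.term("motivation")["p"] < 0.01

    def test_transition_window_shows_pursue_rate_change(self, single_animal_table):
        """Around decoded high-to-low transitions, pursue rates drop from
        the before-window to the after-window (GLM2.2 form)."""
        X, y, sess = build_design(single_animal_table)
        model = GLMHMM(n_states=2, n_restarts=3, random_state=1).fit(X, y, sess)
        der = add_state_columns(add_derived_regressors(single_animal_table), model)
        der = der.rename(columns={"after_transition_h2l": "after_transition"})
        fit = fit_model("GLM2.2", der, method="fixed")
        assert fit.term("after_transition")["estimate"] < 0
        assert fit.term("after_transition")["p"] < 0.01

    def test_motivation_state_model_fits(self, single_animal_table):
        """The motivation ~ EV + Ave.EV model (GLM2.5 form) fits decoded
        states; the generator's transitions are state-history-only, so this
        checks the machinery, not an availability-state coupling."""
        X, y, sess = build_design(single_animal_table)
        model = GLMHMM(n_states=2, n_restarts=3, random_state=1).fit(X, y, sess)
        der = add_state_columns(add_derived_regressors(single_animal_table), model)
        fit = fit_model("GLM2.5", der, method="fixed")
        assert np.isfinite(fit.term("ave_ev")["estimate"])
        assert fit.params["se"].gt(0).all()

    def test_row_order_invariance(self):
        table = _synthetic_logit_table(n=4000, seed=3)
        shuffled = table.sample(frac=1.0, random_state=0)
        a = fit_model("GLM1.2", table, method="fixed", zscore=False)
        b = fit_model("GLM1.2", shuffled, method="fixed", zscore=False)
        np.testing.assert_allclose(
            a.params["estimate"], b.params["estimate"], atol=1e-8
        )


class TestLaggedOutcomeScan:
    def test_memory_horizon_detected(self):
        """An agent whose pursue propensity follows total reward over the
        previous 3 trials shows significant lags 1-3 and null lags 6-10."""
        rng = np.random.default_rng(0)
        n_sess, T = 40, 200
        rows = []
        for s in range(n_sess):
            outcome = np.zeros(T)
            dec = np.zeros(T, dtype=int)
            mag = rng.integers(1, 4, T)
            prob = rng.choice(np.arange(0.35, 1.01, 0.05).round(2), T)
            for t in range(T):
                recent = outcome[max(0, t - 3): t].sum()
                p = expit(-0.5 + 0.35 * recent)
                dec[t] = rng.random() < p
                outcome[t] = mag[t] * (rng.random() < prob[t]) * dec[t]
            rows.append(pd.DataFrame({
                "session_id": f"s{s}", "subject_id": f"m{s % 4}",
                "trial_number": np.arange(1, T + 1),
                "reward_magnitude": mag, "reward_probability": prob,
                "decision": dec, "reward_outcome": outcome,
            }))
        table = add_derived_regressors(pd.concat(rows, ignore_index=True))
        scan = lagged_outcome_scan(table, max_lag=10, method="fixed")
        assert (scan.loc[scan["lag"] <= 3, "p"] < 0.001).all()
        assert (scan.loc[scan["lag"] >= 6, "p"] > 0.001).all()

    def test_single_lag_output(self, single_animal_table):
        der = add_derived_regressors(single_animal_table)
        scan = lagged_outcome_scan(der, max_lag=1, method="fixed")
        assert len(scan) == 1 and scan["lag"].iloc[0] == 1


@pytest.fixture(scope="module")
def tus_dataset():
    """Simulated stimulation dataset: the DRN condition scales off-diagonal
    transition rates by 0.2; controls use the reference agent."""
    agents = {
        "sham": task.default_agent("sham"),
        "VTA": task.default_agent("VTA"),
        "STS": task.default_agent("STS"),
        "DRN": task.perturb_agent(task.default_agent(), transition_scale=0.2,
                                  condition="DRN"),
    }
    tab = task.generate_dataset(3, 4, agents, seed=21)
    der = add_derived_regressors(tab)
    # decode with a model fit to the sham data (the unperturbed reference)
    sham = der[der["condition"] == "sham"]
    X, y, sess = build_design(sham)
    model = GLMHMM(n_states=2, n_restarts=3, random_state=0).fit(X, y, sess)
    return add_state_columns(der, model)


class TestTusContrasts:
    def test_transition_suppression_detected(self, tus_dataset):
        out = tus_contrasts(tus_dataset, model="GLM4.3", method="fixed")
        drn_vs_sham = out[out["contrast"] == "DRN vs sham"]
        main = drn_vs_sham[~drn_vs_sham["term"].str.contains(":")]
        assert (main["estimate"] < 0).all()
        assert (main["p"] < 0.01).all()

    def test_sham_like_contrast_is_null(self, tus_dataset):
        out = tus_contrasts(tus_dataset, model="GLM4.3", target="VTA",
                            controls=("sham",), method="fixed")
        main = out[~out["term"].str.contains(":")]
        assert (main["p"] > 0.05).all()

    def test_missing_condition_level_rejected(self, tus_dataset):
        with pytest.raises(ValueError, match="condition"):
            tus_contrasts(tus_dataset.query("condition != 'VTA'"))

    def test_no_condition_column_rejected(self, single_animal_table):
        with pytest.raises(ValueError, match="condition"):
            tus_contrasts(single_animal_table.drop(columns=["condition"]))

    def test_motivation_occupancy_shift(self, tus_dataset):
        """Suppressed transitions keep the animal in its (typically high)
        starting state longer: DRN raises high-state occupancy."""
        occ = tus_dataset.groupby("condition")["motivation"].mean()
        assert occ["DRN"] > occ["sham"]
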