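"""BOLD time-course machinery: epoching, per-timepoint OLS, LOO peaks, PPI."""

import numpy as np
import pandas as pd
import pytest

from foragehmm.bold import (
    TR,
    bold_design,
    epoch_upsample,
    hrf,
    holm_correct,
    loo_peak_stats,
    ols_timecourse,
    ppi_fit,
    synthesize_bold,
    transition_window_scan,
)
from foragehmm.glmhmm import decode_transitions


def session_betas(n_trials=24, effect=0.8, noise=0.5, seed=0, normalize=True):
    """One synthetic session: inject a per-trial effect and return the
    regressor's beta time course."""
    rng = np.random.default_rng(seed)
    onsets = 12.0 + np.arange(n_trials) * 10.0
    x = rng.normal(0, 1, n_trials)
    series, _ = synthesize_bold(onsets, trial_effects=effect * x,
                                noise_sd=noise, rng=rng)
    ep = epoch_upsample(series, onsets, normalize=normalize)
    betas = ols_timecourse(ep, pd.DataFrame({"x": x[ep.kept]}))
    return betas.loc["x"].to_numpy(), betas.columns.to_numpy(dtype=float)


class TestSynthesisAndEpoching:
    def test_zero_effects_pure_noise_plus_task_response(self):
        onsets = 12.0 + np.arange(10) * 10.0
        s1, t = synthesize_bold(onsets, noise_sd=0.0, rng=0)
        s2, _ = synthesize_bold(onsets, noise_sd=0.0, rng=1)
        np.testing.assert_allclose(s1, s2)  # deterministic without noise

    def test_epoch_sample_count(self):
        series, _ = synthesize_bold(12.0 + np.arange(8) * 10.0, rng=0)
        ep = epoch_upsample(series, 12.0 + np.arange(8) * 10.0)
        assert ep.data.shape[1] == int(round(6 * 15 / TR)) == 70
        assert ep.times[0] == pytest.approx(-1.0)

    def test_constant_series_constant_epochs(self):
        onsets = [10.0, 20.0]
        ep = epoch_upsample(np.ones(50), onsets, normalize=False)
        assert np.allclose(ep.data, 1.0)

    def test_edge_onsets_flagged(self):
        ep = epoch_upsample(np.random.default_rng(0).normal(size=40),
                            [0.3, 20.0, 50.9])
        np.testing.assert_array_equal(ep.kept, [False, True, False])

    def test_impulse_response_peaks_at_hrf_lag(self):
        onsets = np.array([30.0])
        series, _ = synthesize_bold(onsets, noise_sd=0.0, rng=0, duration_s=80)
        ep = epoch_upsample(series, onsets, normalize=False)
        peak_t = ep.times[np.argmax(ep.data[0])]
        # linear interpolation of TR-sampled data localizes the peak to the
        # nearest native sample, i.e. within ~TR/2 of the true HRF peak
        assert peak_t == pytest.approx(4.0, abs=0.7)


class TestOlsTimecourse:
    def test_injected_effect_peaks_near_hrf_latency(self):
        betas, times = session_betas(n_trials=60, effect=1.0, noise=0.2)
        assert times[np.argmax(betas)] == pytest.approx(4.0, abs=1.0)

    def test_null_regressor_near_zero(self):
        rng = np.random.default_rng(3)
        onsets = 12.0 + np.arange(40) * 10.0
        series, _ = synthesize_bold(onsets, rng=rng)
        ep = epoch_upsample(series, onsets)
        betas = ols_timecourse(ep, pd.DataFrame({"null": rng.normal(0, 1, 40)}))
        assert np.abs(betas.loc["null"]).max() < 0.8

    def test_linearity_of_recovered_effect(self):
        # without per-session renormalization the OLS machinery is linear
        b1, t = session_betas(effect=0.5, noise=0.0, seed=4, normalize=False)
        b2, _ = session_betas(effect=1.0, noise=0.0, seed=4, normalize=False)
        win = (t >= 1) & (t <= 5)
        assert b2[win].max() == pytest.approx(2 * b1[win].max(), rel=0.05)

    def test_duplicated_column_rejected(self):
        series, _ = synthesize_bold(12.0 + np.arange(10) * 10.0, rng=0)
        ep = epoch_upsample(series, 12.0 + np.arange(10) * 10.0)
        x = np.random.default_rng(0).normal(size=10)
        with pytest.raises(ValueError, match="collinear"):
            ols_timecourse(ep, pd.DataFrame({"a": x, "b": x}))

    def test_row_mismatch_rejected(self):
        series, _ = synthesize_bold(12.0 + np.arange(10) * 10.0, rng=0)
        ep = epoch_upsample(series, 12.0 + np.arange(10) * 10.0)
        with pytest.raises(ValueError, match="rows"):
            ols_timecourse(ep, pd.DataFrame({"a": np.zeros(7)}))


class TestLooPeakStats:
    def n_sessions_curves(self, n=20, effect=0.6, seed=0):
        curves, times = [], None
        for s in range(n):
            b, times = session_betas(effect=effect, noise=0.6, seed=seed * 1000 + s)
            curves.append(b)
        return np.array(curves), times

    def test_injected_common_effect_detected(self):
        curves, times = self.n_sessions_curves(n=12, effect=0.8, seed=1)
        st = loo_peak_stats(curves, times)
        assert st.t_stat > 3 and st.p_value < 0.01
        assert np.all((st.peak_times >= 1.0) & (st.peak_times <= 5.0))

    def test_identical_curves_peak_at_common_max(self):
        times = np.linspace(-1, 5, 70)
        curve = np.exp(-0.5 * (times - 3.5) ** 2)
        st = loo_peak_stats(np.tile(curve, (5, 1)), times)
        assert np.allclose(st.peak_betas, curve.max())

    def test_no_leakage_from_own_session(self):
        """Permuting session s's curve never changes session s's selected
        peak time (the LOO guarantee, asserted behaviorally)."""
        curves, times = self.n_sessions_curves(n=8, effect=0.5, seed=2)
        st = loo_peak_stats(curves, times)
        rng = np.random.default_rng(0)
        for s in range(len(curves)):
            mod = curves.copy()
            mod[s] = rng.permutation(mod[s])
            st2 = loo_peak_stats(mod, times)
            assert st2.peak_times[s] == st.peak_times[s]

    def test_too_few_sessions_rejected(self):
        with pytest.raises(ValueError, match="3 sessions"):
            loo_peak_stats(np.zeros((2, 10)), np.linspace(-1, 5, 10))

    def null_curves(self, rng, n_sess, n_trials=20):
        """Null sessions: synthetic BOLD with no injected effect, regressed
        on a random trial variable."""
        curves, times = [], None
        for _ in range(n_sess):
            onsets = 12.0 + np.arange(n_trials) * 10.0
            series, _ = synthesize_bold(onsets, rng=rng)
            ep = epoch_upsample(series, onsets)
            x = rng.normal(0, 1, n_trials)
            b = ols_timecourse(ep, pd.DataFrame({"x": x[ep.kept]}))
            curves.append(b.loc["x"].to_numpy())
            times = b.columns.to_numpy(float)
        return np.array(curves), times

    def test_loo_estimate_unbiased_and_less_inflated_than_max_picking(self):
        """Under the null, each LOO-selected peak beta has expectation zero
        (the estimate is selection-unbiased), and the group test rejects far
        less often than the non-LOO variant that picks the peak from the
        all-session mean curve."""
        from scipy import stats as sps

        rng = np.random.default_rng(7)
        n_rep, n_sess = 150, 12
        loo_hits = allin_hits = 0
        mean_peaks = []
        for _ in range(n_rep):
            curves, times = self.null_curves(rng, n_sess)
            st = loo_peak_stats(curves, times)
            loo_hits += st.p_value < 0.05
            mean_peaks.append(st.peak_betas.mean())
            win = (times >= 1) & (times <= 5)
            wi = np.flatnonzero(win)
            j = wi[np.argmax(np.abs(curves.mean(0)[win]))]
            allin_hits += sps.ttest_1samp(curves[:, j], 0).pvalue < 0.05
        # unbiasedness of the estimate: grand mean of selected betas ~ 0
        mean_peaks = np.array(mean_peaks)
        t_bias = mean_peaks.mean() / (mean_peaks.std(ddof=1) / np.sqrt(n_rep))
        assert abs(t_bias) < 3.0
        assert loo_hits < allin_hits


class TestPPI:
    def make_epochs(self, data):
        from foragehmm.bold import EpochedSeries

        times = np.linspace(-1, 5, data.shape[1])
        return EpochedSeries(data, times, np.ones(data.shape[0], dtype=bool))

    def test_constructed_coupling_recovered(self):
        rng = np.random.default_rng(0)
        n_tr, n_t = 80, 70
        seed_data = rng.normal(0, 1, (n_tr, n_t))
        psych = rng.integers(0, 2, n_tr).astype(float)
        target = 0.9 * seed_data * psych[:, None] + rng.normal(0, 0.3, (n_tr, n_t))
        betas = ppi_fit(self.make_epochs(target), self.make_epochs(seed_data), psych)
        assert betas.loc["ppi"].mean() == pytest.approx(0.9, abs=0.1)

    def test_independent_target_null_ppi(self):
        rng = np.random.default_rng(1)
        seed_data = rng.normal(0, 1, (80, 70))
        target = rng.normal(0, 1, (80, 70))
        psych = rng.integers(0, 2, 80).astype(float)
        betas = ppi_fit(self.make_epochs(target), self.make_epochs(seed_data), psych)
        assert abs(betas.loc["ppi"].mean()) < 0.1

    def test_constant_psych_rejected(self):
        rng = np.random.default_rng(2)
        e = self.make_epochs(rng.normal(0, 1, (10, 20)))
        with pytest.raises(ValueError, match="constant"):
            ppi_fit(e, e, np.ones(10))


class TestTransitionWindowScan:
    def test_effect_maximal_at_centered_window(self):
        """An effect injected only inside the centered +-3-trial window is
        strongest when the analysis window is centered too."""
        rng = np.random.default_rng(3)
        epochs, paths = [], []
        for s in range(10):
            T = 60
            z = np.zeros(T, dtype=int)
            z[25:] = 1
            path = decode_transitions(z)
            onsets = 12.0 + np.arange(T) * 10.0
            eff = -0.9 * path.period_mask((-3, 3)).astype(float)
            series, _ = synthesize_bold(onsets, trial_effects=eff,
                                        noise_sd=0.3, rng=rng)
            epochs.append(epoch_upsample(series, onsets))
            paths.append(path)
        scan = transition_window_scan(epochs, paths)
        is_centered = scan["offsets"].apply(lambda o: o == (-3, 3))
        is_extreme = scan["offsets"].apply(lambda o: o in [(-6, 0), (0, 6)])
        centered = scan[is_centered].iloc[0]
        extremes = scan[is_extreme]
        assert abs(centered["mean_peak_beta"]) > abs(extremes["mean_peak_beta"]).max()
        assert len(scan) == 7

    def test_no_transitions_flagged(self):
        rng = np.random.default_rng(4)
        epochs, paths = [], []
        for s in range(4):
            onsets = 12.0 + np.arange(20) * 10.0
            series, _ = synthesize_bold(onsets, rng=rng)
            epochs.append(epoch_upsample(series, onsets))
            paths.append(decode_transitions(np.zeros(20, dtype=int)))
        scan = transition_window_scan(epochs, paths)
        assert scan["t"].isna().all()
        assert (scan["n_transitions"] == 0).all()


class TestRegistryAndHolm:
    def test_design_registry_builds_columns(self, single_animal_table):
        from foragehmm.features import add_derived_regressors

        der = add_derived_regressors(single_animal_table).head(200).copy()
        der["pupil_iti"] = 0.0
        d = bold_design(der, "GLM3.2")
        assert list(d.columns)[:2] == ["reward_magnitude", "reward_probability"]
        with pytest.raises(KeyError):
            bold_design(der, "GLM3.99")

    def test_interaction_terms_are_products(self, single_animal_table):
        from foragehmm.features import add_derived_regressors

        der = add_derived_regressors(single_animal_table).dropna().head(100).copy()
        der["pupil_iti"] = 1.0
        d = bold_design(der, "GLM3.1")
        np.testing.assert_allclose(
            d["richness:behavioral_history"],
            der["richness"] * der["behavioral_history"],
        )

    def test_holm_adjustment_monotone(self):
        p = [0.01, 0.04, 0.03, 0.20]
        adj = holm_correct(p)
        assert np.all(adj >= p)
        assert adj[np.argmin(p)] == pytest.approx(0.04)
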