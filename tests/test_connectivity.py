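"""Band-pass filtering, windowed FNC, dFNC states and the regressions."""

import numpy as np
import pandas as pd
import pytest

import brainpolarity as bp
from brainpolarity import connectivity as conn


def _sine(freq_hz, T=160, tr=2.0):
    t = np.arange(T) * tr
    return np.sin(2 * np.pi * freq_hz * t)


class TestBandpass:
    def test_passband_sinusoid_preserved(self):
        x = _sine(0.10)
        y = bp.bandpass_timecourses(x[None], tr_seconds=2.0)[0]
        mid = slice(30, 130)  # away from filtfilt edge effects
        ratio = y[mid].std() / x[mid].std()
        assert abs(ratio - 1) < 0.05

    def test_stopband_sinusoid_attenuated(self):
        x = _sine(0.01, T=400)
        y = bp.bandpass_timecourses(x[None], tr_seconds=2.0)[0]
        assert y.std() / x.std() < 0.10

    def test_zero_in_zero_out(self):
        y = bp.bandpass_timecourses(np.zeros((3, 100)), tr_seconds=2.0)
        assert np.all(y == 0)

    def test_band_edges_validated(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bp.bandpass_timecourses(np.zeros((2, 100)), tr_seconds=2.0,
                                    low_hz=0.05, high_hz=0.30)
        with pytest.raises(ValueError, match="Nyquist"):
            bp.bandpass_timecourses(np.zeros((2, 100)), tr_seconds=2.0,
                                    low_hz=0.0, high_hz=0.15)


class TestSlidingWindow:
    def test_window_count_arithmetic(self, rng):
        tcs = rng.normal(size=(4, 160))
        wc = bp.sliding_window_fnc(tcs, window_length=22)
        assert wc.n_windows == 160 - 21

    def test_identical_timecourses_give_unit_correlation(self, rng):
        x = rng.normal(size=100)
        wc = bp.sliding_window_fnc(np.vstack([x, x]), window_length=22)
        np.testing.assert_allclose(wc.windows[:, 0], 1.0, atol=1e-12)

    def test_independent_noise_has_near_zero_mean_correlation(self):
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            wc = bp.sliding_window_fnc(rng.normal(size=(2, 300)),
                                       window_length=22)
            means.append(wc.windows[:, 0].mean())
        assert abs(np.mean(means)) < 0.02

    def test_rect_window_matches_numpy_corrcoef(self, rng):
        tcs = rng.normal(size=(3, 40))
        wc = bp.sliding_window_fnc(tcs, window_length=40, taper="rect")
        expected = np.corrcoef(tcs)
        iu = np.triu_indices(3, k=1)
        np.testing.assert_allclose(wc.windows[0], expected[iu], atol=1e-10)

    def test_static_fnc_is_one_window_limit(self, rng):
        tcs = rng.normal(size=(5, 120))
        static = bp.static_fnc(tcs)
        wc = bp.sliding_window_fnc(tcs, window_length=120, taper="rect")
        np.testing.assert_allclose(static, wc.windows[0], atol=1e-12)

    def test_short_scan_rejected(self, rng):
        with pytest.raises(ValueError, match="shorter"):
            bp.sliding_window_fnc(rng.normal(size=(2, 10)), window_length=22)

    def test_taper_is_normalized_and_tapered(self):
        w = conn.tapered_window(22, gaussian_sd=3.0)
        assert w.sum() == pytest.approx(1.0)
        assert w[0] < w[11]  # edges attenuated relative to the middle


class TestDfncStates:
    def _windowed(self, windows):
        return conn.WindowedConnectivity(
            windows=windows, starts=np.arange(len(windows)),
            window_length=22, taper="tapered", pair_index=[(0, 1)] * windows.shape[1])

    def test_planted_states_recovered(self, rng):
        templates = np.array([[0.8, -0.5, 0.1], [-0.6, 0.7, 0.0],
                              [0.0, 0.0, 0.9]])
        truth = rng.integers(0, 3, size=200)
        windows = templates[truth] + rng.normal(0, 0.05, size=(200, 3))
        model = bp.fit_dfnc_states([self._windowed(windows)], k=3, seed=0,
                                   replicates=5)
        labels = model.labels[0]
        # purity after best matching
        purity = max(
            (labels[truth == j] == np.bincount(labels[truth == j]).argmax()).mean()
            for j in range(3))
        assert purity > 0.95

    def test_occupancies_sum_to_one_and_determinism(self, rng):
        windows = rng.normal(size=(100, 6))
        a = bp.fit_dfnc_states([self._windowed(windows)], k=4, seed=1,
                               replicates=3)
        b = bp.fit_dfnc_states([self._windowed(windows)], k=4, seed=1,
                               replicates=3)
        np.testing.assert_allclose(a.occupancy.sum(axis=1), 1.0)
        np.testing.assert_array_equal(a.labels[0], b.labels[0])


class TestDprWithinDfnc:
    def test_planted_coupling_elevates_t(self, rng):
        T, L = 160, 22
        n_win = T - L + 1
        dprs, dfncs = [], []
        for _ in range(6):
            dpr = np.full(T, 2)
            blocks = rng.choice(np.arange(0, T - 30, 30), size=2, replace=False)
            for b in blocks:
                dpr[b : b + 20] = 0          # polarized blocks
            occ = conn.window_polarized_occupancy(dpr, L)
            dfnc = np.where(occ > np.median(occ), 1, 0)  # state 1 rides polarity
            dprs.append(dpr)
            dfncs.append(dfnc)
        table = conn.dpr_within_dfnc_test(dprs, dfncs, window_length=L,
                                          n_states=2)
        assert table.loc[1, "t"] > 5
        assert table.loc[0, "t"] < 0

    def test_independent_labels_yield_small_t(self):
        tvals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            dprs = [rng.integers(0, 3, size=120) for _ in range(4)]
            dfncs = [rng.integers(0, 3, size=120 - 21) for _ in range(4)]
            table = conn.dpr_within_dfnc_test(dprs, dfncs, window_length=22,
                                              n_states=3)
            tvals.extend(table["t"].tolist())
        assert np.mean(np.abs(tvals)) < 2.0

    def test_constant_occupancy_gives_zero_t(self):
        dprs = [np.full(60, 0)]               # always polarized
        dfncs = [np.tile([0, 1], (60 - 21) // 2 + 1)[: 60 - 21]]
        table = conn.dpr_within_dfnc_test(dprs, dfncs, window_length=22,
                                          n_states=2)
        assert (table["t"] == 0).all()

    def test_missing_state_flagged(self):
        dprs = [np.zeros(60, dtype=int)]
        dfncs = [np.zeros(60 - 21, dtype=int)]
        table = conn.dpr_within_dfnc_test(dprs, dfncs, window_length=22,
                                          n_states=2)
        assert table.loc[1, "n_windows"] == 0
        assert np.isnan(table.loc[1, "t"])


def _cohort(rng, n=40):
    return pd.DataFrame({
        "group": ["HC"] * (n // 2) + ["SZ"] * (n - n // 2),
        "age": rng.uniform(20, 60, n),
        "gender": rng.choice(["M", "F"], n),
        "mean_fd": rng.lognormal(-1.6, 0.3, n),
    })


class TestNuisanceRegression:
    def test_exact_linear_relation(self, rng):
        cohort = _cohort(rng)
        x = rng.normal(size=40)
        res = bp.nuisance_regression(2.0 * x, x, cohort)
        assert res["beta"] == pytest.approx(2.0, abs=1e-8)
        assert res["p"] < 1e-12

    def test_null_predictor_has_nominal_false_positive_rate(self):
        pvals = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            cohort = _cohort(rng)
            y = rng.normal(size=40)
            x = rng.normal(size=40)
            pvals.append(bp.nuisance_regression(y, x, cohort)["p"])
        rate = np.mean(np.array(pvals) < 0.05)
        assert 0.0 <= rate <= 0.125

    def test_motion_confound_removed_by_covariate(self, rng):
        # group differs in motion; response driven purely by motion
        n = 60
        cohort = _cohort(rng, n)
        sz = (cohort["group"] == "SZ").to_numpy()
        cohort.loc[sz, "mean_fd"] += 0.3
        y = 5.0 * cohort["mean_fd"].to_numpy() + rng.normal(0, 0.1, n)
        with_fd = bp.nuisance_regression(y, "group", cohort)
        without_fd = bp.nuisance_regression(y, "group", cohort,
                                            covariates=("age", "gender"))
        assert without_fd["p"] < 0.01          # spurious effect
        assert with_fd["p"] > 0.05             # removed by meanFD covariate

    def test_symptom_effect_corrected_for_other_categories(self, rng):
        n = 50
        cohort = _cohort(rng, n)
        cohort["sympt_pos"] = rng.uniform(7, 49, n)
        cohort["sympt_neg"] = rng.uniform(7, 49, n)
        cohort["sympt_gen"] = rng.uniform(16, 112, n)
        y = -0.1 * cohort["sympt_pos"].to_numpy() + rng.normal(0, 0.5, n)
        res = bp.nuisance_regression(
            y, "sympt_pos", cohort,
            extra_covariates=("sympt_neg", "sympt_gen"))
        assert res["beta"] < 0 and res["p"] < 0.01

    def test_collinear_design_rejected(self, rng):
        cohort = _cohort(rng)
        cohort["age"] = cohort["mean_fd"]     # exact collinearity
        with pytest.raises(ValueError, match="collinear"):
            bp.nuisance_regression(rng.normal(size=40), "group", cohort)


class TestMediation:
    def _mediated_data(self, rng, n=60, n_pairs=20):
        cohort = _cohort(rng, n)
        sz = (cohort["group"] == "SZ").to_numpy().astype(float)
        occ = 0.5 - 0.25 * sz + rng.normal(0, 0.05, n)  # group -> occupancy
        betas = rng.uniform(0.5, 1.0, n_pairs)
        fnc = np.tanh(betas[None, :] * occ[:, None]
                      + rng.normal(0, 0.05, (n, n_pairs)))
        return cohort, occ, fnc

    def test_group_effects_absorbed_by_occupancy(self, rng):
        cohort, occ, fnc = self._mediated_data(rng)
        res = conn.fnc_mediation_comparison(fnc, cohort, occ)
        assert res["n_group_sig_without_occupancy"] > 10
        assert (res["n_group_sig_with_occupancy"]
                < res["n_group_sig_without_occupancy"] / 2)
        assert res["occupancy_with_group"]["fdr_sig"].sum() > 10

    def test_constant_occupancy_reduces_to_group_model(self, rng):
        cohort, _, fnc = self._mediated_data(rng)
        res = conn.fnc_mediation_comparison(fnc, cohort,
                                            np.full(len(cohort), 0.4))
        a = res["group_only"]["beta"].to_numpy()
        b = res["group_with_occupancy"]["beta"].to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_null_fnc_has_no_survivors(self):
        counts = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cohort = _cohort(rng, 40)
            fnc = np.tanh(rng.normal(0, 0.2, size=(40, 15)))
            occ = rng.uniform(0.2, 0.6, 40)
            res = conn.fnc_mediation_comparison(fnc, cohort, occ)
            counts.append(res["n_group_sig_without_occupancy"])
        assert np.mean(counts) < 1.0
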