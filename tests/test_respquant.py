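"""Response quantification: kernels, scoring, model inversion, normalization."""

import numpy as np
import pandas as pd
import pytest

from tracefear import design, respquant
from tracefear.respquant import (
    ScrTrialModel,
    burst_response_shape,
    canonical_rf,
    check_train_eval_separation,
    estimate_rf_from_timecourse,
    fit_scr_trial_model,
    glm_quantify,
    normalize_by_cs_minus,
    scr_auc,
    sebr_glm,
    sebr_peak_score,
)
from tracefear.signals import ContinuousSignal


def _single_trial_schedule(session="recall", cs_onset=10.0):
    probe = cs_onset + 15.0 if session == "recall" else None
    us = cs_onset + 17.0 if session == "acquisition" else None
    return design.TrialSchedule(
        session,
        [design.Trial(index=1, condition="CS+", cs_onset=cs_onset,
                      us_onset=us, probe_onset=probe)],
    )


class TestCanonicalRf:
    @pytest.mark.parametrize(
        "kind", ["sebr_canonical", "scr_kernel", "pupil_canonical",
                 "hpr_us_locked", "rar_early", "rar_late"]
    )
    def test_unit_peak_finite_causal(self, kind):
        rf = canonical_rf(kind)
        assert np.all(np.isfinite(rf.values))
        assert np.max(np.abs(rf.values)) == pytest.approx(1.0)
        assert rf.grid[0] == 0.0

    def test_sebr_peaks_near_45ms(self):
        rf = canonical_rf("sebr_canonical")
        assert rf.grid[np.argmax(rf.values)] == pytest.approx(0.045, abs=0.005)

    def test_scr_kernel_delay(self):
        rf = canonical_rf("scr_kernel")
        assert np.all(rf.values[rf.grid < 1.0] == 0.0)
        assert rf.values[rf.grid > 1.5].max() > 0.5


class TestSebrPeakScore:
    def test_constant_envelope(self):
        sched = _single_trial_schedule()
        env = ContinuousSignal("emg", 1000.0, np.full(40_000, 2.5))
        est = sebr_peak_score(env, sched)
        assert est["amplitude"].iloc[0] == pytest.approx(2.5)

    def test_burst_outside_window_ignored(self):
        sched = _single_trial_schedule()
        fs = 1000.0
        x = np.full(40_000, 0.1)
        probe = sched.trials[0].probe_onset
        x[int((probe + 0.150) * fs)] = 9.0  # peaks at 150 ms, outside 20-100
        est = sebr_peak_score(ContinuousSignal("emg", fs, x), sched)
        assert est["amplitude"].iloc[0] == pytest.approx(0.1)

    def test_equals_brute_force_scan(self, rng):
        sched = _single_trial_schedule()
        fs = 1000.0
        x = rng.random(40_000)
        env = ContinuousSignal("emg", fs, x)
        est = sebr_peak_score(env, sched)
        probe = sched.trials[0].probe_onset
        grid = np.arange(len(x)) / fs
        win = (grid >= probe + 0.020 - 1e-12) & (grid <= probe + 0.100 + 1e-12)
        assert est["amplitude"].iloc[0] == np.max(x[win])

    def test_window_exceeding_record_errors(self):
        sched = _single_trial_schedule()
        env = ContinuousSignal("emg", 1000.0, np.zeros(10_000))  # 10 s record
        with pytest.raises(ValueError):
            sebr_peak_score(env, sched)


class TestSebrGlm:
    def test_regression_identity(self):
        sched = _single_trial_schedule()
        fs = 2000.0
        rf = canonical_rf("sebr_canonical", fs)
        x = np.zeros(int(40 * fs))
        onset = 0.030
        i0 = int(round((sched.trials[0].probe_onset + onset) * fs))
        x[i0 : i0 + len(rf.values)] = 2.0 * rf.values
        est = sebr_glm(ContinuousSignal("emg", fs, x), sched, rf)
        assert est["amplitude"].iloc[0] == pytest.approx(2.0, rel=1e-6)
        assert est["latency"].iloc[0] == pytest.approx(onset, abs=1e-9)

    def test_pure_noise_centered_near_zero(self, rng):
        sched = design.generate_schedule("recall", seed=3)
        fs = 2000.0
        x = 0.5 * rng.standard_normal(int((sched.duration + 20) * fs))
        est = sebr_glm(ContinuousSignal("emg", fs, x), sched)
        amps = est["amplitude"].to_numpy()
        se = amps.std(ddof=1) / np.sqrt(len(amps))
        # onset selection maximizes fit, so a small positive bias is
        # possible; the mean must still be within a few SEs of zero
        assert abs(amps.mean()) < 5 * se + 0.05

    def test_matches_independent_onset_scan(self, rng):
        sched = _single_trial_schedule()
        fs = 2000.0
        rf = canonical_rf("sebr_canonical", fs)
        x = rng.standard_normal(int(40 * fs))
        est = sebr_glm(ContinuousSignal("emg", fs, x), sched, rf)
        # brute force re-implementation
        probe = sched.trials[0].probe_onset
        best = (np.inf, None)
        for on in np.arange(0.0, 0.1005, 0.001):
            i0 = int(round((probe + on) * fs))
            y = x[i0 : i0 + len(rf.values)]
            X = np.column_stack([np.ones(len(y)), rf.values])
            beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(res[0]) if len(res) else float(((X @ beta - y) ** 2).sum())
            if rss < best[0]:
                best = (rss, beta[1])
        assert est["amplitude"].iloc[0] == pytest.approx(best[1], rel=1e-9)


class TestScrTrialModel:
    def _forward(self, sched, model, amps, lat, fs=10.0, n_s=40.0):
        lags, shape = burst_response_shape(model)
        n = int(n_s * fs)
        t = np.arange(n) / fs
        trial = sched.trials[0]
        centers = [trial.cs_onset + model.delta_cs,
                   trial.cs_offset + lat,
                   trial.nominal_us_onset + model.delta_us]
        y = np.zeros(n)
        for a, mu in zip(amps, centers):
            y += a * np.interp(t - mu, lags, shape, left=0, right=0)
        return ContinuousSignal("scr", fs, y)

    def test_zero_segment_zero_amplitudes(self):
        sched = _single_trial_schedule("acquisition")
        model = ScrTrialModel()
        sig = ContinuousSignal("scr", 10.0, np.zeros(400))
        est = fit_scr_trial_model(sig, sched, model)
        assert np.allclose(est["amplitude"], 0.0, atol=1e-8)

    def test_noiseless_recovery(self):
        sched = _single_trial_schedule("acquisition")
        model = ScrTrialModel()
        amps = (0.4, 0.7, 1.2)
        lat = 11.3
        sig = self._forward(sched, model, amps, lat)
        est = fit_scr_trial_model(sig, sched, model)
        got = {r.component: r.amplitude for r in est.itertuples()}
        for a, comp in zip(amps, ("cs", "trace", "us")):
            assert got[comp] == pytest.approx(a, rel=0.01)
        lat_hat = est[est.component == "trace"]["latency"].iloc[0]
        assert lat_hat == pytest.approx(lat, abs=0.1)

    def test_truth_at_window_edge_clamps_and_flags(self):
        sched = _single_trial_schedule("acquisition")
        model = ScrTrialModel()
        sig = self._forward(sched, model, (0.0, 1.0, 0.0), 14.6)  # beyond hi=14
        est = fit_scr_trial_model(sig, sched, model)
        row = est[est.component == "trace"].iloc[0]
        assert row.latency <= 14.0 + 1e-6
        assert "lat_at_bound" in row.flag

    def test_masked_samples_excluded(self):
        sched = _single_trial_schedule("acquisition")
        model = ScrTrialModel()
        sig = self._forward(sched, model, (0.5, 0.5, 0.8), 10.0)
        # corrupt the masked US window; estimates must be unaffected
        bad = sig.samples.copy()
        us = sched.trials[0].us_onset
        mask = np.zeros(len(bad), dtype=bool)
        i0, i1 = int((us - 0.2) * 10), int((us + 1.6) * 10)
        mask[i0:i1] = True
        bad[i0:i1] += 50.0
        est_clean = fit_scr_trial_model(sig, sched, model)
        est_masked = fit_scr_trial_model(
            ContinuousSignal("scr", 10.0, bad, mask), sched, model
        )
        np.testing.assert_allclose(
            est_masked["amplitude"], est_clean["amplitude"], atol=1e-6
        )


class TestScrAuc:
    def test_closed_forms(self):
        sched = _single_trial_schedule("acquisition")
        fs = 10.0
        n = 400
        zero = ContinuousSignal("scr", fs, np.zeros(n))
        assert scr_auc(zero, sched)["amplitude"].iloc[0] == 0.0
        const = ContinuousSignal("scr", fs, np.full(n, 3.3))
        assert scr_auc(const, sched)["amplitude"].iloc[0] == pytest.approx(0.0)
        # ramp of slope 1 from CS onset: integral over 17 s = 17^2/2
        t = np.arange(n) / fs
        ramp = np.clip(t - 10.0, 0.0, None)
        got = scr_auc(ContinuousSignal("scr", fs, ramp), sched)["amplitude"].iloc[0]
        assert got == pytest.approx(17.0**2 / 2.0, rel=1e-3)


class TestFittedRf:
    def test_recovers_shifted_kernel(self):
        fs = 10.0
        k = canonical_rf("pupil_canonical", fs)
        curves = np.tile(k.values, (5, 1))
        rf = estimate_rf_from_timecourse(curves, fs=fs, dataset_id="A")
        assert np.max(np.abs(rf.values)) == pytest.approx(1.0)
        # smoothing may shift the argmax slightly
        assert abs(np.argmax(rf.values) - np.argmax(k.values)) <= 10

    def test_noise_input_warns(self, rng):
        curves = 0.001 * rng.standard_normal((5, 170)) + rng.standard_normal(170)
        with pytest.warns(UserWarning, match="SNR"):
            estimate_rf_from_timecourse(curves, fs=10.0, dataset_id="A")

    def test_train_eval_separation_enforced(self):
        fs = 10.0
        rf = estimate_rf_from_timecourse(
            np.tile(canonical_rf("pupil_canonical", fs).values, (3, 1)),
            fs=fs, dataset_id="A",
        )
        with pytest.raises(ValueError, match="same dataset"):
            check_train_eval_separation(rf, "A")
        check_train_eval_separation(rf, "B")
        check_train_eval_separation(rf, "A", override=True)


class TestGlmQuantify:
    def test_single_rf_identity(self):
        sched = _single_trial_schedule("acquisition")
        fs = 10.0
        rf = canonical_rf("pupil_canonical", fs)
        n = 400
        x = np.zeros(n)
        i0 = int(sched.trials[0].cs_onset * fs)
        x[i0 : i0 + len(rf.values)] = 3.0 * rf.values
        est = glm_quantify(ContinuousSignal("pupil", fs, x), sched, rf,
                           anchor="cs", modality="pupil")
        assert est["amplitude"].iloc[0] == pytest.approx(3.0, rel=1e-9)

    def test_two_rf_ols_identity(self):
        sched = _single_trial_schedule("acquisition")
        fs = 10.0
        early = canonical_rf("rar_early", fs)
        late = canonical_rf("rar_late", fs)
        n = 600
        x = np.zeros(n)
        i0 = int(sched.trials[0].nominal_us_onset * fs)
        x[i0 : i0 + len(early.values)] += 1.0 * early.values
        x[i0 : i0 + len(late.values)] += 2.0 * late.values
        est = glm_quantify(ContinuousSignal("rar", fs, x), sched, [early, late],
                           anchor="us", granularity="condition")
        got = {r.component: r.amplitude for r in est.itertuples()
               if r.condition == "CS+"}
        assert got["rar_early"] == pytest.approx(1.0, abs=1e-6)
        assert got["rar_late"] == pytest.approx(2.0, abs=1e-6)

    def test_overlapping_trials_match_normal_equations_oracle(self, rng):
        # closely spaced trials -> overlapping regressors; compare against
        # an independently built design matrix solved by pseudo-inverse
        trials = [
            design.Trial(index=i + 1, condition="CS+" if i % 2 == 0 else "CS-",
                         cs_onset=5.0 + 8.0 * i, us_onset=None, probe_onset=None,
                         trace_duration=15.0)
            for i in range(6)
        ]
        sched = design.TrialSchedule("acquisition", trials)
        fs = 10.0
        rf = canonical_rf("pupil_canonical", fs)
        n = 800
        x = rng.standard_normal(n)
        est = glm_quantify(ContinuousSignal("pupil", fs, x), sched, rf, anchor="cs")
        X = []
        for t in trials:
            col = np.zeros(n)
            i0 = int(t.cs_onset * fs)
            col[i0 : i0 + len(rf.values)] = rf.values[: n - i0]
            X.append(col)
        X.append(np.ones(n))
        X.append(np.linspace(-1, 1, n))
        beta = np.linalg.pinv(np.column_stack(X)) @ x
        np.testing.assert_allclose(est["amplitude"].to_numpy(), beta[:6], atol=1e-8)


class TestNormalizeByCsMinus:
    def _table(self, subject_amps):
        rows = []
        for subj, (minus, plus) in subject_amps.items():
            for i, a in enumerate(minus, start=1):
                rows.append(dict(subject=subj, session="recall", trial_index=i,
                                 condition="CS-", modality="sebr", method="peak",
                                 component="probe", amplitude=a, latency=np.nan,
                                 normalized=False, flag=""))
            for i, a in enumerate(plus, start=len(minus) + 1):
                rows.append(dict(subject=subj, session="recall", trial_index=i,
                                 condition="CS+", modality="sebr", method="peak",
                                 component="probe", amplitude=a, latency=np.nan,
                                 normalized=False, flag=""))
        return pd.DataFrame(rows)

    def test_example(self):
        df = self._table({"s1": ([2.0, 2.0, 2.0], [3.0])})
        out = normalize_by_cs_minus(df)
        assert out[out.condition == "CS+"]["amplitude"].iloc[0] == pytest.approx(1.5)

    def test_cs_minus_mean_is_one_exactly(self, rng):
        df = self._table({f"s{i}": (rng.random(5) + 0.5, rng.random(5) + 0.5)
                          for i in range(4)})
        out = normalize_by_cs_minus(df)
        for _, g in out.groupby("subject"):
            assert g[g.condition == "CS-"]["amplitude"].mean() == pytest.approx(1.0)

    def test_gain_invariance(self, rng):
        df = self._table({f"s{i}": (rng.random(5) + 0.5, rng.random(5) + 0.5)
                          for i in range(3)})
        out1 = normalize_by_cs_minus(df)
        # power-of-two gain: bit-exact invariance
        df2 = df.copy()
        df2["amplitude"] *= 8.0
        out2 = normalize_by_cs_minus(df2)
        np.testing.assert_array_equal(out1["amplitude"], out2["amplitude"])
        # arbitrary gain: invariant to floating-point rounding
        df3 = df.copy()
        df3["amplitude"] *= 7.3
        out3 = normalize_by_cs_minus(df3)
        np.testing.assert_allclose(out1["amplitude"], out3["amplitude"], rtol=1e-12)

    def test_degenerate_cs_minus_flagged(self):
        df = self._table({"s1": ([0.0, 0.0], [1.0]), "s2": ([1.0, 1.0], [2.0])})
        out = normalize_by_cs_minus(df)
        s1 = out[out.subject == "s1"]
        assert s1["amplitude"].isna().all()
        assert s1["flag"].str.contains("cs_minus_degenerate").all()
        assert out[out.subject == "s2"]["amplitude"].notna().all()
        assert len(out.attrs["excluded_groups"]) == 1

    def test_double_normalization_rejected(self):
        df = self._table({"s1": ([1.0, 1.0], [2.0])})
        out = normalize_by_cs_minus(df)
        with pytest.raises(ValueError):
            normalize_by_cs_minus(out)
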