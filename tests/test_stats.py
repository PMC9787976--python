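"""Inference layer: permutation tests, calibration, mixed models, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from tracefear import stats, synthdata
from tracefear.stats import (
    HabituationModel,
    PowerSpec,
    calibrate_trial_average,
    chi2_2x2_yates,
    cluster_permutation_test,
    confirm_calibration,
    fit_habituation,
    hedges_correction,
    lme_condition_test,
    sample_size,
    select_random_structure,
    summary_t_and_d,
)


class TestClusterPermutation:
    def test_identical_conditions_no_clusters(self, rng):
        base = rng.standard_normal((8, 1, 50))
        data = np.repeat(base, 4, axis=1)  # every trial identical per subject
        labels = np.tile([True, False, True, False], (8, 1))
        res = cluster_permutation_test(data, labels, n_perm=100, seed=0)
        assert res.clusters == []
        assert res.min_p == 1.0

    def test_injected_effect_detected(self):
        data, labels = synthdata.synth_null_timecourses(20, 30, 170, 7)
        eff = np.zeros(170)
        eff[60:90] = 1.0  # 3-s window
        sd = data.std()
        for s in range(20):
            data[s][labels[s]] += eff * sd
        res = cluster_permutation_test(data, labels, n_perm=500, seed=2)
        sig = [c for c in res.clusters if c.p < 0.05]
        assert sig
        assert any(c.start_idx < 90 and c.end_idx >= 60 for c in sig)

    def test_deterministic_given_seed(self, rng):
        data, labels = synthdata.synth_null_timecourses(6, 10, 40, 3)
        r1 = cluster_permutation_test(data, labels, n_perm=200, seed=9)
        r2 = cluster_permutation_test(data, labels, n_perm=200, seed=9)
        np.testing.assert_array_equal(r1.null_max_mass, r2.null_max_mass)
        assert [c.p for c in r1.clusters] == [c.p for c in r2.clusters]

    def test_cluster_mass_conservation(self, rng):
        data, labels = synthdata.synth_null_timecourses(10, 20, 170, 11)
        eff = 0.3 * rng.standard_normal(170)
        for s in range(10):
            data[s][labels[s]] += eff
        res = cluster_permutation_test(data, labels, n_perm=50, seed=1)
        supra = np.abs(res.t_obs) > res.t_crit
        total = np.sum(np.abs(res.t_obs)[supra])
        assert sum(c.mass for c in res.clusters) == pytest.approx(total)

    def test_p_values_in_valid_range(self):
        data, labels = synthdata.synth_null_timecourses(8, 20, 100, 13)
        res = cluster_permutation_test(data, labels, n_perm=99, seed=4)
        for c in res.clusters:
            assert 1.0 / 100 <= c.p <= 1.0

    def test_rejects_unbalanced_labels(self, rng):
        data = rng.standard_normal((4, 6, 20))
        labels = np.zeros((4, 6), dtype=bool)
        labels[0, :4] = True
        labels[1:, :3] = True
        with pytest.raises(ValueError):
            cluster_permutation_test(data, labels, n_perm=10)


class TestCalibration:
    def _estimates(self, amps_by_subject):
        rows = []
        for subj, (minus, plus) in amps_by_subject.items():
            order = 0
            for a_m, a_p in zip(minus, plus):
                order += 1
                rows.append(dict(subject=subj, trial_index=2 * order - 1,
                                 condition="CS-", amplitude=a_m))
                rows.append(dict(subject=subj, trial_index=2 * order,
                                 condition="CS+", amplitude=a_p))
        return pd.DataFrame(rows)

    def test_identical_conditions_zero_effect(self):
        vals = {f"s{i}": ([1.0 + i, 2.0 + i], [1.0 + i, 2.0 + i]) for i in range(4)}
        res = calibrate_trial_average(self._estimates(vals), n_max=2)
        assert (res.table["t"] == 0.0).all()
        assert (res.table["cohen_d"] == 0.0).all()

    def test_constant_nonzero_diff_flagged_degenerate(self):
        vals = {f"s{i}": ([1.0], [2.0]) for i in range(4)}  # all diffs exactly 1
        res = calibrate_trial_average(self._estimates(vals), n_max=1)
        assert res.table["flag"].iloc[0] == "zero_variance"
        assert np.isnan(res.table["t"].iloc[0])
        assert res.best_n == 0  # nothing selectable

    def test_d_g_relation_exact(self, rng):
        vals = {f"s{i}": (rng.random(15) + 0.5, rng.random(15) + 0.8)
                for i in range(10)}
        res = calibrate_trial_average(self._estimates(vals), n_max=15)
        for r in res.table.itertuples():
            assert r.hedges_g == pytest.approx(
                r.cohen_d * (1 - 3 / (4 * r.df - 1)), rel=1e-12
            )

    def test_effect_size_grows_with_averaging(self):
        # constant true effect + trial noise: averaging more trials reduces
        # noise, so |d| at n=15 exceeds |d| at n=1 on average
        d1, d15 = [], []
        for seed in range(300):
            df = synthdata.synth_estimate_cohort(
                12, 15, seed=seed, delta=0.25, between_sd=0.4, within_sd=0.8
            )
            res = calibrate_trial_average(df, n_max=15)
            d1.append(res.table["cohen_d"].iloc[0])
            d15.append(res.table["cohen_d"].iloc[14])
        assert np.mean(np.abs(d15)) > np.mean(np.abs(d1))

    def test_confirmation_reevaluates_selected_n(self, rng):
        vals = {f"s{i}": (rng.random(15), rng.random(15) + 0.3) for i in range(8)}
        res = calibrate_trial_average(self._estimates(vals), n_max=15)
        vals2 = {f"s{i}": (rng.random(15), rng.random(15) + 0.3) for i in range(8)}
        conf = confirm_calibration(res, self._estimates(vals2))
        assert len(conf.confirmation) == 1
        assert conf.confirmation["n"].iloc[0] == res.best_n


class TestHabituation:
    def _decay_data(self, lam, n_subj=20, n_trials=30, noise=0.15, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_subj):
            a = rng.lognormal(0, 0.2)
            for t in range(1, n_trials + 1):
                rows.append(dict(subject=f"s{i}", trial_index=t,
                                 condition="CS+" if t % 2 else "CS-",
                                 amplitude=a * np.exp(-lam * (t - 1))
                                 + rng.normal(0, noise)))
        return pd.DataFrame(rows)

    def test_lambda_recovery(self):
        model = fit_habituation(self._decay_data(0.05), "exponential")
        assert 0.03 <= model.lam <= 0.07

    def test_constant_data_boundary(self):
        df = pd.DataFrame(dict(subject="s0", trial_index=np.arange(1, 31),
                               condition="CS+", amplitude=2.0))
        model = fit_habituation(df, "exponential")
        assert model.lam == 0.0

    def test_linear_exact_on_line(self):
        df = pd.DataFrame(dict(subject="s0", trial_index=np.arange(1, 21),
                               condition="CS+",
                               amplitude=5.0 - 0.1 * np.arange(20)))
        model = fit_habituation(df, "linear")
        assert model.slope == pytest.approx(-0.1, abs=1e-10)
        assert model.intercept == pytest.approx(5.0, abs=1e-9)

    def test_frozen_source_dataset(self):
        model = fit_habituation(self._decay_data(0.05), "exponential",
                                dataset_id="exp1")
        assert model.source_dataset == "exp1"


def _lme_cohort(n_subj, n_trials, effect, lam, seed, noise=0.3, slope_sd=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subj):
        intercept = rng.normal(1.0, 0.3)
        slope = rng.normal(1.0, slope_sd)
        order = rng.permutation([True] * (n_trials // 2) + [False] * (n_trials // 2))
        for t, is_plus in enumerate(order, start=1):
            h = np.exp(-lam * (t - 1))
            amp = intercept + slope * h + effect * is_plus + rng.normal(0, noise)
            rows.append(dict(subject=f"s{i}", trial_index=t,
                             condition="CS+" if is_plus else "CS-",
                             amplitude=amp))
    return pd.DataFrame(rows)


class TestLme:
    def test_habituation_without_effect(self):
        df = _lme_cohort(20, 30, effect=0.0, lam=0.08, seed=1, slope_sd=0.3)
        model = HabituationModel("exponential", lam=0.08)
        res = lme_condition_test(df, model)
        assert res.effects["trial"].p < 0.001
        assert res.effects["condition"].p > 0.05

    def test_condition_effect_detected(self):
        df = _lme_cohort(20, 30, effect=0.5, lam=0.05, seed=2, slope_sd=0.3)
        res = lme_condition_test(df, HabituationModel("exponential", lam=0.05))
        assert res.effects["condition"].p < 0.01
        assert 0 < res.effects["condition"].partial_eta_sq < 1

    def test_balanced_no_random_slope_matches_ols_oracle(self):
        # with no subject heterogeneity beyond the intercept, fixed effects
        # agree with OLS on subject-demeaned data
        df = _lme_cohort(15, 30, effect=0.4, lam=0.05, seed=3,
                         noise=0.2, slope_sd=0.0)
        model = HabituationModel("exponential", lam=0.05)
        res = lme_condition_test(df, model, random_structure="intercept")
        d = df.copy()
        d["treg"] = model.trial_regressor(d["trial_index"].to_numpy())
        d["is_plus"] = (d["condition"] == "CS+").astype(float)
        d["y"] = d["amplitude"] - d.groupby("subject")["amplitude"].transform("mean")
        X = np.column_stack([
            d["treg"] - d.groupby("subject")["treg"].transform("mean"),
            d["is_plus"] - d.groupby("subject")["is_plus"].transform("mean"),
            d["treg"] * d["is_plus"]
            - d.groupby("subject")[["treg", "is_plus"]].transform("mean").prod(axis=1),
        ])
        # within-subject projection: compare slope estimates loosely
        beta = np.linalg.lstsq(X, d["y"].to_numpy(), rcond=None)[0]
        assert res.params["treg"] == pytest.approx(beta[0], abs=0.05)
        assert res.params["is_plus"] == pytest.approx(beta[1], abs=0.05)

    def test_type_i_error_near_alpha(self):
        rejections = 0
        n_sim = 120
        for seed in range(n_sim):
            df = _lme_cohort(12, 20, effect=0.0, lam=0.05, seed=seed,
                             slope_sd=0.2)
            res = lme_condition_test(df, HabituationModel("exponential", lam=0.05))
            rejections += res.effects["condition"].p < 0.05
        rate = rejections / n_sim
        assert rate <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n_sim)

    def test_structure_selection_runs(self):
        df = _lme_cohort(10, 20, effect=0.3, lam=0.05, seed=5, slope_sd=0.5)
        structure = select_random_structure(
            df, HabituationModel("exponential", lam=0.05)
        )
        assert structure in ("intercept", "intercept_slope")


class TestPower:
    def test_infinite_effect_limits(self):
        assert sample_size(PowerSpec(d=50.0, design="paired")) == 2
        assert sample_size(PowerSpec(d=50.0, design="two_sample")) == 4

    def test_monotone_in_d_and_power(self):
        ds = [0.2, 0.4, 0.8]
        ns = [sample_size(PowerSpec(d=d)) for d in ds]
        assert ns[0] >= ns[1] >= ns[2]
        powers = [0.5, 0.8, 0.95]
        ns = [sample_size(PowerSpec(d=0.4, power=p)) for p in powers]
        assert ns[0] <= ns[1] <= ns[2]

    def test_exact_vs_normal_approximation_differs(self):
        # the noncentral-t requirement exceeds the z-approximation
        d = 0.44
        z_n = int(np.ceil(((sst.norm.ppf(0.95) + sst.norm.ppf(0.8)) / d) ** 2))
        assert sample_size(PowerSpec(d=d)) > z_n

    def test_two_sided_needs_more(self):
        assert (sample_size(PowerSpec(d=0.4, tails="two"))
                > sample_size(PowerSpec(d=0.4, tails="one")))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(d=-0.2)
        with pytest.raises(ValueError):
            PowerSpec(d=0.4, alpha=1.5)
        with pytest.raises(ValueError):
            PowerSpec(d=0.4, tails="three")


class TestSummaryStats:
    def test_antisymmetry(self):
        a = summary_t_and_d(27.25, 5.01, 28, 25.53, 4.54, 28)
        b = summary_t_and_d(25.53, 4.54, 28, 27.25, 5.01, 28)
        assert a["t"] == pytest.approx(-b["t"])
        assert a["cohen_d"] == pytest.approx(-b["cohen_d"])

    def test_equal_means_zero(self):
        r = summary_t_and_d(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert r["t"] == 0.0
        assert r["cohen_d"] == 0.0

    def test_chi2_identical_rows_zero(self):
        assert chi2_2x2_yates(10, 20, 10, 20)["chi2"] == pytest.approx(0.0)

    def test_chi2_matches_textbook_formula(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(5, 40, 4)
            got = chi2_2x2_yates(a, b, c, d)["chi2"]
            n = a + b + c + d
            expect = (
                n * max(abs(a * d - b * c) - n / 2, 0.0) ** 2
                / ((a + b) * (c + d) * (a + c) * (b + d))
            )
            assert got == pytest.approx(expect, rel=1e-12)

    def test_hedges_correction_factor(self):
        assert hedges_correction(24) == pytest.approx(1 - 3 / 95)
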