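"""Survival layer: counting-process expansion, Cox fits, selection, tertiles."""
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from icans_qeeg.exceptions import (ConfigError, DataError, DegenerateError,
                                   SizeError)
from icans_qeeg.records import PatientTimeline
from icans_qeeg.risk import (baseline_table, expand_counting_process, fit_cox,
                             group_compare, stepwise_select, tertile_analysis,
                             tertile_cutoffs, validate_counting_process)
from icans_qeeg.simulate import CohortSimSpec, simulate_cohort


def _timeline(pid, eeg_days, values, icans_day, censor_day=30.0):
    from icans_qeeg.features import RecordFeatures

    feats = [RecordFeatures(1, v, 1, 1, v, 1, 1.5) for v in values]
    return PatientTimeline(patient_id=pid, eeg_days=list(eeg_days),
                           grades=[0] * len(eeg_days), features=feats,
                           icans_day=icans_day, censor_day=censor_day,
                           covariates={"x": list(values)})


class TestExpansion:
    def test_single_update_then_event(self):
        tl = _timeline("a", [-17.0, 1.0], [0.0, 1.0], icans_day=5.0)
        df = expand_counting_process([tl], "x")
        assert df[["start", "stop"]].values.tolist() == [[0.0, 1.0], [1.0, 5.0]]
        assert df["event"].tolist() == [False, True]
        assert df["x"].tolist() == [0.0, 1.0]

    def test_at_risk_time_conserved(self):
        tls = simulate_cohort(CohortSimSpec(n_patients=120, seed=3))
        df = expand_counting_process(tls, "slowing")
        spans = df.groupby("patient_id").apply(
            lambda s: (s["stop"] - s["start"]).sum(), include_groups=False)
        for tl in tls:
            assert spans[tl.patient_id] == pytest.approx(tl.end_day)

    def test_post_onset_eegs_never_update_covariate(self):
        tl = _timeline("a", [-17.0, 1.0, 3.0], [0.0, 1.0, 99.0], icans_day=2.0)
        df = expand_counting_process([tl], "x")
        assert 99.0 not in df["x"].values

    def test_overlapping_rows_detected(self):
        df = pd.DataFrame({"patient_id": ["a", "a"], "start": [0.0, 3.0],
                           "stop": [5.0, 8.0], "event": [False, True],
                           "x": [0.0, 1.0]})
        with pytest.raises(DataError):
            validate_counting_process(df)

    def test_immediate_event(self):
        tl = _timeline("a", [-17.0], [1.0], icans_day=0.0)
        df = expand_counting_process([tl], "x")
        assert len(df) == 1 and df["event"].iloc[0]
        assert df["stop"].iloc[0] > 0


def brute_force_cox_coef(df):
    """Maximize the (no-ties) Cox partial likelihood on counting-process rows."""
    starts = df["start"].to_numpy()
    stops = df["stop"].to_numpy()
    events = df["event"].to_numpy()
    x = df["x"].to_numpy()

    def neg_pl(beta):
        ll = 0.0
        for t, xi in zip(stops[events], x[events]):
            at_risk = (starts < t) & (t <= stops)
            ll += beta * xi - np.log(np.sum(np.exp(beta * x[at_risk])))
        return -ll

    res = optimize.minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                                   options={"xatol": 1e-10})
    return res.x


class TestFitCox:
    def test_matches_brute_force_partial_likelihood(self):
        # 20 patients, continuous event times (no ties): Efron = exact
        rng = np.random.default_rng(8)
        tls = []
        for i in range(20):
            xv = float(rng.integers(2))
            rate = 0.05 * np.exp(np.log(2.5) * xv)
            t = rng.exponential(1 / rate)
            event = t < 25.0
            tls.append(_timeline(f"p{i}", [-16.0], [xv],
                                 icans_day=t if event else None,
                                 censor_day=25.0))
        df = expand_counting_process(tls, "x")
        fit = fit_cox(df, ["x"], model="time_dependent")[0]
        brute = brute_force_cox_coef(df)
        assert fit.coef == pytest.approx(brute, abs=1e-5)

    def test_recovers_known_hazard_ratio(self):
        spec = CohortSimSpec(n_patients=1000, beta={"group": np.log(2.0)},
                             baseline_hazard=0.02, risk_window_days=None,
                             seed=21)
        tls = simulate_cohort(spec)
        res = fit_cox(baseline_table(tls, "group"), ["group"], "fixed")[0]
        assert 1.6 <= res.hr <= 2.5
        assert res.ci_low <= res.hr <= res.ci_high

    def test_time_dependent_equals_fixed_for_constant_covariate(self):
        spec = CohortSimSpec(n_patients=400, beta={"group": np.log(2.0)},
                             baseline_hazard=0.02, risk_window_days=None,
                             seed=2)
        tls = simulate_cohort(spec)
        fixed = fit_cox(baseline_table(tls, "group"), ["group"], "fixed")[0]
        timedep = fit_cox(expand_counting_process(tls, "group"), ["group"],
                          "time_dependent")[0]
        assert timedep.coef == pytest.approx(fixed.coef, abs=1e-6)

    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "duration": rng.exponential(10, 400),
            "event": rng.random(400) < 0.7,
            "x": rng.standard_normal(400),
        })
        res = fit_cox(df, ["x"], model="fixed")[0]
        assert res.ci_low < 1.0 < res.ci_high

    def test_constant_covariate_degenerate(self):
        df = pd.DataFrame({"duration": [1.0, 2, 3, 4, 5, 6],
                           "event": [True] * 6, "x": [1.0] * 6})
        with pytest.raises(DegenerateError):
            fit_cox(df, ["x"], model="fixed")

    def test_zero_events_degenerate(self):
        df = pd.DataFrame({"duration": [1.0, 2.0], "event": [False, False],
                           "x": [0.0, 1.0]})
        with pytest.raises(DegenerateError):
            fit_cox(df, ["x"], model="fixed")


class TestStepwise:
    def _df(self, n=400, seed=0, effect=np.log(3.0)):
        rng = np.random.default_rng(seed)
        x_true = rng.integers(2, size=n).astype(float)
        nulls = {f"n{i}": rng.standard_normal(n) for i in range(4)}
        rate = 0.05 * np.exp(effect * x_true)
        t = rng.exponential(1 / rate)
        return pd.DataFrame({"duration": np.minimum(t, 30.0),
                             "event": t < 30.0, "x_true": x_true, **nulls})

    def test_selects_true_covariate(self):
        df = self._df()
        selected, results = stepwise_select(
            df, ["x_true", "n0", "n1", "n2", "n3"], model="fixed")
        assert "x_true" in selected
        assert all(r.p_value < 0.05 or r.covariate != "x_true" for r in results)

    def test_single_strong_candidate_equals_univariable(self):
        df = self._df()
        selected, results = stepwise_select(df, ["x_true"], model="fixed")
        uni = fit_cox(df, ["x_true"], model="fixed")[0]
        assert selected == ["x_true"]
        assert results[0].coef == pytest.approx(uni.coef, abs=1e-9)

    def test_all_null_mostly_empty(self):
        empties = 0
        for seed in range(20):
            df = self._df(seed=seed, effect=0.0).drop(columns=["x_true"])
            rng = np.random.default_rng(seed + 100)
            df["x0"] = rng.standard_normal(len(df))
            selected, _ = stepwise_select(df, ["n0", "n1", "n2", "n3", "x0"],
                                          model="fixed")
            if not selected:
                empties += 1
        # P(no entry) ≈ 0.95^5 ≈ 0.77; 20 trials, allow broad binomial band
        assert empties >= 10


class TestTertiles:
    def test_cutoffs_linear_interpolation(self):
        lo, hi = tertile_cutoffs(np.arange(1.0, 10.0))
        assert lo == pytest.approx(11.0 / 3.0, abs=1e-9)
        assert hi == pytest.approx(19.0 / 3.0, abs=1e-9)

    def test_degenerate_ties_warn(self):
        with pytest.warns(RuntimeWarning):
            tertile_cutoffs(np.ones(12))

    def test_too_few_values(self):
        with pytest.raises(SizeError):
            tertile_cutoffs([1.0, 2.0, 3.0])

    def test_dichotomized_risk_detected(self):
        rng = np.random.default_rng(17)
        n = 1000
        x = rng.uniform(0, 3, n)
        upper = x > np.percentile(x, 200.0 / 3.0)
        rate = 0.03 * np.where(upper, 2.0, 1.0)
        t = rng.exponential(1 / rate)
        df = pd.DataFrame({"duration": np.minimum(t, 30.0), "event": t < 30.0,
                           "x": x})
        cuts, res = tertile_analysis(df, "x", model="fixed")
        assert res.hr > 1.0 and res.p_value < 0.05
        assert res.ci_low > 1.0


class TestGroupCompare:
    def test_separated_groups_extreme_u(self):
        a = np.arange(20.0)
        b = np.arange(100.0, 120.0)
        stat, p = group_compare(np.concatenate([a, b]),
                                ["a"] * 20 + ["b"] * 20, kind="continuous")
        assert stat in (0.0, 400.0)
        assert p < 0.001

    def test_chi_square_hand_value(self):
        values = [0] * 10 + [1] * 10
        labels = ["g1"] * 10 + ["g2"] * 10
        stat, p = group_compare(values, labels, kind="categorical")
        assert stat == pytest.approx(20.0)

    def test_null_p_uniformish(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(200):
            v = rng.standard_normal(40)
            lab = np.array(["a"] * 20 + ["b"] * 20)
            rng.shuffle(lab)
            ps.append(group_compare(v, lab, kind="continuous")[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_three_groups_rejected(self):
        with pytest.raises(DataError):
            group_compare([1, 2, 3], ["a", "b", "c"], kind="continuous")

    def test_low_expected_counts_warn(self):
        with pytest.warns(RuntimeWarning):
            group_compare([0, 0, 1, 1], ["a", "a", "b", "b"],
                          kind="categorical")
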