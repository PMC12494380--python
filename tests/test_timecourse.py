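"""Confounder correction, ARIMA screening, rate curves and breakpoints."""

import numpy as np
import pandas as pd
import pytest

from txaging._stats import two_group_pillai
from txaging.differential import SurrogateVariableSet
from txaging.timecourse import (
    RateCurve,
    compare_sex_rate_curves,
    compute_rate_curve,
    correct_confounders_and_average,
    detect_breakpoints,
    select_chronological_features,
)


def _samples(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "donor": [f"d{i}" for i in range(n)],
            "sex": np.array(["F", "M"])[np.arange(n) % 2],
            "age": rng.integers(20, 80, n),
            "tissue": "t",
        },
        index=[f"s{i}" for i in range(n)],
    )


class TestPillai:
    def test_matches_statsmodels_manova(self):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(1)
        a = rng.normal(size=(12, 3))
        b = rng.normal(0.8, 1.0, size=(10, 3))
        pillai, f, p = two_group_pillai(a, b)
        data = pd.DataFrame(np.vstack([a, b]), columns=["y1", "y2", "y3"])
        data["g"] = ["a"] * 12 + ["b"] * 10
        ref = MANOVA.from_formula("y1 + y2 + y3 ~ g", data=data).mv_test()
        tbl = ref.results["g"]["stat"]
        assert pillai == pytest.approx(tbl.loc["Pillai's trace", "Value"], rel=1e-8)
        assert p == pytest.approx(tbl.loc["Pillai's trace", "Pr > F"], rel=1e-6)

    def test_null_neg_log_p_mean(self):
        """Under exchangeability p ~ U(0,1), so E[-log10 p] = 1/ln 10."""
        rng = np.random.default_rng(2)
        vals = [
            -np.log10(
                two_group_pillai(rng.normal(size=(10, 3)), rng.normal(size=(10, 3)))[2]
            )
            for _ in range(800)
        ]
        assert np.mean(vals) == pytest.approx(1 / np.log(10), abs=0.05)


class TestConfounderCorrection:
    def test_zero_svs_identity_and_cell_means(self):
        samples = _samples(6, seed=3)
        samples["age"] = [30, 30, 40, 41, 50, 50]
        samples["sex"] = ["F", "F", "M", "M", "F", "F"]
        vals = pd.DataFrame(
            [[4.0, 6.0, 1.0, 2.0, 3.0, 5.0]], index=["g"], columns=samples.index
        )
        corrected, traj = correct_confounders_and_average(vals, samples, None)
        pd.testing.assert_frame_equal(corrected, vals)
        assert traj["F"].loc["g", 30] == pytest.approx(5.0)  # (4 + 6) / 2
        assert traj["F"].loc["g", 50] == pytest.approx(4.0)
        assert traj["M"].loc["g", 40] == pytest.approx(1.0)

    def test_batch_removal_recovers_trend(self):
        rng = np.random.default_rng(4)
        samples = _samples(150, seed=4)
        age = samples["age"].to_numpy(float)
        batch = rng.normal(size=150)
        truth = 0.05 * age
        obs = truth + 1.5 * batch + rng.normal(0, 0.1, 150)
        vals = pd.DataFrame([obs], index=["g"], columns=samples.index)
        sv = SurrogateVariableSet(
            pd.DataFrame({"SV1": batch}, index=samples.index)
        )
        corrected, _ = correct_confounders_and_average(vals, samples, sv)
        uncorrected_rmse = np.sqrt(np.mean((obs - truth) ** 2))
        corrected_rmse = np.sqrt(
            np.mean((corrected.loc["g"].to_numpy() - truth) ** 2)
        )
        assert corrected_rmse < 0.5 * uncorrected_rmse


class TestChronologicalSelection:
    def test_noise_excluded_integrated_included(self):
        rng = np.random.default_rng(5)
        n = 50
        rows = {}
        for i in range(5):
            rows[f"wn{i}"] = rng.normal(size=n)
        for i in range(5):
            e = rng.normal(size=n)
            ar = np.zeros(n)
            for t in range(1, n):
                ar[t] = 0.7 * ar[t - 1] + e[t]
            rows[f"int{i}"] = np.cumsum(ar)
        traj = pd.DataFrame(rows, index=np.arange(20, 20 + n)).T
        chosen = select_chronological_features(traj)
        sel = chosen.models["selected"]
        assert sel[[f"int{i}" for i in range(5)]].all()
        # AIC occasionally over-differences one white-noise series
        assert sel[[f"wn{i}" for i in range(5)]].sum() <= 1
        for m in chosen.members:
            rec = chosen.models.loc[m]
            assert rec["d"] >= 1 and rec["coef_sum"] > 0

    def test_constant_trajectory_excluded_not_error(self):
        traj = pd.DataFrame(
            [np.zeros(30), np.cumsum(np.random.default_rng(6).normal(size=30))],
            index=["flat", "walk"], columns=np.arange(20, 50),
        )
        chosen = select_chronological_features(traj)
        assert "flat" not in chosen.members

    def test_short_trajectory_rejected(self):
        traj = pd.DataFrame([np.arange(10.0)], index=["g"])
        with pytest.raises(ValueError):
            select_chronological_features(traj)


class TestRateCurve:
    def _planted(self, seed=7, n=240, bp=50):
        rng = np.random.default_rng(seed)
        ages = pd.Series(rng.integers(20, 80, n).astype(float))
        Y = rng.normal(size=(30, n)) * 0.5
        Y[:12] += (ages.to_numpy() > bp) * 1.5
        vals = pd.DataFrame(
            Y, index=[f"g{i}" for i in range(30)], columns=[f"s{i}" for i in range(n)]
        )
        return vals, ages

    def test_peak_near_planted_breakpoint(self):
        vals, ages = self._planted()
        curve = compute_rate_curve(vals, ages, list(vals.index), w_min=5, w_max=15)
        peak_age = curve.ages[np.argmax(curve.rate)]
        assert abs(peak_age - 50) <= 3
        assert (curve.rate >= 0).all()
        assert curve.raw is not None and len(curve.raw) == len(curve.ages)

    def test_feature_order_invariance(self):
        vals, ages = self._planted()
        fwd = compute_rate_curve(vals, ages, list(vals.index), w_min=5, w_max=6)
        rev = compute_rate_curve(vals, ages, list(vals.index)[::-1], w_min=5, w_max=6)
        assert np.allclose(fwd.rate, rev.rate, atol=1e-8)

    def test_too_few_features_rejected(self):
        vals, ages = self._planted()
        with pytest.raises(ValueError):
            compute_rate_curve(vals, ages, list(vals.index)[:2])


class TestBreakpoints:
    def test_hand_example_with_secondary_peak(self):
        curve = RateCurve(
            ages=np.arange(25, 32), rate=np.array([1, 2, 5, 2, 1, 3, 1.0])
        )
        bps = detect_breakpoints(curve)
        assert bps.ages == [27, 30]
        assert bps.breakpoints[0][1] == "global_max"
        assert bps.major[2] == pytest.approx(5.0)

    def test_unimodal_single_breakpoint(self):
        curve = RateCurve(ages=np.arange(40, 45), rate=np.array([1, 2, 3, 2, 1.0]))
        bps = detect_breakpoints(curve)
        assert bps.ages == [42]

    def test_shallow_secondary_peak_suppressed(self):
        # (3.4 - 3.0) / 5.0 = 0.08 < 0.10
        curve = RateCurve(
            ages=np.arange(25, 32), rate=np.array([1, 2, 5, 3.2, 3.0, 3.4, 1.0])
        )
        assert detect_breakpoints(curve).ages == [27]

    def test_flat_curve_warns_empty(self):
        curve = RateCurve(ages=np.arange(20, 26), rate=np.ones(6))
        with pytest.warns(UserWarning):
            assert detect_breakpoints(curve).breakpoints == []

    def test_matches_bruteforce_scan(self):
        """Random curves: detector equals an independent extremum scan."""
        rng = np.random.default_rng(8)
        for _ in range(25):
            rate = np.round(rng.uniform(0, 5, 20), 2)
            curve = RateCurve(ages=np.arange(30, 50), rate=rate)
            if np.ptp(rate) == 0:
                continue
            maxima = [
                i for i in range(1, 19)
                if rate[i] > rate[i - 1] and rate[i] > rate[i + 1]
            ]
            minima = [
                i for i in range(1, 19)
                if rate[i] < rate[i - 1] and rate[i] < rate[i + 1]
            ]
            if rate[0] < rate[1]:
                minima.append(0)
            if rate[19] < rate[18]:
                minima.append(19)
            expected = []
            if maxima:
                g = maxima[int(np.argmax(rate[maxima]))]
                expected.append(30 + g)
                for m in maxima:
                    if m == g or not minima:
                        continue
                    nearest = min(minima, key=lambda j: (abs(j - m), j))
                    if (rate[m] - rate[nearest]) / rate[g] > 0.10:
                        expected.append(30 + m)
            got = detect_breakpoints(curve).ages
            assert sorted(got) == sorted(expected)


class TestSexComparison:
    def test_identical_curves_no_difference(self):
        curve = RateCurve(ages=np.arange(30, 50), rate=np.linspace(1, 3, 20))
        res = compare_sex_rate_curves(curve, curve)
        assert res["p"] == pytest.approx(1.0)

    def test_constant_offset_exact_signed_rank(self):
        """Male curve = female + 0.5 at 20 ages: all-positive differences
        give the extreme two-sided exact signed-rank p of 2^-19."""
        rng = np.random.default_rng(9)
        base = rng.uniform(1, 3, 20)
        f = RateCurve(ages=np.arange(30, 50), rate=base)
        m = RateCurve(ages=np.arange(30, 50), rate=base + 0.5)
        res = compare_sex_rate_curves(f, m)
        assert res["p"] == pytest.approx(2.0**-19, rel=1e-9)
        assert res["male_minus_female_median"] == pytest.approx(0.5)

    def test_planted_earlier_male_breakpoint(self):
        rng = np.random.default_rng(10)
        n = 400
        ages = rng.integers(20, 80, n).astype(float)
        sex = np.array(["F", "M"])[np.arange(n) % 2]
        Y = rng.normal(size=(25, n)) * 0.5
        Y[:10, sex == "M"] += (ages[sex == "M"] > 45) * 1.5
        Y[:10, sex == "F"] += (ages[sex == "F"] > 55) * 1.5
        vals = pd.DataFrame(
            Y, index=[f"g{i}" for i in range(25)],
            columns=[f"s{i}" for i in range(n)],
        )
        kw = dict(w_min=5, w_max=8)
        curve_m = compute_rate_curve(
            vals.loc[:, sex == "M"], pd.Series(ages[sex == "M"]),
            list(vals.index), **kw,
        )
        curve_f = compute_rate_curve(
            vals.loc[:, sex == "F"], pd.Series(ages[sex == "F"]),
            list(vals.index), **kw,
        )
        res = compare_sex_rate_curves(curve_f, curve_m)
        assert res["major_breakpoint_M"][0] < res["major_breakpoint_F"][0]

    def test_disjoint_age_grids_unavailable(self):
        a = RateCurve(ages=np.arange(30, 40), rate=np.linspace(1, 2, 10))
        b = RateCurve(ages=np.arange(60, 70), rate=np.linspace(1, 2, 10))
        with pytest.warns(UserWarning):
            res = compare_sex_rate_curves(a, b)
        assert np.isnan(res["p"])
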