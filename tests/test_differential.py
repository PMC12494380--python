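"""Linear models, SV estimation, differential calls and set statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from txaging._stats import vectorized_ols
from txaging.differential import (
    call_differential,
    classify_sex_bias,
    compare_correlations,
    effect_size_correlation,
    estimate_surrogate_variables,
    fit_interaction_model,
    fit_sex_stratified_model,
    overlap_significance,
    permutation_fdr,
    sample_size_bias_model,
    sv_covariate_correlation,
)
from txaging.preprocess import normalize_scaling
from txaging.simulate import CohortConfig, PlantedEffect, generate_cohort


def _samples(n, seed=0, sex_balance=True):
    rng = np.random.default_rng(seed)
    sexes = np.array(["F", "M"])[np.arange(n) % 2] if sex_balance else rng.choice(
        ["F", "M"], n
    )
    return pd.DataFrame(
        {
            "donor": [f"d{i}" for i in range(n)],
            "sex": sexes,
            "age": rng.integers(20, 80, n),
            "tissue": "t",
        },
        index=[f"s{i}" for i in range(n)],
    )


class TestVectorizedOls:
    def test_matches_statsmodels_per_feature(self):
        """The shared-design kernel must agree with statsmodels OLS."""
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        Y = rng.normal(size=(5, 30))
        fit = vectorized_ols(Y, X)
        for i in range(5):
            ref = sm.OLS(Y[i], X).fit()
            assert np.allclose(fit["beta"][i], ref.params, rtol=1e-10)
            assert np.allclose(fit["se"][i], ref.bse, rtol=1e-10)
            assert np.allclose(fit["p"][i], ref.pvalues, rtol=1e-8)


class TestInteractionModel:
    def test_noiseless_coefficients_exact(self):
        samples = _samples(40)
        sex = samples["sex"].map({"F": 0, "M": 1}).to_numpy(float)
        age = samples["age"].to_numpy(float)
        y = 1.0 + 2.0 * sex + 0.1 * age
        vals = pd.DataFrame([y], index=["f0"], columns=samples.index)
        fit = fit_interaction_model(vals, samples)
        assert fit.loc["f0", "mu"] == pytest.approx(1.0, abs=1e-8)
        assert fit.loc["f0", "alpha_sex"] == pytest.approx(2.0, abs=1e-8)
        assert fit.loc["f0", "beta_age"] == pytest.approx(0.1, abs=1e-8)
        assert fit.loc["f0", "gamma_interaction"] == pytest.approx(0.0, abs=1e-8)

    def test_null_type_one_error(self):
        rng = np.random.default_rng(2)
        samples = _samples(200, seed=2)
        vals = pd.DataFrame(
            rng.normal(size=(1000, 200)),
            index=[f"f{i}" for i in range(1000)],
            columns=samples.index,
        )
        fit = fit_interaction_model(vals, samples)
        frac = (fit["p_gamma_interaction"] < 0.05).mean()
        # binomial 95% band around 0.05 at n = 1000
        assert 0.035 <= frac <= 0.065

    def test_planted_interaction_power(self):
        cfg = CohortConfig(
            n_donors=300, n_genes=120, n_events=10, seed=31,
            effect_blocks=[
                PlantedEffect(
                    kind="interaction", magnitude=4.0, target_features=50,
                    sex_specificity="male_only",
                )
            ],
        )
        cohort = generate_cohort(cfg)
        norm = normalize_scaling(np.log2(cohort.tpm + 1))
        fit = fit_interaction_model(norm.values, cohort.samples)
        targets = cohort.truth[0]["target_features"]
        assert (fit.loc[targets, "p_gamma_interaction"] < 0.05).mean() >= 0.8


class TestSurrogateVariables:
    def test_planted_batch_factor_recovered(self):
        rng = np.random.default_rng(3)
        samples = _samples(100, seed=3)
        batch = rng.normal(size=100)
        vals = rng.normal(size=(150, 100))
        loaded = rng.choice(150, 50, replace=False)
        vals[loaded] += np.outer(rng.normal(0, 1.0, 50), batch)
        frame = pd.DataFrame(
            vals, index=[f"f{i}" for i in range(150)], columns=samples.index
        )
        svs = estimate_surrogate_variables(frame, samples, k=1)
        r = np.corrcoef(svs.sv["SV1"], batch)[0, 1]
        assert abs(r) > 0.9

    def test_no_structure_selects_zero(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            samples = _samples(60, seed=seed)
            frame = pd.DataFrame(
                rng.normal(size=(80, 60)),
                index=[f"f{i}" for i in range(80)],
                columns=samples.index,
            )
            svs = estimate_surrogate_variables(frame, samples, seed=seed)
            hits += svs.k == 0
        assert hits >= 9

    def test_explicit_zero_k(self, plain_frame):
        samples = _samples(40, seed=4)
        frame = plain_frame.copy()
        frame.columns = samples.index
        svs = estimate_surrogate_variables(frame, samples, k=0)
        assert svs.k == 0
        fit = fit_interaction_model(frame, samples, svs)
        assert "SV1" not in fit.columns

    def test_covariate_diagnostics(self):
        rng = np.random.default_rng(5)
        samples = _samples(80, seed=5)
        batch = np.where(rng.random(80) < 0.5, "A", "B")
        vals = rng.normal(size=(100, 80)) + np.where(batch == "A", 0, 2.0)
        frame = pd.DataFrame(
            vals, index=[f"f{i}" for i in range(100)], columns=samples.index
        )
        svs = estimate_surrogate_variables(frame, samples, k=1)
        diag = sv_covariate_correlation(
            svs, pd.DataFrame({"batch": batch}, index=samples.index)
        )
        assert diag["method"].iloc[0] == "point-biserial"
        assert abs(diag["r"].iloc[0]) > 0.8


class TestCalls:
    def _setup(self):
        samples = _samples(100, seed=6)
        young = samples.index[samples["age"] < 40]
        old = samples.index[samples["age"] > 60]
        return samples, young, old

    def test_threshold_logic(self):
        samples, young, old = self._setup()
        raw = pd.DataFrame(
            10.0, index=["f_weak_fc", "f_called", "f_weak_p"], columns=samples.index
        )
        raw.loc["f_weak_fc", old] = 14.0  # fold change 1.4
        raw.loc["f_called", old] = 30.0  # fold change 3
        raw.loc["f_weak_p", old] = 30.0
        pvals = pd.Series(
            {"f_weak_fc": 0.01, "f_called": 0.001, "f_weak_p": 0.06}
        )
        out = call_differential(pvals, raw, samples, "GE")
        assert not out.loc["f_weak_fc", "called"]
        assert out.loc["f_called", "called"]
        assert not out.loc["f_weak_p", "called"]

    def test_delta_psi_gate(self):
        samples, young, old = self._setup()
        raw = pd.DataFrame(0.50, index=["e1", "e2"], columns=samples.index)
        raw.loc["e1", old] = 0.57
        raw.loc["e2", old] = 0.54
        pvals = pd.Series({"e1": 0.001, "e2": 0.001})
        out = call_differential(pvals, raw, samples, "AS")
        assert out.loc["e1", "delta_psi"] == pytest.approx(0.07, abs=1e-12)
        assert bool(out.loc["e1", "called"]) and not bool(out.loc["e2", "called"])


class TestStratified:
    def test_noiseless_sex_specific_slopes(self):
        samples = _samples(60, seed=7)
        age = samples["age"].to_numpy(float)
        female = (samples["sex"] == "F").to_numpy()
        y = np.where(female, 0.2 * age, 0.0)
        vals = pd.DataFrame([y], index=["f0"], columns=samples.index)
        fit = fit_sex_stratified_model(vals, samples)
        assert fit.loc["f0", "beta_F"] == pytest.approx(0.2, abs=1e-10)
        assert fit.loc["f0", "beta_M"] == pytest.approx(0.0, abs=1e-10)

    def test_labels_partition(self):
        calls_f = pd.Series([True, True, False, False], index=list("abcd"))
        calls_m = pd.Series([False, True, True, False], index=list("abcd"))
        lab = classify_sex_bias(calls_f, calls_m)
        assert lab.tolist() == ["female_specific", "common", "male_specific", "none"]

    def test_small_stratum_skipped(self):
        samples = _samples(14, seed=8)
        samples.loc[samples.index[:11], "sex"] = "F"
        samples.loc[samples.index[11:], "sex"] = "M"
        vals = pd.DataFrame(
            np.random.default_rng(8).normal(size=(3, 14)),
            index=["a", "b", "c"], columns=samples.index,
        )
        with pytest.warns(UserWarning):
            fit = fit_sex_stratified_model(vals, samples, min_samples=10)
        assert fit["beta_M"].isna().all() and fit["beta_F"].notna().all()


class TestPermutationFdr:
    def test_fdr_arithmetic_and_null_overlap(self):
        rng = np.random.default_rng(9)
        samples = _samples(80, seed=9)
        raw = pd.DataFrame(
            np.exp(rng.normal(2, 0.3, size=(40, 80))),
            index=[f"f{i}" for i in range(40)],
            columns=samples.index,
        )
        norm = normalize_scaling(np.log2(raw + 1))
        out = permutation_fdr(
            norm.values, raw, samples, "GE", n_perm=100, seed=9
        )
        assert ((out["fdr"] >= 0) & (out["fdr"] <= 1)).all()
        assert len(out["iteration_overlap"]) == 100
        # a null cohort has few original calls and small FDRs
        assert out["fdr"].mean() < 0.2

    def test_minimum_permutations_enforced(self, plain_frame):
        samples = _samples(40, seed=10)
        frame = plain_frame.copy()
        frame.columns = samples.index
        with pytest.raises(ValueError):
            permutation_fdr(frame, frame, samples, "GE", n_perm=10)


class TestSetStatistics:
    def test_hypergeometric_hand_value(self):
        universe = set(range(10))
        a, b = set(range(4)), set(range(5))
        assert overlap_significance(a, b, universe) == pytest.approx(
            6 / 252, rel=1e-12
        )

    def test_degenerate_overlaps(self):
        universe = set(range(8))
        assert overlap_significance({0, 1}, {5, 6}, universe) == pytest.approx(1.0)
        assert overlap_significance(universe, universe, universe) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            overlap_significance(set(), set(), set())

    def test_matches_bruteforce_enumeration(self):
        """Exact tail by enumerating all |B|-subsets of a small universe."""
        universe = list(range(9))
        a = {0, 1, 2, 3}
        b = {0, 1, 4, 5, 6}
        k_obs = len(a & set(b))
        count = sum(
            1
            for comb in itertools.combinations(universe, len(b))
            if len(a & set(comb)) >= k_obs
        )
        brute = count / len(list(itertools.combinations(universe, len(b))))
        assert overlap_significance(a, b, universe) == pytest.approx(brute, rel=1e-12)

    def test_fisher_z_hand_value_and_antisymmetry(self):
        res = compare_correlations(0.5, 100, 0.2, 100)
        assert res["z"] == pytest.approx(2.4136, abs=2e-4)
        assert res["p"] == pytest.approx(0.0158, abs=2e-4)
        swapped = compare_correlations(0.2, 100, 0.5, 100)
        assert swapped["z"] == pytest.approx(-res["z"], rel=1e-12)
        assert swapped["p"] == pytest.approx(res["p"], rel=1e-12)
        assert compare_correlations(0.3, 50, 0.3, 60)["p"] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            compare_correlations(1.0, 50, 0.2, 50)


class TestEffectCorrelation:
    def test_identical_slopes_give_rho_one(self):
        fit = pd.DataFrame(
            {"beta_F": np.arange(10.0), "beta_M": np.arange(10.0),
             "p_F": 0.5, "p_M": 0.5}
        )
        assert effect_size_correlation(fit)["rho"] == pytest.approx(1.0)

    def test_independent_slopes_near_zero(self):
        rng = np.random.default_rng(11)
        fit = pd.DataFrame(
            {"beta_F": rng.normal(size=500), "beta_M": rng.normal(size=500)}
        )
        assert abs(effect_size_correlation(fit)["rho"]) < 0.1


class TestBiasModel:
    def test_noiseless_size_effect(self):
        table = pd.DataFrame(
            {
                "N": 10 + 0.5 * np.array([100, 200, 300, 400, 500.0]),
                "Size": [100, 200, 300, 400, 500],
                "Detected": [1000] * 5,
            }
        )
        with pytest.warns(UserWarning):
            fit = sample_size_bias_model(table)
        assert fit.loc["Size", "coef"] == pytest.approx(0.5, abs=1e-10)
        assert "Detected" not in fit.index

    def test_too_few_tissues_rejected(self):
        table = pd.DataFrame({"N": [1, 2, 3], "Size": [1, 2, 3], "Detected": [4, 5, 6]})
        with pytest.raises(ValueError):
            sample_size_bias_model(table)


def test_sbase_recovery_with_planted_sex_specific_events():
    """30 female-only + 30 male-only planted AS age effects, 150/sex."""
    cfg = CohortConfig(
        n_donors=300, n_genes=30, n_events=300, seed=41,
        effect_blocks=[
            PlantedEffect(kind="age_slope", magnitude=0.25, target_features=30,
                          sex_specificity="female_only", datatype="psi"),
            PlantedEffect(kind="age_slope", magnitude=0.25, target_features=30,
                          sex_specificity="male_only", datatype="psi"),
        ],
    )
    cohort = generate_cohort(cfg)
    norm = normalize_scaling(cohort.psi)
    fit = fit_sex_stratified_model(norm.values, cohort.samples)
    calls_f = call_differential(
        fit["p_F"], cohort.psi, cohort.samples[cohort.samples.sex == "F"], "AS"
    )
    calls_m = call_differential(
        fit["p_M"], cohort.psi, cohort.samples[cohort.samples.sex == "M"], "AS"
    )
    labels = classify_sex_bias(calls_f["called"], calls_m["called"])
    truth_f = cohort.truth[0]["target_features"]
    truth_m = cohort.truth[1]["target_features"]
    recall_f = (labels.loc[truth_f] == "female_specific").mean()
    recall_m = (labels.loc[truth_m] == "male_specific").mean()
    assert recall_f >= 0.8 and recall_m >= 0.8
    contamination = (labels.loc[truth_f + truth_m] == "common").mean()
    assert contamination <= 0.1
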