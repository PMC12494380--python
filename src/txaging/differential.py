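"""Differential expression/splicing with age-by-sex interactions.

Per feature (gene TPM or event PSI, scaled upstream), the interaction
model is

    y_j ~ mu + alpha * SEX_j + beta * AGE_j + gamma * SEX_j * AGE_j
          + sum_k delta_k * SV_kj + eps_j

with sex coded F=0 / M=1 and surrogate variables (SVs) absorbing
unmodeled structure; a gamma deviating from zero marks an age-by-sex
interaction.  The sex-stratified model refits ``y ~ b0 + b_F/M * AGE +
SVs`` within each sex; features age-significant in exactly one sex are
sex-biased (for splice events: sBASEs), in both sexes sex-ubiquitous.

Differential calls combine a coefficient p-value < 0.05 with an effect
gate on the raw scale: group-mean fold change > 1.5 for expression or
|delta PSI| > 0.05 for splicing, with groups old (> 60) vs young (< 40)
for age effects and M vs F for sex effects.  False-discovery behavior is
audited by refitting under donor-label permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from txaging._stats import drop_collinear_columns, fisher_z_compare, vectorized_ols

SEX_CODE = {"F": 0.0, "M": 1.0}


@dataclass
class SurrogateVariableSet:
    """Estimated surrogate variables (samples x k, unit variance)."""

    sv: pd.DataFrame
    method: str = "residual-svd"
    singular_values: np.ndarray = None

    @property
    def k(self) -> int:
        return self.sv.shape[1]


def _design_matrix(samples: pd.DataFrame, svs=None, interaction=True):
    sex = samples["sex"].map(SEX_CODE).to_numpy(float)
    age = samples["age"].to_numpy(float)
    cols = [np.ones(len(samples)), sex, age]
    names = ["intercept", "sex", "age"]
    if interaction:
        cols.append(sex * age)
        names.append("sex:age")
    protect = len(cols)
    if svs is not None and svs.shape[1] > 0:
        sv = svs.loc[samples.index] if isinstance(svs, pd.DataFrame) else svs
        for j in range(sv.shape[1]):
            cols.append(np.asarray(sv)[:, j])
            names.append(f"SV{j + 1}")
    X = np.column_stack(cols)
    return drop_collinear_columns(X, names, protect)


def estimate_surrogate_variables(
    values: pd.DataFrame,
    samples: pd.DataFrame,
    k: int = None,
    n_perm: int = 20,
    quantile: float = 0.95,
    seed: int = 0,
) -> SurrogateVariableSet:
    """Estimate surrogate variables from model residuals.

    The primary design (sex + age + interaction) is regressed out of
    every feature; the leading right-singular vectors of the residual
    matrix are the SVs.  When ``k`` is not supplied it is chosen by a
    permutation (parallel-analysis) test: each residual row is permuted
    independently ``n_perm`` times and a component is retained while its
    singular value exceeds the permutation ``quantile`` for its rank.
    """
    X, _ = _design_matrix(samples, None, interaction=True)
    Y = values.to_numpy(float)
    fit = vectorized_ols(Y, X)
    resid = fit["resid"]
    u, s, vt = np.linalg.svd(resid, full_matrices=False)
    max_k = min(resid.shape) - X.shape[1]
    if k is not None:
        if k > max_k:
            raise ValueError(f"k={k} exceeds residual rank budget {max_k}")
        chosen = k
    else:
        rng = np.random.default_rng(seed)
        perm_s = np.empty((n_perm, len(s)))
        proj = X @ np.linalg.inv(X.T @ X) @ X.T  # hat matrix of the design
        y_perm = Y.copy()
        for b in range(n_perm):
            # permute the raw rows, then residualize: the null spectra then
            # face the same design projection as the observed residuals
            for row in y_perm:
                rng.shuffle(row)
            r_res = y_perm - y_perm @ proj
            perm_s[b] = np.linalg.svd(r_res, compute_uv=False)
        thresh = np.quantile(perm_s, quantile, axis=0)
        chosen = 0
        for j in range(max_k):
            if s[j] > thresh[j]:
                chosen += 1
            else:
                break
    sv = vt[:chosen].T
    if chosen:
        sv = sv / sv.std(axis=0, ddof=0)
    out = pd.DataFrame(
        sv, index=values.columns, columns=[f"SV{j + 1}" for j in range(chosen)]
    )
    return SurrogateVariableSet(out, singular_values=s[:chosen])


def sv_covariate_correlation(
    svs: SurrogateVariableSet, covariates: pd.DataFrame
) -> pd.DataFrame:
    """SV vs known-covariate correlation diagnostics.

    Binary covariates use the point-biserial correlation (Pearson on a
    0/1 coding); all others use Spearman.
    """
    rows = []
    sv = svs.sv
    for cov in covariates.columns:
        x = covariates[cov]
        uniq = x.dropna().unique()
        binary = len(uniq) == 2
        if binary:
            x_num = (x == sorted(map(str, uniq))[-1]).astype(float) if x.dtype == object else x.astype(float)
        for col in sv.columns:
            if binary:
                r, p = stats.pearsonr(x_num, sv[col])
                method = "point-biserial"
            else:
                r, p = stats.spearmanr(x.astype(float), sv[col])
                method = "spearman"
            rows.append({"sv": col, "covariate": cov, "method": method, "r": r, "p": p})
    return pd.DataFrame(rows)


def fit_interaction_model(
    values: pd.DataFrame, samples: pd.DataFrame, svs: SurrogateVariableSet = None
) -> pd.DataFrame:
    """Per-feature OLS of the interaction model; one row per feature.

    Columns: coefficients ``mu, alpha_sex, beta_age, gamma_interaction``
    (plus any SVs) and matching two-sided p-values.
    """
    sv = svs.sv if isinstance(svs, SurrogateVariableSet) else svs
    X, names = _design_matrix(samples, sv, interaction=True)
    fit = vectorized_ols(values.to_numpy(float), X)
    rename = {
        "intercept": "mu",
        "sex": "alpha_sex",
        "age": "beta_age",
        "sex:age": "gamma_interaction",
    }
    out = {}
    for j, name in enumerate(names):
        label = rename.get(name, name)
        out[label] = fit["beta"][:, j]
        out[f"p_{label}"] = fit["p"][:, j]
    return pd.DataFrame(out, index=values.index)


def fit_sex_stratified_model(
    values: pd.DataFrame,
    samples: pd.DataFrame,
    svs_by_sex: dict = None,
    min_samples: int = 10,
) -> pd.DataFrame:
    """Age-only OLS within each sex; columns ``beta_F, p_F, beta_M, p_M``.

    SVs are re-estimated (or supplied) per sex.  A sex stratum smaller
    than ``min_samples`` is skipped with a warning and yields NaNs.
    """
    out = pd.DataFrame(index=values.index)
    for sex in ("F", "M"):
        meta = samples[samples["sex"] == sex]
        if len(meta) < min_samples:
            warnings.warn(f"sex stratum {sex} has {len(meta)} samples; skipped")
            out[f"beta_{sex}"] = np.nan
            out[f"p_{sex}"] = np.nan
            continue
        sv = None
        if svs_by_sex and sex in svs_by_sex:
            svset = svs_by_sex[sex]
            sv = svset.sv if isinstance(svset, SurrogateVariableSet) else svset
        age = meta["age"].to_numpy(float)
        cols, names = [np.ones(len(meta)), age], ["intercept", "age"]
        if sv is not None and sv.shape[1] > 0:
            sv = sv.loc[meta.index]
            for j in range(sv.shape[1]):
                cols.append(sv.to_numpy()[:, j])
                names.append(f"SV{j + 1}")
        X, names = drop_collinear_columns(np.column_stack(cols), names, 2)
        fit = vectorized_ols(values[list(meta.index)].to_numpy(float), X)
        out[f"beta_{sex}"] = fit["beta"][:, 1]
        out[f"p_{sex}"] = fit["p"][:, 1]
    return out


def _age_groups(samples: pd.DataFrame, young_max=40, old_min=60):
    return (
        list(samples.index[samples["age"] < young_max]),
        list(samples.index[samples["age"] > old_min]),
    )


def effect_sizes(
    raw: pd.DataFrame,
    group_a: list,
    group_b: list,
    datatype: str,
    pseudocount: float = 0.01,
) -> pd.Series:
    """Raw-scale effect size of group B vs group A per feature.

    GE: direction-symmetric fold change ``max(mB/mA, mA/mB)`` of group
    mean TPM (zero means padded by ``pseudocount`` and flagged via
    warning).  AS: signed difference of group mean PSI (B - A).
    """
    ma = raw[group_a].mean(axis=1)
    mb = raw[group_b].mean(axis=1)
    if datatype == "GE":
        zeros = (ma == 0) | (mb == 0)
        if zeros.any():
            warnings.warn(f"{int(zeros.sum())} features with zero group-mean TPM; using pseudocount")
        ma = ma + pseudocount * (ma == 0)
        mb = mb + pseudocount * (mb == 0)
        return pd.concat([mb / ma, ma / mb], axis=1).max(axis=1)
    if datatype == "AS":
        return mb - ma
    raise ValueError("datatype must be 'GE' or 'AS'")


def call_differential(
    pvalues: pd.Series,
    raw: pd.DataFrame,
    samples: pd.DataFrame,
    datatype: str,
    contrast: str = "age",
    p_threshold: float = 0.05,
    fc_threshold: float = 1.5,
    dpsi_threshold: float = 0.05,
) -> pd.DataFrame:
    """Combine a coefficient p-value with the raw-scale effect gate.

    A feature is called iff p < ``p_threshold`` and (GE) fold change >
    ``fc_threshold`` or (AS) |delta PSI| > ``dpsi_threshold``.
    """
    if contrast == "age":
        young, old = _age_groups(samples)
        eff = effect_sizes(raw, young, old, datatype)
    elif contrast == "sex":
        f = list(samples.index[samples["sex"] == "F"])
        m = list(samples.index[samples["sex"] == "M"])
        eff = effect_sizes(raw, f, m, datatype)
    else:
        raise ValueError("contrast must be 'age' or 'sex'")
    if datatype == "GE":
        gate = eff > fc_threshold
        eff_name = "fold_change"
    else:
        gate = eff.abs() > dpsi_threshold
        eff_name = "delta_psi"
    called = (pvalues < p_threshold) & gate
    return pd.DataFrame(
        {"p": pvalues, eff_name: eff, "called": called}, index=pvalues.index
    )


def classify_sex_bias(calls_f: pd.Series, calls_m: pd.Series) -> pd.Series:
    """Label age-associated features by sex specificity.

    ``female_specific`` / ``male_specific`` for features significant in
    exactly one sex (the sBASE set for splice events), ``common`` for
    both, ``none`` otherwise.  The three non-trivial labels partition
    the age-associated set.
    """
    lab = pd.Series("none", index=calls_f.index)
    lab[calls_f & ~calls_m] = "female_specific"
    lab[~calls_f & calls_m] = "male_specific"
    lab[calls_f & calls_m] = "common"
    return lab


def permutation_fdr(
    values: pd.DataFrame,
    raw: pd.DataFrame,
    samples: pd.DataFrame,
    datatype: str,
    coefficient: str = "beta_age",
    svs: SurrogateVariableSet = None,
    contrast: str = "age",
    n_perm: int = 1000,
    seed: int = 0,
    **call_kw,
) -> dict:
    """Permutation audit of the differential calls.

    Sex and age labels are shuffled jointly (one donor-label
    permutation per iteration), the interaction model refit and calls
    re-made at the original thresholds.  Returns per-feature FDR (the
    fraction of permutations in which the feature is called) and the
    per-iteration fraction of original calls re-identified.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    fit = fit_interaction_model(values, samples, svs)
    orig = call_differential(
        fit[f"p_{coefficient}"], raw, samples, datatype, contrast, **call_kw
    )
    orig_set = set(orig.index[orig["called"]])
    counts = pd.Series(0, index=values.index, dtype=float)
    overlaps = np.empty(n_perm)
    sv = svs.sv if isinstance(svs, SurrogateVariableSet) else svs
    for b in range(n_perm):
        perm = rng.permutation(len(samples))
        shuffled = samples.copy()
        shuffled[["sex", "age"]] = samples[["sex", "age"]].to_numpy()[perm]
        pfit = fit_interaction_model(values, shuffled, sv)
        pcall = call_differential(
            pfit[f"p_{coefficient}"], raw, shuffled, datatype, contrast, **call_kw
        )
        hits = pcall["called"]
        counts[hits[hits].index] += 1
        overlaps[b] = (
            len(orig_set & set(hits[hits].index)) / len(orig_set) if orig_set else 0.0
        )
    return {
        "fdr": counts / n_perm,
        "iteration_overlap": overlaps,
        "original_calls": orig,
    }


def overlap_significance(set_a, set_b, universe) -> float:
    """Hypergeometric upper-tail p for the overlap of two feature sets."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(set_a) & universe, set(set_b) & universe
    k = len(a & b)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(a), len(b)))


def effect_size_correlation(stratified: pd.DataFrame) -> dict:
    """Spearman correlation between female and male age coefficients."""
    sub = stratified[["beta_F", "beta_M"]].dropna()
    if len(sub) < 5:
        warnings.warn("fewer than 5 paired coefficients; correlation undefined")
        return {"rho": np.nan, "p": np.nan, "n": len(sub)}
    rho, p = stats.spearmanr(sub["beta_F"], sub["beta_M"])
    return {"rho": float(rho), "p": float(p), "n": len(sub)}


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> dict:
    """Fisher z comparison of two independent correlation coefficients."""
    z, p = fisher_z_compare(r1, n1, r2, n2)
    return {"z": z, "p": p}


def sample_size_bias_model(table: pd.DataFrame) -> pd.DataFrame:
    """Regress per-tissue differential counts on cohort size and feature count.

    ``table`` needs columns ``N`` (differential features), ``Size``
    (samples) and ``Detected`` (features surviving preprocessing), one
    row per tissue.  Constant predictors are dropped with a warning.
    """
    if len(table) < 4:
        raise ValueError("need at least 4 tissues")
    import statsmodels.api as sm

    predictors = []
    for col in ("Size", "Detected"):
        if table[col].nunique() <= 1:
            warnings.warn(f"predictor {col!r} is constant; dropped")
        else:
            predictors.append(col)
    if not predictors:
        raise ValueError("all predictors constant")
    X = sm.add_constant(table[predictors].astype(float))
    res = sm.OLS(table["N"].astype(float), X).fit()
    return pd.DataFrame({"coef": res.params, "se": res.bse, "p": res.pvalues})
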