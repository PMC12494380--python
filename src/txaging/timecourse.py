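"""Aging-rate curves and breakpoint detection.

The aging rate of a tissue is estimated per sex in four steps:

1. *Confounder correction* — surrogate-variable contributions are
   subtracted from each feature (sex and age effects are preserved) and
   samples sharing (sex, age in whole years) are averaged into per-age
   trajectories.
2. *Chronological features* — per-age trajectories are screened with
   ARIMA model selection (exhaustive AIC minimization over a bounded
   non-seasonal (p, d, q) grid); a feature is chronological when its
   best model is integrated (d >= 1) and carries at least one AR or MA
   term with non-zero coefficient mass.
3. *Sliding-window MANOVA* — at each age ``i`` and window span ``w`` in
   5..15 years, samples aged in (i-w, i] are compared with (i, i+w] by
   a two-group MANOVA (Pillai trace) on the top-3 PC scores of the
   chronological-feature submatrix (PCA fit once per stratum so per-age
   statistics share a basis).  Per-span -log10 p series are LOESS
   smoothed at bandwidths 0.25..0.75 (step 0.05), averaged, re-smoothed
   at bandwidth 0.5, and finally averaged across spans.
4. *Breakpoints* — the global maximum of the rate curve is always a
   breakpoint; an additional local maximum qualifies when its height
   above the nearest local minimum exceeds 10% of the global maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from txaging._stats import two_group_pillai, vectorized_ols
from txaging.differential import SurrogateVariableSet, _design_matrix


@dataclass
class ChronologicalSet:
    """ARIMA screening outcome: membership plus per-feature model record."""

    members: list
    models: pd.DataFrame  # feature x (p, d, q, aic, coef_sum, selected)
    fitted: pd.DataFrame = None  # in-sample fitted trajectories of members


@dataclass
class RateCurve:
    ages: np.ndarray
    rate: np.ndarray  # mean -log10 p after the two-stage LOESS integration
    window_spans: tuple = (5, 15)
    per_span: dict = field(default_factory=dict)
    raw: pd.Series = None  # span-averaged -log10 p before any smoothing

    def as_series(self) -> pd.Series:
        return pd.Series(self.rate, index=self.ages)


@dataclass
class BreakpointSet:
    breakpoints: list  # (age, kind, rate) with kind in {global_max, local_max}

    @property
    def ages(self) -> list:
        return [b[0] for b in self.breakpoints]

    @property
    def major(self):
        """The breakpoint with the largest rate (the global maximum)."""
        return self.breakpoints[0] if self.breakpoints else None


def correct_confounders_and_average(
    values: pd.DataFrame,
    samples: pd.DataFrame,
    svs: SurrogateVariableSet = None,
) -> tuple:
    """Remove SV contributions, then average samples per (sex, age).

    Returns ``(corrected, trajectories)`` where ``corrected`` is the
    feature x sample matrix with surrogate-variable effects subtracted
    (sex/age structure untouched) and ``trajectories`` maps each sex to
    a features x ages matrix of per-age means (whole years, sorted).
    """
    sv = svs.sv if isinstance(svs, SurrogateVariableSet) else svs
    Y = values.to_numpy(float)
    if sv is not None and sv.shape[1] > 0:
        X, names = _design_matrix(samples, sv, interaction=True)
        fit = vectorized_ols(Y, X)
        sv_cols = [j for j, n in enumerate(names) if n.startswith("SV")]
        Y = Y - fit["beta"][:, sv_cols] @ X[:, sv_cols].T
    corrected = pd.DataFrame(Y, index=values.index, columns=values.columns)
    trajectories = {}
    for sex in ("F", "M"):
        meta = samples[samples["sex"] == sex]
        if meta.empty:
            continue
        ages = sorted(meta["age"].astype(int).unique())
        cols = {
            a: corrected[list(meta.index[meta["age"].astype(int) == a])].mean(axis=1)
            for a in ages
        }
        trajectories[sex] = pd.DataFrame(cols)
    return corrected, trajectories


def _arima_grid_search(y: np.ndarray, max_p=2, max_d=2, max_q=2):
    """Best (p, d, q) by AIC over the bounded non-seasonal grid."""
    from statsmodels.tsa.arima.model import ARIMA

    best = None
    for d in range(max_d + 1):
        for p in range(max_p + 1):
            for q in range(max_q + 1):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = ARIMA(
                            y, order=(p, d, q), trend="c" if d == 0 else "n"
                        ).fit(method_kwargs={"maxiter": 50})
                    aic = res.aic
                except Exception:
                    continue
                if np.isnan(aic):
                    continue
                if best is None or aic < best[0]:
                    coef_sum = float(
                        np.abs(res.arparams).sum() + np.abs(res.maparams).sum()
                    )
                    fitted = np.asarray(res.fittedvalues)
                    best = (aic, (p, d, q), coef_sum, fitted)
    return best


def select_chronological_features(
    trajectories: pd.DataFrame,
    max_p: int = 2,
    max_d: int = 2,
    max_q: int = 2,
    min_length: int = 20,
) -> ChronologicalSet:
    """ARIMA screen of per-age trajectories (features x ages).

    A feature is retained when its AIC-best model has d >= 1 and the sum
    of absolute AR and MA coefficients is positive.  Constant
    trajectories are excluded, not errors.
    """
    if trajectories.shape[1] < min_length:
        raise ValueError(f"trajectories must cover >= {min_length} age points")
    records, members, fitted_rows = [], [], {}
    for feat in trajectories.index:
        y = trajectories.loc[feat].to_numpy(float)
        if np.ptp(y) == 0:
            records.append((feat, -1, -1, -1, np.nan, 0.0, False))
            continue
        best = _arima_grid_search(y, max_p, max_d, max_q)
        if best is None:
            records.append((feat, -1, -1, -1, np.nan, 0.0, False))
            continue
        aic, (p, d, q), coef_sum, fitted = best
        selected = bool(d >= 1 and coef_sum > 0)
        records.append((feat, p, d, q, aic, coef_sum, selected))
        if selected:
            members.append(feat)
            fitted_rows[feat] = fitted
    models = pd.DataFrame(
        records, columns=["feature", "p", "d", "q", "aic", "coef_sum", "selected"]
    ).set_index("feature")
    fitted = (
        pd.DataFrame(fitted_rows, index=trajectories.columns).T
        if fitted_rows
        else pd.DataFrame(columns=trajectories.columns)
    )
    return ChronologicalSet(members, models, fitted)


def _loess(x: np.ndarray, y: np.ndarray, frac: float) -> np.ndarray:
    if len(x) < 3:
        return y.copy()
    frac = min(max(frac, 2.0 / len(x)), 1.0)
    return lowess(y, x, frac=frac, return_sorted=False)


def compute_rate_curve(
    values: pd.DataFrame,
    ages: pd.Series,
    chronological: list,
    w_min: int = 5,
    w_max: int = 15,
    n_pcs: int = 3,
    bandwidths: np.ndarray = None,
    final_bandwidth: float = 0.5,
    min_per_window: int = 3,
) -> RateCurve:
    """Sliding-window MANOVA aging-rate curve on one (sex, tissue) stratum.

    ``values`` is the confounder-corrected feature x sample matrix for
    the stratum, ``ages`` the per-sample ages.  The final rate at each
    age is the mean of the per-span smoothed -log10 p series.
    """
    if len(chronological) < n_pcs:
        raise ValueError(f"need >= {n_pcs} chronological features for {n_pcs} PCs")
    if bandwidths is None:
        bandwidths = np.arange(0.25, 0.751, 0.05)
    sub = values.loc[list(chronological)].to_numpy(float).T  # samples x features
    sub = sub - sub.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(sub, full_matrices=False)
    scores = u[:, :n_pcs] * s[:n_pcs]
    age_arr = np.asarray(ages, float)
    grid = np.arange(int(np.floor(age_arr.min())), int(np.ceil(age_arr.max())) + 1)

    per_span = {}
    per_span_raw = {}
    for w in range(w_min, w_max + 1):
        pts_age, pts_nlp = [], []
        for i in grid:
            left = (age_arr > i - w) & (age_arr <= i)
            right = (age_arr > i) & (age_arr <= i + w)
            if left.sum() < min_per_window or right.sum() < min_per_window:
                continue
            _, _, p = two_group_pillai(scores[left], scores[right])
            pts_age.append(i)
            pts_nlp.append(-np.log10(max(p, 1e-300)))
        if len(pts_age) < 3:
            continue
        x = np.asarray(pts_age, float)
        y = np.asarray(pts_nlp, float)
        per_span_raw[w] = pd.Series(y, index=x.astype(int))
        smoothed = np.mean([_loess(x, y, bw) for bw in bandwidths], axis=0)
        smoothed = _loess(x, smoothed, final_bandwidth)
        per_span[w] = pd.Series(smoothed, index=x.astype(int))
    if not per_span:
        raise ValueError("no age point has populated flanking windows")
    combined = pd.DataFrame(per_span).mean(axis=1, skipna=True)
    combined = combined.clip(lower=0.0)
    raw = pd.DataFrame(per_span_raw).mean(axis=1, skipna=True)
    return RateCurve(
        ages=combined.index.to_numpy(),
        rate=combined.to_numpy(),
        window_spans=(w_min, w_max),
        per_span=per_span,
        raw=raw,
    )


def _local_extrema(rate: np.ndarray) -> tuple:
    """Strict interior local maxima and minima; endpoint minima appended."""
    maxima = [
        i for i in range(1, len(rate) - 1) if rate[i] > rate[i - 1] and rate[i] > rate[i + 1]
    ]
    minima = [
        i for i in range(1, len(rate) - 1) if rate[i] < rate[i - 1] and rate[i] < rate[i + 1]
    ]
    if len(rate) >= 2:
        if rate[0] < rate[1]:
            minima.append(0)
        if rate[-1] < rate[-2]:
            minima.append(len(rate) - 1)
    return maxima, sorted(minima)


def detect_breakpoints(curve: RateCurve, min_relative_drop: float = 0.10) -> BreakpointSet:
    """Qualifying maxima of the rate curve (global first, then local).

    A secondary local maximum ``m`` is reported when
    ``(rate[m] - rate[nearest local minimum]) / rate[global max]``
    exceeds ``min_relative_drop``.  Endpoints are never candidates;
    an all-flat curve yields an empty set.
    """
    rate, ages = curve.rate, curve.ages
    if len(rate) < 5:
        raise ValueError("curve too short for breakpoint detection")
    if np.ptp(rate) == 0:
        warnings.warn("rate curve is flat; no breakpoints")
        return BreakpointSet([])
    maxima, minima = _local_extrema(rate)
    if not maxima:
        warnings.warn("no interior local maximum; no breakpoints")
        return BreakpointSet([])
    peak_vals = rate[maxima]
    g = maxima[int(np.argmax(peak_vals))]  # argmax takes the earliest tie
    gmax = rate[g]
    out = [(int(ages[g]), "global_max", float(gmax))]
    for m in maxima:
        if m == g:
            continue
        if not minima:
            continue
        nearest = min(minima, key=lambda j: (abs(j - m), j))
        if (rate[m] - rate[nearest]) / gmax > min_relative_drop:
            out.append((int(ages[m]), "local_max", float(rate[m])))
    return BreakpointSet(out)


def compare_sex_rate_curves(curve_f: RateCurve, curve_m: RateCurve) -> dict:
    """Paired per-age comparison of female vs male rate curves.

    Wilcoxon signed-rank on the shared age grid (zero differences
    dropped); also reports each sex's major breakpoint.  Identical
    curves are reported as no-difference (p = 1).
    """
    sf = curve_f.as_series()
    sm = curve_m.as_series()
    shared = sf.index.intersection(sm.index)
    if len(shared) < 5:
        warnings.warn("fewer than 5 shared ages; comparison unavailable")
        return {"p": np.nan, "n_shared": int(len(shared))}
    diff = (sm.loc[shared] - sf.loc[shared]).to_numpy()
    if np.all(diff == 0):
        p, stat = 1.0, 0.0
    else:
        from scipy.stats import wilcoxon

        method = "exact" if len(diff) <= 30 else "auto"
        stat, p = wilcoxon(diff, zero_method="wilcox", method=method)
    bp_f = detect_breakpoints(curve_f)
    bp_m = detect_breakpoints(curve_m)
    return {
        "p": float(p),
        "statistic": float(stat),
        "n_shared": int(len(shared)),
        "major_breakpoint_F": bp_f.major,
        "major_breakpoint_M": bp_m.major,
        "male_minus_female_median": float(np.median(diff)),
    }
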