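"""Aging-modulated genes (AMGs) via the trimmed-resampling disturbance test.

Which chronological genes actually carry the aging-rate signal?  The
disturbance procedure removes a random 20% of the chronological set,
recomputes the aging-rate curve and asks (Wilcoxon signed-rank, paired
per age) whether the curve changed.  Over 200 such iterations, genes
whose removal is enriched among the curve-altering iterations (one-sided
Fisher exact test on the removed/kept x significant/non-significant
2x2 table, p < 0.05) are called AMGs.

Two details make the per-iteration test informative rather than
saturated, and both are deliberate design choices:

- The curves are compared on their *unsmoothed* per-age statistics
  (the span-averaged -log10 p before LOESS).  Smoothed curves differ by
  slowly varying, sign-consistent wiggles whenever any features are
  removed, and a signed-rank test — which is scale-free — then flags
  essentially every iteration.
- The comparison is restricted to the neighborhoods of the original
  curve's breakpoints (default +/- 4 years).  Removal of a
  rate-carrying gene collapses its breakpoint peak coherently, while
  removal of background genes perturbs those ages with mixed signs.

Note the identifiability limit this procedure inherits: a gene inside a
large block of redundant, equally informative features cannot alter the
curve by its sole removal (the PC-score signal-to-noise is nearly
invariant to dropping one of many interchangeable carriers), so only
non-redundant rate drivers are discoverable as AMGs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from txaging.timecourse import RateCurve, compute_rate_curve

AGE_WINDOWS = tuple((20 + 5 * i + (1 if i else 0), 25 + 5 * i) for i in range(9))
# (20, 25), (26, 30), (31, 35), ... (61, 65)


@dataclass
class DisturbanceRecord:
    iteration: int
    removed: list
    p: float
    significant: bool
    curve: RateCurve = None


def disturbance_iterations(
    values: pd.DataFrame,
    ages: pd.Series,
    chronological: list,
    n_iter: int = 200,
    trim: float = 0.20,
    seed: int = 0,
    compare: str = "breakpoint_regions",
    region_half_width: int = 4,
    keep_curves: bool = False,
    **rate_kw,
) -> tuple:
    """Trim-and-recompute iterations against the original rate curve.

    Returns ``(original_curve, records)``.  Each iteration removes
    ``floor(trim * n)`` (at least 1) random chronological features,
    recomputes the rate curve with identical settings, and tests the
    paired per-age rates against the original curve (two-sided Wilcoxon
    signed-rank, significant at p < 0.05).

    ``compare="breakpoint_regions"`` (default) pairs the unsmoothed
    per-age rates within ``region_half_width`` years of the original
    curve's breakpoints; ``compare="full_curve"`` pairs the smoothed
    curves over every shared age.
    """
    if compare not in ("breakpoint_regions", "full_curve"):
        raise ValueError("compare must be 'breakpoint_regions' or 'full_curve'")
    chronological = list(chronological)
    if len(chronological) <= 10:
        raise ValueError("chronological set must exceed 10 features")
    rng = np.random.default_rng(seed)
    original = compute_rate_curve(values, ages, chronological, **rate_kw)
    if compare == "breakpoint_regions":
        from txaging.timecourse import detect_breakpoints

        # regions come from the unsmoothed curve: heavy smoothing can merge
        # nearby rate peaks into one plateau and hide a driver's neighborhood
        raw_curve = RateCurve(
            ages=original.raw.index.to_numpy(), rate=original.raw.to_numpy()
        )
        bps = detect_breakpoints(raw_curve)
        if not bps.breakpoints:
            raise ValueError("original curve has no breakpoints to compare around")
        region = sorted(
            {
                a
                for age, _, _ in bps.breakpoints
                for a in range(age - region_half_width, age + region_half_width + 1)
                if a in original.raw.index
            }
        )
        orig_series = original.raw.loc[region]
    else:
        orig_series = original.as_series()
    n_remove = max(1, int(np.floor(trim * len(chronological))))
    records = []
    for it in range(n_iter):
        removed = list(rng.choice(chronological, size=n_remove, replace=False))
        retained = [f for f in chronological if f not in set(removed)]
        try:
            curve = compute_rate_curve(values, ages, retained, **rate_kw)
        except ValueError:
            records.append(DisturbanceRecord(it, removed, np.nan, False))
            continue
        series = curve.raw if compare == "breakpoint_regions" else curve.as_series()
        shared = orig_series.index.intersection(series.index)
        diff = (series.loc[shared] - orig_series.loc[shared]).to_numpy()
        if len(diff) < 5 or np.all(diff == 0):
            p = 1.0
        else:
            _, p = stats.wilcoxon(diff, zero_method="wilcox")
        records.append(
            DisturbanceRecord(
                it, removed, float(p), bool(p < 0.05), curve if keep_curves else None
            )
        )
    return original, records


def call_amgs(
    records: list, chronological: list, p_threshold: float = 0.05
) -> pd.DataFrame:
    """Fisher-exact enrichment of removal among curve-altering iterations.

    Per gene, the 2x2 table counts iterations by (removed vs kept) x
    (significant vs not); the one-sided alternative asks whether the
    gene's removal is over-represented in significant iterations.
    Genes never removed in any iteration are excluded with a warning.
    """
    if len(records) < 50:
        raise ValueError("need >= 50 disturbance iterations")
    sig = np.array([r.significant for r in records])
    removed_sets = [set(r.removed) for r in records]
    rows = []
    never = []
    for gene in chronological:
        in_iter = np.array([gene in s for s in removed_sets])
        if not in_iter.any():
            never.append(gene)
            continue
        a = int((in_iter & sig).sum())  # removed, significant
        b = int((in_iter & ~sig).sum())  # removed, not
        c = int((~in_iter & sig).sum())  # kept, significant
        d = int((~in_iter & ~sig).sum())  # kept, not
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((gene, a, b, c, d, float(p), bool(p < p_threshold)))
    if never:
        warnings.warn(f"{len(never)} genes never removed in any iteration; excluded")
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "removed_sig", "removed_nonsig",
            "kept_sig", "kept_nonsig", "p", "amg",
        ],
    ).set_index("gene")


def label_sex_specific_amgs(amg_f: pd.DataFrame, amg_m: pd.DataFrame) -> pd.Series:
    """female_specific / male_specific / common labels from per-sex AMG calls."""
    set_f = set(amg_f.index[amg_f["amg"]])
    set_m = set(amg_m.index[amg_m["amg"]])
    labels = {}
    for g in set_f | set_m:
        if g in set_f and g in set_m:
            labels[g] = "common"
        elif g in set_f:
            labels[g] = "female_specific"
        else:
            labels[g] = "male_specific"
    return pd.Series(labels, dtype=object)


def classify_expression_patterns(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Window-mean pattern labels of (ARIMA-fitted) age trajectories.

    Age points are grouped into nine 5-year windows (20-25, 26-30, ...,
    61-65).  A gene is ``up_at_young`` when its mean fitted level over
    ages 31-40 strictly exceeds that over 20-30, and
    ``monotone_decline`` when successive window means never increase.
    Genes whose trajectory leaves any window empty are left unlabeled.
    """
    ages = trajectories.columns.to_numpy(float)
    rows = []
    for gene in trajectories.index:
        y = trajectories.loc[gene].to_numpy(float)
        wmeans = []
        ok = True
        for lo, hi in AGE_WINDOWS:
            m = (ages >= lo) & (ages <= hi)
            if not m.any():
                ok = False
                break
            wmeans.append(float(y[m].mean()))
        if not ok:
            rows.append((gene, np.nan, np.nan, False))
            continue
        young = float(y[(ages >= 20) & (ages <= 30)].mean())
        thirties = float(y[(ages >= 31) & (ages <= 40)].mean())
        up_at_young = thirties > young
        monotone = bool(np.all(np.diff(wmeans) <= 0))
        rows.append((gene, up_at_young, monotone, True))
    return pd.DataFrame(
        rows, columns=["gene", "up_at_young", "monotone_decline", "labeled"]
    ).set_index("gene")
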