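"""Filters, imputation, region merging and scaling normalization.

The canonical preprocessing order is samples -> genes -> splice events ->
imputation (sample removal changes every per-event statistic, so it comes
first), exposed as :func:`preprocess_cohort`.

Splice events must clear seven criteria to enter the analysis: few
missing values, adequate junction-read support, non-constant and
non-degenerate PSI (range, SD, mean away from 0/1), and an expressed host
gene.  Continuous matrices are normalized per feature by centering and
dividing by the average absolute deviation from the mean, which puts TPM
and PSI on a comparable scale while staying robust to heavy tails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from txaging.data import Cohort

EVENT_RULES = (
    "missingness",  # missing fraction must be < 5%
    "junction_support",  # mean junction counts must be > 10
    "constant",  # PSI must vary across samples
    "range",  # max(PSI) - min(PSI) must be > 0.05
    "sd",  # SD(PSI) must be > 0.01
    "mean_psi",  # mean PSI must lie in [0.05, 0.95]
    "gene_tpm",  # host-gene average TPM must be > 1
)


@dataclass
class FilterReport:
    """Bookkeeping for one filtering pass."""

    axis: str  # "features" or "samples"
    retained: list
    removed: dict = field(default_factory=dict)  # id -> first failing rule

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def rule_counts(self) -> dict:
        counts: dict = {}
        for rule in self.removed.values():
            counts[rule] = counts.get(rule, 0) + 1
        return counts

    def to_dict(self) -> dict:
        return {
            "axis": self.axis,
            "n_retained": self.n_retained,
            "n_removed": self.n_removed,
            "rule_counts": self.rule_counts(),
            "retained": list(self.retained),
            "removed": dict(self.removed),
        }


@dataclass
class NormalizedMatrix:
    """Feature-wise centered matrix scaled by average absolute deviation."""

    values: pd.DataFrame
    mean: pd.Series
    avedis: pd.Series


def filter_genes(tpm: pd.DataFrame) -> tuple:
    """Drop genes whose average TPM is below 1."""
    if tpm.empty:
        raise ValueError("empty TPM matrix")
    means = tpm.mean(axis=1)
    keep = means >= 1.0  # removal rule is strict: average TPM < 1
    retained = list(tpm.index[keep])
    removed = {g: "low_expression" for g in tpm.index[~keep]}
    if not retained:
        warnings.warn("all genes fall below the average-TPM threshold")
    return retained, FilterReport("features", retained, removed)


def filter_samples_by_missingness(psi: pd.DataFrame) -> tuple:
    """Drop samples missing PSI for more than 50% of events."""
    frac = psi.isna().mean(axis=0)
    keep = frac <= 0.5  # "more than 50%" is strict
    retained = list(psi.columns[keep])
    removed = {s: "psi_missingness" for s in psi.columns[~keep]}
    return retained, FilterReport("samples", retained, removed)


def filter_splice_events(
    psi: pd.DataFrame,
    junction_counts: pd.DataFrame,
    tpm: pd.DataFrame,
    gene_map: pd.Series,
    max_missing: float = 0.05,
    min_junction: float = 10.0,
    min_range: float = 0.05,
    min_sd: float = 0.01,
    mean_band: tuple = (0.05, 0.95),
    min_gene_tpm: float = 1.0,
) -> tuple:
    """Apply the seven event-level criteria; an event is retained iff all hold.

    The report records the first failing rule (in the documented order)
    for each removed event.
    """
    missing_gene = [e for e in psi.index if e not in gene_map.index]
    if missing_gene:
        raise KeyError(f"events without a host-gene mapping: {missing_gene[:5]}")
    gene_mean_tpm = tpm.mean(axis=1)
    retained, removed = [], {}
    miss = psi.isna().mean(axis=1)
    jc_mean = junction_counts.mean(axis=1)
    for ev in psi.index:
        row = psi.loc[ev].dropna()
        sd = row.std(ddof=1) if len(row) > 1 else 0.0
        rng_ = row.max() - row.min() if len(row) else 0.0
        mean = row.mean() if len(row) else np.nan
        gene = gene_map.loc[ev]
        gtpm = gene_mean_tpm.get(gene, 0.0)
        if miss.loc[ev] >= max_missing:
            removed[ev] = "missingness"
        elif jc_mean.loc[ev] <= min_junction:
            removed[ev] = "junction_support"
        elif not sd > 0:
            removed[ev] = "constant"
        elif not rng_ > min_range:
            removed[ev] = "range"
        elif not sd > min_sd:
            removed[ev] = "sd"
        elif not (mean_band[0] <= mean <= mean_band[1]):
            removed[ev] = "mean_psi"
        elif not gtpm > min_gene_tpm:
            removed[ev] = "gene_tpm"
        else:
            retained.append(ev)
    return retained, FilterReport("features", retained, removed)


def impute_missing_psi(psi: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """kNN imputation of missing PSI entries.

    Each missing entry becomes the uniform mean of the entry in the ``k``
    nearest samples (Euclidean distance over jointly observed events).
    Observed entries are untouched; outputs are clamped to [0, 1].
    """
    if not psi.isna().to_numpy().any():
        return psi.copy()
    n_samples = psi.shape[1]
    if k >= n_samples:
        warnings.warn(f"k={k} >= {n_samples} samples; reducing to {n_samples - 1}")
        k = n_samples - 1
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    # samples are the kNN observations -> transpose to samples x events
    filled = imputer.fit_transform(psi.to_numpy(float).T).T
    filled = np.clip(filled, 0.0, 1.0)
    out = psi.copy()
    out.loc[:, :] = np.where(psi.isna().to_numpy(), filled, psi.to_numpy(float))
    return out


def merge_brain_regions(
    cohort: Cohort, region_map: dict, brain_tissues=None
) -> Cohort:
    """Collapse brain tissues into per-donor functional-region pseudo-samples.

    ``region_map`` maps each brain tissue label to one functional region.
    Each donor x region pseudo-sample carries the arithmetic mean of the
    donor's available member-region TPM/PSI/junction values.
    ``brain_tissues`` declares which tissue labels are brain (default:
    the keys of ``region_map``); a declared brain tissue missing from
    the map is an error, and non-brain samples pass through unchanged.
    """
    if brain_tissues is None:
        brain_tissues = set(region_map)
    unmapped = set(brain_tissues) & set(cohort.samples["tissue"]) - set(region_map)
    if unmapped:
        raise KeyError(f"brain tissues missing from region_map: {sorted(unmapped)}")
    is_brain = cohort.samples["tissue"].isin(set(brain_tissues))
    brain = cohort.samples[is_brain]
    rest = cohort.samples[~is_brain]

    new_rows, tpm_cols, psi_cols, jc_cols, ids = [], [], [], [], []
    for (donor, region), grp in brain.groupby(
        [brain["donor"], brain["tissue"].map(region_map)], sort=True
    ):
        sid = f"{donor}.{region}"
        ids.append(sid)
        new_rows.append((sid, donor, grp["sex"].iloc[0], grp["age"].iloc[0], region, region))
        cols = list(grp.index)
        tpm_cols.append(cohort.tpm[cols].mean(axis=1))
        psi_cols.append(cohort.psi[cols].mean(axis=1))  # NaN-aware mean
        jc_cols.append(cohort.junction_counts[cols].mean(axis=1))

    samples = pd.DataFrame(
        new_rows, columns=["sample", "donor", "sex", "age", "tissue", "region"]
    ).set_index("sample") if new_rows else brain.iloc[0:0]
    samples = pd.concat([rest, samples])
    tpm = pd.concat(
        [cohort.tpm[list(rest.index)]] + ([pd.concat(tpm_cols, axis=1, keys=ids)] if ids else []),
        axis=1,
    )
    psi = pd.concat(
        [cohort.psi[list(rest.index)]] + ([pd.concat(psi_cols, axis=1, keys=ids)] if ids else []),
        axis=1,
    )
    jc = pd.concat(
        [cohort.junction_counts[list(rest.index)]]
        + ([pd.concat(jc_cols, axis=1, keys=ids)] if ids else []),
        axis=1,
    )
    return Cohort(samples, tpm, psi, jc, cohort.features, cohort.truth)


def normalize_scaling(matrix: pd.DataFrame) -> NormalizedMatrix:
    """Center each feature and divide by its average absolute deviation.

    ``norm(y) = (y - mean(y)) / AveDis(y)`` with
    ``AveDis(y) = mean(|y - mean(y)|)`` taken across samples.  Constant
    rows have AveDis 0 and are rejected.
    """
    vals = matrix.to_numpy(float)
    mean = vals.mean(axis=1)
    dev = vals - mean[:, None]
    avedis = np.abs(dev).mean(axis=1)
    bad = np.flatnonzero(avedis == 0)
    if bad.size:
        raise ValueError(
            f"constant feature rows cannot be scaled: {list(matrix.index[bad][:5])}"
        )
    out = pd.DataFrame(dev / avedis[:, None], index=matrix.index, columns=matrix.columns)
    return NormalizedMatrix(
        out, pd.Series(mean, index=matrix.index), pd.Series(avedis, index=matrix.index)
    )


def preprocess_cohort(cohort: Cohort, knn_k: int = 10) -> tuple:
    """samples -> genes -> events -> imputation; returns (cohort, reports)."""
    keep_samples, rep_s = filter_samples_by_missingness(cohort.psi)
    sub = cohort.subset_samples(keep_samples)
    keep_genes, rep_g = filter_genes(sub.tpm)
    gene_map = sub.event_gene_map()
    events_with_genes = [e for e in sub.psi.index if gene_map.get(e) in set(keep_genes)]
    keep_events, rep_e = filter_splice_events(
        sub.psi.loc[events_with_genes],
        sub.junction_counts.loc[events_with_genes],
        sub.tpm.loc[keep_genes],
        gene_map,
    )
    rep_e.removed.update(
        {e: "gene_tpm" for e in sub.psi.index if e not in set(events_with_genes)}
    )
    psi = impute_missing_psi(sub.psi.loc[keep_events], k=knn_k)
    kept_features = cohort.features.loc[list(keep_genes) + list(keep_events)]
    out = Cohort(
        samples=sub.samples,
        tpm=sub.tpm.loc[keep_genes],
        psi=psi,
        junction_counts=sub.junction_counts.loc[keep_events],
        features=kept_features,
        truth=cohort.truth,
    )
    return out, {"samples": rep_s, "genes": rep_g, "events": rep_e}
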