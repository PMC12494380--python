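"""Principal-component signal-to-variation ratio (pcSVR).

pcSVR measures how far two groups of samples sit apart in the dominant
principal-component subspace, relative to the dispersion within each
group:

    pcSVR(X, Y) = ||mean(X) - mean(Y)||_2 / sqrt(s2_X / N_x + s2_Y / N_y)

where ``s2`` is the mean squared Euclidean distance of group members to
their group centroid (denominator N - 1).  With a single PC this reduces
to the classical two-sample signal-to-noise ratio.  Groups that differ
only by sampling noise give pcSVR near 1; intrinsic group differences
push it above 1.

Significance is assessed empirically: the observed statistic is the mean
pcSVR over repeated labeled subsamples (half the smaller group per
side), and the null distribution repeats the same-size draws ignoring
the group labels, splitting each draw randomly into two pseudo-groups.
PCA is refit on every draw so observed and null statistics face the same
estimation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from txaging.data import Cohort


@dataclass
class GroupEmbedding:
    """PC scores of two sample groups in a shared basis."""

    scores_x: np.ndarray  # N_x x n_pcs
    scores_y: np.ndarray  # N_y x n_pcs
    n_pcs: int
    variance_captured: float


@dataclass
class PcsvrResult:
    statistic: float
    mean_x: np.ndarray = None
    mean_y: np.ndarray = None
    var_x: float = np.nan
    var_y: float = np.nan
    null_values: np.ndarray = None
    empirical_p: float = np.nan
    p_resolution: float = np.nan  # 1/n_iter; a reported p of 0 means p < this
    settings: dict = field(default_factory=dict)


def _pc_scores(samples_by_features: np.ndarray, variance_cutoff: float) -> tuple:
    """Centered PCA scores of the smallest PC prefix exceeding the cutoff.

    Returns (scores, n_pcs, variance_captured).
    """
    if not 0 < variance_cutoff < 1:
        raise ValueError("variance_cutoff must lie in (0, 1)")
    x = samples_by_features - samples_by_features.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        raise ValueError("matrix has no variance; PCA undefined")
    cum = np.cumsum(var) / total
    n_pcs = int(np.searchsorted(cum, variance_cutoff) + 1)
    n_pcs = min(n_pcs, len(s))
    return u[:, :n_pcs] * s[:n_pcs], n_pcs, float(cum[n_pcs - 1])


def fit_pca_embedding(
    values: pd.DataFrame,
    groups: dict,
    variance_cutoff: float = 0.8,
) -> GroupEmbedding:
    """Embed two labeled groups into the shared dominant PC subspace.

    Parameters
    ----------
    values
        Features x samples matrix (already normalized upstream; PCA
        centers but does not rescale features).
    groups
        ``{label: [sample ids]}`` with exactly two labels.
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    (la, ids_a), (lb, ids_b) = groups.items()
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    ordered = list(ids_a) + list(ids_b)
    mat = values[ordered].to_numpy(float).T  # samples x features
    scores, n_pcs, captured = _pc_scores(mat, variance_cutoff)
    return GroupEmbedding(
        scores_x=scores[: len(ids_a)],
        scores_y=scores[len(ids_a) :],
        n_pcs=n_pcs,
        variance_captured=captured,
    )


def _pcsvr_from_scores(sx: np.ndarray, sy: np.ndarray) -> tuple:
    mx, my = sx.mean(axis=0), sy.mean(axis=0)
    nx, ny = len(sx), len(sy)
    vx = float(((sx - mx) ** 2).sum() / (nx - 1))
    vy = float(((sy - my) ** 2).sum() / (ny - 1))
    denom = np.sqrt(vx / nx + vy / ny)
    if denom == 0:
        raise ZeroDivisionError("zero within-group dispersion in both groups")
    return float(np.linalg.norm(mx - my) / denom), mx, my, vx, vy


def compute_pcsvr(embedding: GroupEmbedding) -> PcsvrResult:
    """Evaluate the pcSVR statistic on an embedded group pair."""
    stat, mx, my, vx, vy = _pcsvr_from_scores(embedding.scores_x, embedding.scores_y)
    return PcsvrResult(statistic=stat, mean_x=mx, mean_y=my, var_x=vx, var_y=vy)


def pcsvr_statistic(
    values: pd.DataFrame, groups: dict, variance_cutoff: float = 0.8
) -> float:
    """One-shot pcSVR on the full groups (PCA fit once on both together)."""
    emb = fit_pca_embedding(values, groups, variance_cutoff)
    return compute_pcsvr(emb).statistic


def empirical_pvalue(
    values: pd.DataFrame,
    groups: dict,
    scheme: str = "subsample",
    n_iter: int = 1000,
    variance_cutoff: float = 0.8,
    seed: int = 0,
    rng: np.random.Generator = None,
) -> PcsvrResult:
    """Label-free empirical p-value for the pcSVR of two groups.

    The observed statistic is the mean pcSVR over ``n_iter`` labeled
    subsamples of size ``s = floor(0.5 * min(N_x, N_y))`` per group.  The
    null repeats ``n_iter`` draws of ``2s`` samples from the pooled
    cohort — without replacement for ``scheme="subsample"``, with
    replacement for ``scheme="bootstrap"`` — split randomly into two
    pseudo-groups of ``s``.  ``empirical_p`` is the fraction of null
    values strictly greater than the observed mean.
    """
    if scheme not in ("subsample", "bootstrap"):
        raise ValueError("scheme must be 'subsample' or 'bootstrap'")
    if rng is None:
        rng = np.random.default_rng(seed)
    (la, ids_a), (lb, ids_b) = groups.items()
    na, nb = len(ids_a), len(ids_b)
    if min(na, nb) < 4:
        raise ValueError("each group needs at least 4 samples")
    s = int(0.5 * min(na, nb))
    pool = list(ids_a) + list(ids_b)
    mat = values[pool].to_numpy(float).T  # samples x features
    idx_a = np.arange(na)
    idx_b = np.arange(na, na + nb)
    n_all = na + nb

    observed = np.empty(n_iter)
    for i in range(n_iter):
        take = np.concatenate(
            [rng.choice(idx_a, s, replace=False), rng.choice(idx_b, s, replace=False)]
        )
        scores, _, _ = _pc_scores(mat[take], variance_cutoff)
        observed[i] = _pcsvr_from_scores(scores[:s], scores[s:])[0]
    obs_mean = float(observed.mean())

    null = np.empty(n_iter)
    replace = scheme == "bootstrap"
    for i in range(n_iter):
        take = rng.choice(n_all, 2 * s, replace=replace)
        scores, _, _ = _pc_scores(mat[take], variance_cutoff)
        null[i] = _pcsvr_from_scores(scores[:s], scores[s:])[0]

    p = float(np.mean(null > obs_mean))
    return PcsvrResult(
        statistic=obs_mean,
        null_values=null,
        empirical_p=p,
        p_resolution=1.0 / n_iter,
        settings={
            "scheme": scheme,
            "n_iter": n_iter,
            "subsample_size": s,
            "variance_cutoff": variance_cutoff,
        },
    )


def _contrast_groups(samples: pd.DataFrame, contrast: str, young_max=40, old_min=60):
    """Sample-id groups for the sex (F vs M) or age (young vs old) contrast."""
    if contrast == "sex":
        return {
            "F": list(samples.index[samples["sex"] == "F"]),
            "M": list(samples.index[samples["sex"] == "M"]),
        }
    if contrast == "age":
        return {
            "young": list(samples.index[samples["age"] < young_max]),
            "old": list(samples.index[samples["age"] > old_min]),
        }
    raise ValueError("contrast must be 'sex' or 'age'")


def pcsvr_screen(
    cohort: Cohort,
    contrast: str,
    datatypes: tuple = ("GE", "AS"),
    exclude_sex_chromosomes: bool = False,
    variance_cutoff: float = 0.8,
    scheme: str = "subsample",
    n_iter: int = 1000,
    p_cutoff: float = 0.1,
    min_group: int = 4,
    sex_filter: str = None,
    log_tpm: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """pcSVR with empirical p per tissue x datatype.

    ``contrast="age"`` compares young (age < 40) vs old (age > 60)
    donors, the middle band excluded.  ``sex_filter`` restricts the age
    contrast to one sex (per-sex age effects).  Strata with fewer than
    ``min_group`` samples in either group are flagged skipped.
    """
    rng = np.random.default_rng(seed)
    drop = set(cohort.sex_chromosome_features()) if exclude_sex_chromosomes else set()
    rows = []
    for tissue, meta in cohort.samples.groupby("tissue", sort=True):
        if sex_filter is not None:
            meta = meta[meta["sex"] == sex_filter]
        groups = _contrast_groups(meta, contrast)
        sizes = {k: len(v) for k, v in groups.items()}
        for dt in datatypes:
            if dt == "GE":
                mat = cohort.tpm[list(meta.index)]
                mat = np.log2(mat + 1.0) if log_tpm else mat
            else:
                mat = cohort.psi[list(meta.index)]
            if drop:
                mat = mat.loc[[f for f in mat.index if f not in drop]]
            row = {
                "tissue": tissue,
                "datatype": dt,
                "contrast": contrast,
                "chromosomes": "autosomal" if exclude_sex_chromosomes else "all",
                **{f"n_{k}": v for k, v in sizes.items()},
            }
            if min(sizes.values()) < min_group:
                row.update(
                    pcsvr=np.nan, p=np.nan, significant=False, skipped="group_too_small"
                )
            else:
                res = empirical_pvalue(
                    mat, groups, scheme=scheme, n_iter=n_iter,
                    variance_cutoff=variance_cutoff, rng=rng,
                )
                row.update(
                    pcsvr=res.statistic,
                    p=res.empirical_p,
                    significant=res.empirical_p < p_cutoff,
                    skipped="",
                )
            rows.append(row)
    return pd.DataFrame(rows)
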