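"""Splicing-factor regulatory networks from three lines of evidence.

An edge from a splicing factor (SF) to a splice event is accepted only
when all three independent criteria pass:

1. *Correlation* — Spearman correlation between SF expression (TPM) and
   event PSI across the aging cohort, p < 0.05, computed per sex.
2. *Knockdown* — the event's PSI responds to shRNA depletion of the SF
   (per-event regression of PSI on the Control/shRNA arm indicator,
   coefficient significantly non-zero).
3. *Motif* — an SF binding-score profile over the +/- 300 nt flanks of
   the event's alternative splice sites (40-nt window, 1-nt step) shows
   a localized signal: overall maximum score > 1 and a rank-sum test
   between the highest- and lowest-scoring 20-window bins at p < 0.05.

The conjunction keeps only links supported by observational,
perturbational and sequence evidence simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from txaging._stats import vectorized_ols


@dataclass
class MotifEvidence:
    sf: str
    event: str
    max_score: float
    p: float
    passed: bool


def correlate_sf_events(
    sf_tpm: pd.DataFrame,
    event_psi: pd.DataFrame,
    min_samples: int = 5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of each SF's TPM with each event's PSI.

    Both matrices are features x samples over the same (sex-stratified)
    sample set.  Pairs in strata below ``min_samples`` or with constant
    SF expression are skipped.
    """
    common = [c for c in sf_tpm.columns if c in set(event_psi.columns)]
    rows = []
    for sf in sf_tpm.index:
        x = sf_tpm.loc[sf, common].to_numpy(float)
        for ev in event_psi.index:
            y = event_psi.loc[ev, common].to_numpy(float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < min_samples or np.ptp(x[ok]) == 0:
                rows.append((sf, ev, np.nan, np.nan, False, True))
                continue
            rho, p = stats.spearmanr(x[ok], y[ok])
            rows.append((sf, ev, rho, p, bool(p < p_threshold), False))
    return pd.DataFrame(
        rows, columns=["sf", "event", "rho", "p", "passed", "skipped"]
    )


def knockdown_differential(
    tables: pd.DataFrame, p_threshold: float = 0.05
) -> pd.DataFrame:
    """Control-vs-shRNA regression per (SF, event).

    ``tables`` is the long knockdown format (columns ``sf, event, arm,
    replicate, psi``).  PSI is regressed on an shRNA indicator; the
    group coefficient ``beta_g`` and its two-sided p-value are reported.
    """
    rows = []
    for (sf, ev), grp in tables.groupby(["sf", "event"], sort=True):
        arms = set(grp["arm"])
        if arms != {"Control", "shRNA"}:
            raise ValueError(f"({sf}, {ev}): need both Control and shRNA arms")
        if (grp["arm"].value_counts() < 2).any():
            raise ValueError(f"({sf}, {ev}): need >= 2 replicates per arm")
        g = (grp["arm"] == "shRNA").to_numpy(float)
        X = np.column_stack([np.ones(len(g)), g])
        fit = vectorized_ols(grp["psi"].to_numpy(float)[None, :], X)
        beta, p = float(fit["beta"][0, 1]), float(fit["p"][0, 1])
        rows.append((sf, ev, beta, p, bool(p < p_threshold), int(len(g))))
    return pd.DataFrame(
        rows, columns=["sf", "event", "beta_g", "p", "passed", "n"]
    )


def motif_binding_evidence(
    profile: np.ndarray,
    sf: str = "",
    event: str = "",
    bin_width: int = 20,
    max_score_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> MotifEvidence:
    """Localized-binding test on one sliding-window score profile.

    Scores are cut into consecutive bins of ``bin_width`` windows (a
    trailing partial bin is dropped); the bins with the highest and
    lowest mean scores are compared by a two-sided Wilcoxon rank-sum
    test.  The evidence passes iff the overall maximum score exceeds
    ``max_score_threshold`` and the test p-value is below
    ``p_threshold``.
    """
    profile = np.asarray(profile, float)
    n_bins = len(profile) // bin_width
    if n_bins < 2:
        raise ValueError("profile shorter than two bins")
    bins = profile[: n_bins * bin_width].reshape(n_bins, bin_width)
    means = bins.mean(axis=1)
    hi, lo = bins[int(np.argmax(means))], bins[int(np.argmin(means))]
    res = stats.mannwhitneyu(hi, lo, alternative="two-sided", method="auto")
    max_score = float(profile.max())
    passed = bool(max_score > max_score_threshold and res.pvalue < p_threshold)
    return MotifEvidence(sf, event, max_score, float(res.pvalue), passed)


def motif_evidence_table(profiles: dict, **kw) -> pd.DataFrame:
    """Apply :func:`motif_binding_evidence` to a ``{(sf, event): profile}`` dict."""
    rows = []
    for (sf, ev), prof in profiles.items():
        e = motif_binding_evidence(prof, sf, ev, **kw)
        rows.append((sf, ev, e.max_score, e.p, e.passed))
    return pd.DataFrame(rows, columns=["sf", "event", "max_score", "p", "passed"])


def build_network(
    correlations: pd.DataFrame,
    knockdown: pd.DataFrame,
    motif: pd.DataFrame,
    sf_set=None,
    event_set=None,
    sex: str = "",
) -> pd.DataFrame:
    """Intersect the three evidence tables into regulatory edges.

    ``sf_set``/``event_set`` restrict the candidate space (age-associated
    SFs annotated as splicing-related, and sBASEs, in the full
    pipeline).  An edge exists iff the pair passes all three criteria.
    """
    def _key(df):
        return df.set_index(["sf", "event"])

    corr, kd, mot = _key(correlations), _key(knockdown), _key(motif)
    pairs = corr.index
    missing_kd = pairs.difference(kd.index)
    missing_mot = pairs.difference(mot.index)
    if len(missing_kd) or len(missing_mot):
        offenders = list(missing_kd[:5]) + list(missing_mot[:5])
        raise KeyError(f"evidence tables disagree on pairs, e.g. {offenders}")
    rows = []
    for sf, ev in pairs:
        if sf_set is not None and sf not in set(sf_set):
            continue
        if event_set is not None and ev not in set(event_set):
            continue
        c, k, m = corr.loc[(sf, ev)], kd.loc[(sf, ev)], mot.loc[(sf, ev)]
        if bool(c["passed"]) and bool(k["passed"]) and bool(m["passed"]):
            rows.append(
                {
                    "sf": sf,
                    "event": ev,
                    "sex": sex,
                    "rho": c["rho"],
                    "p_corr": c["p"],
                    "beta_g": k["beta_g"],
                    "p_kd": k["p"],
                    "motif_max_score": m["max_score"],
                    "p_motif": m["p"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sf", "event", "sex", "rho", "p_corr",
            "beta_g", "p_kd", "motif_max_score", "p_motif",
        ],
    )


def to_graphml(edges: pd.DataFrame, path) -> None:
    """Export an edge table as GraphML (SF and event nodes typed)."""
    import networkx as nx

    g = nx.DiGraph()
    for _, row in edges.iterrows():
        g.add_node(row["sf"], kind="sf")
        g.add_node(row["event"], kind="event")
        g.add_edge(row["sf"], row["event"], rho=float(row["rho"]), sex=str(row["sex"]))
    nx.write_graphml(g, path)
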