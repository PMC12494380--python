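"""Synthetic cohorts with planted, recoverable structure.

Every downstream stage of the pipeline is exercised against cohorts from
this module, where the ground truth is known exactly: which genes carry a
sex shift, an age slope, an age-by-sex interaction or a non-linear
trajectory with a known breakpoint age; which splicing factor drives
which splice events; which latent batch factors contaminate the data.

Generation model
----------------
Expression is simulated on the log-TPM scale and splicing on the
logit-PSI scale, each as

    link(value)_ij = baseline_i + planted_ij + batch_ij + noise_ij

then back-transformed, which keeps TPM positive and PSI inside [0, 1]
without clipping.  Planted magnitudes are specified in within-group SD
units for expression and in delta-PSI units for splicing; on the logit
scale a delta-PSI of ``m`` at baseline ``p0`` is applied as
``m / (p0 * (1 - p0))``, the first-order inverse of the logistic slope.

Magnitude semantics per effect kind:

- ``sex_shift``      — male-minus-female shift.
- ``age_slope``      — total change across the cohort age span
                       (per-year slope = magnitude / span).
- ``interaction``    — difference in total age change between the sexes
                       (carried by the sex named in ``sex_specificity``).
- ``breakpoint_trajectory`` — flat until ``breakpoint_age``, then a
                       linear ramp reaching ``magnitude`` at the oldest age.
- ``sf_regulation``  — target-event logit-PSI coupled to the standardized
                       expression of the ``regulator`` gene with weight
                       ``magnitude`` (delta-PSI per SD of regulator).

Latent batch factors load on a random 30% of features.  Missing PSI
entries are assigned completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from txaging.data import EVENT_TYPES, Cohort

_KINDS = {"sex_shift", "age_slope", "interaction", "breakpoint_trajectory", "sf_regulation"}
_SEX_SPEC = {"female_only", "male_only", "both"}


class ConfigurationError(ValueError):
    """Raised for invalid cohort/effect configurations."""


@dataclass
class PlantedEffect:
    """One block of features carrying a known effect.

    ``target_features`` may be explicit ids or an integer count, in which
    case the generator assigns ids (disjoint from other blocks) and
    records them in the realized truth.
    """

    kind: str
    magnitude: float
    target_features: object = None  # ids, or an int count to auto-assign
    breakpoint_age: Optional[float] = None
    sex_specificity: str = "both"
    regulator: Optional[str] = None  # sf_regulation only; auto-assigned if None
    datatype: str = "tpm"  # "tpm" (genes) or "psi" (events)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(f"unknown effect kind {self.kind!r}")
        if self.sex_specificity not in _SEX_SPEC:
            raise ConfigurationError(f"unknown sex_specificity {self.sex_specificity!r}")
        if not np.isfinite(self.magnitude):
            raise ConfigurationError("effect magnitude must be finite")
        if self.kind == "breakpoint_trajectory" and self.breakpoint_age is None:
            raise ConfigurationError("breakpoint_trajectory requires breakpoint_age")
        if self.kind == "sf_regulation":
            self.datatype = "psi"


@dataclass
class CohortConfig:
    """Study-design knobs for :func:`generate_cohort`."""

    n_donors: int = 200
    sex_ratio: float = 0.5  # fraction of female donors
    age_range: tuple = (20, 79)
    tissues: Sequence[str] = ("tissueA",)
    n_genes: int = 300
    n_events: int = 300
    effect_blocks: Sequence[PlantedEffect] = field(default_factory=list)
    n_latent_factors: int = 0
    missing_psi_rate: float = 0.0
    seed: int = 0
    # noise/baseline knobs (stand-ins where the data source is silent)
    log_tpm_baseline: tuple = (2.0, 1.0)  # mean, sd of per-gene baseline
    expr_noise_sd: tuple = (0.3, 0.6)  # per-gene SD drawn uniformly
    psi_noise_sd: tuple = (0.25, 0.45)  # per-event logit-scale SD
    latent_sd: float = 0.4  # loading scale of batch factors
    latent_feature_fraction: float = 0.3
    sex_chrom_fraction: float = 0.05  # genes placed on chrX/chrY

    def __post_init__(self) -> None:
        if self.n_donors < 4:
            raise ConfigurationError("n_donors must be >= 4")
        lo, hi = self.age_range
        if not (20 <= lo < hi <= 79):
            raise ConfigurationError("age_range must lie within [20, 79]")
        for frac in (self.sex_ratio, self.missing_psi_rate):
            if not 0 <= frac <= 1:
                raise ConfigurationError("rates must lie in [0, 1]")
        if self.n_genes < 1 or self.n_events < 1:
            raise ConfigurationError("need at least one gene and one event")
        for eff in self.effect_blocks:
            if eff.kind == "breakpoint_trajectory" and not (
                lo <= eff.breakpoint_age <= hi
            ):
                raise ConfigurationError("breakpoint_age outside age_range")


def _sex_mask(sexes: np.ndarray, spec: str) -> np.ndarray:
    if spec == "female_only":
        return sexes == "F"
    if spec == "male_only":
        return sexes == "M"
    return np.ones(sexes.shape, bool)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Simulate a cohort realizing ``config.effect_blocks``.

    Deterministic for a fixed config (seed included).  The returned
    cohort's ``truth`` lists each effect with its resolved target ids.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    span = hi - lo

    # --- donors ---------------------------------------------------------
    n = config.n_donors
    donors = [f"D{i:04d}" for i in range(n)]
    n_female = int(round(config.sex_ratio * n))
    sexes_donor = np.array(["F"] * n_female + ["M"] * (n - n_female))
    rng.shuffle(sexes_donor)
    ages_donor = rng.integers(lo, hi + 1, size=n)

    sample_rows = []
    for t in config.tissues:
        for d, s, a in zip(donors, sexes_donor, ages_donor):
            sample_rows.append((f"{d}.{t}", d, s, int(a), t, ""))
    samples = pd.DataFrame(
        sample_rows, columns=["sample", "donor", "sex", "age", "tissue", "region"]
    ).set_index("sample")
    m = len(samples)
    sexes = samples["sex"].to_numpy()
    ages = samples["age"].to_numpy(float)

    # --- features -------------------------------------------------------
    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    event_ids = [f"E{i:04d}" for i in range(config.n_events)]
    n_sex_chrom = int(round(config.sex_chrom_fraction * config.n_genes))
    chroms = np.array([f"chr{c}" for c in rng.integers(1, 23, size=config.n_genes)], object)
    if n_sex_chrom:
        idx = rng.choice(config.n_genes, size=n_sex_chrom, replace=False)
        xy = rng.choice(["chrX", "chrY"], size=n_sex_chrom, p=[0.8, 0.2])
        chroms[idx] = xy
    host = rng.choice(gene_ids, size=config.n_events, replace=True)
    etype = rng.choice(EVENT_TYPES, size=config.n_events)
    starts = rng.integers(1_000, 1_000_000, size=config.n_events)
    gene_feat = pd.DataFrame(
        {
            "kind": "gene",
            "gene": gene_ids,
            "chromosome": chroms,
            "event_type": "",
            "start": -1,
            "end": -1,
        },
        index=pd.Index(gene_ids, name="feature"),
    )
    gene_chrom = dict(zip(gene_ids, chroms))
    event_feat = pd.DataFrame(
        {
            "kind": "event",
            "gene": host,
            "chromosome": [gene_chrom[g] for g in host],
            "event_type": etype,
            "start": starts,
            "end": starts + rng.integers(50, 300, size=config.n_events),
        },
        index=pd.Index(event_ids, name="feature"),
    )
    features = pd.concat([gene_feat, event_feat])

    # --- baselines ------------------------------------------------------
    mu0, sd0 = config.log_tpm_baseline
    gene_base = rng.normal(mu0, sd0, size=config.n_genes)
    gene_sd = rng.uniform(*config.expr_noise_sd, size=config.n_genes)
    psi_base_p = rng.uniform(0.15, 0.85, size=config.n_events)
    psi_base = logit(psi_base_p)
    psi_sd = rng.uniform(*config.psi_noise_sd, size=config.n_events)

    log_tpm = gene_base[:, None] + np.zeros((config.n_genes, m))
    logit_psi = psi_base[:, None] + np.zeros((config.n_events, m))

    # --- resolve effect targets (disjoint across auto-assigned blocks) --
    free_genes = list(gene_ids)
    free_events = list(event_ids)
    realized = []
    for eff in config.effect_blocks:
        pool = free_events if eff.datatype == "psi" else free_genes
        if isinstance(eff.target_features, (int, np.integer)):
            k = int(eff.target_features)
            if k > len(pool):
                raise ConfigurationError("not enough free features for effect block")
            chosen = list(rng.choice(pool, size=k, replace=False))
            for c in chosen:
                pool.remove(c)
        elif eff.target_features is None:
            raise ConfigurationError("effect block has an empty target set")
        else:
            chosen = list(eff.target_features)
            if not chosen:
                raise ConfigurationError("effect block has an empty target set")
        regulator = eff.regulator
        if eff.kind == "sf_regulation" and regulator is None:
            regulator = free_genes[0] if free_genes else gene_ids[0]
            if regulator in free_genes:
                free_genes.remove(regulator)
        realized.append(
            {
                "kind": eff.kind,
                "magnitude": float(eff.magnitude),
                "target_features": chosen,
                "breakpoint_age": eff.breakpoint_age,
                "sex_specificity": eff.sex_specificity,
                "regulator": regulator,
                "datatype": eff.datatype,
            }
        )

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    event_pos = {e: i for i, e in enumerate(event_ids)}

    def _scale(rec, i):
        """Planted-unit -> link-scale conversion for feature i."""
        if rec["datatype"] == "psi":
            p0 = psi_base_p[i]
            return 1.0 / (p0 * (1.0 - p0))
        return gene_sd[i]

    for rec in realized:
        pos = gene_pos if rec["datatype"] == "tpm" else event_pos
        mat = log_tpm if rec["datatype"] == "tpm" else logit_psi
        mask = _sex_mask(sexes, rec["sex_specificity"])
        mag = rec["magnitude"]
        for fid in rec["target_features"]:
            i = pos[fid]
            s = _scale(rec, i)
            if rec["kind"] == "sex_shift":
                mat[i, sexes == "M"] += mag * s
            elif rec["kind"] == "age_slope":
                mat[i, mask] += mag * s * (ages[mask] - lo) / span
            elif rec["kind"] == "interaction":
                mat[i, mask] += mag * s * (ages[mask] - lo) / span
            elif rec["kind"] == "breakpoint_trajectory":
                bp = rec["breakpoint_age"]
                ramp = np.clip(ages - bp, 0, None) / max(hi - bp, 1.0)
                mat[i, mask] += mag * s * ramp[mask]
            # sf_regulation applied after noise (couples to realized SF level)

    # --- latent batch factors ------------------------------------------
    n_feat = config.n_genes + config.n_events
    latent_loadings = None
    factor_values = None
    if config.n_latent_factors > 0:
        factor_values = rng.normal(size=(config.n_latent_factors, m))
        latent_loadings = np.zeros((config.n_latent_factors, n_feat))
        n_loaded = max(1, int(round(config.latent_feature_fraction * n_feat)))
        for f in range(config.n_latent_factors):
            idx = rng.choice(n_feat, size=n_loaded, replace=False)
            latent_loadings[f, idx] = rng.normal(0, config.latent_sd, size=n_loaded)
        batch = latent_loadings.T @ factor_values  # features x samples
        log_tpm += batch[: config.n_genes] * gene_sd[:, None]
        logit_psi += batch[config.n_genes :] * psi_sd[:, None]

    # --- noise ----------------------------------------------------------
    log_tpm += rng.normal(size=log_tpm.shape) * gene_sd[:, None]
    logit_psi += rng.normal(size=logit_psi.shape) * psi_sd[:, None]

    # --- SF -> event coupling on realized expression --------------------
    for rec in realized:
        if rec["kind"] != "sf_regulation":
            continue
        gi = gene_pos[rec["regulator"]]
        z = log_tpm[gi] - log_tpm[gi].mean()
        sd = z.std()
        if sd > 0:
            z = z / sd
        mask = _sex_mask(sexes, rec["sex_specificity"])
        for fid in rec["target_features"]:
            i = event_pos[fid]
            logit_psi[i, mask] += rec["magnitude"] * _scale(rec, i) * z[mask]

    tpm = pd.DataFrame(np.exp(log_tpm), index=gene_ids, columns=samples.index)
    psi_vals = expit(logit_psi)

    # --- missingness (MCAR) --------------------------------------------
    if config.missing_psi_rate > 0:
        miss = rng.random(psi_vals.shape) < config.missing_psi_rate
        psi_vals = np.where(miss, np.nan, psi_vals)
    psi = pd.DataFrame(psi_vals, index=event_ids, columns=samples.index)

    jc_mean = np.exp(rng.normal(np.log(60.0), 0.5, size=config.n_events))
    jc = pd.DataFrame(
        rng.poisson(jc_mean[:, None], size=(config.n_events, m)),
        index=event_ids,
        columns=samples.index,
    )

    return Cohort(samples, tpm, psi, jc, features, truth=realized)


def generate_driver_trajectories(
    n_features: int = 50,
    breakpoint_ages: Sequence[int] = (45, 55),
    step: float = 0.8,
    driver_noise_sd: float = 0.25,
    background_noise_sd: float = 0.06,
    ages: Sequence[int] = tuple(range(20, 80)),
    seed: int = 0,
) -> tuple:
    """Per-age trajectory matrix with a few non-redundant rate drivers.

    Emulates a chronological-gene set in which a small number of
    *driver* genes each carry a step change at their own breakpoint age
    (amplitude ``step``, per-age noise ``driver_noise_sd``) on top of a
    quiet background of ``n_features - len(breakpoint_ages)`` genes
    (noise ``background_noise_sd``).  Each driver is the sole carrier of
    its breakpoint, so its removal genuinely alters the aging-rate
    curve — the ground truth the disturbance procedure is meant to
    recover.

    Returns ``(trajectories, driver_ids)`` with trajectories a
    features x ages DataFrame.
    """
    n_drivers = len(breakpoint_ages)
    if n_drivers >= n_features:
        raise ValueError("need more features than drivers")
    rng = np.random.default_rng(seed)
    age_arr = np.asarray(list(ages), float)
    names = [f"g{i:03d}" for i in range(n_features)]
    Y = np.vstack(
        [
            rng.normal(size=(n_drivers, len(age_arr))) * driver_noise_sd,
            rng.normal(size=(n_features - n_drivers, len(age_arr)))
            * background_noise_sd,
        ]
    )
    for j, bp in enumerate(breakpoint_ages):
        Y[j] += (age_arr > bp) * step
    traj = pd.DataFrame(Y, index=names, columns=age_arr.astype(int))
    return traj, names[:n_drivers]


def generate_knockdown_experiment(
    sf_ids: Sequence[str],
    events: Sequence[str],
    targets: Mapping[str, Sequence[str]],
    n_reps: int = 4,
    effect: float = 0.3,
    noise_sd: float = 0.01,
    baseline_psi: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate control-vs-shRNA PSI tables for splicing-factor knockdowns.

    Events listed in ``targets[sf]`` shift by ``effect`` (delta-PSI) in
    the shRNA arm; all other events differ only by replicate noise.

    Returns a long table with columns ``sf, event, arm, replicate, psi``.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 (no residual degrees of freedom)")
    unknown = set(targets) - set(sf_ids)
    if unknown:
        raise KeyError(f"unknown sf ids in targets: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    events = list(events)
    if baseline_psi is None:
        baseline_psi = dict(zip(events, rng.uniform(0.2, 0.7, size=len(events))))
    rows = []
    for sf in sf_ids:
        hit = set(targets.get(sf, ()))
        for ev in events:
            base = baseline_psi[ev]
            for arm, shift in (("Control", 0.0), ("shRNA", effect if ev in hit else 0.0)):
                vals = np.clip(base + shift + rng.normal(0, noise_sd, n_reps), 0, 1)
                rows.extend(
                    (sf, ev, arm, r + 1, v) for r, v in enumerate(vals)
                )
    return pd.DataFrame(rows, columns=["sf", "event", "arm", "replicate", "psi"])


def generate_motif_profiles(
    events: Sequence[str],
    regulators: Sequence[str],
    planted_pairs: Sequence[tuple],
    region_half_width: int = 300,
    window: int = 40,
    peak_score: float = 2.0,
    seed: int = 0,
) -> dict:
    """Per-(SF, event) sliding-window binding-score profiles.

    Each profile covers the +/- ``region_half_width`` nt flank of an
    event's alternative splice sites scanned with a ``window``-nt window
    at step 1 nt, hence ``2 * region_half_width - window + 1`` scores.
    Planted pairs carry one contiguous elevated segment whose scores
    exceed 1; all other pairs are flat low-score noise with maximum < 1.

    Returns ``{(sf, event): np.ndarray of window scores}``.
    """
    events, regulators = list(events), list(regulators)
    if set(events) & set(regulators):
        raise ValueError("event and regulator id namespaces overlap")
    n_windows = 2 * region_half_width - window + 1
    if n_windows < 40:
        raise ValueError("region too short for the binned motif test")
    rng = np.random.default_rng(seed)
    planted = {tuple(p) for p in planted_pairs}
    profiles = {}
    for sf in regulators:
        for ev in events:
            base = rng.uniform(0.02, 0.30, size=n_windows)
            if (sf, ev) in planted:
                width = min(30, n_windows // 4)
                start = rng.integers(0, n_windows - width)
                base[start : start + width] = peak_score + rng.normal(
                    0, 0.05, size=width
                )
            profiles[(sf, ev)] = base
    return profiles
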