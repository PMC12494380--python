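"""End-to-end orchestration: simulate -> preprocess -> analyses -> reports.

Glue used by the command-line interface and the smoke tests; each stage
delegates to the corresponding module and writes its tab-delimited
report into the output directory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from txaging import amg as amg_mod
from txaging import differential as diff_mod
from txaging import network as net_mod
from txaging import pcsvr as pcsvr_mod
from txaging import timecourse as tc_mod
from txaging.data import Cohort
from txaging.preprocess import normalize_scaling, preprocess_cohort
from txaging.simulate import (
    CohortConfig,
    PlantedEffect,
    generate_cohort,
    generate_knockdown_experiment,
    generate_motif_profiles,
)


def default_demo_config(seed: int = 0, n_donors: int = 240) -> CohortConfig:
    """A cohort exercising every pipeline stage with planted truth."""
    return CohortConfig(
        n_donors=n_donors,
        n_genes=200,
        n_events=300,
        effect_blocks=[
            PlantedEffect(kind="sex_shift", magnitude=1.5, target_features=20),
            PlantedEffect(kind="age_slope", magnitude=1.5, target_features=20),
            PlantedEffect(
                kind="age_slope", magnitude=0.25, target_features=15,
                sex_specificity="female_only", datatype="psi",
            ),
            PlantedEffect(
                kind="age_slope", magnitude=0.25, target_features=15,
                sex_specificity="male_only", datatype="psi",
            ),
            PlantedEffect(
                kind="breakpoint_trajectory", magnitude=2.0, target_features=25,
                breakpoint_age=50,
            ),
            PlantedEffect(kind="sf_regulation", magnitude=0.15, target_features=5),
        ],
        n_latent_factors=1,
        missing_psi_rate=0.01,
        seed=seed,
    )


def run_pipeline(cohort: Cohort, outdir, seed: int = 0, n_iter_pcsvr: int = 200,
                 n_amg_iter: int = 60, quick: bool = True) -> dict:
    """Run every analysis stage on ``cohort``, writing reports to ``outdir``.

    ``quick`` scales the heavier resampling stages down to smoke-test
    sizes; the per-stage functions accept full-size settings directly.
    Returns the in-memory results keyed by stage.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results = {}

    clean, reports = preprocess_cohort(cohort)
    (out / "filter_report.json").write_text(
        json.dumps({k: v.to_dict() for k, v in reports.items()}, indent=1)
    )
    results["preprocess"] = reports

    screen = pd.concat(
        [
            pcsvr_mod.pcsvr_screen(
                clean, contrast, n_iter=n_iter_pcsvr, seed=seed
            )
            for contrast in ("sex", "age")
        ],
        ignore_index=True,
    )
    screen.to_csv(out / "pcsvr_results.tsv", sep="\t", index=False)
    results["pcsvr"] = screen

    norm_tpm = normalize_scaling(np.log2(clean.tpm + 1.0))
    norm_psi = normalize_scaling(clean.psi)
    svs = diff_mod.estimate_surrogate_variables(norm_tpm.values, clean.samples, seed=seed)
    fit_ge = diff_mod.fit_interaction_model(norm_tpm.values, clean.samples, svs)
    fit_as = diff_mod.fit_interaction_model(norm_psi.values, clean.samples, svs)
    strat_ge = diff_mod.fit_sex_stratified_model(norm_tpm.values, clean.samples)
    strat_as = diff_mod.fit_sex_stratified_model(norm_psi.values, clean.samples)
    calls_f = diff_mod.call_differential(
        strat_as["p_F"], clean.psi, clean.samples[clean.samples.sex == "F"], "AS"
    )
    calls_m = diff_mod.call_differential(
        strat_as["p_M"], clean.psi, clean.samples[clean.samples.sex == "M"], "AS"
    )
    sbase = diff_mod.classify_sex_bias(calls_f["called"], calls_m["called"])
    fits = pd.concat({"GE": fit_ge, "AS": fit_as}, names=["datatype"])
    fits.to_csv(out / "fits.tsv", sep="\t")
    pd.concat({"GE": strat_ge, "AS": strat_as}, names=["datatype"]).to_csv(
        out / "stratified_fits.tsv", sep="\t"
    )
    sbase.rename("label").to_frame().to_csv(out / "calls.tsv", sep="\t")
    results["differential"] = {
        "fit_ge": fit_ge, "fit_as": fit_as,
        "stratified_ge": strat_ge, "stratified_as": strat_as, "sbase": sbase,
    }

    # regulatory network on planted SF targets (if any) plus decoys
    sf_truth = [t for t in clean.truth if t["kind"] == "sf_regulation"]
    if sf_truth:
        regulators = [t["regulator"] for t in sf_truth]
        sbase_events = [e for e in sbase.index if sbase[e] != "none"]
        candidate_events = sorted(
            set(sbase_events) | {e for t in sf_truth for e in t["target_features"]}
        )[:50]
        targets = {
            t["regulator"]: [e for e in t["target_features"] if e in candidate_events]
            for t in sf_truth
        }
        kd = generate_knockdown_experiment(
            regulators, candidate_events, targets, seed=seed
        )
        profiles = generate_motif_profiles(
            candidate_events, regulators,
            [(sf, e) for sf, evs in targets.items() for e in evs],
            seed=seed,
        )
        corr = net_mod.correlate_sf_events(
            clean.tpm.loc[[r for r in regulators if r in clean.tpm.index]],
            clean.psi.loc[[e for e in candidate_events if e in clean.psi.index]],
        )
        kd_fit = net_mod.knockdown_differential(kd)
        motif = net_mod.motif_evidence_table(profiles)
        pairs = set(map(tuple, corr[["sf", "event"]].to_numpy()))
        kd_fit = kd_fit[[tuple(x) in pairs for x in kd_fit[["sf", "event"]].to_numpy()]]
        motif = motif[[tuple(x) in pairs for x in motif[["sf", "event"]].to_numpy()]]
        edges = net_mod.build_network(corr, kd_fit, motif)
        edges.to_csv(out / "edges.tsv", sep="\t", index=False)
        results["network"] = edges

    corrected, trajectories = tc_mod.correct_confounders_and_average(
        norm_tpm.values, clean.samples, svs
    )
    rate_rows = []
    bp_rows = []
    amg_tables = {}
    for sex in ("F", "M"):
        meta = clean.samples[clean.samples["sex"] == sex]
        traj = trajectories.get(sex)
        if traj is None or traj.shape[1] < 20:
            continue
        max_pq = 1 if quick else 2
        chrono = tc_mod.select_chronological_features(
            traj.iloc[: (60 if quick else len(traj))], max_p=max_pq, max_q=max_pq
        )
        if len(chrono.members) < 3:
            continue
        curve = tc_mod.compute_rate_curve(
            corrected[list(meta.index)], meta["age"], chrono.members,
            w_min=5, w_max=8 if quick else 15,
        )
        bps = tc_mod.detect_breakpoints(curve)
        rate_rows.extend((sex, a, r) for a, r in zip(curve.ages, curve.rate))
        bp_rows.extend((sex, a, k, v) for a, k, v in bps.breakpoints)
        if len(chrono.members) > 10:
            _, records = amg_mod.disturbance_iterations(
                corrected[list(meta.index)], meta["age"], chrono.members,
                n_iter=n_amg_iter, seed=seed,
                w_min=5, w_max=8 if quick else 15,
            )
            amg_tables[sex] = amg_mod.call_amgs(records, chrono.members)
    pd.DataFrame(rate_rows, columns=["sex", "age", "rate"]).to_csv(
        out / "rates.tsv", sep="\t", index=False
    )
    pd.DataFrame(bp_rows, columns=["sex", "age", "kind", "rate"]).to_csv(
        out / "breakpoints.tsv", sep="\t", index=False
    )
    results["breakpoints"] = bp_rows
    if amg_tables:
        pd.concat(amg_tables, names=["sex"]).to_csv(out / "amg.tsv", sep="\t")
        results["amg"] = amg_tables
    return results
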