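"""End-to-end seeded pipeline: simulate -> fit -> profiles -> stats -> classify.

``run_pipeline`` executes the full workflow on synthetic inputs and writes
a manifest (config hash, seeds, per-output hashes) so a run can be
reproduced and verified stage by stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from cortexdti import classification, cortical_profiles, group_stats, synthetic_data, tensor_fit
from cortexdti.io import RunConfig


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on seeded synthetic data; returns the manifest.

    Stages: (1) phantom + forward-simulated DWI + tensor fit + cortical
    profiles + regional aggregation; (2) synthetic three-cohort tables +
    group statistics (MANCOVA, post-hoc family with FDR); (3) classifier
    selection, binary and multiclass evaluation.  All randomness derives
    from ``config.seed``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config),
                      "config_hash": config.digest(), "outputs": {}, "stages": []}

    # -- stage 1: phantom imaging chain -----------------------------------
    spec = synthetic_data.PhantomSpec(
        geometry=config.phantom_geometry,
        theta_deg=config.phantom_theta_deg,
        sigma_deg=config.phantom_sigma_deg,
        seed=config.seed,
    )
    ribbon, true_tensors, truth = synthetic_data.make_phantom(spec)
    bvals, bvecs = synthetic_data.make_gradient_scheme()
    snr = np.inf if config.dwi_snr <= 0 else config.dwi_snr
    dwi = synthetic_data.simulate_dwi(true_tensors, bvals, bvecs, snr=snr,
                                      seed=config.seed + 1)
    tensors = tensor_fit.fit_tensor(dwi, method="ols")
    potential = cortical_profiles.solve_ribbon_potential(ribbon, tol=config.solver_tol)
    profiles, drops = cortical_profiles.trace_profiles(
        potential, ribbon, step_h=config.step_h_mm
    )
    metrics = [
        cortical_profiles.sample_profile_metrics(p, tensors) for p in profiles
    ]
    table = cortical_profiles.aggregate_regions(metrics, ribbon.region_map)
    if config.angle_unit == "degrees":
        table["AngleR"] = np.rad2deg(table["AngleR"])
    table_path = out / "region_features.csv"
    table.to_csv(table_path)
    manifest["stages"].append({
        "name": "phantom_profiles",
        "n_profiles": len(profiles),
        "dropped": drops,
        "true_theta_deg": truth["theta_deg"],
    })
    manifest["outputs"]["region_features.csv"] = _file_hash(table_path)

    # -- stage 2: cohorts + statistics ------------------------------------
    cohorts = synthetic_data.make_cohorts(seed=config.seed + 2)
    all_subjects = pd.concat(cohorts.values(), ignore_index=True)
    cohorts_path = out / "cohorts.csv"
    all_subjects.to_csv(cohorts_path, index=False)
    manifest["outputs"]["cohorts.csv"] = _file_hash(cohorts_path)

    sel = cohorts["selection"].copy()
    sel["dx2"] = classification.binarize_diagnosis(sel["diagnosis"])
    mv, per_out = group_stats.mancova(
        sel,
        outcomes=["MD_wholebrain", "AngleR_wholebrain", "PerpPD_wholebrain",
                  "ParlPD_wholebrain", "GM_fr"],
        group="dx2",
        covariates=["age", "head_movement"],
    )
    stats_rows = [dataclasses.asdict(mv)] + [dataclasses.asdict(r) for r in per_out.values()]
    stats_path = out / "group_stats.json"
    stats_path.write_text(json.dumps(stats_rows, indent=1, default=str))
    manifest["stages"].append({"name": "group_stats",
                               "multivariate_p": mv.p})
    manifest["outputs"]["group_stats.json"] = _file_hash(stats_path)

    # -- stage 3: classification ------------------------------------------
    feature_cols = [f"AngleR_{r}" for r in
                    [c.removeprefix("AngleR_") for c in sel.columns
                     if c.startswith("AngleR_") and c != "AngleR_wholebrain"]]
    selected = classification.pca_filter(cohorts["selection"][feature_cols])
    multi_features = ["AngleR_wholebrain"] + selected
    selection = classification.select_classifier(
        cohorts["selection"], multi_features,
        n_runs=config.n_selection_runs, k_folds=config.k_folds,
        master_seed=config.seed,
    )
    counts, report = classification.train_and_evaluate(
        cohorts["training"], cohorts["test"], selection.winner,
        multi_features, seed=config.seed,
    )
    counts_path = out / "confusion_multiclass.csv"
    counts.to_csv(counts_path)
    report_path = out / "classification_report.json"
    report_path.write_text(json.dumps({
        "selection": dataclasses.asdict(selection),
        "features": multi_features,
        "multiclass_accuracy_pct": report.accuracy,
        "per_class": report.per_class,
    }, indent=1))
    manifest["stages"].append({
        "name": "classification",
        "winner": selection.winner,
        "accuracy_pct": report.accuracy,
    })
    manifest["outputs"]["confusion_multiclass.csv"] = _file_hash(counts_path)
    manifest["outputs"]["classification_report.json"] = _file_hash(report_path)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
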