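"""End-to-end orchestration: simulate -> qc -> behavior -> fit/decode ->
evaluate -> cross-predict, with a serialisable config, seed bookkeeping
and a manifest tying every output to the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, evaluation, qc, synthetic
from .containers import write_trial_table
from .decoder import run_reconstruction
from .encoding import make_cv_folds
from .synthetic import ReportMixture, TuningSpec


@dataclass
class RunConfig:
    """Fully serialisable description of a pipeline run."""

    seed: int = 0
    n_runs: int = 10
    trials_per_coherence: int = 16
    coherence_levels: dict = field(
        default_factory=lambda: dict(synthetic.DEFAULT_COHERENCES))
    report_mixtures: dict = field(default_factory=lambda: {
        k: dataclasses.asdict(v) for k, v in synthetic.DEFAULT_REPORT_MIXTURES.items()})
    lattice_radius: float = 2.0        # voxel cluster = lattice ball of this radius
    noise_sd: float = 1.0
    informative_fraction: float = 0.75
    searchlight_radius: float = 4.0
    regularizer: str = "arctan"
    labels: tuple = ("stimulus", "report")
    fit: str = "ensemble"
    gaze_rate: float = 100.0
    fixation_sd: float = 0.1
    run_qc: bool = True

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["labels"] = list(d["labels"])
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["labels"] = tuple(d.get("labels", ("stimulus", "report")))
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    def mixtures(self) -> dict:
        return {k: ReportMixture(**v) for k, v in self.report_mixtures.items()}


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage and write artifacts plus a manifest.

    Identical config and seed produce identical outputs. Returns the
    manifest dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31))
             for name, s in zip(
                 ["trials", "reports", "voxels", "betas", "gaze"], ss.spawn(5))}
    manifest: dict = {"config_hash": config.config_hash, "seeds": seeds,
                      "stages": {}}
    (outdir / "config.json").write_text(config.to_json())

    # --- simulate -----------------------------------------------------
    trials = synthetic.generate_trial_sequence(
        config.n_runs, config.trials_per_coherence, config.coherence_levels,
        seed=seeds["trials"])
    trials = synthetic.simulate_reports(trials, config.mixtures(),
                                        seed=seeds["reports"])
    coords = synthetic.ball_coords(config.lattice_radius)
    voxels = synthetic.generate_voxel_population(
        coords.shape[0], coords=coords,
        tuning_spec=TuningSpec(noise_sd=config.noise_sd,
                               informative_fraction=config.informative_fraction),
        seed=seeds["voxels"])
    betas = synthetic.simulate_betas(trials, voxels, seed=seeds["betas"])
    gaze = synthetic.simulate_gaze(trials, fixation_sd=config.fixation_sd,
                                   sampling_rate=config.gaze_rate,
                                   seed=seeds["gaze"])
    write_trial_table(trials, outdir / "events.tsv")
    betas.to_files(outdir / "betas")
    manifest["stages"]["simulate"] = {
        "n_trials": int(len(trials)), "n_voxels": int(voxels.n_voxels)}

    # --- fixation qc --------------------------------------------------
    if config.run_qc:
        report = qc.reject_trials(gaze, trials)
        trials = qc.apply_qc(trials, report)
        (outdir / "qc_report.json").write_text(json.dumps({
            "run_sd": report.run_sd, "noise_threshold": report.noise_threshold,
            "excluded_runs": report.excluded_runs,
            "rejected_trials": report.rejected_trials,
            "fraction_rejected": report.fraction_rejected}, indent=1))
        manifest["stages"]["qc"] = {
            "rejected": len(report.rejected_trials),
            "fraction_rejected": report.fraction_rejected}
    else:
        trials = trials.copy()
        trials["valid"] = np.isfinite(trials["theta_r"].to_numpy(dtype=float))

    # --- behavior -----------------------------------------------------
    full = trials[trials["coherence"] == "full"]
    screening = behavior.screen_participant(full)
    (outdir / "screening.json").write_text(json.dumps({
        "p95_deviation": screening.p95_deviation,
        "rood_rate": screening.rood_rate, "include": screening.include,
        "reasons": screening.reasons}, indent=1))
    manifest["stages"]["behavior"] = {"include": screening.include}

    per_trial = trials[["trial_id", "run", "coherence"]].copy()
    dev = behavior.circular_deviation(trials["theta_s"].fillna(0.0),
                                      trials["theta_r"].fillna(0.0))
    per_trial["fca"] = np.where(
        np.isfinite(trials["theta_r"].to_numpy(dtype=float)),
        behavior.fca(dev), np.nan)
    per_trial.to_csv(outdir / "trial_fca.csv", index=False)

    # --- encoding + decoding ------------------------------------------
    all_results = []
    model_sets = {}
    for coh in config.coherence_levels:
        for label in config.labels:
            cv = make_cv_folds(trials, coh, label)
            res, models = run_reconstruction(
                betas, trials, cv, regularizer=config.regularizer,
                fit=config.fit, seed=config.seed)
            all_results.append(res)
            model_sets[(coh, label)] = (cv, models)
    results = pd.concat(all_results, ignore_index=True)
    results.to_csv(outdir / "reconstructions.csv", index=False)
    manifest["stages"]["decode"] = {
        "model_sets": len(model_sets), "n_decoded": int(len(results))}

    # --- evaluate -----------------------------------------------------
    summary = evaluation.aggregate(results)
    summary.to_csv(outdir / "summary.csv", index=False)

    # --- cross-predict: zero-coherence report model -> full stimulus --
    cross = {}
    if ("zero", "report") in model_sets and "full" in config.coherence_levels:
        _, report_models = model_sets[("zero", "report")]
        cv_full = make_cv_folds(trials, "full", "stimulus")
        try:
            _, bfca = evaluation.cross_predict(
                betas, trials, cv_full, report_models, seed=config.seed)
            cross["report_zero_to_stimulus_full_bfca"] = bfca
        except KeyError as e:
            cross["report_zero_to_stimulus_full_bfca"] = None
            cross["error"] = str(e)
    (outdir / "cross_prediction.json").write_text(json.dumps(cross, indent=1))
    manifest["stages"]["cross_predict"] = cross

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
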