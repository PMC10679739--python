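"""Trial-wise GLM: single-trial response-amplitude estimation.

One GLM per run containing one boxcar-convolved regressor per trial (a
"least-squares-all" model), six head-motion nuisance regressors and an
intercept. Per-voxel ordinary least squares yields the trials x voxels
amplitude matrix consumed by the encoding stage. When amplitudes are
supplied directly (e.g. by the synthetic generator) this stage is a
pass-through.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BetaMatrix
from .synthetic import STIMULUS_S

N_NUISANCE = 6


@dataclass
class DesignMatrix:
    """Per-run design: trial regressors, nuisance columns, intercept."""

    X: np.ndarray                 # (n_scans, n_trials + 6 + 1)
    column_labels: list[str]
    frame_times: np.ndarray
    trial_ids: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.trial_ids.size


def build_design_matrix(trials_run: pd.DataFrame, tr: float, n_scans: int,
                        nuisance: np.ndarray | None = None,
                        hrf: str = "spm") -> DesignMatrix:
    """Build the trial-wise design for one run.

    Each trial contributes a 2 s boxcar at its stimulus onset convolved
    with the canonical hemodynamic response and sampled at scan times.
    """
    from nilearn.glm.first_level import compute_regressor

    frame_times = np.arange(n_scans) * tr
    onsets = trials_run["onset"].to_numpy(dtype=float)
    if np.any(onsets + STIMULUS_S > n_scans * tr):
        bad = trials_run["trial_id"].to_numpy()[onsets + STIMULUS_S > n_scans * tr]
        raise ValueError(f"trial onsets beyond run end: {bad.tolist()}")
    n_trials = len(trials_run)

    cols = np.empty((n_scans, n_trials))
    for i, on in enumerate(onsets):
        reg, _ = compute_regressor(
            np.array([[on], [STIMULUS_S], [1.0]]), hrf, frame_times)
        cols[:, i] = reg[:, 0]
        if not np.any(cols[:, i]):
            raise ValueError(f"trial regressor {i} is all zero")

    if nuisance is None:
        nuisance = np.zeros((n_scans, 0))
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.shape[0] != n_scans:
        raise ValueError("nuisance length must match scan count")
    if nuisance.size and nuisance.shape[1] != N_NUISANCE:
        raise ValueError(f"expected {N_NUISANCE} nuisance columns")

    X = np.column_stack([cols, nuisance, np.ones(n_scans)])
    labels = ([f"trial_{int(t)}" for t in trials_run["trial_id"]]
              + [f"motion_{k}" for k in range(nuisance.shape[1])]
              + ["intercept"])
    return DesignMatrix(X=X, column_labels=labels, frame_times=frame_times,
                        trial_ids=trials_run["trial_id"].to_numpy())


def estimate_trial_betas(series: np.ndarray, design: DesignMatrix,
                         coords: np.ndarray | None = None,
                         roi_labels: np.ndarray | None = None,
                         runs: np.ndarray | int = 0) -> BetaMatrix:
    """Per-voxel ordinary least squares; trial columns only are returned."""
    series = np.asarray(series, dtype=float)
    if series.shape[0] != design.X.shape[0]:
        raise ValueError("series length must match design scan count")
    rank = np.linalg.matrix_rank(design.X)
    if rank < design.X.shape[1]:
        # Name candidate collinear columns via near-zero QR pivots.
        _, R = np.linalg.qr(design.X)
        d = np.abs(np.diag(R))
        bad = [design.column_labels[i] for i in np.where(d < d.max() * 1e-10)[0]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design.X, series, rcond=None)
    values = beta[: design.n_trials]
    if coords is None:
        coords = np.stack([np.arange(series.shape[1]),
                           np.zeros(series.shape[1], dtype=int),
                           np.zeros(series.shape[1], dtype=int)], axis=1)
    if np.isscalar(runs):
        runs = np.full(design.n_trials, runs)
    return BetaMatrix(values=values, trial_ids=design.trial_ids, runs=runs,
                      coords=coords, roi_labels=roi_labels)


def estimate_session_betas(trials: pd.DataFrame, runs_data: dict,
                           voxels_coords: np.ndarray, tr: float,
                           roi_labels: np.ndarray | None = None) -> BetaMatrix:
    """Run the trial-wise GLM for every run and stack the valid-trial rows.

    ``runs_data`` maps run label -> (series, nuisance). Trials flagged
    invalid are still modelled as regressors (keeping the design well
    specified) but dropped from the output rows.
    """
    mats = []
    for run, g in trials.groupby("run", sort=True):
        series, nuisance = runs_data[run]
        design = build_design_matrix(g, tr, series.shape[0], nuisance)
        bm = estimate_trial_betas(series, design, coords=voxels_coords,
                                  roi_labels=roi_labels, runs=run)
        keep = g["valid"].to_numpy(dtype=bool)
        mats.append(bm.select_trials(keep))
    values = np.vstack([m.values for m in mats])
    return BetaMatrix(values=values,
                      trial_ids=np.concatenate([m.trial_ids for m in mats]),
                      runs=np.concatenate([m.runs for m in mats]),
                      coords=voxels_coords, roi_labels=roi_labels)
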