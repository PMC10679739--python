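"""Searchlight maximum-likelihood reconstruction of direction.

For a searchlight of voxels (Euclidean lattice radius 4 by default) the
fitted tuning functions give a predicted response vector g(theta) for
every candidate direction. The single-trial response vector is scored
against a multivariate normal with mean g(theta) and a shrinkage-
regularised residual covariance, and the direction is reconstructed as
the grid argmax of the log-likelihood over 1°..360° in 1° steps.

The covariance is the (1/t)-normalised Gram matrix of training residuals
mixed with the diagonal of sample variances; the mixing coefficient is a
monotone function of the voxel-to-trial ratio that equals 1/2 at a ratio
of one and tends to 0 and 1 in the respective limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular
from scipy.spatial import cKDTree

from .angles import DEFAULT_GRID
from .containers import BetaMatrix
from .encoding import CvFolds, FdtfModel, fit_fdtf_ensemble, fit_voxel_gpr, \
    predict_means_at

SEARCHLIGHT_RADIUS = 4.0


def extract_searchlight(coords: np.ndarray, center, radius: float = SEARCHLIGHT_RADIUS
                        ) -> np.ndarray:
    """Indices of voxels within Euclidean lattice distance ``radius`` of center.

    The ball is clipped at the volume borders (only voxels present in
    ``coords`` are returned); the center itself is included.
    """
    coords = np.asarray(coords, dtype=float)
    tree = cKDTree(coords)
    idx = tree.query_ball_point(np.asarray(center, dtype=float), radius + 1e-9)
    idx = np.sort(np.asarray(idx, dtype=int))
    return idx


def residual_covariance(B_train: np.ndarray, predictions: np.ndarray) -> np.ndarray:
    """Raw residual covariance (1/t) R^T R of training responses.

    ``predictions`` are the tuning-function means at the training
    directions; t is the number of training trials in the fold.
    """
    B = np.asarray(B_train, dtype=float)
    H = np.asarray(predictions, dtype=float)
    if B.shape != H.shape:
        raise ValueError("training betas and predictions must have equal shape")
    t = B.shape[0]
    if t == 0:
        raise ValueError("no training trials")
    R = B - H
    return (R.T @ R) / t


def mixing_coefficient(v: int, t: int, method: str = "arctan") -> float:
    """Shrinkage mixing coefficient as a function of the voxel/trial ratio.

    ``logistic``: r = 1 / (1 + exp(-ln(v/t))) = (v/t) / (1 + v/t).
    ``arctan``:   r = 1/2 + arctan(ln(v/t)) / pi.
    Both equal 1/2 at v = t, tend to 0 as v/t -> 0 and to 1 as v/t -> inf.
    ``printed-arctan`` is the arctan form without the 1/2 offset, kept for
    comparison only: it is 0 at v = t and tends to ±1/2 in the limits,
    violating the three properties above.
    """
    if v <= 0 or t <= 0:
        raise ValueError("voxel and trial counts must be positive")
    x = np.log(v / t)
    if method == "logistic":
        return float(1.0 / (1.0 + np.exp(-x)))
    if method == "arctan":
        return float(0.5 + np.arctan(x) / np.pi)
    if method == "printed-arctan":
        return float(np.arctan(x) / np.pi)
    raise ValueError(f"unknown regularizer {method!r}")


def shrink_covariance(Sigma: np.ndarray, r: float) -> np.ndarray:
    """Convex mix of the covariance with the diagonal of its own variances."""
    if not 0.0 <= r <= 1.0:
        raise ValueError("mixing coefficient must lie in [0, 1]")
    Sigma = np.asarray(Sigma, dtype=float)
    return (1.0 - r) * Sigma + r * np.diag(np.diag(Sigma))


@dataclass
class SearchlightModel:
    """Fitted searchlight: member tuning functions plus shrunk covariance."""

    center: np.ndarray
    member_idx: np.ndarray
    models: list[FdtfModel]
    G: np.ndarray                  # (n_grid, v) predicted means over the grid
    Sigma: np.ndarray              # shrunk residual covariance
    mixing_r: float
    t_train: int
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    chol: np.ndarray | None = None
    logdet: float = 0.0

    def __post_init__(self):
        if self.chol is None:
            try:
                self.chol = cholesky(self.Sigma, lower=True)
            except np.linalg.LinAlgError as e:
                raise np.linalg.LinAlgError(
                    "searchlight covariance is not positive definite; "
                    "increase shrinkage") from e
            self.logdet = 2.0 * float(np.log(np.diag(self.chol)).sum())

    @property
    def n_voxels(self) -> int:
        return len(self.models)


def build_searchlight_model(B_train: np.ndarray, theta_train: np.ndarray,
                            center=None, member_idx=None,
                            regularizer: str = "arctan",
                            fit: str = "ensemble", seed: int = 0,
                            grid: np.ndarray | None = None,
                            label_type: str = "stimulus", coherence: str = "",
                            fold: int | None = None) -> SearchlightModel:
    """Fit tuning functions and the shrunk residual covariance for one fold.

    ``fit='ensemble'`` uses the shared-grid marginal-likelihood search
    (default at searchlight scale); ``fit='exact'`` runs the per-voxel
    gradient optimiser.
    """
    if grid is None:
        grid = DEFAULT_GRID
    t, v = B_train.shape
    if fit == "ensemble":
        models = fit_fdtf_ensemble(B_train, theta_train, label_type=label_type,
                                   coherence=coherence, fold=fold, grid=grid)
    elif fit == "exact":
        models = [fit_voxel_gpr(B_train[:, j], theta_train, seed=seed + j,
                                label_type=label_type, coherence=coherence,
                                fold=fold, grid=grid)
                  for j in range(v)]
    else:
        raise ValueError(f"unknown fit mode {fit!r}")
    H = predict_means_at(models, theta_train)
    Sigma_raw = residual_covariance(B_train, H)
    r = mixing_coefficient(v, t, regularizer)
    Sigma = shrink_covariance(Sigma_raw, r)
    G = np.column_stack([m.mu_grid for m in models])
    return SearchlightModel(
        center=np.asarray(center) if center is not None else np.zeros(3),
        member_idx=(np.asarray(member_idx) if member_idx is not None
                    else np.arange(v)),
        models=models, G=G, Sigma=Sigma, mixing_r=r, t_train=t,
        grid=np.asarray(grid, dtype=float))


def loglik_profile(beta_row: np.ndarray, model: SearchlightModel) -> np.ndarray:
    """Multivariate-normal log-likelihood of one trial at every grid direction."""
    beta_row = np.asarray(beta_row, dtype=float)
    v = model.n_voxels
    D = model.G - beta_row[None, :]
    W = solve_triangular(model.chol, D.T, lower=True)
    quad = np.einsum("ij,ij->j", W, W)
    return -0.5 * (v * np.log(2.0 * np.pi) + model.logdet + quad)


def decode_trial(profile: np.ndarray, grid: np.ndarray | None = None) -> float:
    """Grid argmax of the log-likelihood profile; ties go to the smallest angle.

    A decoded 360° is reported as 0° for convention consistency.
    """
    profile = np.asarray(profile, dtype=float)
    if not np.all(np.isfinite(profile)):
        raise ValueError("log-likelihood profile must be finite")
    if grid is None:
        grid = DEFAULT_GRID
    return float(grid[int(np.argmax(profile))] % 360.0)


def decode_block(B_test: np.ndarray, model: SearchlightModel) -> np.ndarray:
    """Decode every row of a test block; returns directions in degrees."""
    out = np.empty(B_test.shape[0])
    for i in range(B_test.shape[0]):
        out[i] = decode_trial(loglik_profile(B_test[i], model), model.grid)
    return out


def run_reconstruction(betas: BetaMatrix, trials: pd.DataFrame, cv: CvFolds,
                       centers: np.ndarray | None = None,
                       radius: float = SEARCHLIGHT_RADIUS,
                       regularizer: str = "arctan", fit: str = "ensemble",
                       seed: int = 0,
                       train_label_override: str | None = None,
                       models_by_fold: dict[int, list[SearchlightModel]] | None = None,
                       ) -> tuple[pd.DataFrame, dict[int, list[SearchlightModel]]]:
    """Decode every valid trial once per searchlight per fold.

    ``centers`` defaults to a single searchlight spanning all voxels of
    the beta matrix (cluster mode). Passing ``models_by_fold`` (as
    returned by a previous call) reuses fitted models, which is how
    cross-condition prediction decodes one condition's data with another
    condition's models.

    Returns a tidy per-trial DataFrame and the fitted models keyed by
    test run.
    """
    label_col = "theta_s" if cv.label_type == "stimulus" else "theta_r"
    theta_all = trials[label_col].to_numpy(dtype=float)
    # map trial_id -> row of the beta matrix
    row_of = {tid: i for i, tid in enumerate(betas.trial_ids)}

    if centers is None:
        center_list = [None]
    else:
        center_list = list(np.atleast_2d(centers))
    fitted: dict[int, list[SearchlightModel]] = {}
    records = []
    for fold in cv.folds:
        train_rows = np.array([row_of[t] for t in trials["trial_id"].iloc[fold.train_idx]])
        test_rows = np.array([row_of[t] for t in trials["trial_id"].iloc[fold.test_idx]])
        th_train = theta_all[fold.train_idx]
        if models_by_fold is None:
            sl_models = []
            for c, ctr in enumerate(center_list):
                if ctr is None:
                    midx = np.arange(betas.n_voxels)
                    ctr_arr = betas.coords.mean(axis=0)
                else:
                    midx = extract_searchlight(betas.coords, ctr, radius)
                    ctr_arr = np.asarray(ctr)
                sl = build_searchlight_model(
                    betas.values[np.ix_(train_rows, midx)], th_train,
                    center=ctr_arr, member_idx=midx, regularizer=regularizer,
                    fit=fit, seed=seed + 1000 * c,
                    label_type=train_label_override or cv.label_type,
                    coherence=cv.coherence, fold=fold.test_run)
                sl_models.append(sl)
            fitted[fold.test_run] = sl_models
        else:
            if fold.test_run not in models_by_fold:
                raise KeyError(f"no fitted model for fold (test run {fold.test_run})")
            sl_models = models_by_fold[fold.test_run]
        for sl in sl_models:
            theta_hat = decode_block(betas.values[np.ix_(test_rows, sl.member_idx)], sl)
            for k, trial_pos in enumerate(fold.test_idx):
                records.append({
                    "trial_id": int(trials["trial_id"].iloc[trial_pos]),
                    "run": int(trials["run"].iloc[trial_pos]),
                    "fold": fold.test_run,
                    "center_x": float(sl.center[0]), "center_y": float(sl.center[1]),
                    "center_z": float(sl.center[2]),
                    "label_type": cv.label_type, "coherence": cv.coherence,
                    "theta_true": float(theta_all[trial_pos]),
                    "theta_hat": float(theta_hat[k]),
                })
    result = pd.DataFrame.from_records(records)
    if models_by_fold is not None:
        fitted = models_by_fold
    return result, fitted
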