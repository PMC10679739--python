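"""Per-voxel cyclic Gaussian-process tuning functions.

Each voxel's trial-wise response amplitude is modelled as an unknown
smooth periodic function of direction plus Gaussian noise,

    beta_i = f(theta_i) + eps_i,   eps_i ~ N(0, sigma_n^2),

with a zero-mean GP prior on ``f`` (after per-voxel centering) under the
periodic (exp-sine-squared) kernel

    k(a, b) = sigma_f^2 * exp(-2 sin^2((a - b) / 2) / ell^2),

angles in radians. This "full distribution tuning function" captures both
the direction-conditional mean and spread without presupposing a fixed
channel basis. Hyperparameters (ell, sigma_f^2, sigma_n^2) maximise the
log marginal likelihood. Models are fitted per voxel, per coherence, per
label (stimulus vs. report), per leave-one-run-out fold.

Two fitting routes are provided: :func:`fit_voxel_gpr`, gradient-based
multi-start optimisation for a single voxel, and
:func:`fit_fdtf_ensemble`, a profiled-scale grid search that shares the
expensive Cholesky factorisations across all voxels of a searchlight and
is the default for pipeline-scale problems. Both maximise the same
marginal likelihood over the same kernel family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

from .angles import DEG2RAD, DEFAULT_GRID

LENGTH_SCALE_BOUNDS = (0.05, 10.0)   # radians-equivalent
VAR_FLOOR_FACTOR = 1e-6
VAR_CEIL_FACTOR = 10.0
MIN_TRAIN_TRIALS = 16
JITTER = 1e-10


def cyclic_kernel(theta_a_deg, theta_b_deg, length_scale: float,
                  signal_var: float = 1.0) -> np.ndarray:
    """Periodic kernel matrix between two sets of directions (degrees)."""
    if length_scale <= 0:
        raise ValueError("length_scale must be positive")
    a = np.atleast_1d(np.asarray(theta_a_deg, dtype=float)) * DEG2RAD
    b = np.atleast_1d(np.asarray(theta_b_deg, dtype=float)) * DEG2RAD
    s = np.sin(0.5 * (a[:, None] - b[None, :]))
    return signal_var * np.exp(-2.0 * s**2 / length_scale**2)


# ---------------------------------------------------------------------------
# Cross-validation folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fold:
    test_run: int
    train_idx: np.ndarray   # positional indices into the trial table
    test_idx: np.ndarray


@dataclass
class CvFolds:
    """Leave-one-run-out folds for one (coherence, label) condition."""

    coherence: str
    label_type: str          # "stimulus" or "report"
    folds: list[Fold]

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def make_cv_folds(trials: pd.DataFrame, coherence: str,
                  label_type: str = "stimulus") -> CvFolds:
    """Build leave-one-run-out folds over the valid trials of one coherence.

    Report-label folds additionally require a recorded report. Runs whose
    test set would be empty are skipped with a warning; at least two runs
    with valid trials are required.
    """
    if label_type not in ("stimulus", "report"):
        raise ValueError("label_type must be 'stimulus' or 'report'")
    mask = (trials["coherence"] == coherence) & trials["valid"].astype(bool)
    if label_type == "report":
        mask &= np.isfinite(trials["theta_r"].to_numpy(dtype=float))
    idx = np.where(mask.to_numpy())[0]
    runs = trials["run"].to_numpy()[idx]
    uruns = np.unique(runs)
    if uruns.size < 2:
        raise ValueError("need at least two runs with valid trials")
    folds = []
    for r in uruns:
        test = idx[runs == r]
        train = idx[runs != r]
        if test.size == 0:
            warnings.warn(f"run {r} has no valid test trials; fold skipped")
            continue
        folds.append(Fold(test_run=int(r), train_idx=train, test_idx=test))
    return CvFolds(coherence=coherence, label_type=label_type, folds=folds)


# ---------------------------------------------------------------------------
# Single-voxel model
# ---------------------------------------------------------------------------

@dataclass
class FdtfModel:
    """Fitted cyclic GP tuning function for one voxel."""

    length_scale: float
    signal_var: float
    noise_var: float
    center: float                 # training mean, restored at prediction
    theta_train: np.ndarray       # degrees
    alpha: np.ndarray             # K^{-1} (y - center)
    chol: np.ndarray | None       # lower Cholesky of K
    log_marginal_likelihood: float
    n_train: int
    label_type: str = "stimulus"
    coherence: str = ""
    fold: int | None = None
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    mu_grid: np.ndarray | None = None
    var_grid: np.ndarray | None = None

    def predict(self, theta_deg=None):
        return predict_fdtf(self, theta_deg)


def _neg_lml_and_grad(log_params, y, sin_half_sq, n):
    ell, sf2, sn2 = np.exp(log_params)
    K = sf2 * np.exp(-2.0 * sin_half_sq / ell**2)
    Ks = K.copy()
    K[np.diag_indices(n)] += sn2 + JITTER
    try:
        L = cholesky(K, lower=True)
    except np.linalg.LinAlgError:
        return 1e25, np.zeros(3)
    alpha = cho_solve((L, True), y)
    lml = (-0.5 * y @ alpha - np.log(np.diag(L)).sum()
           - 0.5 * n * np.log(2.0 * np.pi))
    Kinv = cho_solve((L, True), np.eye(n))
    W = np.outer(alpha, alpha) - Kinv
    # dK/dlog(ell) = K_signal * 4 sin^2 / ell^2 ; dK/dlog(sf2) = K_signal ;
    # dK/dlog(sn2) = sn2 I
    dK_ell = Ks * (4.0 * sin_half_sq / ell**2)
    g = np.array([
        0.5 * np.sum(W * dK_ell),
        0.5 * np.sum(W * Ks),
        0.5 * np.trace(W) * sn2,
    ])
    return -lml, -g


def fit_voxel_gpr(betas_j, thetas_deg, n_restarts: int = 5, seed: int = 0,
                  length_scale_bounds=LENGTH_SCALE_BOUNDS,
                  label_type: str = "stimulus", coherence: str = "",
                  fold: int | None = None,
                  grid: np.ndarray | None = None) -> FdtfModel:
    """Fit one voxel's tuning function by marginal-likelihood maximisation.

    L-BFGS-B in log hyperparameter space with analytic gradients and
    seeded multi-start. Variance bounds scale with the sample variance of
    the responses. A degenerate voxel (zero variance) or total optimiser
    failure falls back to a flat model with a warning.
    """
    y = np.asarray(betas_j, dtype=float)
    th = np.asarray(thetas_deg, dtype=float)
    n = y.size
    if n < MIN_TRAIN_TRIALS:
        raise ValueError(f"need at least {MIN_TRAIN_TRIALS} training trials, got {n}")
    center = float(y.mean())
    yc = y - center
    var = float(yc.var())
    if grid is None:
        grid = DEFAULT_GRID
    if var <= 0:
        warnings.warn("constant responses; returning flat model")
        return _flat_model(center, th, n, grid, label_type, coherence, fold)

    d = 0.5 * DEG2RAD * (th[:, None] - th[None, :])
    sin_half_sq = np.sin(d) ** 2
    lo = np.log([length_scale_bounds[0], VAR_FLOOR_FACTOR * var, VAR_FLOOR_FACTOR * var])
    hi = np.log([length_scale_bounds[1], VAR_CEIL_FACTOR * var, VAR_CEIL_FACTOR * var])
    bounds = list(zip(lo, hi))

    rng = np.random.default_rng(seed)
    starts = [np.log([1.0, 0.5 * var, 0.5 * var])]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(rng.uniform(lo, hi))

    best = None
    for x0 in starts:
        res = minimize(_neg_lml_and_grad, x0, args=(yc, sin_half_sq, n),
                       jac=True, method="L-BFGS-B", bounds=bounds)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or best.fun >= 1e24:
        warnings.warn("hyperparameter optimisation failed; returning flat model")
        return _flat_model(center, th, n, grid, label_type, coherence, fold)

    ell, sf2, sn2 = np.exp(best.x)
    model = _build_model(yc, th, ell, sf2, sn2, center, -best.fun,
                         label_type, coherence, fold, grid)
    return model


def _flat_model(center, th, n, grid, label_type, coherence, fold) -> FdtfModel:
    m = FdtfModel(length_scale=1.0, signal_var=0.0, noise_var=JITTER,
                  center=center, theta_train=np.asarray(th, dtype=float),
                  alpha=np.zeros(n), chol=None,
                  log_marginal_likelihood=-np.inf, n_train=n,
                  label_type=label_type, coherence=coherence, fold=fold,
                  grid=np.asarray(grid, dtype=float),
                  mu_grid=np.full(len(grid), center),
                  var_grid=np.full(len(grid), JITTER))
    return m


def _build_model(yc, th, ell, sf2, sn2, center, lml, label_type, coherence,
                 fold, grid) -> FdtfModel:
    n = yc.size
    K = cyclic_kernel(th, th, ell, sf2)
    K[np.diag_indices(n)] += sn2 + JITTER
    L = cholesky(K, lower=True)
    alpha = cho_solve((L, True), yc)
    model = FdtfModel(length_scale=float(ell), signal_var=float(sf2),
                      noise_var=float(sn2), center=center,
                      theta_train=th.copy(), alpha=alpha, chol=L,
                      log_marginal_likelihood=float(lml), n_train=n,
                      label_type=label_type, coherence=coherence, fold=fold,
                      grid=np.asarray(grid, dtype=float))
    model.mu_grid, model.var_grid = predict_fdtf(model, model.grid)
    return model


def predict_fdtf(model: FdtfModel, theta_deg=None):
    """GP posterior predictive mean and variance at the given directions.

    The predictive variance includes the noise variance: it describes the
    distribution of a new single-trial response at that direction (the
    direction-conditional likelihood), not just the tuning-curve mean.
    """
    if theta_deg is None:
        theta_deg = model.grid
        if model.mu_grid is not None:
            return model.mu_grid, model.var_grid
    th = np.atleast_1d(np.asarray(theta_deg, dtype=float))
    if model.chol is None:  # flat model
        return (np.full(th.shape, model.center),
                np.full(th.shape, model.noise_var + model.signal_var))
    Ks = cyclic_kernel(th, model.theta_train, model.length_scale, model.signal_var)
    mu = Ks @ model.alpha + model.center
    V = solve_triangular(model.chol, Ks.T, lower=True)
    var = model.signal_var + model.noise_var - np.einsum("ij,ij->j", V, V)
    return mu, np.maximum(var, JITTER)


def log_marginal_likelihood(betas_j, thetas_deg, length_scale, signal_var,
                            noise_var) -> float:
    """Log marginal likelihood of centered responses under given kernel."""
    y = np.asarray(betas_j, dtype=float)
    yc = y - y.mean()
    th = np.asarray(thetas_deg, dtype=float)
    n = y.size
    K = cyclic_kernel(th, th, length_scale, signal_var)
    K[np.diag_indices(n)] += noise_var + JITTER
    L = cholesky(K, lower=True)
    alpha = cho_solve((L, True), yc)
    return float(-0.5 * yc @ alpha - np.log(np.diag(L)).sum()
                 - 0.5 * n * np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Ensemble (searchlight-scale) fitting
# ---------------------------------------------------------------------------

def fit_fdtf_ensemble(B_train: np.ndarray, thetas_deg, length_scales=None,
                      signal_fracs=None, label_type: str = "stimulus",
                      coherence: str = "", fold: int | None = None,
                      grid: np.ndarray | None = None) -> list[FdtfModel]:
    """Fit all voxels of a training block over a shared hyperparameter grid.

    Responses are standardised per voxel; for each candidate
    (length-scale, signal-fraction) pair the overall variance scale is
    profiled out analytically, so one Cholesky factorisation per candidate
    serves every voxel. Each voxel keeps the candidate maximising its
    profiled marginal likelihood and receives an exact GP posterior under
    those hyperparameters.
    """
    B = np.asarray(B_train, dtype=float)
    th = np.asarray(thetas_deg, dtype=float)
    t, v = B.shape
    if t < MIN_TRAIN_TRIALS:
        raise ValueError(f"need at least {MIN_TRAIN_TRIALS} training trials, got {t}")
    if grid is None:
        grid = DEFAULT_GRID
    if length_scales is None:
        length_scales = np.geomspace(0.1, 6.0, 13)
    if signal_fracs is None:
        signal_fracs = np.linspace(0.02, 0.98, 13)

    centers = B.mean(axis=0)
    Yc = B - centers
    scales = Yc.std(axis=0)
    live = scales > 0
    S = np.where(live, scales, 1.0)
    Y = Yc / S

    C_by_ell = {float(ell): cyclic_kernel(th, th, float(ell)) for ell in length_scales}
    best_pll = np.full(v, -np.inf)
    best_ell = np.full(v, length_scales[0], dtype=float)
    best_s = np.full(v, signal_fracs[0], dtype=float)
    best_c = np.ones(v)
    eye = np.eye(t)
    for ell, C in C_by_ell.items():
        for s in signal_fracs:
            Kt = s * C + (1.0 - s + JITTER) * eye
            L = cholesky(Kt, lower=True)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            V = solve_triangular(L, Y, lower=True)
            q = np.einsum("ij,ij->j", V, V)          # y^T Ktilde^{-1} y per voxel
            c_hat = np.maximum(q / t, 1e-12)
            pll = -0.5 * t * np.log(c_hat) - 0.5 * logdet - 0.5 * t \
                - 0.5 * t * np.log(2.0 * np.pi)
            better = pll > best_pll
            best_pll = np.where(better, pll, best_pll)
            best_ell = np.where(better, ell, best_ell)
            best_s = np.where(better, s, best_s)
            best_c = np.where(better, c_hat, best_c)

    # Group voxels sharing (ell, s) so each group reuses one factorisation.
    keys: dict[tuple[float, float], list[int]] = {}
    for j in range(v):
        keys.setdefault((float(best_ell[j]), float(best_s[j])), []).append(j)
    models_by_idx: dict[int, FdtfModel] = {}
    for (ell, s), idxs in keys.items():
        C = C_by_ell[ell]
        Kt = s * C + (1.0 - s + JITTER) * eye
        L = cholesky(Kt, lower=True)
        Ks_grid = s * cyclic_kernel(grid, th, ell)     # unit-variance cross-kernel
        Vg = solve_triangular(L, Ks_grid.T, lower=True)
        diag_red = np.einsum("ij,ij->j", Vg, Vg)
        for j in idxs:
            if not live[j]:
                models_by_idx[j] = _flat_model(centers[j], th, t, grid,
                                               label_type, coherence, fold)
                continue
            c = best_c[j] * S[j] ** 2                  # total variance scale
            sf2, sn2 = c * s, c * (1.0 - s)
            alpha_unit = cho_solve((L, True), Y[:, j])
            # Full-scale K = (sqrt(c_hat) * S * L)(...)^T, so rescale the
            # unit-space quantities back to response units.
            alpha = alpha_unit / (best_c[j] * S[j])
            m = FdtfModel(length_scale=ell, signal_var=float(sf2),
                          noise_var=float(sn2), center=float(centers[j]),
                          theta_train=th.copy(), alpha=alpha,
                          chol=np.sqrt(best_c[j]) * S[j] * L,
                          log_marginal_likelihood=float(
                              best_pll[j] - t * np.log(S[j])),
                          n_train=t, label_type=label_type,
                          coherence=coherence, fold=fold,
                          grid=np.asarray(grid, dtype=float))
            m.mu_grid = S[j] * (Ks_grid @ alpha_unit) + centers[j]
            m.var_grid = np.maximum(c * (1.0 - diag_red), JITTER)
            models_by_idx[j] = m
    return [models_by_idx[j] for j in range(v)]


def predict_means_at(models: list[FdtfModel], theta_deg) -> np.ndarray:
    """Posterior predictive means of many voxels at arbitrary directions.

    Returns an (n_theta, n_voxels) matrix; used for training-angle
    residuals and for the decoding grid. Voxels sharing a length-scale
    share the cross-kernel computation.
    """
    th = np.atleast_1d(np.asarray(theta_deg, dtype=float))
    out = np.empty((th.size, len(models)))
    by_ell: dict[float, list[int]] = {}
    for j, m in enumerate(models):
        if m.chol is None:
            out[:, j] = m.center
        else:
            by_ell.setdefault(float(m.length_scale), []).append(j)
    for ell, idxs in by_ell.items():
        m0 = models[idxs[0]]
        C = cyclic_kernel(th, m0.theta_train, ell)
        for j in idxs:
            m = models[j]
            out[:, j] = m.signal_var * (C @ m.alpha) + m.center
    return out
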