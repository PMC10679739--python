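"""Behavioral accuracy metrics and participant screening.

Performance on the continuous motion-report task is summarised by the
absolute circular deviation between stimulus and report, rescaled to
feature-continuous accuracy (FCA): 0° error -> 100 %, 90° -> 50 % (chance
for uniform guessing), 180° -> 0 %.

Response distributions are modelled with a three-component von Mises
mixture on the signed report error: a target component centred at 0°, an
"opposite" component centred at 180° (capturing axis confusions), and a
circular-uniform guessing component. The opposite-component weight is the
rate of reports of opposite direction (ROOD). Participants are screened
out when the 95th percentile of the absolute deviation at full coherence
exceeds 36.5° or when the fitted ROOD rate exceeds 5 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ive, logsumexp

from .angles import DEG2RAD, circdist_deg, signed_error_deg

# Screening cutoffs for the full-coherence condition.
P95_DEVIATION_CUTOFF_DEG = 36.5
ROOD_CUTOFF = 0.05

# Concentration floor: below this a von Mises component is indistinguishable
# from the uniform component and the mixture weights are unidentifiable.
KAPPA_FLOOR = 0.5
KAPPA_CEIL = 500.0


def circular_deviation(theta_s, theta_r):
    """Absolute circular deviation |Δx| between two directions, in [0, 180].

    Implemented as the shortest-arc distance on the circle so that the
    FCA rescaling by 180° is well defined.
    """
    theta_s = np.asarray(theta_s, dtype=float)
    theta_r = np.asarray(theta_r, dtype=float)
    if not (np.all(np.isfinite(theta_s)) and np.all(np.isfinite(theta_r))):
        raise ValueError("directions must be finite")
    return circdist_deg(theta_s, theta_r)


def fca(deviation):
    """Feature-continuous accuracy in percent: (180 - |Δx|) / 180 * 100."""
    deviation = np.asarray(deviation, dtype=float)
    if np.any(deviation < 0) or np.any(deviation > 180):
        raise ValueError("deviation must lie in [0, 180] degrees")
    return (180.0 - deviation) / 180.0 * 100.0


@dataclass
class VmmmFit:
    """Maximum-likelihood fit of the von Mises mixture to report errors."""

    w_detect: float
    w_opposite: float
    w_guess: float
    kappa: float
    loglik: float
    n_trials: int
    converged: bool = True

    @property
    def rood_rate(self) -> float:
        return self.w_opposite

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.w_detect, self.w_opposite, self.w_guess])


def _log_vm_pdf(x_rad: np.ndarray, mu_rad: float, kappa: float) -> np.ndarray:
    # log I0(kappa) computed via the exponentially scaled Bessel function
    # to stay finite for large concentrations.
    log_i0 = np.log(ive(0, kappa)) + kappa
    return kappa * np.cos(x_rad - mu_rad) - np.log(2.0 * np.pi) - log_i0


def _solve_kappa(r_bar: float) -> float:
    """Invert the mean resultant length A(kappa) = I1/I0 for kappa."""
    r = float(np.clip(r_bar, 0.0, 1.0 - 1e-12))
    if r <= 0.0:
        return KAPPA_FLOOR
    # Banerjee et al. approximation for p = 2, refined by Newton steps.
    kappa = r * (2.0 - r**2) / (1.0 - r**2)
    kappa = float(np.clip(kappa, KAPPA_FLOOR, KAPPA_CEIL))
    for _ in range(25):
        a = ive(1, kappa) / ive(0, kappa)
        da = 1.0 - a / kappa - a**2
        if da <= 0:
            break
        step = (a - r) / da
        kappa = float(np.clip(kappa - step, KAPPA_FLOOR, KAPPA_CEIL))
        if abs(step) < 1e-10 * (1.0 + kappa):
            break
    return kappa


def _em_vmmm(x_rad: np.ndarray, w0: np.ndarray, kappa0: float,
             max_iter: int = 500, tol: float = 1e-10) -> tuple[np.ndarray, float, float]:
    n = x_rad.size
    w = w0.copy()
    kappa = kappa0
    log_uniform = -np.log(2.0 * np.pi)
    prev_ll = -np.inf
    for _ in range(max_iter):
        logp = np.column_stack([
            np.log(w[0] + 1e-300) + _log_vm_pdf(x_rad, 0.0, kappa),
            np.log(w[1] + 1e-300) + _log_vm_pdf(x_rad, np.pi, kappa),
            np.full(n, np.log(w[2] + 1e-300) + log_uniform),
        ])
        norm = logsumexp(logp, axis=1)
        ll = float(norm.sum())
        resp = np.exp(logp - norm[:, None])
        w = resp.mean(axis=0)
        mass = resp[:, 0].sum() + resp[:, 1].sum()
        if mass > 1e-8:
            r_bar = (resp[:, 0] @ np.cos(x_rad) + resp[:, 1] @ np.cos(x_rad - np.pi)) / mass
            kappa = _solve_kappa(r_bar)
        if ll - prev_ll < tol * (1.0 + abs(ll)) and ll >= prev_ll:
            prev_ll = ll
            break
        prev_ll = ll
    return w, kappa, prev_ll


def fit_vmmm(errors_deg, n_restarts: int = 10, seed: int = 0) -> VmmmFit:
    """Fit the target/opposite/guess von Mises mixture to signed report errors.

    Parameters
    ----------
    errors_deg:
        Signed circular errors (report minus target) in degrees, interpreted
        on (-180, 180]. At least 20 trials are required.
    n_restarts:
        Number of seeded EM restarts; the best log-likelihood wins.
    seed:
        Seed for the restart initialisations (the fit is deterministic
        given the seed).

    The two von Mises components share a single concentration ``kappa``,
    which is floored at a small value below which they would be
    indistinguishable from the uniform component.
    """
    x = np.asarray(errors_deg, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise ValueError(f"need at least 20 trials to fit the mixture, got {x.size}")
    x_rad = signed_error_deg(0.0, x) * DEG2RAD

    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float, float] | None = None
    starts = [(np.array([0.6, 0.1, 0.3]), 8.0)]
    for _ in range(max(0, n_restarts - 1)):
        starts.append((rng.dirichlet(np.ones(3)), float(np.exp(rng.uniform(np.log(0.5), np.log(50.0))))))
    for w0, k0 in starts:
        w, kappa, ll = _em_vmmm(x_rad, np.asarray(w0, dtype=float), k0)
        if np.isfinite(ll) and (best is None or ll > best[2]):
            best = (w, kappa, ll)
    if best is None:
        raise RuntimeError("von Mises mixture fit failed to converge from any restart")
    w, kappa, ll = best
    return VmmmFit(
        w_detect=float(w[0]), w_opposite=float(w[1]), w_guess=float(w[2]),
        kappa=float(kappa), loglik=ll, n_trials=int(x.size),
    )


@dataclass
class ScreeningResult:
    """Outcome of the behavioral inclusion screen on full-coherence trials."""

    p95_deviation: float
    rood_rate: float
    include: bool
    reasons: list[str] = field(default_factory=list)
    n_trials: int = 0


def screen_participant(full_coherence_trials: pd.DataFrame,
                       p95_cutoff: float = P95_DEVIATION_CUTOFF_DEG,
                       rood_cutoff: float = ROOD_CUTOFF,
                       seed: int = 0) -> ScreeningResult:
    """Apply the behavioral exclusion rules to a full-coherence trial table.

    A participant is excluded when the 95th percentile of |Δx| exceeds
    ``p95_cutoff`` (imprecise reporting) or when the fitted opposite-report
    weight exceeds ``rood_cutoff`` (systematic 180° confusions).
    """
    t = full_coherence_trials
    mask = np.isfinite(np.asarray(t["theta_r"], dtype=float))
    theta_s = np.asarray(t["theta_s"], dtype=float)[mask]
    theta_r = np.asarray(t["theta_r"], dtype=float)[mask]
    if theta_s.size < 20:
        raise ValueError(f"too few reported full-coherence trials for screening ({theta_s.size})")

    dev = circular_deviation(theta_s, theta_r)
    p95 = float(np.percentile(dev, 95))  # linear interpolation
    fit = fit_vmmm(signed_error_deg(theta_s, theta_r), seed=seed)

    reasons = []
    if p95 > p95_cutoff:
        reasons.append(f"p95 deviation {p95:.1f} deg exceeds {p95_cutoff} deg")
    if fit.w_opposite > rood_cutoff:
        reasons.append(f"ROOD rate {fit.w_opposite:.3f} exceeds {rood_cutoff}")
    return ScreeningResult(
        p95_deviation=p95, rood_rate=fit.w_opposite,
        include=not reasons, reasons=reasons, n_trials=int(theta_s.size),
    )
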