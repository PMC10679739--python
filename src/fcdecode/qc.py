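"""Fixation quality control from gaze recordings.

Two screens are applied. Run-level: the standard deviation of gaze
position is computed per run, the distribution of run SDs (pooled over
subjects) is smoothed with a kernel density estimate, and runs above the
0.9 quantile of the smoothed distribution — the noisiest ~10 % — are
excluded. Trial-level: a trial is rejected when radial gaze distance
from fixation exceeds 2 degrees of visual angle continuously for more
than 200 ms during its 2 s stimulation window. Missing samples and
blinks are not interpolated and never count toward an excursion's
duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr
from scipy.stats import gaussian_kde

from .synthetic import STIMULUS_S

DEVIATION_THRESHOLD_DVA = 2.0
MIN_EXCURSION_S = 0.2
RUN_NOISE_QUANTILE = 0.9


@dataclass
class QcReport:
    run_sd: dict
    noise_threshold: float | None
    excluded_runs: list
    rejected_trials: list = field(default_factory=list)   # (trial_id, reason)
    unscorable_trials: list = field(default_factory=list)
    fraction_rejected: float = 0.0


def run_position_sd(gaze: pd.DataFrame) -> pd.Series:
    """Per-run gaze-position standard deviation (radial, valid samples only)."""
    def _sd(g):
        v = g[g["valid"].astype(bool)]
        return float(np.sqrt(v["x"].var() + v["y"].var()))
    return gaze.groupby("run").apply(_sd, include_groups=False)


def run_noise_threshold(run_sds, quantile: float = RUN_NOISE_QUANTILE) -> float:
    """Gaze-noise cutoff: the KDE-smoothed distribution's 0.9 quantile.

    The run-SD sample (all runs, all subjects) is smoothed with a Gaussian
    KDE (normal-reference bandwidth); the threshold is the value where the
    estimated CDF reaches ``quantile``, i.e. the noisiest ~10 % of runs
    fall above it.
    """
    x = np.asarray(run_sds, dtype=float)
    if x.size < 10:
        raise ValueError(f"need at least 10 run SDs, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate run-SD sample (all values equal)")
    kde = gaussian_kde(x)
    h = float(np.sqrt(kde.covariance[0, 0]))

    def cdf(q):
        return float(ndtr((q - x) / h).mean()) - quantile

    lo, hi = x.min() - 6 * h, x.max() + 6 * h
    return float(brentq(cdf, lo, hi))


def reject_trials(gaze: pd.DataFrame, trials: pd.DataFrame,
                  deviation_threshold: float = DEVIATION_THRESHOLD_DVA,
                  min_duration: float = MIN_EXCURSION_S,
                  run_sd_threshold: float | None = None,
                  pooled_run_sds=None) -> QcReport:
    """Apply the fixation-control rules to a session.

    A trial is rejected iff radial gaze distance exceeds the deviation
    threshold continuously for more than ``min_duration`` inside its
    stimulation window (strict inequalities at both thresholds). Invalid
    samples neither extend an excursion's duration nor terminate it
    (a blink mid-excursion does not reset the clock). Trials with no
    gaze coverage are flagged unscorable. If a run-SD threshold is
    supplied (or derivable from ``pooled_run_sds``), whole runs above it
    are excluded.
    """
    run_sds = run_position_sd(gaze)
    threshold = run_sd_threshold
    if threshold is None and pooled_run_sds is not None:
        threshold = run_noise_threshold(pooled_run_sds)
    excluded_runs = ([int(r) for r, sd in run_sds.items() if sd > threshold]
                     if threshold is not None else [])

    rejected, unscorable = [], []
    for run, g in gaze.groupby("run"):
        time = g["time"].to_numpy(dtype=float)
        dt = float(np.median(np.diff(time))) if time.size > 1 else 0.0
        r = np.hypot(g["x"].to_numpy(dtype=float), g["y"].to_numpy(dtype=float))
        valid = g["valid"].to_numpy(dtype=bool)
        t_run = trials[trials["run"] == run]
        for row in t_run.itertuples(index=False):
            if int(row.run) in excluded_runs:
                rejected.append((int(row.trial_id), "run excluded by noise screen"))
                continue
            m = (time >= row.onset) & (time < row.onset + STIMULUS_S)
            if not np.any(m):
                unscorable.append(int(row.trial_id))
                continue
            rr, vv = r[m], valid[m]
            # accumulate continuous supra-threshold duration; invalid samples
            # add nothing but do not break the excursion
            dur, broke = 0.0, False
            for k in range(rr.size):
                if not vv[k]:
                    continue
                if rr[k] > deviation_threshold:
                    dur += dt
                    if dur > min_duration:
                        broke = True
                        break
                else:
                    dur = 0.0
            if broke:
                rejected.append((int(row.trial_id),
                                 f"gaze > {deviation_threshold} dva for > "
                                 f"{min_duration * 1000:.0f} ms"))
    n_trials = len(trials)
    frac = (len(rejected)) / n_trials if n_trials else 0.0
    return QcReport(run_sd={int(k): float(v) for k, v in run_sds.items()},
                    noise_threshold=threshold, excluded_runs=excluded_runs,
                    rejected_trials=rejected, unscorable_trials=unscorable,
                    fraction_rejected=frac)


def apply_qc(trials: pd.DataFrame, report: QcReport) -> pd.DataFrame:
    """Return a trial table with the QC validity mask applied."""
    bad = {t for t, _ in report.rejected_trials} | set(report.unscorable_trials)
    out = trials.copy()
    out["valid"] = out["valid"].astype(bool) & ~out["trial_id"].isin(bad) \
        & np.isfinite(out["theta_r"].to_numpy(dtype=float))
    return out
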