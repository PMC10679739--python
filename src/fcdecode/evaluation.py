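"""Reconstruction scoring and cross-condition generalization.

Reconstructions are scored with feature-continuous accuracy (FCA) and its
label-balanced variant (BFCA): per-trial FCA integrated over the sorted
true directions with the trapezoid rule and circular closure, divided by
the full circle. With balanced labels the two agree closely; with skewed
label distributions BFCA removes the spurious advantage of always
predicting the label mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import circular_deviation, fca

CHANCE_FCA = 50.0


def score_fca(theta_true, theta_hat) -> float:
    """Mean per-trial FCA, in percent."""
    theta_true = np.asarray(theta_true, dtype=float)
    theta_hat = np.asarray(theta_hat, dtype=float)
    if theta_true.shape != theta_hat.shape:
        raise ValueError("true and predicted directions must align")
    return float(np.mean(fca(circular_deviation(theta_true, theta_hat))))


def score_bfca(theta_true, theta_hat, circular_closure: bool = True) -> float:
    """Balanced FCA: trapezoidal integral of FCA over sorted true directions.

    Trials are sorted by the true direction; duplicate directions are
    averaged before integration (zero-width trapezoids otherwise). With
    ``circular_closure`` the first sorted point is re-appended at
    theta + 360° so the integral covers the whole circle; the sum of
    trapezoid areas is divided by 360°.
    """
    theta_true = np.asarray(theta_true, dtype=float)
    theta_hat = np.asarray(theta_hat, dtype=float)
    if theta_true.shape != theta_hat.shape:
        raise ValueError("true and predicted directions must align")
    if theta_true.size < 2:
        raise ValueError("need at least two trials")
    f = fca(circular_deviation(theta_true, theta_hat))
    order = np.argsort(theta_true, kind="stable")
    th = theta_true[order]
    f = f[order]
    # average duplicates
    uth, inv = np.unique(th, return_inverse=True)
    if uth.size < th.size:
        fsum = np.zeros(uth.size)
        cnt = np.zeros(uth.size)
        np.add.at(fsum, inv, f)
        np.add.at(cnt, inv, 1.0)
        th, f = uth, fsum / cnt
    if th.size < 2:
        raise ValueError("degenerate support: all true directions identical")
    if circular_closure:
        th = np.append(th, th[0] + 360.0)
        f = np.append(f, f[0])
    return float(np.trapezoid(f, th) / (th[-1] - th[0] if not circular_closure
                                        else 360.0))


@dataclass
class AccuracySummary:
    group: str
    coherence: str
    label_type: str
    mean_fca: float
    bfca: float
    n_trials: int
    chance: float = CHANCE_FCA


def aggregate(results: pd.DataFrame,
              voxel_groups: dict[tuple, str] | None = None) -> pd.DataFrame:
    """Per-group, per-condition accuracy summary of reconstruction results.

    ``voxel_groups`` maps searchlight center (x, y, z) tuples to group
    names (e.g. ROI labels); unmapped centers fall into "all". Empty
    groups produce a warning row with n = 0.
    """
    df = results.copy()
    if voxel_groups:
        df["group"] = [voxel_groups.get((x, y, z), "all") for x, y, z in
                       zip(df["center_x"], df["center_y"], df["center_z"])]
    else:
        df["group"] = "all"
    rows = []
    for (grp, coh, lab), g in df.groupby(["group", "coherence", "label_type"]):
        rows.append(AccuracySummary(
            group=grp, coherence=coh, label_type=lab,
            mean_fca=score_fca(g["theta_true"], g["theta_hat"]),
            bfca=score_bfca(g["theta_true"].to_numpy(), g["theta_hat"].to_numpy()),
            n_trials=len(g)).__dict__)
    return pd.DataFrame(rows)


def cross_predict(betas_data, trials, cv_data, models_by_fold,
                  radius=None, seed: int = 0):
    """Decode one condition's data with models fitted in another condition.

    ``cv_data`` describes the data condition (its label defines the
    decoding target); ``models_by_fold`` holds the model condition's
    fitted searchlights keyed by held-out run, so the fold structure is
    respected: models trained without run k decode run k's data. Returns
    the per-trial results plus the BFCA of decoded versus data-condition
    labels.
    """
    from .decoder import run_reconstruction

    results, _ = run_reconstruction(betas_data, trials, cv_data,
                                    models_by_fold=models_by_fold, seed=seed)
    bfca = score_bfca(results["theta_true"].to_numpy(),
                      results["theta_hat"].to_numpy())
    return results, bfca


def above_chance_ttest(values, chance: float = CHANCE_FCA):
    """One-tailed one-sample t-test of accuracy values against chance."""
    res = stats.ttest_1samp(np.asarray(values, dtype=float), chance,
                            alternative="greater")
    return float(res.statistic), float(res.pvalue)
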