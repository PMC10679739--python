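"""Shared in-memory containers and their plain-text serialisation.

Trial tables are pandas DataFrames in a BIDS-events-like layout (one row
per trial). Response amplitudes live in a :class:`BetaMatrix`: a dense
trials x voxels array plus voxel lattice coordinates and ROI labels,
written as a TSV matrix with a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TRIAL_COLUMNS = [
    "trial_id", "run", "coherence", "coherence_level", "bin_index",
    "theta_s", "theta_r", "onset", "duration", "iti", "valid",
]


@dataclass
class BetaMatrix:
    """Trial-wise response-amplitude estimates for a set of voxels."""

    values: np.ndarray              # (n_trials, n_voxels)
    trial_ids: np.ndarray           # (n_trials,)
    runs: np.ndarray                # (n_trials,) run label per trial
    coords: np.ndarray              # (n_voxels, 3) integer lattice positions
    roi_labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.trial_ids = np.asarray(self.trial_ids)
        self.runs = np.asarray(self.runs)
        self.coords = np.asarray(self.coords)
        if self.values.ndim != 2:
            raise ValueError("values must be a trials x voxels matrix")
        if self.values.shape[0] != self.trial_ids.shape[0]:
            raise ValueError("trial_ids must align with matrix rows")
        if self.values.shape[1] != self.coords.shape[0]:
            raise ValueError("coords must align with matrix columns")
        if self.roi_labels is None:
            self.roi_labels = np.array(["none"] * self.n_voxels)
        else:
            self.roi_labels = np.asarray(self.roi_labels)

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def select_trials(self, mask_or_idx) -> "BetaMatrix":
        return BetaMatrix(self.values[mask_or_idx], self.trial_ids[mask_or_idx],
                          self.runs[mask_or_idx], self.coords, self.roi_labels,
                          dict(self.meta))

    def select_voxels(self, idx) -> "BetaMatrix":
        idx = np.asarray(idx)
        return BetaMatrix(self.values[:, idx], self.trial_ids, self.runs,
                          self.coords[idx], self.roi_labels[idx], dict(self.meta))

    def to_files(self, prefix: str | Path) -> None:
        """Write the matrix as TSV plus a JSON sidecar with voxel metadata."""
        prefix = Path(prefix)
        df = pd.DataFrame(self.values)
        df.insert(0, "trial_id", self.trial_ids)
        df.insert(1, "run", self.runs)
        df.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
        sidecar = {
            "coords": self.coords.tolist(),
            "roi_labels": list(map(str, self.roi_labels)),
            "meta": self.meta,
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_files(cls, prefix: str | Path) -> "BetaMatrix":
        prefix = Path(prefix)
        df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
        sidecar = json.loads(prefix.with_suffix(".json").read_text())
        values = df.drop(columns=["trial_id", "run"]).to_numpy(dtype=float)
        return cls(values, df["trial_id"].to_numpy(), df["run"].to_numpy(),
                   np.asarray(sidecar["coords"]),
                   np.asarray(sidecar["roi_labels"]), sidecar.get("meta", {}))


def write_trial_table(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_trial_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    df["valid"] = df["valid"].astype(bool)
    return df
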