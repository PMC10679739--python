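"""Synthetic experiment generator.

Emulates a continuous motion-direction session: random dot kinematograms
at three coherence levels (16 trials each per run, 10 runs), motion
directions pseudo-randomised through 8 hidden 45° bins, continuous
reports drawn from a target/opposite/guess von Mises mixture, voxel
populations with smooth cyclic tuning, trial-wise response amplitudes
with Gaussian noise, volumetric BOLD runs, and gaze traces for fixation
control. Every operation takes an explicit seed and is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .angles import DEG2RAD, wrap_deg
from .containers import BetaMatrix, TRIAL_COLUMNS

#: Hidden randomisation bin edges in degrees (bin 1 is centred on 0° = up).
BIN_EDGES = (337.5, 22.5, 67.5, 112.5, 157.5, 202.5, 247.5, 292.5)
N_BINS = 8
BIN_WIDTH = 45.0

#: Coherence labels with numeric coherence levels. The intermediate level
#: mirrors a staircase-titrated value; it is a configuration parameter.
DEFAULT_COHERENCES = {"zero": 0.0, "intermediate": 0.1947, "full": 1.0}

ITI_VALUES = (3.0, 5.0, 7.0, 9.0)
#: Truncated-geometric decay for the ITI distribution: shorter ITIs are
#: more frequent, halving in probability per step.
ITI_DECAY = 0.5

FIXATION_S = 0.5
STIMULUS_S = 2.0
RESPONSE_S = 7.5

MAX_CONSECUTIVE_BIN = 2
MAX_CONSECUTIVE_COHERENCE = 3


class ConfigurationError(ValueError):
    """An infeasible design-constraint combination."""


def bin_of(theta_deg) -> np.ndarray:
    """1-based hidden-bin index of a direction."""
    return (np.floor(wrap_deg(np.asarray(theta_deg) + BIN_WIDTH / 2) / BIN_WIDTH)
            .astype(int) % N_BINS) + 1


def bin_center(bin_index) -> np.ndarray:
    return wrap_deg((np.asarray(bin_index) - 1) * BIN_WIDTH)


def iti_probabilities() -> np.ndarray:
    p = ITI_DECAY ** np.arange(len(ITI_VALUES))
    return p / p.sum()


def _order_run_labels(items: list[tuple[str, int]], rng: np.random.Generator,
                      max_attempts: int = 500) -> list[tuple[str, int]]:
    """Order one run's (coherence, bin) labels under the run-length rules.

    Random greedy selection with restarts: at every position a label is
    drawn from the remaining multiset, excluding labels that would create
    a third identical bin or a fourth identical coherence in a row.
    """
    for _ in range(max_attempts):
        remaining: dict[tuple[str, int], int] = {}
        for it in items:
            remaining[it] = remaining.get(it, 0) + 1
        seq: list[tuple[str, int]] = []
        ok = True
        while sum(remaining.values()):
            cands, weights = [], []
            for lab, cnt in remaining.items():
                if cnt == 0:
                    continue
                coh, b = lab
                if (len(seq) >= MAX_CONSECUTIVE_BIN
                        and all(s[1] == b for s in seq[-MAX_CONSECUTIVE_BIN:])):
                    continue
                if (len(seq) >= MAX_CONSECUTIVE_COHERENCE
                        and all(s[0] == coh for s in seq[-MAX_CONSECUTIVE_COHERENCE:])):
                    continue
                cands.append(lab)
                weights.append(cnt)
            if not cands:
                ok = False
                break
            w = np.asarray(weights, dtype=float)
            lab = cands[rng.choice(len(cands), p=w / w.sum())]
            remaining[lab] -= 1
            seq.append(lab)
        if ok:
            return seq
    raise ConfigurationError("could not order run labels under the run-length constraints")


def generate_trial_sequence(n_runs: int = 10, trials_per_coherence: int = 16,
                            coherence_levels: dict[str, float] | None = None,
                            seed: int = 0) -> pd.DataFrame:
    """Generate a session's trial table.

    Each run presents every coherence level ``trials_per_coherence`` times.
    Directions are uniform within 8 hidden 45° bins; across the session each
    (coherence, bin) cell is perfectly balanced, the same bin never occurs
    more than twice in a row and the same coherence never more than three
    times in a row. At zero coherence the direction is a label only: the
    stimulus contains no net motion and the label has no generative effect
    on voxel responses downstream.
    """
    if coherence_levels is None:
        coherence_levels = dict(DEFAULT_COHERENCES)
    if n_runs < 1 or trials_per_coherence < 1:
        raise ConfigurationError("n_runs and trials_per_coherence must be positive")
    total_per_coh = n_runs * trials_per_coherence
    if total_per_coh % N_BINS:
        raise ConfigurationError(
            f"n_runs * trials_per_coherence = {total_per_coh} is not divisible by "
            f"the {N_BINS} randomisation bins")
    rng = np.random.default_rng(seed)

    # Per coherence: balanced session-level bin multiset, shuffled and split
    # into equal-sized per-run chunks.
    per_run_bins: dict[str, list[np.ndarray]] = {}
    for coh in coherence_levels:
        bins = np.repeat(np.arange(1, N_BINS + 1), total_per_coh // N_BINS)
        rng.shuffle(bins)
        per_run_bins[coh] = np.array_split(bins, n_runs)

    rows = []
    trial_id = 0
    for run in range(1, n_runs + 1):
        items = [(coh, int(b)) for coh in coherence_levels
                 for b in per_run_bins[coh][run - 1]]
        seq = _order_run_labels(items, rng)
        t = 0.0
        for coh, b in seq:
            theta = wrap_deg(bin_center(b) + rng.uniform(-BIN_WIDTH / 2, BIN_WIDTH / 2))
            iti = float(rng.choice(ITI_VALUES, p=iti_probabilities()))
            rows.append({
                "trial_id": trial_id, "run": run, "coherence": coh,
                "coherence_level": float(coherence_levels[coh]),
                "bin_index": int(b), "theta_s": float(theta), "theta_r": np.nan,
                "onset": t + FIXATION_S, "duration": STIMULUS_S, "iti": iti,
                "valid": True,
            })
            t += FIXATION_S + STIMULUS_S + RESPONSE_S + iti
            trial_id += 1
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


# ---------------------------------------------------------------------------
# Behavioral reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReportMixture:
    """Per-coherence report-generation mixture.

    A report is the target direction plus von Mises noise with probability
    ``w_detect``, the opposite direction plus the same noise with
    probability ``w_opposite``, and a uniform guess otherwise.
    """

    w_detect: float
    w_opposite: float
    w_guess: float
    kappa: float

    def validate(self) -> None:
        w = np.array([self.w_detect, self.w_opposite, self.w_guess])
        if np.any(w < 0):
            raise ValueError("mixture weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError(f"mixture weights must sum to 1, got {w.sum()}")
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")


#: Defaults emulate a well-performing included participant: precise
#: detection at full coherence (clears the 36.5° / 5 % ROOD screen),
#: substantial guessing at the titrated intermediate level, pure guessing
#: at zero coherence.
DEFAULT_REPORT_MIXTURES = {
    "zero": ReportMixture(0.0, 0.0, 1.0, 8.0),
    "intermediate": ReportMixture(0.60, 0.03, 0.37, 4.5),
    "full": ReportMixture(0.97, 0.005, 0.025, 20.0),
}


def simulate_reports(trials: pd.DataFrame,
                     mixture: dict[str, ReportMixture] | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Draw reported directions for every trial.

    At zero coherence there is no direction signal, so the detection and
    opposite weights are forced to zero and reports are uniform guesses.
    """
    if mixture is None:
        mixture = dict(DEFAULT_REPORT_MIXTURES)
    rng = np.random.default_rng(seed)
    out = trials.copy()
    comps = np.empty(len(out), dtype=object)
    theta_r = np.empty(len(out))
    for i, row in enumerate(out.itertuples(index=False)):
        mix = mixture[row.coherence]
        mix.validate()
        if row.coherence_level == 0.0:
            mix = replace(mix, w_detect=0.0, w_opposite=0.0,
                          w_guess=1.0)
        comp = rng.choice(3, p=[mix.w_detect, mix.w_opposite, mix.w_guess])
        if comp == 2:
            theta_r[i] = rng.uniform(0.0, 360.0)
        else:
            center = row.theta_s + (180.0 if comp == 1 else 0.0)
            noise = rng.vonmises(0.0, mix.kappa) / DEG2RAD if mix.kappa > 0 else \
                rng.uniform(-180.0, 180.0)
            theta_r[i] = wrap_deg(center + noise)
        comps[i] = ("detect", "opposite", "guess")[comp]
    out["theta_r"] = theta_r
    out["report_component"] = comps
    out["valid"] = True
    return out


# ---------------------------------------------------------------------------
# Voxel populations and response amplitudes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TuningSpec:
    """Distributional description of a simulated voxel population.

    Tuning profiles are rescaled von Mises bumps (optionally plus a second
    harmonic), the minimal smooth cyclic family: heterogeneous amplitudes,
    widths (concentrations) and preferred directions, a flat baseline, and
    per-voxel Gaussian trial noise. Amplitudes are in the same arbitrary
    response units as the noise standard deviation.
    """

    amplitude_range: tuple[float, float] = (0.8, 1.2)
    width_range: tuple[float, float] = (1.0, 4.0)   # von Mises concentration
    baseline_range: tuple[float, float] = (-0.5, 0.5)
    noise_sd: float = 1.0
    informative_fraction: float = 0.75
    second_harmonic_fraction: float = 0.2
    second_harmonic_scale: float = 0.3


@dataclass
class VoxelPopulation:
    coords: np.ndarray            # (n, 3) int lattice positions, unique
    roi_label: np.ndarray         # (n,) str
    tuning_amplitude: np.ndarray  # (n,) response units; 0 iff uninformative
    tuning_width: np.ndarray      # (n,) von Mises concentration
    tuning_phase: np.ndarray      # (n,) degrees, preferred direction
    baseline: np.ndarray          # (n,) response units
    noise_sd: np.ndarray          # (n,) >= 0
    informative: np.ndarray       # (n,) bool
    amp2: np.ndarray | None = None    # second-harmonic amplitude
    phase2: np.ndarray | None = None  # second-harmonic phase, degrees
    seed: int | None = None

    def __post_init__(self):
        if self.amp2 is None:
            self.amp2 = np.zeros(self.n_voxels)
        if self.phase2 is None:
            self.phase2 = np.zeros(self.n_voxels)
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be nonnegative")
        if len(np.unique(self.coords, axis=0)) != self.n_voxels:
            raise ValueError("voxel coordinates must be unique")

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    def tuning(self, theta_deg) -> np.ndarray:
        """Noise-free tuned response, shape (n_theta, n_voxels).

        Each voxel responds with ``baseline + amplitude * b(theta)`` where
        ``b`` is a von Mises bump peaking at 1 at the preferred direction,
        plus an optional period-180° second harmonic.
        """
        th = np.atleast_1d(np.asarray(theta_deg, dtype=float))[:, None] * DEG2RAD
        d1 = th - self.tuning_phase[None, :] * DEG2RAD
        f = self.baseline[None, :] + self.tuning_amplitude[None, :] * np.exp(
            self.tuning_width[None, :] * (np.cos(d1) - 1.0))
        d2 = 2.0 * (th - self.phase2[None, :] * DEG2RAD)
        f = f + self.amp2[None, :] * np.exp(self.tuning_width[None, :] * (np.cos(d2) - 1.0))
        return f


def ball_coords(radius: float, center: tuple[int, int, int] = (0, 0, 0)) -> np.ndarray:
    """Integer lattice points within Euclidean distance ``radius`` of center."""
    r = int(math.floor(radius))
    ax = np.arange(-r, r + 1)
    g = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    g = g[(g ** 2).sum(axis=1) <= radius ** 2]
    g = g[np.lexsort((g[:, 2], g[:, 1], g[:, 0]))]
    return g + np.asarray(center, dtype=int)


def generate_voxel_population(n_voxels: int, grid_shape: tuple[int, int, int] = (8, 8, 8),
                              tuning_spec: TuningSpec | None = None, seed: int = 0,
                              coords: np.ndarray | None = None,
                              roi_label: str = "cluster") -> VoxelPopulation:
    """Draw a voxel population with heterogeneous smooth cyclic tuning.

    Preferred directions are stratified over [0, 360) (a jittered even
    grid) so that even small populations jointly identify direction.
    """
    spec = tuning_spec or TuningSpec()
    rng = np.random.default_rng(seed)
    if coords is None:
        capacity = int(np.prod(grid_shape))
        if n_voxels > capacity:
            raise ConfigurationError(
                f"n_voxels={n_voxels} exceeds lattice capacity {capacity}")
        idx = np.arange(n_voxels)
        coords = np.stack(np.unravel_index(idx, grid_shape), axis=1)
    else:
        coords = np.asarray(coords)
        if n_voxels != coords.shape[0]:
            raise ValueError("n_voxels must match provided coords")

    informative = rng.random(n_voxels) < spec.informative_fraction
    amp = np.where(informative, rng.uniform(*spec.amplitude_range, n_voxels), 0.0)
    width = rng.uniform(*spec.width_range, n_voxels)
    phase = wrap_deg(rng.permutation(np.linspace(0.0, 360.0, n_voxels, endpoint=False))
                     + rng.uniform(-180.0 / max(n_voxels, 1), 180.0 / max(n_voxels, 1),
                                   n_voxels))
    baseline = rng.uniform(*spec.baseline_range, n_voxels)
    has2 = informative & (rng.random(n_voxels) < spec.second_harmonic_fraction)
    amp2 = np.where(has2, spec.second_harmonic_scale
                    * rng.uniform(*spec.amplitude_range, n_voxels), 0.0)
    phase2 = rng.uniform(0.0, 360.0, n_voxels)
    return VoxelPopulation(
        coords=coords, roi_label=np.array([roi_label] * n_voxels),
        tuning_amplitude=amp, tuning_width=width, tuning_phase=phase,
        baseline=baseline, noise_sd=np.full(n_voxels, float(spec.noise_sd)),
        informative=informative, amp2=amp2, phase2=phase2, seed=seed,
    )


#: Multiplier on tuned signal per coherence: full-strength sensory drive at
#: 100 %, attenuated drive at the titrated intermediate level; at zero
#: coherence the drive is the report-generating latent at full strength.
DEFAULT_COHERENCE_GAIN = {"zero": 1.0, "intermediate": 0.5, "full": 1.0}


def driving_direction(trials: pd.DataFrame, drive: str = "auto") -> np.ndarray:
    """Per-trial direction that drives voxel responses.

    ``auto``: the stimulus direction wherever coherent motion is present;
    at zero coherence the report-generating latent (the report itself for
    pure guessing), since the stimulus label carries no motion signal.
    """
    if drive == "stimulus":
        return trials["theta_s"].to_numpy(dtype=float)
    if drive == "report":
        return trials["theta_r"].to_numpy(dtype=float)
    if drive != "auto":
        raise ValueError(f"unknown drive {drive!r}")
    theta = trials["theta_s"].to_numpy(dtype=float).copy()
    zero = trials["coherence_level"].to_numpy(dtype=float) == 0.0
    theta[zero] = trials["theta_r"].to_numpy(dtype=float)[zero]
    return theta


def simulate_betas(trials: pd.DataFrame, voxels: VoxelPopulation, seed: int = 0,
                   drive: str = "auto",
                   coherence_gain: dict[str, float] | None = None) -> BetaMatrix:
    """Simulate trial-wise response amplitudes: tuning plus Gaussian noise.

    ``beta[i, j] = baseline_j + gain(coherence_i) * amplitude_j * bump_j(theta_i)
    + eps`` with ``eps ~ Normal(0, noise_sd_j^2)``. Trials whose driving
    direction is undefined (e.g. zero-coherence trials without a report)
    contribute baseline plus noise only.
    """
    if len(trials) == 0 or voxels.n_voxels == 0:
        raise ValueError("trials and voxels must be nonempty")
    gain_map = coherence_gain or DEFAULT_COHERENCE_GAIN
    rng = np.random.default_rng(seed)
    theta = driving_direction(trials, drive)
    gain = np.array([gain_map.get(c, 1.0) for c in trials["coherence"]])

    ok = np.isfinite(theta)
    tuned_sig = voxels.tuning(np.where(ok, theta, 0.0)) - voxels.baseline[None, :]
    tuned = np.tile(voxels.baseline, (len(trials), 1)) \
        + np.where(ok[:, None], gain[:, None] * tuned_sig, 0.0)

    eps = rng.standard_normal(tuned.shape) * voxels.noise_sd[None, :]
    return BetaMatrix(
        values=tuned + eps, trial_ids=trials["trial_id"].to_numpy(),
        runs=trials["run"].to_numpy(), coords=voxels.coords,
        roi_labels=voxels.roi_label,
        meta={"seed": int(seed), "drive": drive},
    )


# ---------------------------------------------------------------------------
# Volumetric BOLD simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoldNoiseSpec:
    """Scan-noise description for volumetric simulation."""

    sigma: float = 1.0        # thermal noise SD, response units
    ar_coef: float = 0.4      # AR(1) temporal autocorrelation
    motion_amp: float = 0.0   # coupling of voxel signal to motion courses
    trial_noise_sd: float = 0.0  # amplitude noise on top of the tuned response


def simulate_bold_run(trials_run: pd.DataFrame, voxels: VoxelPopulation,
                      tr: float = 0.8, noise_spec: BoldNoiseSpec | None = None,
                      seed: int = 0, n_scans: int | None = None,
                      drive: str = "auto"):
    """Simulate one run's volumetric time series plus nuisance regressors.

    Per voxel the signal is the sum of 2 s stimulus boxcars (amplitude from
    the tuned generative model) convolved with the canonical hemodynamic
    response, a flat baseline, six random-walk motion courses (optionally
    coupled into the signal) and AR(1) Gaussian noise.

    Returns ``(series, nuisance, frame_times)`` with shapes
    ``(n_scans, n_voxels)``, ``(n_scans, 6)`` and ``(n_scans,)``.
    """
    from nilearn.glm.first_level import compute_regressor

    if tr <= 0:
        raise ValueError("tr must be positive")
    spec = noise_spec or BoldNoiseSpec()
    rng = np.random.default_rng(seed)
    onsets = trials_run["onset"].to_numpy(dtype=float)
    itis = trials_run["iti"].to_numpy(dtype=float)
    t_end = float(onsets[-1] + STIMULUS_S + RESPONSE_S + itis[-1]) + 16.0
    needed = int(np.ceil(t_end / tr))
    if n_scans is None:
        n_scans = needed
    elif n_scans * tr < onsets[-1] + STIMULUS_S:
        raise ValueError("run too short for the trial schedule")
    frame_times = np.arange(n_scans) * tr

    # One convolved boxcar per trial, unit amplitude.
    X = np.empty((n_scans, len(trials_run)))
    for i, on in enumerate(onsets):
        reg, _ = compute_regressor(
            np.array([[on], [STIMULUS_S], [1.0]]), "spm", frame_times)
        X[:, i] = reg[:, 0]

    theta = driving_direction(trials_run, drive)
    ok = np.isfinite(theta)
    amp = voxels.tuning(np.where(ok, theta, 0.0)) - voxels.baseline[None, :]
    amp[~ok] = 0.0
    if spec.trial_noise_sd > 0:
        amp = amp + rng.standard_normal(amp.shape) * spec.trial_noise_sd

    series = X @ amp + voxels.baseline[None, :]

    nuisance = np.cumsum(rng.standard_normal((n_scans, 6)) * 0.01, axis=0)
    if spec.motion_amp > 0:
        series = series + nuisance @ (rng.standard_normal((6, voxels.n_voxels))
                                      * spec.motion_amp)
    if spec.sigma > 0:
        from scipy.signal import lfilter
        white = rng.standard_normal(series.shape) * spec.sigma
        series = series + lfilter([1.0], [1.0, -spec.ar_coef], white, axis=0)
    return series, nuisance, frame_times


# ---------------------------------------------------------------------------
# Gaze simulation
# ---------------------------------------------------------------------------

def simulate_gaze(trials: pd.DataFrame, fixation_sd: float = 0.1,
                  excursions: list[tuple[int, float, float, float]] = (),
                  blinks: list[tuple[int, float, float]] = (),
                  sampling_rate: float = 1000.0, seed: int = 0,
                  padding: float = 1.0) -> pd.DataFrame:
    """Simulate gaze traces around fixation, with optional fixation breaks.

    Baseline gaze is isotropic Gaussian jitter around fixation (degrees of
    visual angle per axis). ``excursions`` is a list of
    ``(trial_id, onset_s, duration_s, amplitude_dva)`` offsets injected
    during the trial's 2 s stimulation window (onset relative to stimulus
    onset); offsets outside that window raise. ``blinks`` mark samples
    invalid with no position.
    """
    rng = np.random.default_rng(seed)
    frames = []
    dt = 1.0 / sampling_rate
    exc = list(excursions)
    for tr_id, on, dur, _amp in exc:
        if on < 0 or on + dur > STIMULUS_S:
            raise ValueError(
                f"excursion for trial {tr_id} at {on}+{dur}s lies outside the "
                f"{STIMULUS_S}s stimulation window")
    for run, g in trials.groupby("run", sort=True):
        t_end = float(g["onset"].max() + STIMULUS_S + RESPONSE_S) + padding
        time = np.arange(0.0, t_end, dt)
        x = rng.standard_normal(time.size) * fixation_sd
        y = rng.standard_normal(time.size) * fixation_sd
        valid = np.ones(time.size, dtype=bool)
        onset_by_trial = dict(zip(g["trial_id"], g["onset"]))
        for tr_id, on, dur, amp in exc:
            if tr_id in onset_by_trial:
                t0 = onset_by_trial[tr_id] + on
                m = (time >= t0) & (time < t0 + dur)
                x[m] += amp
        for tr_id, on, dur in blinks:
            if tr_id in onset_by_trial:
                t0 = onset_by_trial[tr_id] + on
                m = (time >= t0) & (time < t0 + dur)
                valid[m] = False
                x[m] = np.nan
                y[m] = np.nan
        frames.append(pd.DataFrame({
            "run": run, "time": time, "x": x, "y": y, "valid": valid,
        }))
    return pd.concat(frames, ignore_index=True)
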