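# Methods

## Scope

`fcdecode` implements the desk-scale analysis chain for feature-continuous
motion decoding from fMRI: synthetic experiment generation, trial-wise GLM
amplitude estimation, per-voxel cyclic Gaussian-process tuning functions,
searchlight maximum-likelihood reconstruction with shrinkage-regularised
covariance, FCA/BFCA evaluation, cross-condition generalization, von Mises
mixture behavioral screening, and gaze-based fixation QC. MRI acquisition
and preprocessing (realignment, smoothing, normalisation), localizer-based
ROI definition, adaptive staircases and group-level ANOVA machinery are out
of scope; ROI membership is an input label.

## Experimental design emulated by the generator

A session has 10 runs; each run presents three coherence levels (0 %, an
intermediate titrated level, 100 %) 16 times each, i.e. 48 trials per run
and 160 trials per coherence per session. Directions are pseudo-randomised
through 8 hidden 45° bins with edges at 337.5°, 22.5°, …, 292.5° (0° = up,
clockwise positive); directions are uniform within a bin, every
(coherence, bin) cell is balanced across the session (20 trials), the same
bin never occurs more than twice in a row, the same coherence never more
than three times. The orderer is a random greedy sampler with restarts, so
the constraints hold by construction. Trials are 0.5 s fixation + 2 s
stimulus + 7.5 s response; inter-trial intervals take values {3, 5, 7, 9} s
under a truncated geometric distribution with decay 0.5 (probabilities
8/15, 4/15, 2/15, 1/15) — "shorter more frequent than longer" is the only
constraint the design imposes, and the decay parameter is configurable.

**Reports** are drawn per coherence from a three-component mixture: target
von Mises, opposite (180°-shifted) von Mises sharing the same concentration
κ, and a circular-uniform guess. Defaults describe a well-performing,
includable participant: full coherence (w_detect, w_opposite, w_guess, κ) =
(0.97, 0.005, 0.025, 20), intermediate (0.60, 0.03, 0.37, 4.5), zero
(0, 0, 1, –). At zero coherence detection and opposite weights are forced
to zero: there is no direction signal to detect. The full-coherence values
put the simulated observer comfortably inside the screening rules (95th
percentile of |Δθ| ≲ 30° < 36.5°, ROOD 0.5 % < 5 %); the intermediate
values give a mean FCA around 70 %, between chance and ceiling, as a
titrated level should.

**Voxels** have von Mises bump tuning — baseline + amplitude ·
exp(κ_w(cos(θ−φ)−1)) — optionally plus a period-180° second harmonic on a
random 20 % of informative voxels. This is the minimal smooth cyclic
family; real voxel tuning profiles are heterogeneous and smooth but have no
published generative form. Preferred directions are stratified over the
circle (jittered even grid) so small populations jointly identify
direction. Defaults: amplitudes U(0.8, 1.2), concentrations U(1, 4),
baselines U(−0.5, 0.5), 75 % informative, per-trial Gaussian noise SD 1.0 —
i.e. single-trial tuning modulation comparable to noise, a realistic
regime for trial-wise fMRI amplitudes. Recovery tests that require "high
SNR" set the noise SD explicitly (0.2).

**Zero-coherence semantics.** The sequencer assigns a direction label at
0 % coherence, but that label has no generative effect on responses.
Voxel responses on zero-coherence trials are driven by the
report-generating latent (for pure guessing, the report itself) through
the same tuning functions — the "shared code" hypothesis. The generator
can instead drive them with the (independent) stimulus label to emulate
a cohort in which reports carry no neural signal; the cross-prediction
tests use both settings.

**What the generator does not emulate:** dot-level stimulus physics,
retinotopy or spatial autocorrelation of tuning across neighbouring
voxels, physiological noise structure beyond AR(1) + motion coupling in
the volumetric mode, attention/arousal drifts, and between-subject
variability. Passing recovery tests therefore show that the estimator
chain is correct and well-calibrated under its own assumptions, not that
real cortical data meet those assumptions.

## Trial-wise GLM

One GLM per run ("least-squares-all"): one regressor per trial (2 s boxcar
at stimulus onset convolved with the canonical HRF, via nilearn), six
motion nuisance regressors, an intercept. Per-voxel OLS; only trial
columns are returned. No prewhitening and no drift model by default — the
generator's AR(1) noise option exists to stress-test that choice. Trials
excluded by QC stay in the design (keeping it well specified) but are
dropped from the output rows. Rank deficiency raises with the names of the
collinear columns.

## Cyclic GP tuning functions

Responses are centred per voxel; the GP prior is zero-mean with the
periodic kernel k(a,b) = σ_f²·exp(−2 sin²((a−b)/2)/ℓ²) (angles in
radians), the canonical cyclic choice that imposes no fixed channel
basis. The predictive variance includes σ_n², so each direction's
"vertical section" is the likelihood of a new single-trial response.

Hyperparameters maximise the log marginal likelihood. Two routes:

* `fit_voxel_gpr` — L-BFGS-B in log space with analytic gradients, 5
  seeded restarts, bounds ℓ ∈ [0.05, 10] rad-equivalent and variances in
  [10⁻⁶, 10] × var(β̂). Falls back to a flat model (σ_f² = 0) with a
  warning on degenerate input or total optimiser failure.
* `fit_fdtf_ensemble` — the pipeline default at searchlight scale. Per
  voxel the responses are standardised; for each candidate (ℓ, signal
  fraction s) on a 13 × 13 grid the total variance scale is profiled out
  analytically, so a single Cholesky factorisation of the t × t kernel
  matrix serves all voxels of the searchlight. Each voxel keeps its
  profiled-likelihood optimum and receives an exact GP posterior under
  those hyperparameters. This is a grid-resolution approximation to the
  same optimum (tests bound the marginal-likelihood gap against the
  gradient route) at roughly 1/50th the cost for 257 voxels × 10 folds.

Folds are leave-one-run-out per (coherence, label): at 10 runs × 160
trials, at most 144 training points per fold. Report-label folds drop
trials without a recorded report.

## Searchlight decoding

Searchlights are Euclidean balls of radius 4 in voxel index units
(isotropic voxels), clipped at volume borders; an uncut ball has 257
members. Residuals use the GP posterior mean at the training angles; the
GP noise ends up in the covariance diagonal rather than being counted
twice. Σ̂ = (1/t)R̂ᵀR̂ with t the fold's training-trial count, shrunk as
(1−r)Σ̂ + r·diag(Σ̂). The arctan mixing rule is implemented with a +1/2
offset — r = 1/2 + arctan(ln(v/t))/π — because the offset-free form is
inconsistent with the three properties the rule must satisfy (r(1) = 1/2,
limits 0 and 1); the uncorrected form remains available as
`printed-arctan` for comparison and a test documents its violations. The
logistic alternative is exactly (v/t)/(1+v/t). One pooled Σ̂ per
searchlight per fold, Cholesky-factorised once; each test trial's
360-point log-likelihood profile is evaluated against the cached grid
means and maximised by grid search (ties to the smallest angle; 360° is
reported as 0°). Searchlights are independent: results do not depend on
evaluation order.

## Scoring

FCA = (180° − |Δθ|)/180° × 100 with |Δθ| the shortest-arc distance (the
plain angular difference must be wrapped for the rescaling to make
sense). BFCA sorts trials by true direction, averages duplicates,
re-appends the first point at θ+360° (without this closure the integral
under-covers the circle; a flag disables it), integrates per-trial FCA by
the trapezoid rule and divides by 360°. Cross-condition prediction reuses
the fold structure: models trained without run k in condition A decode
run k's trials in condition B; the headline comparison is the
zero-coherence report model predicting full-coherence stimuli.
Generalization against chance uses a one-tailed one-sample t-test at 50.

## Behavioral screening

The mixture is fitted by EM on signed errors in (−180°, 180°] with shared
κ, 10 seeded restarts (Dirichlet weights, log-uniform κ), best likelihood
wins; κ is obtained by inverting the mean-resultant equation with Newton
refinement and floored at 0.5, below which a von Mises component is
indistinguishable from the uniform component and the weights become
unidentifiable. Exclusion: 95th percentile (linear interpolation) of
|Δθ| > 36.5° at full coherence, or fitted opposite weight > 0.05.

## Fixation QC

Run noise: SD of gaze position per run (radial combination of per-axis
SDs, valid samples only); Gaussian KDE with the normal-reference (Scott)
bandwidth over the pooled run SDs; threshold where the smoothed CDF
reaches 0.9 (root-found with Brent's method), excluding the noisiest
~10 % of runs. Trial rejection: radial distance > 2 dva continuously for
> 200 ms inside the 2 s stimulus window, strict inequalities; "more than
200 ms" is read as one continuous supra-threshold excursion —
discontinuous excursions do not sum. Invalid samples (blinks, dropouts)
are not interpolated; they neither extend an excursion's duration nor
terminate it. Trials without gaze coverage are flagged unscorable rather
than silently kept.

## Numerical choices and degenerate inputs

Kernel matrices carry a 1e-10 jitter; predictive variances are floored at
the same value. Constant-response voxels yield flat models instead of
failing. The covariance Cholesky raises with a message advising more
shrinkage if Σ̂ is not positive definite. All randomness flows through
`numpy.random.default_rng` with explicit seeds; the pipeline derives
per-stage seeds from one master seed via `SeedSequence` and records them
in the manifest next to the config hash, so identical config + seed gives
bitwise-identical outputs.

## Problem sizes in the test suite

The recovery suite runs one synthetic subject (10 runs × 48 trials) with
a single 257-voxel searchlight-sized cluster, the natural desk-scale unit
of this analysis: searchlights are independent, so whole-brain mapping is
the same computation repeated. The sequencer's constraint invariants are
exercised across 60 seeds; mixture recovery uses n = 5,000 reports;
Monte-Carlo chance checks use 10⁵ pairs.

## Known limitations

* The ensemble fitter quantises hyperparameters to its grid; voxels whose
  optimal length-scale falls outside [0.1, 6] rad are clipped.
* The trial-wise GLM assumes the canonical HRF used by the simulator;
  HRF mismatch on real data biases amplitude estimates.
* BFCA's trapezoid integral is exact only as label coverage of the circle
  becomes dense; with very few distinct directions it inherits their
  spacing.
* The volumetric mode models noise as AR(1) plus optional motion
  coupling; real scanner noise is richer.
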