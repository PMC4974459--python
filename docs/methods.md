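# Methods

## Convoy model

TS intensity is modelled as the superposition of per-polymerase signals.
Polymerase *i* initiates at `t0 + i*t_space` (regular spacing) and moves at
a constant `v_el` (kb/min). Its contribution is 0 until it enters the MS2
repeat (`l_pre` nt downstream of the initiation site), grows linearly from
0 to 1 across the repeat (`l_ms2` nt), and stays at 1 until its transcript
is released — `t_proc` seconds after the polymerase passes the cleavage
site at `l_pre + l_ms2 + l_post` nt — at which point it drops to 0.

Assumptions: the continuum approximation of the discrete stem-loops (a
constant synthesis rate of loops; the per-loop staircase is far below
measurement noise); no pausing, backtracking or premature termination;
release is instantaneous after the deterministic delay `t_proc`.

Phase durations follow in closed form: `up = (n_pol-1)*t_space +
l_ms2/v_el`, `down = (n_pol-1)*t_space`, `plateau = l_post/v_el + t_proc -
(n_pol-1)*t_space` (clamped at 0 with a `truncated` flag). A full plateau
sits at exactly `n_pol` RNA equivalents.

**Geometry defaults** (`GeneGeometry`, all config-overridable, in nt):
`l_pre = 2000`, `l_ms2 = 2800` (128 stem-loop units of ~22 nt with 3-nt
linkers), `l_post = 4500`. The reporter lengths are not published;
`l_post` is set so that post-repeat transit plus release at the typical
fitted kinetics (~4.1 kb/min, ~103 s) takes roughly the observed ~170-s
nascent residency. Every algorithm takes the geometry as a parameter and
no test depends on these specific values being "true".

## Cycle detection and fitting

Isolated cycles are maximal above-threshold segments (default threshold
0.5 RNA equivalents) flanked by at least `min_off_frames = 3` silent
frames; segments touching the movie boundary are flagged non-isolated.
Fitted segments include up to `min_off_frames` of silent padding so the
baseline constrains the fit.

The fit minimizes the sum of squared differences between the sampled model
and the trace. Because release is instantaneous, the sampled model is a
step function of the release-timing parameters: the gradient with respect
to `t_proc` vanishes almost everywhere and derivative-based least squares
stalls. The continuous parameters are therefore optimized with Nelder-Mead
in an observable-space parameterization — UP-ramp start `a`, MS2 transit
time `m = l_ms2/v_el`, DOWN duration `d = (n_pol-1)*t_space`, and first
release time `r` — in which each coordinate moves one visible feature of
the cycle and the long curved valley of the native
`(t_space, v_el, t_proc, t0)` space disappears. `t0` is a free nuisance
parameter recovered from `a` and the geometry.

`n_pol` is searched over an integer grid spanning ±50% of the peak
intensity (ties broken toward smaller values). The peak undercounts
strongly truncated cycles (releases begin before the last initiation, so
the signal saturates at a dynamic steady state); when the best fit cannot
reach the noise floor — estimated per-frame from second differences, which
vanish for the piecewise-linear noiseless signal — or prefers the grid
edge, the grid is extended toward the count implied by total visible
duration times the steady UP slope (`1/t_space`).

The elongation rate is reported as a lower bound when the profile of the
refit residual is flat in `v_el` (relative change < 1% when `v_el` is
doubled, nuisance parameters re-optimized from a warm start with
restarts); `v_el` is then the smallest rate within 1% of the optimum. On
noiseless data `v_el` always retains a weak signature through the UP-ramp
shoulders (`up − down = l_ms2/v_el` even without a plateau), so the flag
trips only when measurement noise hides that signature — a stochastic
event, matching the observation that a minimal value is obtained in a
fraction (roughly 60%) of real cycles rather than in all truncated ones.

Pooled analysis: ordinary least squares of per-cycle UP-ramp duration on
`n_pol` has slope `t_space` and intercept `l_ms2/v_el − t_space`; the
pooled rate is `l_ms2/(slope + intercept)`. Inter-convoy gaps run from the
end of one cycle's UP ramp to the start of the next cycle's UP ramp, and
their exponential time constant is the maximum-likelihood mean.

## Movie quantification and calibration

Bleach correction fits the per-frame nuclear mean with a sum of three
exponentials and rescales every frame so its fitted value matches frame 1.
The three time constants are often poorly separated over a short movie;
the bounded least-squares accepts the best point reached in the flat
valley (the correction only needs the fitted curve, not identifiable
components) and falls back to a mono-exponential with a warning only if
the fit is unusable.

Spot enhancement is a two-stage Gaussian bandpass, `G_small * (I - G_large
* I)`, with placeholder kernels `sigma_small = 1` px and `sigma_large = 5`
px (the original tool's kernel sizes are not published; both are config
keys). The TS is tracked as the brightest voxel above threshold inside a
user region, carrying the last known position through dark frames, with
exact ties resolved to the lowest (z, y, x). Quantification performs two
rounds of 3D Gaussian fitting in a window of half-size `ceil(3 sigma)` per
axis: round one unconstrained; round two with `sigma_xy`/`sigma_z` bounded
to the median ± sd over pre-detected frames and the background fixed at
its median. The lateral and axial sds are treated as `sigma_xy` and
`sigma_z`. TS intensity is the integrated Gaussian above background,
`A (2π)^{3/2} σ_xy² σ_z`.

Calibration divides the a.u. trace by `I_final` (mean of the last four
frames, requiring an active TS at movie end) and multiplies by the
absolute nascent count measured in the high-power calibration stack (21
planes every 0.3 µm; the physical PSF is unchanged so the axial sigma in
planes scales with the z-step). The single-molecule reference intensity is
the average of per-molecule Gaussian fits with per-spot local backgrounds;
fits that absorbed a neighbour (σ > 2.5× nominal), duplicate detections
(< 2 voxels apart) and >3-robust-sd outliers are discarded. A per-cell
rescale factor (cell molecule mean over cohort molecule mean) accounts for
cell-to-cell coat-protein availability.

Validation movies — acquired with illumination high enough to see single
molecules in every frame — are processed with the same scheme; each
detected molecule divided by the reference should measure ~1 RNA
equivalent. On synthetic validation movies (12 frames, ~30 molecules of
2000 a.u. on a 100 a.u. background, tri-exponential bleaching with
amplitudes (0.5, 0.3, 0.2) and time constants (2000, 400, 80) s,
Poisson-Gaussian camera noise) the scheme returns means near 1.05 with a
spread near 0.3, the scale of the published validation.

FRAP normalization divides the spot trace by total cell fluorescence and
then by the mean pre-bleach ratio, cancelling global bleaching exactly.

## ON/OFF segmentation and dwell fits

Traces are smoothed with a centered moving average (window 3), classified
against a threshold (conventionally 1.0× the mean single-molecule
intensity; the multiplier is a config key), and runs shorter than
`min_state_frames = 2` are merged into the flanking state — shortest run
first, earlier run first on ties (merging, rather than deletion with gap
filling, was chosen for idempotence: re-segmenting the reconstructed state
signal reproduces the periods). First and last periods are censored and
excluded from dwell fits by default; a survival-likelihood option keeps
them (exponential MLE becomes total time over event count; the
bi-exponential EM adds the expected residual life `d + tau` for censored
observations in the M step).

Mono-exponential dwell MLE is the sample mean. The bi-exponential mixture
is fit by EM with 10 seeded restarts (first start from the 35%/85%
quantiles, the rest randomized); components are reported sorted by tau. On
truly mono data the two components typically converge (tau ratio < 2).

## Four-state promoter model

States OFF2a/OFF2b ↔ OFF1 ↔ ON. OFF1→OFF2 uses a single rate `k_off2`
with branch probabilities (`f1`, `1-f1`) into OFF2a/OFF2b — equivalent to
separate rates `k_off2a = f1*k_off2`, `k_off2b = (1-f1)*k_off2` — because
exactly one scalar is later solved from the data. While ON, initiations
are Poisson at `k_ini`; each nascent RNA is released at `k_release` per
molecule (exponential TS residence, the form implied by the steady-state
mean equation) and each mature RNA decays at `k_deg`.

The chain is a tree, so detailed balance gives the stationary law in
closed form (weights relative to OFF1: `k_on1/k_off1`,
`f1*k_off2/k_on2a`, `(1-f1)*k_off2/k_on2b`). Steady-state means:
`mean_nascent = k_ini*π_ON/k_release`, `mean_mature = k_ini*π_ON/k_deg`,
hence the identity `mean_mature/mean_nascent = k_release/k_deg` used to
fix `k_release` from observed means; `k_off2` is then the unique solution
of `mean_mature = target` (linear in `k_off2`; negative solutions mark the
combination infeasible rather than raising). The derived closed form is
validated against simulation, not against any published expression.

The population Monte-Carlo advances independent cells in fixed steps
(default: 3,000 cells, 36,000 steps of 1 s — 10 h). Promoter transitions
fire with probability `rate*dt` (guarded by `dt * exit rate < 0.1`);
initiation counts are exact Poisson draws and release/decay are binomial
thinnings, so only the state-switching is discretized. Cells start in the
analytic stationary state with Poisson-distributed counts at the
stationary means — runs are long relative to `1/k_deg = 75` min, making
results insensitive to this choice while tightening convergence tests. An
event-driven Gillespie sampler is the cross-check scheme. The fixed-step
kernel is compiled with numba (a vectorized numpy path covers
installations without it).

Distribution comparison: two-sample KS on mature counts; χ² on nascent
counts over integer bins pooled until every expected cell is ≥ 5 (nascent
distributions carry many ties — zeros from silent TS — which invalidate
KS). The combined score is the product of the two p-values. The grid
search completes each combination from the observed means, simulates,
scores, ranks by the product, and reports the arithmetic mean of each grid
axis (plus the solved rates) over the top 10 feasible combinations.
Default grid: `1/k_ini` ∈ {2.3, 2.6, 3.0, 3.4, 3.7, 4.0, 4.3, 4.6} s,
`f1` ∈ {0.6, 0.7, 0.8, 0.9}, `1/k_on2b` ∈ {20, 30, 40, 50} min,
`k_off1` ∈ {1/90, 1/110, 1/130, 1/160} s⁻¹, `1/k_on1` ∈ {1, 1.5, 2, 2.5,
3} min, with `1/k_on2a = 5` min and `k_deg = 1/75` min⁻¹ fixed (2,560
combinations).

## Synthetic data: what it emulates and what it does not

The generators reproduce the features the estimators rely on: tri-phasic
convoy cycles with additive (default sd 0.5 RNA equivalents) and optional
multiplicative Gaussian noise; regular or exponential inter-initiation
spacing; promoter-driven initiation as a marked point process over the
exact CTMC path; diffraction-limited 3D Gaussian spots (σ_xy 1.3 px, σ_z
1.0 plane) on a uniform fluorescent background; global tri-exponential
bleaching; and Poisson shot noise in its matched-variance Gaussian
approximation plus read noise. They do not emulate nuclear texture, cell
boundaries, molecule diffusion within a frame (molecules are static per
frame and repositioned between frames), spot overlap statistics of dense
nuclei, or detector artefacts. Passing tests therefore demonstrate
correctness of the estimators under the stated noise model, not
performance on real microscopy.

The published noise magnitude on TS traces is not stated numerically; the
default additive sd of 0.5 RNA equivalents is a test parameter chosen for
visual similarity to published traces, not a measured truth.

## Problem sizes and numerical choices

Tests and the acceptance script run on one CPU at sizes chosen as the
package's own desk-scale defaults: validation-movie batches of 10 movies
of ~30 molecules (the in-suite variant uses 3 movies); noiseless fit round
trips over randomized parameter sets spanning `n_pol` 3–40, `t_space`
2–12 s, `v_el` 1–6 kb/min, `t_proc` 30–200 s; 50 seeded noisy replicates
at the 19-polymerase regime; and grid-search self-consistency on the
reduced 3×2×2×2×2 endpoint grid with 3,000-cell observations (10 h, 1-s
steps) and 1,500-cell candidate simulations (5 h, 2-s steps — the
transition probabilities stay below 0.07 per step, and a power analysis
showed 300-cell simulations cannot rank 48 shape-only alternatives
reliably). Dwell-fit recoveries use 2,000–5,000 events.

Degenerate inputs are defined errors, not silent behavior: empty traces,
cycles under 8 frames, fewer than 3 pre-detected frames, a TS dark at
movie end, all-identical `n_pol` in the pooled regression, fewer than 2
χ² bins after pooling, fixed-step instability (the offending rate is
named), and an all-infeasible grid each raise with a specific message.

## Known limitations

* Strongly truncated, noisy cycles leave `n_pol` only weakly identified
  (the steady-state plateau hides the polymerase count); the duration
  heuristic recovers clean cases but noisy ones can still lock onto the
  peak-based count.
* The bi-exponential EM can merge components when the tau ratio is small
  (< ~2) or the minor weight is tiny; restarts mitigate but do not
  eliminate this.
* The χ² pooling rule (expected ≥ 5) makes the nascent p-value depend
  weakly on the pooling order at very small samples.
* `k_off2` is solved from means only; distribution-shape mismatch between
  model and data is absorbed by the grid search, not by the solver.
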