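# Methods

This note records the models smtkit implements, the assumptions behind
them, the defaults that matter, and the numerical choices made where the
design was genuinely open. Conventions: coordinates are 0-based with
pixel centers at integer coordinates; raw track tables store pixels and
frames; all analysis-facing lengths are µm and times seconds, converted
through the attached acquisition metadata (pixel size, frame interval,
exposure, emission wavelength, NA, axial detection depth dZ).

## Detection and localization

Frames are bandpass filtered with a difference of Gaussians
(`bandpass_low_px` = 1 px against pixel noise; `bandpass_high_px`
defaults to twice the Airy radius, the spot scale). The detection
Threshold applies to the *filtered* value: candidates are 3×3 local
maxima above Threshold inside the ROI, and maxima closer than one Airy
radius are merged to the brighter one so a single emitter is never fit
twice. Sub-pixel positions come from least-squares fits of an isotropic
2D Gaussian plus constant offset in a (2·`fit_window`+1)² window
(default 9×9). An isotropic PSF is the right model for diffraction-
limited emitters; windows clipped by the image edge are fit if ≥ 60% of
the window remains, otherwise dropped. Residuals are inverse-variance
weighted with var ≈ counts (shot-noise limit); without this weighting
the reported center standard errors underestimate the true scatter of
repeated fits by ~50% on Poisson-noise spots. Photometry (Airy
disk/donut means, SNR) is always computed on the **raw** frame — the
filter is for candidate finding only; intensities are physical counts.
Disk membership is d ≤ ceil(r_Airy); the donut is
ceil(r_Airy)+2 < d ≤ ceil(r_Airy)+3 (ceiling keeps the full Airy core;
the discretization is not prescribed by the formulas). "Particle
intensity" is the *mean* over the disk, matching the SNR definition as a
ratio of mean intensities.

## Linking

Within each frame pair, all (open track end, detection) pairs within the
max jump are accepted greedily in order of increasing distance; ties
break on lower detection index, then lower track id, making the result
independent of detection order. A track end stays open `gaps_to_close`
frames (default 1); the same MJ applies across a gap by default (a
conservative choice — a flag scales it by √(gap+1) instead). Closed gaps
are filled by linear interpolation and flagged `interpolated`; flagged
rows are excluded from every displacement statistic by default so no
fabricated displacement enters a histogram. Tracks shorter than
`shortest_track` (default 2) are discarded.

## QC metrics and sweeps

The SNR gate is the fraction of detections with SNR < 1.5; the
mistracking proxy is the fraction of second-nearest-neighbor distances
(tracked localization in frame n → detections in frame n+1) within MJ.
Particles whose next frame holds fewer than two detections cannot define
a second neighbor and leave the denominator. Sweep targets default to 1%
(1–5% is a reasonable range). The MJ sweep builds the second-NN distance
pool once — from a linking at the largest radius under consideration —
and treats each candidate MJ as a threshold on that fixed pool; this
makes the reported fraction exactly non-decreasing in MJ, whereas
re-linking at every radius changes the denominator and can produce small
non-monotonicities at radii too small to track anything.

## Two-state jump-distance kinetics

Displacement histograms at lags 1..6 (0.01 µm bins) are fit
simultaneously. The transition-aware variant propagates the two-state
generator [[−k_OFF, k_OFF], [k_ON, −k_ON]] over 10 sub-intervals per
frame, holding the state constant within a sub-interval; this yields the
distribution of time-spent-free within each lag, and the displacement
density is the corresponding mixture of 2D Gaussians with per-component
MSD 4(D_free·f + D_bound·(1−f))τ + 4σ². One recursion pass serves all
lags. The static variant is a two-component mixture with the bound
weight as a free parameter (Spot-On convention), with parameter bounds
D_free ∈ [0.05, 75], D_bound ∈ [1e-5, 0.05] µm²/s and localization error
∈ [0.01, 0.075] µm. Localization error enters as 2σ² variance per axis
per displacement. Defocalization: the free population is thinned by the
survival of a uniform-start molecule in an absorbing axial slab of depth
dZ (default 0.7 µm), the odd-term Fourier series truncated at 20 terms;
below Dτ/dZ² = 0.01 the series converges too slowly and the short-time
flux asymptotic 1 − (4/dZ)√(Dτ/π) is used instead. Bin probabilities are
renormalized per lag because the observed histograms are themselves
per-lag normalized. The objective is the Poisson deviance of counts
(robust in sparse tails; least squares on densities would overweight the
peak), minimized by L-BFGS-B on box-mapped parameters with 5 seeded
multistarts. Bootstrap errors resample whole tracks with replacement,
realized as per-track multiplicities applied as histogram weights (an
exact track bootstrap without rebuilding tables), each refit from the
full-data optimum. With only two estimates the sd is the plain ddof=1
sample standard deviation (= |difference|/√2).

Identifiability caveat: with 6 lags spanning ~72 ms and rates ~1 s⁻¹,
individual rates are weakly constrained but their ratio — hence
F_bound — is robust; parameter-recovery tests check F_bound, D's and σ.

## Richardson–Lucy MSD-distribution inversion

The van Hove density uses the 2D radial measure throughout
(2π∫G r dr = 1); the printed update rule is implemented with the same
polar measure, the only choice consistent with the normalization of
q(r, M). The M grid is 200 log-spaced points over [1e-5, 10] µm² and the
starting distribution is exp(−M/M₀) with M₀ the mean squared
displacement implied by the data. Each iteration enforces positivity and
renormalizes; G_sⁿ is floored at 1e-12 before division; iteration stops
at relative L1 change < 1e-6 or 2000 iterations (the forward-model L1
residual is monitored and a rare increase warns rather than aborts —
useful for noisy empirical histograms). Mobility-group boundaries are
interior local minima of P after a 3-point moving average on the log-M
axis; tracks are assigned by their time-averaged squared displacement at
the analysis lag (120 ms for fast SMT, 0.8 s for slow SMT), and group
fractions carry a 100-resample seeded track bootstrap. Power-law
exponents come from linear regression of log MSD on log τ.

## Angular anisotropy

Angles between consecutive displacement vectors are mapped to [0°, 360°);
the forward sector is [330°, 360°) ∪ [0°, 30°] and the backward sector
[150°, 210°], boundaries inclusive (a measure-zero choice).
Displacements below 1e-6 px have no direction and are skipped with a
count. AC = log₂(P_fwd/P_bwd) with a 100-resample bootstrap sd; empty
sectors give signed infinity with a warning. The spatial curve pools
lags 1..6 and bins triplets by mean jump magnitude (default 50–400 nm in
50 nm steps, minimum 100 triplets per bin). Note that localization noise
on bound molecules produces genuinely negative AC (consecutive apparent
jumps anti-correlate), so AC ≈ 0 is expected only for freely diffusing
populations.

## Dwell times and photobleaching correction

r_min is the 99th percentile (linear interpolation between order
statistics) of reference frame-to-frame displacements; N_min is the
smallest N with [1 − exp(−r_min²/4D_freeΔt)]^N < 1%, computed in log
space so near-0/near-1 regimes stay exact; r_max is the reference's 99th
percentile at lag N_min. A bound segment is a maximal run of consecutive
frames whose every frame-to-frame displacement is ≤ r_min, every in-run
N_min-lag displacement is ≤ r_max (violating windows are cut out), and
which spans at least max(N_min, 2) localizations. Closed (interpolated)
gaps do not break a run; a broken track does. Durations are
(frames − 1)·Δt. Survival uses the closed inequality S(t) = P(duration ≥ t)
on the sorted unique durations, with 2.5/97.5 bootstrap percentiles
(100 seeded resamples). The triple-exponential fit uses 10 seeded
multistarts with log-spaced rate initializations; amplitudes are kept
nonnegative by squaring and rates positive by exponentiation. The
photobleaching rate is the slowest rate among components carrying ≥ 0.1%
of the total amplitude — redundant components collapse to zero amplitude
on few-scale data and must not masquerade as the slow rate. The
correction divides by e^(−k_PB(t−t₀)) with t₀ the first survival point,
and normalization multiplies by F_bound so the intercept equals the
bound fraction.

Because r_min is a 99th percentile, ~1% of truly-bound displacements
exceed it, breaking bound runs at ~0.01/Δt per second; this loss affects
the reference and the target protein identically and is removed by the
same correction that removes bleaching — which is exactly why the
correction is calibrated on a reference survival rather than on a
fluorometric bleaching measurement.

## Diffusive-state classification

Tracks are cut into non-overlapping 7-localization sub-tracks (windows
with gaps or interpolated points are skipped; remainders dropped). The
per-axis displacement covariance is tridiagonal:
diag 2DΔt + 2σ² − 4DRΔt, off-diag −σ² + 2DRΔt, with blur coefficient
R = exposure/(6·frame interval) for uniform illumination. Since this is
a·I + b·T with T the 0/1 tridiagonal matrix, projecting displacements
once onto the discrete-sine eigenbasis makes every likelihood evaluation
a length-6 dot product; the implementation is verified against dense
multivariate-normal evaluation to 1e-8 (observed 1e-14). x and y are
independent realizations sharing parameters. The M-step minimizes the
exact weighted negative log-likelihood over (D, σ²) by a few projected
Newton steps accepting only improvements, so the EM log-likelihood is
non-decreasing by construction; σ is floored at 1e-4 µm. Defaults follow
the stated protocol: K ∈ 1..15, 50 reinitializations, 200 perturbation
proposals (log-normal jitter, sd 0.1 in log space on D and σ; Dirichlet
jitter on π; accepted on likelihood improvement, then refined by EM), 5
repeat runs with the lowest BIC kept, convergence at 1e-7 log-likelihood
change, up to 10,000 iterations. BIC = −2 logL + (3K−1)·ln(12·n_subtracks).
Sub-tracks are assigned to their maximum-posterior state only when the
top-two posterior gap exceeds 0.2; raw fractions are rescaled by F_bound
with the free population reported explicitly. States are reported sorted
by D ascending so labels are permutation-stable.

## Simulator

Emitters switch states as an exact continuous-time Markov chain
(exponential waiting times, stationary start); per-frame Brownian
increments use the occupancy-weighted diffusivity, which is *exact* for
positions sampled at frame boundaries because a Brownian increment given
a piecewise-constant D path is Gaussian with variance 2∫D dt. Observed
positions add i.i.d. Gaussian localization error; photobleaching is an
exponential clock; boundaries reflect at the FOV edges. The axial
detection slab is a *visibility* effect by default: a molecule outside
|z| ≤ dZ/2 is simply not observed that frame and may re-enter, which is
what HILO imaging does and what gap-closing trackers record. An
"absorbing" mode (gone for good) exists for studying the
absorbing-boundary defocalization correction; fitting visibility-slab
data with the absorbing-series correction at the true dZ overestimates
long-lag loss because re-entry is ignored — the reason the
parameter-recovery tests run with the slab off and an effectively
unbounded detection depth in the fit. Rendering draws each emitter as a
pixel-integrated Gaussian PSF scaled to a photon budget on a constant
background with Poisson shot noise, clipped to 16 bits.

### What the simulator does and does not emulate

It reproduces the statistical structure the analyses assume: multi-state
Markov diffusion, Gaussian localization error, exponential bleaching,
Poisson camera noise, defocalization. It does not emulate nuclear
geometry, chromatin-tethered anti-correlated (fractional) motion, dense
heterogeneous backgrounds, or drift. Passing tests therefore demonstrate
correctness of the estimators under their own model assumptions — not
robustness to every artifact of real nuclei; sub-diffusive inputs for
the power-law tests are generated analytically (fractional-Brownian
covariance via Cholesky), not mechanistically.

## Problem sizes in the test suite

The shipped tests run at desk scale, chosen to keep the full suite in a
few minutes while leaving comfortable statistical margins: ~2000 tracks
(≈ 20k–50k jumps) for isotropy/MSD/bound-fraction recovery with 30
bootstrap resamples; 10,000 sub-tracks with K swept 1..5, 10
reinitializations, 20 perturbations, one repeat run and a 300-iteration
cap for state-count selection; forward-generated van Hove mixtures for
inversion accuracy; 6000 segment durations for the dwell chain. The
library defaults remain the full protocol values listed above.

## Known limitations

* The defocalization correction uses the absorbing-slab series without
  an empirical re-entry correction; with gap closing enabled the
  effective dZ is larger than the optical sheet depth.
* Rates k_ON/k_OFF from fast-SMT lags are weakly identified individually
  (their ratio is robust); treat them as such.
* The RL inversion is unregularized; very noisy van Hove tails can
  produce spurious shoulders — the moving-average smoothing before
  minima detection mitigates but does not remove this.
* Linking is nearest-neighbor with gap closing; no global (LAP/Kalman)
  optimization, no merge/split events, no drift correction.
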