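# smtkit

Single-molecule tracking (SMT) analysis for live-cell protein dynamics:
detection and linking of single fluorophores in 2D fluorescence movies,
quantitative tracking quality control, and the downstream kinetic stack
used to characterize transcription-factor–chromatin interactions —
two-state jump-distance kinetics, Richardson–Lucy inversion of the
displacement distribution, angular anisotropy, photobleaching-corrected
dwell times, and EM classification of diffusive states. A ground-truth
simulator makes every stage testable without a microscope.

## Who it is for

Labs doing fast SMT (continuous ~10 ms imaging of HaloTag/JF-labeled
proteins under HILO illumination) and slow SMT (stroboscopic imaging of
the bound population) who want a scriptable, reproducible alternative to
GUI pipelines, with the quality-control metrics and downstream models in
one place.

## The models at the core

**Detection / linking.** Difference-of-Gaussians bandpass, thresholded
local maxima inside an ROI, sub-pixel localization by least-squares
Gaussian PSF fits (with calibrated center standard errors σx, σy;
σ_total = √(σx²+σy²) summarizes precision). Nearest-neighbor linking is
greedy shortest-first with max jump MJ, gap closing, and a minimum track
length.

**QC.** Per-detection SNR = (I_particle − I_background)/I_background with
the particle intensity averaged over the Airy disk
(r_Airy = 1.22 λ / (2 ρ NA) pixels) and the background over a donut
(r_Airy+2, r_Airy+3]. Mistracking is bounded by the fraction of
second-nearest-neighbor distances (frame n → n+1) within MJ. Both metrics
drive parameter sweeps for Threshold and MJ.

**Bound fraction.** Jump histograms at lags 1..L are fit simultaneously to
a two-state model — bound (D_bound) ⇌ free (D_free) with rates k_ON, k_OFF
and F_bound = k_ON/(k_ON+k_OFF) — either transition-aware (state occupancy
propagated within each lag) or as a static Spot-On-style mixture. Both
include localization error and axial defocalization of the free
population; errors come from a track bootstrap.

**Mobility structure.** The van Hove correlation G_s(r, τ) is expanded as
G_s = ∫P(M) q(r, M) dM with q(r, M) = (1/πM)·exp(−r²/M); Richardson–Lucy
iteration recovers P(M), whose local minima split tracks into mobility
groups; per-group ensemble MSDs are fit to MSD ~ τ^α. The anisotropy
coefficient AC = log₂[P(−30°..30°)/P(150°..210°)] quantifies directional
bias of consecutive jumps (0 for Brownian motion, negative under
confinement).

**Dwell times.** Bound-segment thresholds (r_min, N_min, r_max) are
calibrated on a stably bound reference (histone H2B): r_min is its 99th
displacement percentile, and N_min the smallest frame count for which a
free molecule passes the r_min gate with probability
p₁^N = [1 − exp(−r_min²/4DΔt)]^N below 1%. Segment-duration survival
S(t) = 1 − CDF(t) is corrected by the reference photobleaching rate k_PB
(slowest component of a triple-exponential fit):
S_corr(t) = S_raw(t)/e^(−k_PB(t−t₀)), then scaled to the bound fraction.

**Diffusive states.** 7-frame sub-tracks are classified by EM over a
camera-aware Gaussian process (static noise σ + motion blur
R = exposure/6Δt; tridiagonal displacement covariance diagonalized in the
sine basis), with random reinitializations, parameter-jitter
perturbations, and BIC selection of the state count K.

## Worked example

Simulate a half-bound two-state receptor at fast-SMT conditions and
recover its kinetics:

```python
from smtkit.simulate import two_state_config, simulate_tracks
from smtkit import jump_kinetics as jk
from smtkit.anisotropy import angles, anisotropy_coefficient

cfg = two_state_config(d_bound=0.01, d_free=5.0, k_on=1.0, k_off=1.0,
                       n_particles=2000, n_frames=12, dt_s=0.012,
                       loc_sigma_um=0.03, fov_um=50.0, seed=1)
table, truth = simulate_tracks(cfg)

hist = jk.jump_histograms(table, n_lags=6, bin_width_um=0.01)
fit = jk.fit_two_state_kinetic(hist, table.acq, seed=1)
print(f"f_bound = {fit.f_bound:.3f}  (k_on = {fit.k_on:.2f}/s, k_off = {fit.k_off:.2f}/s)")

a = angles(table, 1)
ac, sd = anisotropy_coefficient(a["theta_deg"], seed=1)
print(f"AC = {ac:.3f} +/- {sd:.3f}")
```

prints

```
f_bound = 0.510  (k_on = 0.97/s, k_off = 0.93/s)
AC = -1.046 +/- 0.038
```

The fit recovers the simulated bound fraction (truth 0.5) along with
D_free ≈ 4.9 µm²/s, D_bound ≈ 0.01 µm²/s and the 30 nm localization
error. The strongly negative AC is expected here: half the molecules are
bound, and localization noise on an immobile emitter anti-correlates
consecutive apparent jumps, biasing angles toward 180°. Pure free
diffusion gives AC ≈ 0.

The same analyses are available from the shell:

```bash
smtkit simulate --config sim.yaml --out-tracks tracks.csv --seed 1
smtkit kinetics --tracks tracks.csv --model kinetic --lags 6 --out fit.json
smtkit pipeline --config pipeline.yaml   # movie -> detect -> link -> QC -> analyses
```

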