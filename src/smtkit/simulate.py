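"""Ground-truth simulator for single-molecule tracking experiments.

Generates 2D trajectories of emitters that switch between diffusive states
under a continuous-time Markov chain, with Gaussian localization error,
exponential photobleaching, reflecting field-of-view boundaries, and an
optional rendering step that turns the truth into 16-bit camera frames
(Gaussian PSF + Poisson shot noise), emulating HILO acquisition.

Given the piecewise-constant diffusivity along a state path, the
displacement of a Brownian particle over one frame is Gaussian with
per-axis variance ``2 * integral(D dt)``; the simulator therefore draws
per-frame increments from the occupancy-weighted diffusivity, which is
exact for positions sampled at frame boundaries even when states switch
within a frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AcquisitionParams, TrackTable


@dataclass
class SimConfig:
    """Configuration of a multi-state diffusion simulation.

    ``diffusivities`` lists per-state D in µm²/s; ``labels`` names each state
    ("bound"/"free"); ``rates`` is the generator matrix Q (s⁻¹) with
    Q[i, j] the switching rate from state i to state j (diagonal ignored,
    rebuilt so rows sum to zero).
    """

    diffusivities: tuple[float, ...] = (0.01, 5.0)
    labels: tuple[str, ...] = ("bound", "free")
    rates: np.ndarray | None = None  # KxK generator, s^-1
    n_particles: int = 200
    n_frames: int = 20
    dt_s: float = 0.012
    loc_sigma_um: float = 0.03
    bleach_rate_s: float = 0.0
    fov_um: float = 25.0
    axial_slab_um: float | None = None  # detection slab depth dZ (µm); None = off
    axial_mode: str = "visible"  # "visible": re-entry allowed; "absorbing": lost for good
    substeps: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.diffusivities)
        if any(d < 0 for d in self.diffusivities):
            raise ValueError("diffusivities must be >= 0")
        if self.rates is None:
            self.rates = np.zeros((k, k))
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (k, k):
            raise ValueError("rates must be KxK")
        if np.any(self.rates - np.diag(np.diag(self.rates)) < 0):
            raise ValueError("off-diagonal switching rates must be >= 0")
        np.fill_diagonal(self.rates, 0.0)
        np.fill_diagonal(self.rates, -self.rates.sum(axis=1))

    @property
    def n_states(self) -> int:
        return len(self.diffusivities)

    def stationary_distribution(self) -> np.ndarray:
        q = self.rates
        if np.allclose(q, 0):
            return np.full(self.n_states, 1.0 / self.n_states)
        # left null vector of Q
        a = np.vstack([q.T, np.ones(self.n_states)])
        b = np.zeros(self.n_states + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0, None)
        return pi / pi.sum()


def two_state_config(
    d_bound: float = 0.01,
    d_free: float = 5.0,
    k_on: float = 1.0,
    k_off: float = 1.0,
    **kwargs,
) -> SimConfig:
    """Bound + free two-state config; ``k_on`` is free→bound, ``k_off`` bound→free."""
    rates = np.array([[0.0, k_off], [k_on, 0.0]])
    return SimConfig(diffusivities=(d_bound, d_free), labels=("bound", "free"), rates=rates, **kwargs)


@dataclass
class SimTruth:
    """Ground truth: per-particle-per-frame positions, states and alive flags."""

    df: pd.DataFrame  # particle, frame, true_x_um, true_y_um, true_state, alive
    bleach_time_s: np.ndarray  # per particle
    config: SimConfig

    def state_fractions(self) -> np.ndarray:
        alive = self.df[self.df["alive"]]
        counts = np.bincount(alive["true_state"].to_numpy(), minlength=self.config.n_states)
        return counts / max(counts.sum(), 1)


def _sample_state_path(rng, q, pi, t_end):
    """Exact CTMC path: (event_times, states) with event_times[0] = 0."""
    k = q.shape[0]
    times = [0.0]
    states = [int(rng.choice(k, p=pi))]
    t = 0.0
    while True:
        s = states[-1]
        rate = -q[s, s]
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= t_end:
            break
        p = q[s].copy()
        p[s] = 0.0
        p /= p.sum()
        times.append(t)
        states.append(int(rng.choice(k, p=p)))
    return np.array(times), np.array(states, dtype=int)


def _occupancy_per_interval(event_times, states, edges, k):
    """Time spent in each state within each [edges[i], edges[i+1]) interval."""
    n_int = len(edges) - 1
    occ = np.zeros((n_int, k))
    seg_start = event_times
    seg_end = np.append(event_times[1:], edges[-1])
    for t0, t1, s in zip(seg_start, seg_end, states):
        if t1 <= edges[0] or t0 >= edges[-1]:
            continue
        i0 = max(int(np.searchsorted(edges, t0, side="right")) - 1, 0)
        i1 = min(int(np.searchsorted(edges, t1, side="left")), n_int)
        for i in range(i0, i1):
            lo = max(t0, edges[i])
            hi = min(t1, edges[i + 1])
            if hi > lo:
                occ[i, s] += hi - lo
    return occ


def simulate_tracks(config: SimConfig, acq: AcquisitionParams | None = None) -> tuple[TrackTable, SimTruth]:
    """Simulate observed tracks plus ground truth.

    Returns a :class:`TrackTable` (observed = true + localization error, in
    pixels) and a :class:`SimTruth`. Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    if acq is None:
        # without an axial slab the virtual detection depth is effectively
        # unbounded; 100 µm makes the defocalization correction negligible
        acq = AcquisitionParams(
            frame_interval_s=config.dt_s,
            exposure_s=config.dt_s,
            axial_range_um=config.axial_slab_um or 100.0,
        )
    k = config.n_states
    d = np.asarray(config.diffusivities)
    pi = config.stationary_distribution()
    dt = config.dt_s
    sub = max(int(config.substeps), 1)
    dt_sub = dt / sub
    t_end = config.n_frames * dt
    edges = np.arange(config.n_frames * sub + 1) * dt_sub

    rows_particle, rows_frame = [], []
    true_x_all, true_y_all, state_all, alive_all = [], [], [], []
    bleach_times = np.full(config.n_particles, np.inf)
    if config.bleach_rate_s > 0:
        bleach_times = rng.exponential(1.0 / config.bleach_rate_s, size=config.n_particles)

    half_slab = config.axial_slab_um / 2.0 if config.axial_slab_um else None

    for p in range(config.n_particles):
        if np.allclose(config.rates, 0):
            s0 = int(rng.choice(k, p=pi))
            occ = np.zeros((config.n_frames * sub, k))
            occ[:, s0] = dt_sub
            ev_t, ev_s = np.array([0.0]), np.array([s0])
        else:
            ev_t, ev_s = _sample_state_path(rng, config.rates, pi, t_end)
            occ = _occupancy_per_interval(ev_t, ev_s, edges, k)
        # per-substep effective variance: 2 * sum_k D_k * time_in_k
        var_sub = 2.0 * occ @ d  # µm², per axis
        steps_x = rng.normal(0.0, 1.0, size=len(var_sub)) * np.sqrt(var_sub)
        steps_y = rng.normal(0.0, 1.0, size=len(var_sub)) * np.sqrt(var_sub)
        x0 = rng.uniform(0, config.fov_um)
        y0 = rng.uniform(0, config.fov_um)
        xs = x0 + np.concatenate([[0.0], np.cumsum(steps_x)])
        ys = y0 + np.concatenate([[0.0], np.cumsum(steps_y)])
        # reflecting boundaries via folding
        xs = _reflect(xs, config.fov_um)
        ys = _reflect(ys, config.fov_um)
        xs = xs[::sub][: config.n_frames]
        ys = ys[::sub][: config.n_frames]

        # dominant state per frame
        occ_frame = occ.reshape(config.n_frames, sub, k).sum(axis=1)
        dom = occ_frame.argmax(axis=1)

        frame_times = np.arange(config.n_frames) * dt
        alive = frame_times < bleach_times[p]
        if half_slab is not None:
            # axial diffusion through the detection sheet: a molecule outside
            # the slab is simply not observed that frame and may re-enter
            z = np.concatenate([[rng.uniform(-half_slab, half_slab)], np.zeros(len(var_sub))])
            z[1:] = rng.normal(0.0, 1.0, size=len(var_sub)) * np.sqrt(var_sub)
            z = np.cumsum(z)
            z_frames = z[::sub][: config.n_frames]
            outside = np.abs(z_frames) > half_slab
            if config.axial_mode == "absorbing":
                outside = np.maximum.accumulate(outside)
            alive = alive & ~outside

        rows_particle.append(np.full(config.n_frames, p))
        rows_frame.append(np.arange(config.n_frames))
        true_x_all.append(xs)
        true_y_all.append(ys)
        state_all.append(dom)
        alive_all.append(alive)

    if not rows_particle:
        rows_particle = [np.array([], dtype=int)]
        rows_frame = [np.array([], dtype=int)]
        true_x_all, true_y_all = [np.array([])], [np.array([])]
        state_all = [np.array([], dtype=int)]
        alive_all = [np.array([], dtype=bool)]
    truth_df = pd.DataFrame(
        {
            "particle": np.concatenate(rows_particle),
            "frame": np.concatenate(rows_frame),
            "true_x_um": np.concatenate(true_x_all),
            "true_y_um": np.concatenate(true_y_all),
            "true_state": np.concatenate(state_all),
            "alive": np.concatenate(alive_all),
        }
    )
    truth = SimTruth(df=truth_df, bleach_time_s=bleach_times, config=config)

    obs = truth_df[truth_df["alive"]].copy()
    n_obs = len(obs)
    px = acq.pixel_size_um
    obs_x = obs["true_x_um"].to_numpy() + rng.normal(0, config.loc_sigma_um, n_obs)
    obs_y = obs["true_y_um"].to_numpy() + rng.normal(0, config.loc_sigma_um, n_obs)
    table_df = pd.DataFrame(
        {
            "track_id": obs["particle"].to_numpy(),
            "frame": obs["frame"].to_numpy(),
            "x_px": obs_x / px,
            "y_px": obs_y / px,
            "sigma_x_px": config.loc_sigma_um / px,
            "sigma_y_px": config.loc_sigma_um / px,
            "interpolated": False,
            "true_state": obs["true_state"].to_numpy(),
            "true_x_px": obs["true_x_um"].to_numpy() / px,
            "true_y_px": obs["true_y_um"].to_numpy() / px,
        }
    )
    # drop 1-frame leftovers so the table satisfies shortest_track >= 2
    sizes = table_df.groupby("track_id")["frame"].transform("size")
    table_df = table_df[sizes >= 2].reset_index(drop=True)
    return TrackTable(table_df, acq), truth


def _reflect(x: np.ndarray, box: float) -> np.ndarray:
    """Fold coordinates back into [0, box] (reflecting boundary)."""
    period = 2.0 * box
    x = np.mod(x, period)
    return np.where(x > box, period - x, x)


def render_movie(
    truth: SimTruth,
    acq: AcquisitionParams,
    psf_sigma_px: float = 1.3,
    photons_per_frame: float = 500.0,
    background_level: float = 100.0,
    fov_px: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Render ground-truth positions into a 16-bit camera movie.

    Each alive emitter becomes a pixel-integrated 2D Gaussian carrying
    ``photons_per_frame`` counts on a constant background; Poisson shot
    noise is applied to the whole frame. Values above 65535 are clipped.
    """
    from scipy.special import erf

    rng = np.random.default_rng(seed)
    px = acq.pixel_size_um
    if fov_px is None:
        fov_px = int(np.ceil(truth.config.fov_um / px))
    n_frames = truth.config.n_frames
    movie = np.zeros((n_frames, fov_px, fov_px), dtype=float)
    movie += background_level

    df = truth.df[truth.df["alive"]]
    half = int(np.ceil(4 * psf_sigma_px))
    s2 = psf_sigma_px * np.sqrt(2.0)
    for frame, grp in df.groupby("frame"):
        img = movie[int(frame)]
        for xu, yu in zip(grp["true_x_um"], grp["true_y_um"]):
            xc, yc = xu / px, yu / px
            ix, iy = int(round(xc)), int(round(yc))
            x_lo, x_hi = max(ix - half, 0), min(ix + half + 1, fov_px)
            y_lo, y_hi = max(iy - half, 0), min(iy + half + 1, fov_px)
            if x_lo >= x_hi or y_lo >= y_hi:
                continue
            xg = np.arange(x_lo, x_hi)
            yg = np.arange(y_lo, y_hi)
            fx = 0.5 * (erf((xg + 0.5 - xc) / s2) - erf((xg - 0.5 - xc) / s2))
            fy = 0.5 * (erf((yg + 0.5 - yc) / s2) - erf((yg - 0.5 - yc) / s2))
            img[np.ix_(yg, xg)] += photons_per_frame * np.outer(fy, fx)

    noisy = rng.poisson(movie).astype(np.float64)
    return np.clip(noisy, 0, 65535).astype(np.uint16)
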