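"""Two-state (bound + free) kinetic modeling of jump-distance histograms.

Displacement histograms at lags 1..L frames are fit simultaneously to a
two-state model of molecules switching between a bound state (diffusivity
D_bound) and a free state (D_free) with rates k_ON (free→bound) and k_OFF
(bound→free). Two model variants are provided:

* ``kinetic`` — transition-aware: within a lag the state occupancy evolves
  under the 2×2 Markov generator; the displacement density is a mixture
  over the fraction of the lag spent free, computed by discretizing each
  frame interval into sub-intervals. The bound fraction is the stationary
  occupancy F_bound = k_ON / (k_ON + k_OFF).
* ``spoton`` — a static two-component mixture (no switching within a lag),
  in the style of the Spot-On tool; F_bound is a direct mixture weight.

Both variants include localization error (per-axis variance σ² added per
localization) and the axial defocalization depletion of the free
population: a molecule diffusing out of the detection slab of depth dZ is
lost, thinning long jumps. Fit errors come from bootstrapping tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core import AcquisitionParams, TrackTable

#: Default parameter bounds (Spot-On two-state conventions).
DEFAULT_BOUNDS = {
    "d_free": (0.05, 75.0),  # µm²/s
    "d_bound": (1e-5, 0.05),  # µm²/s
    "loc_error": (0.01, 0.075),  # µm
    "k_on": (0.005, 500.0),  # 1/s
    "k_off": (0.005, 500.0),  # 1/s
}

N_SUBSTEPS_PER_FRAME = 10
N_DEFOC_TERMS = 20


@dataclass
class JumpHistogramSet:
    bin_edges_um: np.ndarray
    counts: np.ndarray  # (n_lags, n_bins)
    n_jumps: np.ndarray  # per lag
    dt_base_s: float
    lags: np.ndarray  # frame lags, 1..L

    @property
    def n_lags(self) -> int:
        return len(self.lags)

    def densities(self) -> np.ndarray:
        """Counts normalized to probability densities per lag."""
        widths = np.diff(self.bin_edges_um)
        return self.counts / np.maximum(self.n_jumps[:, None], 1) / widths


@dataclass
class TwoStateFit:
    k_on: float  # 1/s, free -> bound
    k_off: float  # 1/s, bound -> free
    d_bound: float  # µm²/s
    d_free: float  # µm²/s
    loc_error_um: float
    f_bound: float
    model_variant: str  # "kinetic" | "spoton"
    objective: float
    success: bool
    bootstrap_sd: dict[str, float] | None = None
    boundary_hit: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {
            "k_on": self.k_on,
            "k_off": self.k_off,
            "d_bound": self.d_bound,
            "d_free": self.d_free,
            "loc_error_um": self.loc_error_um,
            "f_bound": self.f_bound,
        }


def bound_fraction(k_on: float, k_off: float) -> float:
    """Stationary bound fraction F_bound = k_ON / (k_ON + k_OFF)."""
    if k_on < 0 or k_off < 0:
        raise ValueError("rates must be >= 0")
    if k_on == 0 and k_off == 0:
        raise ValueError("bound fraction undefined when both rates are zero")
    return k_on / (k_on + k_off)


def jump_histograms(
    table: TrackTable,
    n_lags: int = 6,
    bin_width_um: float = 0.01,
    r_max_um: float | None = None,
) -> JumpHistogramSet:
    """Displacement histograms at lags 1..n_lags (uniform bins, µm).

    Jumps spanning interpolated (gap-closed) localizations are excluded.
    Lags with no jumps are dropped with a warning.
    """
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    per_lag = []
    lags = []
    for lag in range(1, n_lags + 1):
        r = table.displacements(lag)["r_um"].to_numpy()
        if len(r) == 0:
            warnings.warn(f"no jumps at lag {lag}; lag dropped")
            continue
        per_lag.append(r)
        lags.append(lag)
    if not per_lag:
        raise ValueError("no displacements at any lag")
    if r_max_um is None:
        r_max_um = float(max(np.quantile(r, 0.999) for r in per_lag)) * 1.2
    r_max_um = max(r_max_um, 3 * bin_width_um)  # degenerate (all-zero) data
    edges = np.arange(0.0, r_max_um + bin_width_um, bin_width_um)
    counts = np.stack([np.histogram(r, bins=edges)[0] for r in per_lag])
    return JumpHistogramSet(
        bin_edges_um=edges,
        counts=counts.astype(float),
        n_jumps=np.array([len(r) for r in per_lag], dtype=float),
        dt_base_s=table.acq.frame_interval_s,
        lags=np.array(lags),
    )


def defocalization_survival(d_tau_um2: np.ndarray | float, dz_um: float, n_terms: int = N_DEFOC_TERMS) -> np.ndarray:
    """Fraction of molecules still inside an absorbing axial slab.

    Uniform start inside a slab of depth dZ with absorbing walls; the
    survival after accumulating axial diffusion D·τ is the odd-term
    Fourier series truncated at ``n_terms`` terms. For very small
    depletion (Dτ/dZ² < 0.01) the series converges too slowly, so the
    short-time boundary-flux asymptotic S ≈ 1 − (4/dZ)·sqrt(Dτ/π) is used
    instead.
    """
    d_tau = np.atleast_1d(np.asarray(d_tau_um2, dtype=float))
    x = d_tau / dz_um**2
    n = 2 * np.arange(n_terms) + 1  # 1, 3, 5, ...
    coef = 8.0 / (n**2 * np.pi**2)
    expo = np.exp(-np.outer(d_tau, (n * np.pi / dz_um) ** 2))
    series = expo @ coef
    asymptotic = 1.0 - 4.0 * np.sqrt(np.maximum(x, 0.0) / np.pi)
    out = np.where(x < 0.01, asymptotic, series)
    return np.clip(out, 0.0, 1.0)


def _free_time_weights(k_on: float, k_off: float, max_frames: int, dt: float, n_sub: int = N_SUBSTEPS_PER_FRAME):
    """Distribution of time spent free within lags of 1..max_frames frames.

    The frame interval is split into ``n_sub`` sub-intervals; the state is
    held constant within a sub-interval and propagated between them by the
    exact 2-state transition matrix. Starting from the stationary
    occupancy, returns for each lag m an array w[j] = P(j of the m·n_sub
    sub-intervals were spent free), j = 0..m·n_sub.
    """
    s = k_on + k_off
    delta = dt / n_sub
    if s == 0:
        pi_b, pi_f = 0.5, 0.5
        p_stay_b = p_stay_f = 1.0
    else:
        pi_b = k_on / s
        pi_f = k_off / s
        decay = np.exp(-s * delta)
        # P[i, j]: from state i to state j over one sub-interval (b=0, f=1)
        p_stay_b = pi_b + decay * pi_f
        p_stay_f = pi_f + decay * pi_b
    p_bf = 1.0 - p_stay_b
    p_fb = 1.0 - p_stay_f

    n_steps = max_frames * n_sub
    # w[state, j]: prob of state after i sub-intervals with j free sub-intervals
    w = np.zeros((2, n_steps + 1))
    w[0, 0] = pi_b
    w[1, 0] = pi_f
    out = {}
    for i in range(1, n_steps + 1):
        nb = np.zeros_like(w)
        # occupy current sub-interval in current state, then transition
        nb[0, :] += w[0] * p_stay_b
        nb[1, :] += w[0] * p_bf
        nb[0, 1:] += w[1, :-1] * p_fb
        nb[1, 1:] += w[1, :-1] * p_stay_f
        w = nb
        if i % n_sub == 0:
            m = i // n_sub
            out[m] = w.sum(axis=0)[: i + 1].copy()
    return out


def _bin_probabilities(edges: np.ndarray, msd_comps: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Probability mass per radial bin for a mixture of 2D Gaussians.

    Component c has CDF(r) = 1 - exp(-r²/M_c); masses are renormalized to
    sum to 1 over the histogram support (matching per-lag normalized
    counts, as the observed histograms are themselves truncated).
    """
    cdf = 1.0 - np.exp(-np.outer(edges**2, 1.0 / np.maximum(msd_comps, 1e-12)))
    mass = np.diff(cdf, axis=0) @ weights
    total = mass.sum()
    return mass / total if total > 0 else np.full(len(edges) - 1, 1.0 / (len(edges) - 1))


def predict_histograms(
    params: dict[str, float],
    hist: JumpHistogramSet,
    acq: AcquisitionParams,
    variant: str = "kinetic",
) -> np.ndarray:
    """Model bin probabilities (n_lags, n_bins) for either variant."""
    dt = hist.dt_base_s
    dz = acq.axial_range_um
    d_b, d_f, sig = params["d_bound"], params["d_free"], params["loc_error"]
    edges = hist.bin_edges_um
    out = np.empty_like(hist.counts)

    if variant == "kinetic":
        wdict = _free_time_weights(params["k_on"], params["k_off"], int(hist.lags.max()), dt)
        for li, m in enumerate(hist.lags):
            w = wdict[int(m)]
            tau = m * dt
            frac_free = np.arange(len(w)) / (len(w) - 1)
            msd = 4.0 * (d_f * frac_free + d_b * (1.0 - frac_free)) * tau + 4.0 * sig**2
            # free molecules defocalize in proportion to their free time
            z = defocalization_survival(d_f * frac_free * tau, dz)
            out[li] = _bin_probabilities(edges, msd, w * z)
    elif variant == "spoton":
        f_b = params["f_bound"]
        for li, m in enumerate(hist.lags):
            tau = m * dt
            msd = np.array([4.0 * d_b * tau + 4.0 * sig**2, 4.0 * d_f * tau + 4.0 * sig**2])
            z_free = defocalization_survival(d_f * tau, dz)[0]
            out[li] = _bin_probabilities(edges, msd, np.array([f_b, (1.0 - f_b) * z_free]))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return out


def _poisson_deviance(counts: np.ndarray, n_jumps: np.ndarray, probs: np.ndarray) -> float:
    mu = np.maximum(n_jumps[:, None] * probs, 1e-12)
    c = counts
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(c > 0, c * np.log(c / mu), 0.0)
    return float(2.0 * np.sum(mu - c + term))


def _fit_variant(
    hist: JumpHistogramSet,
    acq: AcquisitionParams,
    variant: str,
    bounds: dict,
    n_starts: int,
    seed: int,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, float, bool]:
    if variant == "kinetic":
        names = ["k_on", "k_off", "d_bound", "d_free", "loc_error"]
    else:
        names = ["f_bound", "d_bound", "d_free", "loc_error"]

    lo = np.array([bounds.get(n, (0.01, 0.99))[0] for n in names])
    hi = np.array([bounds.get(n, (0.01, 0.99))[1] for n in names])
    if variant == "spoton":
        lo[0], hi[0] = 1e-4, 1.0 - 1e-4

    def unpack(z):
        # log-scale interpolation for rate/diffusivity params, linear for fractions
        p = {}
        for i, n in enumerate(names):
            if n in ("f_bound", "loc_error"):
                p[n] = lo[i] + (hi[i] - lo[i]) * z[i]
            else:
                p[n] = lo[i] * (hi[i] / lo[i]) ** z[i]
        return p

    def objective(z):
        z = np.clip(z, 0.0, 1.0)
        probs = predict_histograms(unpack(z), hist, acq, variant)
        return _poisson_deviance(hist.counts, hist.n_jumps, probs)

    rng = np.random.default_rng(seed)
    best = None
    starts = []
    if x0 is not None:
        starts.append(np.clip(x0, 0.0, 1.0))
    while len(starts) < n_starts:
        starts.append(rng.uniform(0.05, 0.95, size=len(names)))
    for z0 in starts:
        res = minimize(
            objective,
            z0,
            method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * len(names),
            options={"maxiter": 300, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x, float(best.fun), bool(best.success)


def _make_fit(z, fun, ok, variant, bounds) -> TwoStateFit:
    if variant == "kinetic":
        names = ["k_on", "k_off", "d_bound", "d_free", "loc_error"]
    else:
        names = ["f_bound", "d_bound", "d_free", "loc_error"]
    lo = np.array([bounds.get(n, (1e-4, 1 - 1e-4))[0] for n in names])
    hi = np.array([bounds.get(n, (1e-4, 1 - 1e-4))[1] for n in names])
    p = {}
    hit = []
    for i, n in enumerate(names):
        if n in ("f_bound", "loc_error"):
            p[n] = lo[i] + (hi[i] - lo[i]) * float(np.clip(z[i], 0, 1))
        else:
            p[n] = lo[i] * (hi[i] / lo[i]) ** float(np.clip(z[i], 0, 1))
        if z[i] < 1e-3 or z[i] > 1 - 1e-3:
            hit.append(n)
    if hit:
        warnings.warn(f"fit parameter(s) at bounds: {hit}")
    if variant == "kinetic":
        f_b = bound_fraction(p["k_on"], p["k_off"])
        return TwoStateFit(p["k_on"], p["k_off"], p["d_bound"], p["d_free"], p["loc_error"],
                           f_b, "kinetic", fun, ok, boundary_hit=hit)
    return TwoStateFit(np.nan, np.nan, p["d_bound"], p["d_free"], p["loc_error"],
                       p["f_bound"], "spoton", fun, ok, boundary_hit=hit)


def fit_two_state_kinetic(
    hist: JumpHistogramSet,
    acq: AcquisitionParams,
    bounds: dict | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> TwoStateFit:
    """Transition-aware two-state fit of multi-lag jump histograms.

    Minimizes the Poisson deviance of observed vs model-predicted counts
    across all lags simultaneously, with ``n_starts`` seeded random
    multistarts. Requires at least 2 lags so the transition rates are
    identifiable from the lag dependence.
    """
    if hist.n_lags < 2:
        raise ValueError("kinetic fit needs histograms at >= 2 lags")
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    z, fun, ok = _fit_variant(hist, acq, "kinetic", bounds, n_starts, seed)
    if not ok:
        warnings.warn("kinetic fit optimizer reported non-convergence; best point returned")
    return _make_fit(z, fun, ok, "kinetic", bounds)


def fit_two_state_spoton(
    hist: JumpHistogramSet,
    acq: AcquisitionParams,
    bounds: dict | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> TwoStateFit:
    """Static two-component mixture fit (Spot-On style, no transitions)."""
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    z, fun, ok = _fit_variant(hist, acq, "spoton", bounds, n_starts, seed)
    return _make_fit(z, fun, ok, "spoton", bounds)


def bootstrap_fit(
    table: TrackTable,
    variant: str = "kinetic",
    n_boot: int = 100,
    n_lags: int = 6,
    bin_width_um: float = 0.01,
    bounds: dict | None = None,
    seed: int = 0,
) -> tuple[TwoStateFit, dict[str, float]]:
    """Fit plus per-parameter bootstrap standard deviations.

    Tracks are resampled with replacement ``n_boot`` times and the
    histograms refit, each refit starting from the full-data optimum
    (single start). A resample is realized as per-track multiplicities
    applied as histogram weights — an exact track bootstrap without
    rebuilding the table. More than 20% resample failures aborts.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    hist = jump_histograms(table, n_lags=n_lags, bin_width_um=bin_width_um)
    fit_fn = fit_two_state_kinetic if variant == "kinetic" else fit_two_state_spoton
    full = fit_fn(hist, table.acq, bounds=bounds, n_starts=5, seed=seed)
    z_full, _, _ = _fit_variant(hist, table.acq, variant, bounds, 1, seed,
                                x0=_pack(full, bounds, variant))

    # per-lag displacement pools with their source track index
    track_ids = table.df["track_id"].unique()
    tid_index = {t: i for i, t in enumerate(track_ids)}
    pools = []
    for lag in hist.lags:
        disp = table.displacements(int(lag))
        pools.append(
            (disp["r_um"].to_numpy(), disp["track_id"].map(tid_index).to_numpy())
        )

    rng = np.random.default_rng(seed + 1)
    samples: list[dict[str, float]] = []
    failures = 0
    for _ in range(n_boot):
        mult = np.bincount(
            rng.integers(0, len(track_ids), size=len(track_ids)), minlength=len(track_ids)
        ).astype(float)
        counts = np.stack(
            [np.histogram(r, bins=hist.bin_edges_um, weights=mult[t])[0] for r, t in pools]
        )
        n_jumps = np.array([mult[t].sum() for _, t in pools])
        if np.any(n_jumps == 0):
            failures += 1
            continue
        bh = JumpHistogramSet(hist.bin_edges_um, counts, n_jumps, hist.dt_base_s, hist.lags)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                z, fun, ok = _fit_variant(bh, table.acq, variant, bounds, 1, seed, x0=z_full)
                samples.append(_make_fit(z, fun, ok, variant, bounds).as_dict())
        except Exception:
            failures += 1
    if failures > 0.2 * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap refits failed")
    sd = {
        k: float(np.nanstd([s[k] for s in samples], ddof=1))
        for k in samples[0]
    }
    full.bootstrap_sd = sd
    return full, sd


def _pack(fit: TwoStateFit, bounds: dict, variant: str) -> np.ndarray:
    names = (["k_on", "k_off", "d_bound", "d_free", "loc_error"] if variant == "kinetic"
             else ["f_bound", "d_bound", "d_free", "loc_error"])
    vals = fit.as_dict()
    vals["loc_error"] = vals.pop("loc_error_um")
    z = []
    for n in names:
        lo, hi = bounds.get(n, (1e-4, 1 - 1e-4))
        v = np.clip(vals[n], lo, hi)
        if n in ("f_bound", "loc_error"):
            z.append((v - lo) / (hi - lo))
        else:
            z.append(np.log(v / lo) / np.log(hi / lo))
    return np.clip(np.array(z), 0.0, 1.0)
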