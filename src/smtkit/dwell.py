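"""Residence-time analysis for slow-SMT data.

Pipeline: calibrate bound-motion thresholds on a stably chromatin-bound
reference (histone H2B), call bound segments in transcription-factor
tracks, compile the survival distribution S(t) = 1 - CDF(t) of segment
durations, estimate the photobleaching rate k_PB as the slowest rate of a
triple-exponential fit to the reference survival, correct the TF survival
for bleaching, and normalize its intercept to the bound fraction.

Threshold calibration: r_min is the 99th percentile of reference
frame-to-frame displacements. A freely diffusing molecule (diffusivity
D_free) stays below r_min in one frame interval Δt with probability
p1 = 1 - exp(-r_min² / (4 D_free Δt)); N_min is the smallest number of
consecutive frames for which p1^N_min drops below the misclassification
bound (1% by default). r_max is the 99th percentile of reference
displacements at lag N_min and removes slow drifters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import TrackTable


@dataclass(frozen=True)
class BoundCallParams:
    r_min_um: float
    n_min: int
    r_max_um: float
    d_free_um2s: float = 5.0
    p_cut: float = 0.01

    def __post_init__(self) -> None:
        if self.r_min_um > self.r_max_um:
            raise ValueError("r_min must be <= r_max")
        if self.n_min < 1:
            raise ValueError("n_min must be >= 1")
        if not (0 < self.p_cut < 1):
            raise ValueError("p_cut must be in (0, 1)")


@dataclass
class SurvivalCurve:
    t_s: np.ndarray
    s: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    variant: str = "raw"  # raw | bleach_corrected | normalized
    k_pb: float | None = None
    f_bound: float | None = None
    n_segments: int = 0


@dataclass
class TripleExpFit:
    amplitudes: np.ndarray  # A1..A3, matched to rates
    rates: np.ndarray  # k1 >= k2 >= k3 (1/s)
    ssr: float
    success: bool

    @property
    def k_pb(self) -> float:
        """Photobleaching rate: the slowest decay rate carrying weight.

        Components with amplitude below 1e-3 of the total are vestigial
        (redundant components collapse to zero amplitude when the data hold
        fewer than three scales) and are ignored.
        """
        total = self.amplitudes.sum()
        real = self.rates[self.amplitudes > 1e-3 * total]
        return float(real[-1]) if len(real) else float(self.rates[-1])

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.sum(self.amplitudes[:, None] * np.exp(-np.outer(self.rates, t)), axis=0)


def calibrate_rmin(reference: TrackTable, percentile: float = 99.0) -> float:
    """99th percentile of reference frame-to-frame displacements (µm).

    Linear interpolation between order statistics (numpy default).
    """
    r = reference.displacements(1)["r_um"].to_numpy()
    if len(r) < 100:
        raise ValueError(f"need >= 100 displacements to calibrate r_min, got {len(r)}")
    return float(np.percentile(r, percentile))


def compute_nmin(r_min_um: float, d_free_um2s: float, dt_s: float, p_cut: float = 0.01) -> int:
    """Smallest N with p1^N < p_cut, p1 = 1 - exp(-r_min²/(4 D Δt)).

    Computed in log space so the result stays exact even when p1 is very
    close to 0 or 1 (where a naive power loop would stall on rounding).
    """
    if min(r_min_um, d_free_um2s, dt_s) <= 0 or not (0 < p_cut <= 1):
        raise ValueError("all arguments must be positive, p_cut in (0, 1]")
    x = (r_min_um**2) / (4.0 * d_free_um2s * dt_s)
    p1 = -np.expm1(-x)
    if p1 <= 0.0 or p_cut == 1.0:
        return 1
    # log p1 = log(1 - e^-x); for large x, log(1 - eps) ~ -eps = -e^-x
    log_p1 = float(np.log1p(-np.exp(-x))) if x < 30 else float(-np.exp(-x))
    ratio = np.log(p_cut) / log_p1
    if log_p1 >= 0.0 or not np.isfinite(ratio) or ratio > 1e15:
        raise ValueError(
            "r_min is so large relative to sqrt(4 D dt) that N_min overflows; "
            "this threshold would never exclude a free molecule"
        )
    n = max(int(np.floor(ratio)) + 1, 1)
    # settle the strict inequality at the floating-point edge
    while n > 1 and (n - 1) * log_p1 < np.log(p_cut):
        n -= 1
    while n * log_p1 >= np.log(p_cut):
        n += 1
    return n


def per_frame_bound_probability(r_min_um: float, d_free_um2s: float, dt_s: float) -> float:
    """p1 = 1 - exp(-r_min²/(4 D Δt)): chance a free molecule stays within r_min."""
    return float(-np.expm1(-(r_min_um**2) / (4.0 * d_free_um2s * dt_s)))


def calibrate_rmax(reference: TrackTable, n_min: int, percentile: float = 99.0) -> float:
    """99th percentile of reference displacements at lag ``n_min`` (µm)."""
    r = reference.displacements(n_min)["r_um"].to_numpy()
    if len(r) == 0:
        raise ValueError(f"no reference track has {n_min + 1}+ localizations")
    return float(np.percentile(r, percentile))


def calibrate_bound_call(
    reference: TrackTable, d_free_um2s: float = 5.0, p_cut: float = 0.01
) -> BoundCallParams:
    """Full threshold calibration (r_min, N_min, r_max) from a reference table."""
    r_min = calibrate_rmin(reference)
    n_min = compute_nmin(r_min, d_free_um2s, reference.acq.frame_interval_s, p_cut)
    r_max = max(calibrate_rmax(reference, n_min), r_min)
    return BoundCallParams(r_min_um=r_min, n_min=n_min, r_max_um=r_max, d_free_um2s=d_free_um2s, p_cut=p_cut)


def call_bound_segments(table: TrackTable, params: BoundCallParams) -> pd.DataFrame:
    """Bound segments: (track_id, start_frame, end_frame, n_frames, duration_s).

    A segment is a maximal run of consecutive frames in which every lag-1
    displacement is <= r_min and every in-run lag-N_min displacement is
    <= r_max, at least max(N_min, 2) localizations long. Gap-closed
    (interpolated) localizations do not break a run; a broken track does.
    Duration = (n_frames - 1) · Δt.
    """
    px = table.acq.pixel_size_um
    dt = table.acq.frame_interval_s
    r_min_px = params.r_min_um / px
    r_max_px = params.r_max_um / px
    nmin = params.n_min
    min_loc = max(nmin, 2)

    out = []
    for tid, grp in table.df.groupby("track_id"):
        frames = grp["frame"].to_numpy()
        x = grp["x_px"].to_numpy(dtype=float)
        y = grp["y_px"].to_numpy(dtype=float)
        if len(frames) < min_loc:
            continue
        step_ok = (np.diff(frames) == 1) & (np.hypot(np.diff(x), np.diff(y)) <= r_min_px)
        # maximal runs of consecutive ok steps
        for i0, i1 in _runs_true(step_ok):
            # localizations i0 .. i1+1 inclusive
            lo, hi = i0, i1 + 1
            valid = np.ones(hi - lo + 1, dtype=bool)
            if hi - lo >= nmin:
                for i in range(lo, hi - nmin + 1):
                    d = np.hypot(x[i + nmin] - x[i], y[i + nmin] - y[i])
                    if d > r_max_px:
                        valid[i - lo : i - lo + nmin + 1] = False
            for j0, j1 in _runs_true(valid):
                n_loc = j1 - j0 + 1
                if n_loc < min_loc:
                    continue
                a, b = lo + j0, lo + j1
                out.append((tid, int(frames[a]), int(frames[b]), n_loc, (n_loc - 1) * dt))
    return pd.DataFrame(out, columns=["track_id", "start_frame", "end_frame", "n_frames", "duration_s"])


def _runs_true(mask: np.ndarray):
    """Yield (start, stop) inclusive index pairs of maximal True runs."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.insert(idx[breaks + 1], 0, idx[0])
    stops = np.append(idx[breaks], idx[-1])
    yield from zip(starts, stops)


def survival(segments: pd.DataFrame | np.ndarray, n_boot: int = 100, seed: int = 0) -> SurvivalCurve:
    """Raw survival S(t) = fraction of segment durations >= t.

    Evaluated on the sorted unique durations; the 95% CI comes from
    ``n_boot`` seeded bootstrap resamples of segments (2.5/97.5
    percentiles).
    """
    if isinstance(segments, pd.DataFrame):
        durations = segments["duration_s"].to_numpy(dtype=float)
    else:
        durations = np.asarray(segments, dtype=float)
    if len(durations) == 0:
        raise ValueError("no bound segments")
    t = np.unique(durations)
    s = _survival_at(durations, t)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(t)))
    for b in range(n_boot):
        res = rng.choice(durations, size=len(durations), replace=True)
        boots[b] = _survival_at(res, t)
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    return SurvivalCurve(t_s=t, s=s, ci_low=lo, ci_high=hi, variant="raw", n_segments=len(durations))


def _survival_at(durations: np.ndarray, t: np.ndarray) -> np.ndarray:
    srt = np.sort(durations)
    # fraction >= t  (closed at t)
    return 1.0 - np.searchsorted(srt, t, side="left") / len(srt)


def fit_triple_exponential(curve: SurvivalCurve, n_starts: int = 10, seed: int = 0) -> TripleExpFit:
    """Fit S(t) ≈ A1 e^(-k1 t) + A2 e^(-k2 t) + A3 e^(-k3 t).

    Nonlinear least squares with ``n_starts`` seeded multistarts (rates
    initialized log-spaced over the observed time range, amplitudes from
    the data scale); the best sum of squared residuals wins. Rates are
    returned sorted descending, so ``rates[-1]`` is the slowest decay —
    the photobleaching rate when the input is the reference survival.
    """
    t, s = curve.t_s, curve.s
    if len(t) < 10:
        raise ValueError("need >= 10 time points for a triple-exponential fit")
    if np.ptp(s) < 1e-12:
        raise ValueError("survival curve is constant; triple-exponential fit is degenerate")
    rng = np.random.default_rng(seed)
    t_span = max(t.max() - t.min(), t[t > 0].min() if np.any(t > 0) else 1.0)

    def resid(theta):
        a = theta[:3] ** 2  # amplitudes >= 0 via squaring
        k = np.exp(theta[3:])
        return np.sum(a[:, None] * np.exp(-np.outer(k, t)), axis=0) - s

    best = None
    k_anchor = np.log(np.array([10.0, 1.0, 0.1]) / t_span)
    for i in range(n_starts):
        jitter = rng.normal(0, 0.5, size=3) if i else np.zeros(3)
        theta0 = np.concatenate([np.sqrt(np.full(3, s[0] / 3.0)), k_anchor + jitter])
        try:
            res = least_squares(resid, theta0, max_nfev=5000)
        except Exception:
            continue
        ssr = float(np.sum(res.fun**2))
        if best is None or ssr < best[0]:
            best = (ssr, res)
    if best is None:
        raise RuntimeError("triple-exponential fit failed for every start")
    ssr, res = best
    amps = res.x[:3] ** 2
    rates = np.exp(res.x[3:])
    order = np.argsort(rates)[::-1]
    return TripleExpFit(amplitudes=amps[order], rates=rates[order], ssr=ssr, success=res.success)


def photobleach_correct(raw: SurvivalCurve, k_pb: float, t0: float | None = None) -> SurvivalCurve:
    """Divide out the bleaching decay: S_corr(t) = S_raw(t) / e^(-k_PB (t - t0)).

    ``t0`` defaults to the first point of the survival curve, so
    S_corr(t0) = S_raw(t0). The CI is transformed identically.
    """
    if k_pb < 0:
        raise ValueError("k_pb must be >= 0")
    if t0 is None:
        t0 = float(raw.t_s[0])
    factor = np.exp(k_pb * (raw.t_s - t0))
    return replace(
        raw,
        s=raw.s * factor,
        ci_low=raw.ci_low * factor,
        ci_high=raw.ci_high * factor,
        variant="bleach_corrected",
        k_pb=k_pb,
    )


def normalize_to_bound_fraction(curve: SurvivalCurve, f_bound: float) -> SurvivalCurve:
    """Scale the survival so its y-intercept equals the bound fraction."""
    if not (0 < f_bound <= 1):
        raise ValueError("f_bound must be in (0, 1]")
    return replace(
        curve,
        s=curve.s * f_bound,
        ci_low=curve.ci_low * f_bound,
        ci_high=curve.ci_high * f_bound,
        variant="normalized",
        f_bound=f_bound,
    )
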