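"""Richardson-Lucy inversion of the displacement distribution.

The self-part of the van Hove correlation G_s(r, τ) — the probability
density of single-molecule displacements at lag τ — is modeled as a
superposition of 2D Gaussians

    G_s(r, τ) = ∫ P(M) q(r, M) dM,    q(r, M) = (1/(πM)) exp(-r²/M),

where M is the (per-molecule) mean-squared displacement at that lag and
P(M) the density of MSDs across the ensemble. P(M) is recovered by the
Richardson-Lucy iteration

    P_{n+1}(M) = P_n(M) ∫ [G_s(r) / G_s^n(r)] q(r, M) 2πr dr,

starting from P_0(M) ∝ exp(-M/M0), with positivity and normalization
enforced at every step. Local minima of the converged P(M) partition
tracks into mobility groups; per-group ensemble MSDs are then fit to a
power law MSD ~ τ^α.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .core import TrackTable

EPS_FLOOR = 1e-12


@dataclass
class VanHove:
    r_um: np.ndarray  # bin centers
    g: np.ndarray  # density, normalized so 2π ∫ g r dr = 1
    lag_s: float
    n_jumps: int


@dataclass
class MSDDistribution:
    m_um2: np.ndarray  # log-spaced MSD grid
    p: np.ndarray  # density over M, ∫ p dM = 1
    lag_s: float
    n_iterations: int
    converged: bool
    residual_l1: float = np.nan


@dataclass
class MobilityGroups:
    boundaries_um2: np.ndarray  # M values at P(M) local minima, sorted
    labels: pd.Series  # track_id -> group (1 = lowest mobility)
    fractions: np.ndarray
    fractions_sd: np.ndarray
    track_msd_um2: pd.Series = field(default=None)

    @property
    def n_groups(self) -> int:
        return len(self.boundaries_um2) + 1


def van_hove(
    table: TrackTable,
    lag_frames: int = 1,
    r_edges_um: np.ndarray | None = None,
) -> VanHove:
    """Displacement density at a lag, with the 2D radial normalization."""
    disp = table.displacements(lag_frames)
    if len(disp) == 0:
        raise ValueError(f"no displacements at lag {lag_frames}")
    r = disp["r_um"].to_numpy()
    if r_edges_um is None:
        r_max = max(np.quantile(r, 0.999) * 1.5, r.max() * 1.01)
        r_edges_um = np.linspace(0.0, r_max, 151)
    counts, edges = np.histogram(r, bins=r_edges_um)
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    # counts/N = G(r) * 2π r Δr
    with np.errstate(divide="ignore", invalid="ignore"):
        g = counts / (len(r) * 2.0 * np.pi * centers * widths)
    g[~np.isfinite(g)] = 0.0
    return VanHove(r_um=centers, g=g, lag_s=lag_frames * table.acq.frame_interval_s, n_jumps=len(r))


def default_m_grid(n: int = 200, m_lo: float = 1e-5, m_hi: float = 10.0) -> np.ndarray:
    return np.logspace(np.log10(m_lo), np.log10(m_hi), n)


def _trapz_weights(x: np.ndarray) -> np.ndarray:
    w = np.zeros_like(x)
    dx = np.diff(x)
    w[:-1] += dx / 2.0
    w[1:] += dx / 2.0
    return w


def rl_invert(
    vhc: VanHove,
    m_grid_um2: np.ndarray | None = None,
    m0_um2: float | None = None,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> MSDDistribution:
    """Invert a van Hove density into an MSD distribution P(M).

    ``m0_um2`` sets the scale of the exponential starting guess; it
    defaults to the median squared displacement of the data. Iteration
    stops when the relative L1 change of P drops below ``tol``. The L1
    residual between the measured and forward-modeled van Hove is
    monitored; an increase triggers a warning but not an abort.
    """
    if m_grid_um2 is None:
        m_grid_um2 = default_m_grid()
    m = np.asarray(m_grid_um2, dtype=float)
    r = vhc.r_um
    g_obs = np.clip(vhc.g, 0.0, None)

    if m0_um2 is None:
        # median M consistent with the observed density: median r² works as a scale
        w_r = 2.0 * np.pi * r * _trapz_weights(r)
        m0_um2 = float(np.sum(g_obs * w_r * r**2) / max(np.sum(g_obs * w_r), EPS_FLOOR))
        m0_um2 = max(m0_um2, m[0])

    w_m = _trapz_weights(m)  # integration over M
    w_r = 2.0 * np.pi * r * _trapz_weights(r)  # 2D radial integration over r
    kernel = np.exp(-np.outer(r**2, 1.0 / m)) / (np.pi * m)[None, :]  # q(r_i, M_j)

    p = np.exp(-m / m0_um2)
    p /= np.sum(p * w_m)

    converged = False
    prev_resid = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        g_model = kernel @ (p * w_m)
        ratio = g_obs / np.clip(g_model, EPS_FLOOR, None)
        update = (ratio * w_r) @ kernel  # ∫ ratio(r) q(r,M) 2πr dr
        p_new = np.clip(p * update, 0.0, None)
        norm = np.sum(p_new * w_m)
        if norm <= 0:
            raise RuntimeError("RL iteration collapsed to zero density")
        p_new /= norm
        change = np.sum(np.abs(p_new - p) * w_m)
        resid = np.sum(np.abs(g_obs - g_model) * w_r)
        if resid > prev_resid * (1.0 + 1e-9) and it > 5:
            warnings.warn(f"RL residual increased at iteration {it}")
        prev_resid = resid
        p = p_new
        if change < tol:
            converged = True
            break

    return MSDDistribution(
        m_um2=m, p=p, lag_s=vhc.lag_s, n_iterations=it, converged=converged, residual_l1=prev_resid
    )


def find_group_boundaries(pm: MSDDistribution, smoothing: int = 3) -> np.ndarray:
    """M values at interior local minima of P(M) on the log-M axis.

    A light moving-average smoothing (window ``smoothing``) suppresses
    single-cell ripple before minima detection; endpoints are excluded.
    An empty array means a single mobility group.
    """
    p = pm.p
    if smoothing and smoothing > 1:
        kern = np.ones(smoothing) / smoothing
        p = np.convolve(p, kern, mode="same")
    # minima of p = peaks of -p; ignore near-zero plateaus at the grid edges
    occupied = p > p.max() * 1e-6
    idx_min, _ = signal.find_peaks(-p)
    idx_min = [i for i in idx_min if occupied[:i].any() and occupied[i + 1 :].any()]
    return pm.m_um2[np.asarray(idx_min, dtype=int)] if idx_min else np.array([])


def track_msd_at_lag(table: TrackTable, lag_frames: int) -> pd.Series:
    """Per-track time-averaged squared displacement (µm²) at a lag."""
    disp = table.displacements(lag_frames)
    if len(disp) == 0:
        return pd.Series(dtype=float)
    return disp.assign(r2=disp["r_um"] ** 2).groupby("track_id")["r2"].mean()


def classify_tracks(
    table: TrackTable,
    boundaries_um2: np.ndarray,
    lag_frames: int = 1,
    n_boot: int = 100,
    seed: int = 0,
) -> MobilityGroups:
    """Assign each track to the mobility group containing its MSD at the lag.

    Group 1 is the lowest-mobility bin. Tracks shorter than the lag are
    excluded (their count is in ``labels.attrs["n_excluded"]``). Group
    fractions carry a seeded bootstrap sd over tracks.
    """
    boundaries = np.sort(np.asarray(boundaries_um2, dtype=float))
    msd = track_msd_at_lag(table, lag_frames)
    n_excluded = table.n_tracks - len(msd)
    if len(msd) == 0:
        raise ValueError("no track has enough localizations at this lag")
    labels = pd.Series(
        np.searchsorted(boundaries, msd.to_numpy()) + 1, index=msd.index, name="rl_group"
    )
    labels.attrs["n_excluded"] = n_excluded
    n_groups = len(boundaries) + 1
    lab_arr = labels.to_numpy()
    fractions = np.bincount(lab_arr - 1, minlength=n_groups) / len(lab_arr)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, n_groups))
    for b in range(n_boot):
        res = rng.choice(lab_arr, size=len(lab_arr), replace=True)
        boots[b] = np.bincount(res - 1, minlength=n_groups) / len(res)
    return MobilityGroups(
        boundaries_um2=boundaries,
        labels=labels,
        fractions=fractions,
        fractions_sd=boots.std(axis=0, ddof=1),
        track_msd_um2=msd,
    )


def ensemble_msd(table: TrackTable, max_lag: int, track_ids=None) -> pd.DataFrame:
    """Ensemble MSD(τ) with s.e.m. over displacements, optionally restricted."""
    rows = []
    for lag in range(1, max_lag + 1):
        disp = table.displacements(lag)
        if track_ids is not None:
            disp = disp[disp["track_id"].isin(track_ids)]
        if len(disp) == 0:
            continue
        r2 = disp["r_um"].to_numpy() ** 2
        rows.append(
            (lag, lag * table.acq.frame_interval_s, r2.mean(), r2.std(ddof=1) / np.sqrt(len(r2)), len(r2))
        )
    return pd.DataFrame(rows, columns=["lag", "tau_s", "msd_um2", "sem_um2", "n"])


def group_msd_powerlaw(
    table: TrackTable,
    groups: MobilityGroups,
    max_lag: int = 6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group ensemble MSD curves and power-law fits MSD = c · τ^α.

    Returns (fit table, curve table). α comes from linear regression of
    log MSD on log τ; groups with fewer than 3 lag points are skipped.
    """
    fits, curves = [], []
    for grp in range(1, groups.n_groups + 1):
        ids = groups.labels.index[groups.labels == grp]
        if len(ids) == 0:
            continue
        msd = ensemble_msd(table, max_lag, track_ids=ids)
        msd.insert(0, "group", grp)
        curves.append(msd)
        valid = msd[msd["msd_um2"] > 0]
        if len(valid) < 3:
            continue
        res = stats.linregress(np.log(valid["tau_s"]), np.log(valid["msd_um2"]))
        fits.append((grp, res.slope, float(np.exp(res.intercept)), res.stderr, len(ids)))
    fit_df = pd.DataFrame(fits, columns=["group", "alpha", "prefactor_um2", "alpha_stderr", "n_tracks"])
    curve_df = pd.concat(curves, ignore_index=True) if curves else pd.DataFrame()
    return fit_df, curve_df
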