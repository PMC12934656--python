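"""Angular-displacement statistics.

The angle formed by three successive localizations (two consecutive jump
vectors) is isotropic for pure Brownian motion; confined or anisotropic
motion biases it. The anisotropy coefficient (AC) summarizes the bias as

    AC = log2[ P(-30° <= θ <= 30°) / P(150° <= θ <= 210°) ],

the log2 ratio of forward to backward turning probabilities. AC = 0 for
Brownian motion, AC < 0 for confined motion (backward bias).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import TrackTable

#: Displacements shorter than this (pixels) have no defined direction.
ZERO_DISP_PX = 1e-6


def angles(table: TrackTable, lag: int = 1) -> pd.DataFrame:
    """Turning angles between consecutive displacement vectors at a lag.

    Returns a DataFrame with ``theta_deg`` in [0, 360) (0 = continuing
    forward, 180 = full reversal) and ``mean_disp_um``, the mean magnitude
    of the two jumps, used for spatial binning. Triplets containing a
    zero-length displacement are skipped; their count is in
    ``df.attrs["n_undefined"]``.
    """
    disp = table.displacements(lag)
    thetas, mean_disp, n_undef = [], [], 0
    for _, grp in disp.groupby("track_id"):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        dx = grp["dx"].to_numpy()
        dy = grp["dy"].to_numpy()
        r_um = grp["r_um"].to_numpy()
        # consecutive vector pairs: displacement at frame f followed by f+lag
        nxt = {f: i for i, f in enumerate(frames)}
        for i, f in enumerate(frames):
            j = nxt.get(f + lag)
            if j is None:
                continue
            r1 = np.hypot(dx[i], dy[i])
            r2 = np.hypot(dx[j], dy[j])
            if r1 < ZERO_DISP_PX or r2 < ZERO_DISP_PX:
                n_undef += 1
                continue
            ang = np.degrees(np.arctan2(dy[j], dx[j]) - np.arctan2(dy[i], dx[i]))
            thetas.append(ang % 360.0)
            mean_disp.append(0.5 * (r_um[i] + r_um[j]))
    out = pd.DataFrame({"theta_deg": thetas, "mean_disp_um": mean_disp})
    out.attrs["n_undefined"] = n_undef
    return out


def angles_pooled(table: TrackTable, n_lags: int = 6) -> pd.DataFrame:
    """Angles pooled over lags 1..n_lags (for the spatial anisotropy curve)."""
    parts = [angles(table, lag) for lag in range(1, n_lags + 1)]
    return pd.concat(parts, ignore_index=True) if parts else angles(table, 1)


def _ac_from_angles(theta_deg: np.ndarray) -> float:
    theta = np.asarray(theta_deg, dtype=float) % 360.0
    fwd = np.mean((theta >= 330.0) | (theta <= 30.0))
    bwd = np.mean((theta >= 150.0) & (theta <= 210.0))
    if bwd == 0 or fwd == 0:
        warnings.warn("forward or backward sector empty; AC is infinite")
        return np.inf if bwd == 0 else -np.inf
    return float(np.log2(fwd / bwd))


def anisotropy_coefficient(
    theta_deg: np.ndarray | pd.Series,
    n_boot: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Anisotropy coefficient with a bootstrap standard deviation.

    The sd comes from ``n_boot`` resamples (with replacement) of the angle
    triplets; infinite resample values (an empty sector) are excluded.
    """
    theta = np.asarray(theta_deg, dtype=float)
    if len(theta) == 0:
        raise ValueError("no angles provided")
    ac = _ac_from_angles(theta)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b = _ac_from_angles(rng.choice(theta, size=len(theta), replace=True))
        if np.isfinite(b):
            boots.append(b)
    sd = float(np.std(boots, ddof=1)) if len(boots) > 1 else np.nan
    return ac, sd


def polar_histogram(theta_deg, bin_width_deg: float = 10.0) -> pd.DataFrame:
    """Binned angle counts (36 bins of 10° by default) for polar plots."""
    edges = np.arange(0.0, 360.0 + bin_width_deg, bin_width_deg)
    counts, _ = np.histogram(np.asarray(theta_deg) % 360.0, bins=edges)
    return pd.DataFrame({"theta_lo_deg": edges[:-1], "theta_hi_deg": edges[1:], "count": counts})


def spatial_anisotropy(
    pairs: pd.DataFrame,
    distance_edges_um: np.ndarray | None = None,
    min_count: int = 100,
    n_boot: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """AC as a function of mean displacement magnitude.

    ``pairs`` is the output of :func:`angles` / :func:`angles_pooled`.
    Default bins span 50–400 nm in 50 nm steps. Bins holding fewer than
    ``min_count`` triplets are reported with NaN AC.
    """
    if distance_edges_um is None:
        distance_edges_um = np.arange(0.05, 0.4001, 0.05)
    edges = np.asarray(distance_edges_um, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = pairs[(pairs["mean_disp_um"] >= lo) & (pairs["mean_disp_um"] < hi)]
        if len(sel) < min_count:
            rows.append((lo, hi, len(sel), np.nan, np.nan))
            continue
        ac, sd = anisotropy_coefficient(sel["theta_deg"].to_numpy(), n_boot=n_boot, seed=seed)
        rows.append((lo, hi, len(sel), ac, sd))
    return pd.DataFrame(rows, columns=["r_lo_um", "r_hi_um", "n", "ac", "ac_sd"])
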