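"""Diffusive-state classification of sub-tracks by perturbation EM.

Tracks are cut into non-overlapping sub-tracks of 7 localizations (6
displacements per axis). Each sub-track is modeled as a draw from one of K
diffusive states; within a state the per-axis displacement vector is a
zero-mean multivariate normal with the camera-aware covariance

    diagonal        2 D Δt + 2 σ² − 4 D R Δt
    first off-diag  −σ² + 2 D R Δt
    zero beyond,

where σ is the static localization noise and R = exposure/(6·Δt) the
motion-blur coefficient for uniform illumination. Because that covariance
is ``a·I + b·T`` with T the 0/1 tridiagonal matrix, its eigenbasis is the
discrete sine transform; projecting each displacement vector once makes
every likelihood evaluation O(n) per sub-track.

EM estimates (π_k, D_k, σ_k) and per-sub-track posteriors; random
reinitializations plus parameter-jitter perturbations guard against local
optima; the Bayesian information criterion selects K. Sub-tracks whose top
two posteriors differ by less than a gap threshold are left unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import TrackTable

SIGMA_FLOOR_UM = 1e-4
D_FLOOR = 1e-9


@dataclass
class SubTrackSet:
    """Sub-track displacements (N, 2 axes, n_disp) in µm plus provenance."""

    disp_um: np.ndarray
    pos_um: np.ndarray  # (N, 2, n_disp+1) positions, for per-state MSDs
    meta: pd.DataFrame  # parent track_id, start_frame
    dt_s: float
    exposure_s: float

    def __len__(self) -> int:
        return self.disp_um.shape[0]

    @property
    def n_disp(self) -> int:
        return self.disp_um.shape[2]

    @property
    def blur_coefficient(self) -> float:
        return self.exposure_s / self.dt_s / 6.0


@dataclass
class StateModel:
    k: int
    d_um2s: np.ndarray  # sorted ascending
    sigma_um: np.ndarray
    pi: np.ndarray
    posteriors: np.ndarray  # (N, K)
    log_likelihood: float
    bic: float
    converged: bool
    n_iterations: int
    settings: dict = field(default_factory=dict)


def split_subtracks(table: TrackTable, split_length: int = 7) -> SubTrackSet:
    """Cut tracks into non-overlapping windows of ``split_length`` localizations.

    Windows must consist of consecutive frames with no interpolated
    (gap-closed) localizations; trailing remainders shorter than
    ``split_length`` are dropped, as are tracks shorter than it.
    """
    if split_length < 3:
        raise ValueError("split_length must be >= 3")
    px = table.acq.pixel_size_um
    disp, pos, meta = [], [], []
    for tid, grp in table.df.groupby("track_id"):
        frames = grp["frame"].to_numpy()
        x = grp["x_px"].to_numpy(dtype=float) * px
        y = grp["y_px"].to_numpy(dtype=float) * px
        interp = grp["interpolated"].to_numpy(dtype=bool)
        i = 0
        while i + split_length <= len(frames):
            f = frames[i : i + split_length]
            if np.any(np.diff(f) != 1) or np.any(interp[i : i + split_length]):
                i += 1  # slide past the defect, realign on clean data
                continue
            xs = x[i : i + split_length]
            ys = y[i : i + split_length]
            pos.append(np.stack([xs, ys]))
            disp.append(np.stack([np.diff(xs), np.diff(ys)]))
            meta.append((tid, int(f[0])))
            i += split_length
    n = len(disp)
    shape_d = (n, 2, split_length - 1)
    shape_p = (n, 2, split_length)
    return SubTrackSet(
        disp_um=np.array(disp).reshape(shape_d) if n else np.empty(shape_d),
        pos_um=np.array(pos).reshape(shape_p) if n else np.empty(shape_p),
        meta=pd.DataFrame(meta, columns=["track_id", "start_frame"]),
        dt_s=table.acq.frame_interval_s,
        exposure_s=table.acq.exposure_s,
    )


def _sine_basis(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Eigenbasis of the 0/1 tridiagonal matrix T (DST-I): (U, cosines)."""
    k = np.arange(1, n + 1)
    i = np.arange(1, n + 1)
    u = np.sqrt(2.0 / (n + 1)) * np.sin(np.outer(i, k) * np.pi / (n + 1))
    c = np.cos(k * np.pi / (n + 1))
    return u, c


def _eigvals(d, s2, dt, blur, cos):
    """Covariance eigenvalues λ_k = D·g_k + σ²·h_k (both coefficients >= 0)."""
    g = 2.0 * dt * (1.0 - 2.0 * blur * (1.0 - cos))
    h = 2.0 * (1.0 - cos)
    return d * g + s2 * h, g, h


def _state_loglik(z2sum, d, s2, dt, blur, cos):
    """Per-sub-track log-likelihood (both axes) for one state."""
    lam, _, _ = _eigvals(d, s2, dt, blur, cos)
    lam = np.maximum(lam, 1e-300)
    const = -np.sum(np.log(2.0 * np.pi * lam))  # per axis
    return const - 0.5 * z2sum @ (1.0 / lam)


def _mstep_update(d0, s20, s_k, dt, blur, cos, n_steps: int = 8):
    """Minimize sum_k [log λ_k + s_k/λ_k] over (D, σ²) by projected Newton.

    ``s_k`` is the responsibility-weighted mean squared DST coefficient per
    mode. Only improving steps are taken, so EM monotonicity is preserved.
    """
    g = 2.0 * dt * (1.0 - 2.0 * blur * (1.0 - cos))
    h = 2.0 * (1.0 - cos)
    lo = np.array([D_FLOOR, SIGMA_FLOOR_UM**2])

    def fval(p):
        lam = p[0] * g + p[1] * h
        if lam.min() <= 0:
            return np.inf
        return (np.log(lam) + s_k / lam).sum()

    p = np.maximum(np.array([d0, s20]), lo)
    f = fval(p)
    for _ in range(n_steps):
        lam = p[0] * g + p[1] * h
        w = 1.0 / lam - s_k / lam**2
        grad = np.array([np.sum(g * w), np.sum(h * w)])
        w2 = -1.0 / lam**2 + 2.0 * s_k / lam**3
        hess = np.array(
            [[np.sum(g * g * w2), np.sum(g * h * w2)], [np.sum(g * h * w2), np.sum(h * h * w2)]]
        )
        try:
            step = np.linalg.solve(hess + 1e-12 * np.eye(2), -grad)
        except np.linalg.LinAlgError:
            step = -grad
        if not np.all(np.isfinite(step)) or step @ grad > 0:
            step = -grad * np.minimum(p, 1.0)  # scaled gradient fallback
        t = 1.0
        improved = False
        for _ in range(20):
            cand = np.maximum(p + t * step, lo)
            fc = fval(cand)
            if fc < f - 1e-15:
                p, f = cand, fc
                improved = True
                break
            t *= 0.5
        if not improved:
            break
        if np.linalg.norm(t * step) < 1e-14:
            break
    return p[0], p[1]


def em_fit(
    subtracks: SubTrackSet,
    k: int,
    seed: int = 0,
    max_iter: int = 10000,
    tol: float = 1e-7,
    init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> StateModel:
    """Fit a K-state mixture to sub-track displacements by EM.

    The x and y displacement sequences are independent realizations sharing
    parameters. Convergence: absolute log-likelihood change below ``tol``
    (default 1e-7) or ``max_iter`` iterations. The log-likelihood is
    non-decreasing by construction (only improving M-step updates are
    accepted).
    """
    n = len(subtracks)
    if k < 1 or n < k:
        raise ValueError("need k >= 1 and at least k sub-tracks")
    nd = subtracks.n_disp
    dt, blur = subtracks.dt_s, subtracks.blur_coefficient
    u, cos = _sine_basis(nd)
    z = np.einsum("nad,dk->nak", subtracks.disp_um, u)
    z2sum = np.sum(z**2, axis=1)  # (N, nd): summed over both axes

    rng = np.random.default_rng(seed)
    if init is None:
        msd1 = np.mean(subtracks.disp_um**2) * 2  # per-pair scale
        d_hi = max(msd1 / (2 * dt), 1e-3)
        d = np.sort(np.exp(rng.uniform(np.log(max(d_hi * 1e-4, D_FLOOR)), np.log(d_hi), k)))
        sig = rng.uniform(0.01, 0.075, k)
        pi = np.full(k, 1.0 / k)
    else:
        d, sig, pi = (np.array(v, dtype=float) for v in init)
    s2 = sig**2

    loglik_prev = -np.inf
    log_post = np.zeros((n, k))
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        for j in range(k):
            log_post[:, j] = np.log(max(pi[j], 1e-300)) + _state_loglik(z2sum, d[j], s2[j], dt, blur, cos)
        mx = log_post.max(axis=1)
        resp = np.exp(log_post - mx[:, None])
        tot = resp.sum(axis=1)
        loglik = float((mx + np.log(tot)).sum())
        resp /= tot[:, None]
        pi = resp.mean(axis=0)
        for j in range(k):
            w = resp[:, j]
            tot = w.sum()
            if tot < 1e-12:
                continue
            s_k = (w @ z2sum) / (2.0 * tot)  # mean over N weighted, 2 axes
            d[j], s2[j] = _mstep_update(d[j], s2[j], s_k, dt, blur, cos)
        if abs(loglik - loglik_prev) < tol:
            converged = True
            loglik_prev = loglik
            break
        loglik_prev = loglik

    order = np.argsort(d)
    d, s2, pi = d[order], s2[order], pi[order]
    for j in range(k):
        log_post[:, j] = np.log(max(pi[j], 1e-300)) + _state_loglik(z2sum, d[j], s2[j], dt, blur, cos)
    norm = logsumexp(log_post, axis=1)
    loglik = float(np.sum(norm))
    posteriors = np.exp(log_post - norm[:, None])
    n_params = 3 * k - 1
    bic = -2.0 * loglik + n_params * np.log(n * 2 * nd)
    return StateModel(
        k=k,
        d_um2s=d,
        sigma_um=np.sqrt(s2),
        pi=pi,
        posteriors=posteriors,
        log_likelihood=loglik,
        bic=bic,
        converged=converged,
        n_iterations=it,
        settings={"max_iter": max_iter, "tol": tol, "seed": seed},
    )


def _loglik_at(subtracks, d, s2, pi, z2sum, cos):
    dt, blur = subtracks.dt_s, subtracks.blur_coefficient
    lp = np.stack(
        [np.log(max(pi[j], 1e-300)) + _state_loglik(z2sum, d[j], s2[j], dt, blur, cos) for j in range(len(d))],
        axis=1,
    )
    return float(np.sum(logsumexp(lp, axis=1)))


def select_model(
    subtracks: SubTrackSet,
    k_range: range | list[int] = range(1, 16),
    n_reinit: int = 50,
    n_perturb: int = 200,
    n_runs: int = 5,
    seed: int = 0,
    max_iter: int = 10000,
    tol: float = 1e-7,
) -> StateModel:
    """BIC model selection over K with reinitializations and perturbations.

    For each K: ``n_reinit`` random EM starts, each followed by
    ``n_perturb`` parameter-jitter proposals (log-normal on D and σ,
    Dirichlet on π; accepted when the likelihood improves, then refined by
    EM). The whole sweep is repeated ``n_runs`` times and the run with the
    lowest overall BIC is returned.
    """
    u, cos = _sine_basis(subtracks.n_disp)
    z = np.einsum("nad,dk->nak", subtracks.disp_um, u)
    z2sum = np.sum(z**2, axis=1)

    best_overall = None
    master = np.random.default_rng(seed)
    for _ in range(n_runs):
        run_seed = int(master.integers(2**31 - 1))
        rng = np.random.default_rng(run_seed)
        best_run = None
        for k in k_range:
            best_k = None
            for _ in range(n_reinit):
                model = em_fit(subtracks, k, seed=int(rng.integers(2**31 - 1)), max_iter=max_iter, tol=tol)
                d, s2, pi = model.d_um2s.copy(), model.sigma_um.copy() ** 2, model.pi.copy()
                ll = model.log_likelihood
                accepted = False
                for _ in range(n_perturb):
                    d_p = np.maximum(d * np.exp(rng.normal(0, 0.1, k)), D_FLOOR)
                    s2_p = np.maximum(s2 * np.exp(rng.normal(0, 0.2, k)), SIGMA_FLOOR_UM**2)
                    pi_p = rng.dirichlet(np.maximum(pi, 1e-3) * 50)
                    ll_p = _loglik_at(subtracks, d_p, s2_p, pi_p, z2sum, cos)
                    if ll_p > ll:
                        d, s2, pi, ll = d_p, s2_p, pi_p, ll_p
                        accepted = True
                if accepted:
                    model = em_fit(
                        subtracks, k, seed=0, max_iter=max_iter, tol=tol, init=(d, np.sqrt(s2), pi)
                    )
                if best_k is None or model.log_likelihood > best_k.log_likelihood:
                    best_k = model
            if best_run is None or best_k.bic < best_run.bic:
                best_run = best_k
        if best_overall is None or best_run.bic < best_overall.bic:
            best_overall = best_run
    return best_overall


def assign_states(model: StateModel, gap: float = 0.2) -> np.ndarray:
    """Per-sub-track state labels (1-based) or 0 = unassigned.

    A sub-track is assigned to its maximum-posterior state only when the
    difference between its two highest posteriors exceeds ``gap``.
    """
    post = model.posteriors
    if model.k == 1:
        return np.ones(len(post), dtype=int)
    srt = np.sort(post, axis=1)
    confident = (srt[:, -1] - srt[:, -2]) > gap
    labels = post.argmax(axis=1) + 1
    labels[~confident] = 0
    return labels


def state_fractions(labels: np.ndarray, k: int) -> np.ndarray:
    """Occupancy fractions over assigned sub-tracks only."""
    assigned = labels[labels > 0]
    if len(assigned) == 0:
        raise ValueError("no sub-track passed the posterior-gap filter")
    return np.bincount(assigned - 1, minlength=k) / len(assigned)


def normalized_state_fractions(
    labels: np.ndarray, k: int, f_bound: float, n_boot: int = 100, seed: int = 0
) -> pd.DataFrame:
    """State fractions rescaled so they sum to the bound fraction.

    The slow-SMT sub-tracks only sample the bound population, so raw state
    fractions are multiplied by f_bound and the free population is
    reported as an explicit ``unbound`` row of weight 1 - f_bound.
    Bootstrap sd over sub-tracks, seeded.
    """
    if not (0 < f_bound <= 1):
        raise ValueError("f_bound must be in (0, 1]")
    frac = state_fractions(labels, k)
    rng = np.random.default_rng(seed)
    assigned = labels[labels > 0]
    boots = np.empty((n_boot, k))
    for b in range(n_boot):
        res = rng.choice(assigned, size=len(assigned), replace=True)
        boots[b] = np.bincount(res - 1, minlength=k) / len(res)
    sd = boots.std(axis=0, ddof=1) * f_bound
    rows = [(f"state_{j + 1}", frac[j] * f_bound, sd[j]) for j in range(k)]
    rows.append(("unbound", 1.0 - f_bound, np.nan))
    return pd.DataFrame(rows, columns=["state", "fraction", "fraction_sd"])


def state_msd(subtracks: SubTrackSet, labels: np.ndarray, max_lag: int | None = None) -> pd.DataFrame:
    """Ensemble MSD(τ) per assigned state with s.e.m.

    States are indexed as given by ``labels`` (already sorted by
    diffusivity in :func:`em_fit`); empty states are omitted.
    """
    n_loc = subtracks.pos_um.shape[2]
    if max_lag is None:
        max_lag = n_loc - 1
    rows = []
    for state in sorted(set(labels) - {0}):
        sel = subtracks.pos_um[labels == state]
        for lag in range(1, min(max_lag, n_loc - 1) + 1):
            diff = sel[:, :, lag:] - sel[:, :, :-lag]
            r2 = np.sum(diff**2, axis=1).ravel()
            rows.append(
                (state, lag, lag * subtracks.dt_s, r2.mean(), r2.std(ddof=1) / np.sqrt(len(r2)), len(r2))
            )
    return pd.DataFrame(rows, columns=["state", "lag", "tau_s", "msd_um2", "sem_um2", "n"])
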