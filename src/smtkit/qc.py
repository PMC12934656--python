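"""Quantitative tracking quality control.

Two families of metrics, computable per movie or on an ensemble:

* **SNR photometry** — for each detection, the particle intensity is the
  mean raw-frame intensity over the Airy disk (radius
  r_Airy = 1.22 λ / (2 ρ NA) pixels) and the local background the mean
  over a donut with radii (r_Airy + 2, r_Airy + 3];
  SNR = (I_particle − I_background)/I_background. The fraction of
  detections with SNR below a cutoff (1.5) gauges whether bona fide
  particles are being detected.
* **Second-nearest-neighbor mistracking** — the distance from a tracked
  particle to the *second* nearest detection in the next frame; the
  fraction of such distances inside the max jump radius upper-bounds the
  probability that the nearest-neighbor link picked the wrong particle.

Parameter sweeps over Threshold and max jump turn both metrics into
objective parameter-selection rules (target fraction 1% by default; 1–5%
is a reasonable range).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AcquisitionParams, Detection, LinkingParams, ROIMask, TrackTable

log = logging.getLogger(__name__)


@dataclass
class QCReport:
    fraction_snr_below: float
    snr_cutoff: float
    fraction_2nn_within_mj: float | None
    mj_px: float | None
    snr_histogram: pd.DataFrame | None = None
    displacement_histogram: pd.DataFrame | None = None
    second_nn_histogram: pd.DataFrame | None = None
    per_frame_counts: pd.DataFrame | None = None
    median_sigma_total_px: float | None = None

    def to_dict(self) -> dict:
        out = {
            "fraction_snr_below": self.fraction_snr_below,
            "snr_cutoff": self.snr_cutoff,
            "fraction_2nn_within_mj": self.fraction_2nn_within_mj,
            "mj_px": self.mj_px,
            "median_sigma_total_px": self.median_sigma_total_px,
        }
        return out


def airy_radius(acq: AcquisitionParams) -> tuple[float, int]:
    """Airy radius r = 1.22 λ / (2 ρ NA) in pixels: (continuous, mask integer).

    The integer radius (ceiling) defines disk membership for photometry
    masks, keeping the full Airy core.
    """
    r = 1.22 * acq.wavelength_nm / (2.0 * acq.pixel_size_nm * acq.numerical_aperture)
    return float(r), int(np.ceil(r))


def photometry(
    image: np.ndarray, detection: Detection, acq: AcquisitionParams
) -> tuple[float, float]:
    """Mean intensity over the Airy disk and over the background donut.

    Disk: pixels with center distance d <= ceil(r_Airy) from the fitted
    position; donut: ceil(r_Airy) + 2 < d <= ceil(r_Airy) + 3. Detections
    whose donut is clipped by the image edge are flagged and excluded from
    QC fractions. The detection's photometry and SNR fields are filled in
    place; the intensity pair is returned.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    _, r_disk = airy_radius(acq)
    r_outer = r_disk + 3
    x, y = detection.x, detection.y
    if x - r_outer < -0.5 or x + r_outer > w - 0.5 or y - r_outer < -0.5 or y + r_outer > h - 0.5:
        detection.flagged = True
        return np.nan, np.nan
    x_lo, x_hi = int(np.floor(x - r_outer)), int(np.ceil(x + r_outer)) + 1
    y_lo, y_hi = int(np.floor(y - r_outer)), int(np.ceil(y + r_outer)) + 1
    x_lo, y_lo = max(x_lo, 0), max(y_lo, 0)
    x_hi, y_hi = min(x_hi, w), min(y_hi, h)
    yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    d = np.hypot(xx - x, yy - y)
    disk = d <= r_disk
    donut = (d > r_disk + 2) & (d <= r_disk + 3)
    if disk.sum() == 0 or donut.sum() == 0:
        detection.flagged = True
        return np.nan, np.nan
    particle = float(image[y_lo:y_hi, x_lo:x_hi][disk].mean())
    background = float(image[y_lo:y_hi, x_lo:x_hi][donut].mean())
    detection.particle_intensity = particle
    detection.background_intensity = background
    detection.snr = snr(particle, background) if background > 0 else np.nan
    if not background > 0:
        detection.flagged = True
    return particle, background


def snr(particle_intensity: float, background_intensity: float) -> float:
    """SNR = (I_particle - I_background) / I_background."""
    if background_intensity <= 0:
        raise ValueError("background intensity must be > 0")
    return (particle_intensity - background_intensity) / background_intensity


def snr_fraction_below(
    snr_values: np.ndarray | pd.Series, cutoff: float = 1.5
) -> tuple[float, pd.DataFrame]:
    """Fraction of detections with SNR below the cutoff, plus a histogram."""
    s = np.asarray(snr_values, dtype=float)
    s = s[np.isfinite(s)]
    if len(s) == 0:
        raise ValueError("no unflagged detections with finite SNR")
    frac = float(np.mean(s < cutoff))
    edges = np.linspace(0.0, max(s.max(), cutoff) * 1.05, 51)
    counts, _ = np.histogram(s, bins=edges)
    hist = pd.DataFrame({"snr_lo": edges[:-1], "snr_hi": edges[1:], "count": counts})
    return frac, hist


def second_nn_distances(detections: pd.DataFrame, table: TrackTable) -> np.ndarray:
    """Distance from each tracked localization to the 2nd nearest detection
    in the following frame.

    Localizations whose next frame holds fewer than two detections cannot
    define a second neighbor and are skipped.
    """
    by_frame = {
        int(f): grp[["x_px", "y_px"]].to_numpy(dtype=float)
        for f, grp in detections.groupby("frame")
    }
    real = table.df[~table.df["interpolated"]]
    dists = []
    n_excluded = 0
    for _, row in real.iterrows():
        nxt = by_frame.get(int(row["frame"]) + 1)
        if nxt is None or len(nxt) < 2:
            n_excluded += 1
            continue
        d = np.hypot(nxt[:, 0] - row["x_px"], nxt[:, 1] - row["y_px"])
        dists.append(np.partition(d, 1)[1])
    if n_excluded:
        log.info("%d tracked localization(s) excluded from 2nd-NN metric", n_excluded)
    return np.asarray(dists)


def second_nn_within_mj(
    detections: pd.DataFrame,
    table: TrackTable,
    mj_px: float,
) -> tuple[float, pd.DataFrame]:
    """Second-nearest-neighbor mistracking metric.

    Fraction of second-nearest-neighbor distances (see
    :func:`second_nn_distances`) within the max jump radius, plus their
    histogram.
    """
    dists = second_nn_distances(detections, table)
    if len(dists) == 0:
        raise ValueError("no tracked particle has >= 2 detections in its next frame")
    frac = float(np.mean(dists <= mj_px))
    edges = np.linspace(0.0, max(dists.max(), mj_px) * 1.05, 51)
    counts, _ = np.histogram(dists, bins=edges)
    hist = pd.DataFrame({"d_lo_px": edges[:-1], "d_hi_px": edges[1:], "count": counts})
    return frac, hist


def threshold_sweep(
    movie: np.ndarray,
    thresholds: list[float],
    acq: AcquisitionParams,
    detection_params=None,
    roi: ROIMask | None = None,
    snr_cutoff: float = 1.5,
    target: float = 0.01,
) -> tuple[pd.DataFrame, float | None]:
    """fraction_snr_below as a function of Threshold.

    One detection pass per threshold (ascending); recommends the smallest
    threshold whose fraction falls below ``target``, or None.
    """
    from .detect import DetectionParams, detect_movie

    if detection_params is None:
        detection_params = DetectionParams()
    rows = []
    recommended = None
    for thr in sorted(thresholds):
        params = DetectionParams(
            threshold=thr,
            bandpass_low_px=detection_params.bandpass_low_px,
            bandpass_high_px=detection_params.bandpass_high_px,
            fit_window_px=detection_params.fit_window_px,
        )
        det = detect_movie(movie, params, roi=roi, acq=acq)
        if len(det) == 0:
            rows.append((thr, 0, np.nan))
            continue
        ok = det[~det["flagged"]] if "flagged" in det.columns else det
        try:
            frac, _ = snr_fraction_below(ok["snr"], cutoff=snr_cutoff)
        except ValueError:
            rows.append((thr, len(det), np.nan))
            continue
        rows.append((thr, len(det), frac))
        if recommended is None and frac < target:
            recommended = thr
    return pd.DataFrame(rows, columns=["threshold", "n_detections", "fraction_snr_below"]), recommended


def maxjump_sweep(
    detections: pd.DataFrame,
    mj_values: list[float],
    params: LinkingParams,
    acq: AcquisitionParams | None = None,
    target: float = 0.01,
) -> tuple[pd.DataFrame, float | None]:
    """fraction_2nn_within_mj as a function of the max jump radius.

    The second-nearest-neighbor distance pool is built once, from a
    linking at the largest radius in the sweep; each candidate MJ is then
    a threshold on that fixed histogram — which makes the fraction exactly
    non-decreasing in MJ and mirrors sweeping the radius over one
    second-NN histogram. Recommends the largest MJ whose fraction stays
    below ``target`` (mobility constraints on MJ are the user's
    responsibility), or None.
    """
    from .link import link_tracks

    mj_values = sorted(mj_values)
    p = LinkingParams(
        max_jump_px=max(mj_values),
        gaps_to_close=params.gaps_to_close,
        shortest_track=params.shortest_track,
        scale_mj_across_gap=params.scale_mj_across_gap,
    )
    table = link_tracks(detections, p, acq=acq)
    dists = second_nn_distances(detections, table) if len(table) else np.array([])
    if len(dists) == 0:
        return pd.DataFrame(columns=["mj_px", "fraction_2nn_within_mj"]), None
    rows = []
    recommended = None
    for mj in mj_values:
        frac = float(np.mean(dists <= mj))
        rows.append((mj, frac))
        if frac < target:
            recommended = mj
    return pd.DataFrame(rows, columns=["mj_px", "fraction_2nn_within_mj"]), recommended


def qc_report(
    detections: pd.DataFrame,
    table: TrackTable | None = None,
    mj_px: float | None = None,
    snr_cutoff: float = 1.5,
) -> QCReport:
    """Bundle the QC metrics for one movie into a report."""
    from .detect import localization_precision
    from .link import tracked_fraction as _tf

    ok = detections
    if "flagged" in detections.columns:
        ok = detections[~detections["flagged"]]
    frac_snr, snr_hist = snr_fraction_below(ok["snr"], cutoff=snr_cutoff)
    frac_2nn, nn_hist, counts, disp_hist, med_sigma = None, None, None, None, None
    if table is not None and mj_px is not None and len(table) > 0:
        try:
            frac_2nn, nn_hist = second_nn_within_mj(detections, table, mj_px)
        except ValueError:
            pass
        counts = _tf(detections, table)
        disp = table.displacements(1)
        if len(disp):
            edges = np.linspace(0.0, disp["r"].max() * 1.05 + 1e-9, 51)
            c, _ = np.histogram(disp["r"], bins=edges)
            disp_hist = pd.DataFrame({"r_lo_px": edges[:-1], "r_hi_px": edges[1:], "count": c})
    if "sigma_x_px" in detections.columns and detections["sigma_x_px"].notna().any():
        try:
            med_sigma = localization_precision(
                detections["sigma_x_px"].to_numpy(), detections["sigma_y_px"].to_numpy()
            )["median_sigma_total_px"]
        except ValueError:
            pass
    return QCReport(
        fraction_snr_below=frac_snr,
        snr_cutoff=snr_cutoff,
        fraction_2nn_within_mj=frac_2nn,
        mj_px=mj_px,
        snr_histogram=snr_hist,
        second_nn_histogram=nn_hist,
        displacement_histogram=disp_hist,
        per_frame_counts=counts,
        median_sigma_total_px=med_sigma,
    )
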