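"""Shared domain types, unit conventions, and track-table validation.

Conventions used throughout the package:

* Coordinates are 0-based; frame 0 is the first image; pixel centers sit at
  integer coordinates.
* The raw track table stores positions in **pixels** and time in **frames**;
  analysis-facing quantities are reported in µm and seconds via the attached
  :class:`AcquisitionParams`.
* Gap-closed (interpolated) localizations carry ``interpolated=True`` and are
  excluded from displacement statistics by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical column order of the track-table CSV schema.
TRACK_COLUMNS = [
    "track_id",
    "frame",
    "x_px",
    "y_px",
    "sigma_x_px",
    "sigma_y_px",
    "amplitude",
    "particle_intensity",
    "background_intensity",
    "snr",
    "second_nn_px",
    "interpolated",
]

#: Columns that must be present for any analysis to run.
REQUIRED_COLUMNS = ["track_id", "frame", "x_px", "y_px"]


@dataclass(frozen=True)
class AcquisitionParams:
    """Microscope acquisition metadata attached to every track table.

    Parameters
    ----------
    pixel_size_nm
        Physical size of one camera pixel in the sample plane (nm).
    frame_interval_s
        Time between consecutive frame starts (s).
    exposure_s
        Illumination time per frame (s); at most ``frame_interval_s``.
    wavelength_nm
        Emission wavelength of the fluorophore (nm).
    numerical_aperture
        Objective NA.
    axial_range_um
        Axial detection depth dZ (µm), used by the defocalization
        correction of the free population in jump-distance fits.
    """

    pixel_size_nm: float = 104.0
    frame_interval_s: float = 0.012
    exposure_s: float = 0.012
    wavelength_nm: float = 580.0
    numerical_aperture: float = 1.45
    axial_range_um: float = 0.7

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_nm",
            "frame_interval_s",
            "exposure_s",
            "wavelength_nm",
            "numerical_aperture",
            "axial_range_um",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.exposure_s > self.frame_interval_s + 1e-12:
            raise ValueError("exposure_s must not exceed frame_interval_s")

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    def px_to_um(self, value_px):
        return np.asarray(value_px, dtype=float) * self.pixel_size_um

    def um_to_px(self, value_um):
        return np.asarray(value_um, dtype=float) / self.pixel_size_um


@dataclass
class Detection:
    """One sub-pixel localization in one frame, with photometry.

    ``x, y`` are continuous pixel coordinates; ``sigma_x, sigma_y`` are the
    per-axis standard errors of the fitted center (localization
    uncertainty, pixels). Photometry fields are filled by the QC module;
    ``snr`` follows (I_particle - I_background) / I_background.
    """

    frame: int
    x: float
    y: float
    sigma_x: float = np.nan
    sigma_y: float = np.nan
    amplitude: float = np.nan
    particle_intensity: float = np.nan
    background_intensity: float = np.nan
    snr: float = np.nan
    second_nn_px: float = np.nan
    flagged: bool = False

    @property
    def sigma_total(self) -> float:
        return float(np.hypot(self.sigma_x, self.sigma_y))


def detections_to_df(detections) -> pd.DataFrame:
    """Stack Detection objects into the track-table column schema (no track_id)."""
    rows = [
        {
            "frame": d.frame,
            "x_px": d.x,
            "y_px": d.y,
            "sigma_x_px": d.sigma_x,
            "sigma_y_px": d.sigma_y,
            "amplitude": d.amplitude,
            "particle_intensity": d.particle_intensity,
            "background_intensity": d.background_intensity,
            "snr": d.snr,
            "second_nn_px": d.second_nn_px,
            "flagged": d.flagged,
        }
        for d in detections
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LinkingParams:
    """Nearest-neighbor linking parameters.

    ``max_jump_px`` is the maximum frame-to-frame displacement (MJ),
    ``gaps_to_close`` the number of frames a particle may vanish while its
    track stays open, and ``shortest_track`` the minimum number of
    localizations for a track to be kept.
    """

    max_jump_px: float = 6.0
    gaps_to_close: int = 1
    shortest_track: int = 2
    scale_mj_across_gap: bool = False

    def __post_init__(self) -> None:
        if not self.max_jump_px > 0:
            raise ValueError("max_jump_px must be > 0")
        if self.gaps_to_close < 0:
            raise ValueError("gaps_to_close must be >= 0")
        if self.shortest_track < 2:
            raise ValueError("shortest_track must be >= 2")


@dataclass
class ROIMask:
    """Region of interest: a closed polygon in pixel coordinates.

    ``vertices`` is an (n, 2) array of (x, y) pairs. ``contains`` tests
    points; ``to_mask`` rasterizes onto an image shape.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if self.vertices.shape[0] < 3 or self.vertices.shape[1] != 2:
            raise ValueError("ROI polygon needs at least 3 (x, y) vertices")

    def contains(self, x, y) -> np.ndarray:
        from matplotlib.path import Path

        pts = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])
        return Path(self.vertices).contains_points(pts, radius=1e-9)

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return self.contains(xx.ravel(), yy.ravel()).reshape(shape)

    @classmethod
    def full_frame(cls, shape: tuple[int, int]) -> "ROIMask":
        h, w = shape
        return cls(np.array([[-0.5, -0.5], [w - 0.5, -0.5], [w - 0.5, h - 0.5], [-0.5, h - 0.5]]))


@dataclass
class TrackTable:
    """Tidy table of linked localizations plus acquisition metadata.

    ``df`` holds one row per localization with at least
    ``track_id, frame, x_px, y_px`` (full schema in :data:`TRACK_COLUMNS`);
    rows are sorted by (track_id, frame).
    """

    df: pd.DataFrame
    acq: AcquisitionParams = field(default_factory=AcquisitionParams)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"track table missing required column(s): {missing}")
        if "interpolated" not in self.df.columns:
            self.df = self.df.assign(interpolated=False)
        self.df = self.df.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_tracks(self) -> int:
        return self.df["track_id"].nunique()

    def track_lengths(self) -> pd.Series:
        return self.df.groupby("track_id").size()

    def displacements(self, lag: int = 1, include_interpolated: bool = False) -> pd.DataFrame:
        return displacements(self, lag, include_interpolated=include_interpolated)


def validate_track_table(table: TrackTable, params: LinkingParams) -> list[str]:
    """Check the TrackTable invariants; return a list of human-readable violations.

    An empty list means the table is well formed: rows sorted by
    (track_id, frame), frames strictly increasing within a track with gaps
    at most ``gaps_to_close + 1``, no duplicate (track_id, frame), and every
    track at least ``shortest_track`` localizations long.
    """
    df = table.df
    violations: list[str] = []

    sort_keys = df[["track_id", "frame"]].to_numpy()
    if len(df) > 1:
        order = np.lexsort((sort_keys[:, 1], sort_keys[:, 0]))
        if not np.array_equal(order, np.arange(len(df))):
            violations.append("rows not sorted by (track_id, frame)")

    for tid, grp in df.groupby("track_id"):
        frames = grp["frame"].to_numpy()
        if len(frames) != len(np.unique(frames)):
            violations.append(f"track {tid}: duplicate (track_id, frame) rows")
        diffs = np.diff(np.sort(frames))
        if np.any(diffs == 0):
            pass  # covered by the duplicate check above
        elif np.any(diffs > params.gaps_to_close + 1):
            worst = int(diffs.max()) - 1
            violations.append(
                f"track {tid}: gap of {worst} missing frame(s) exceeds gaps_to_close={params.gaps_to_close}"
            )
        if len(frames) < params.shortest_track:
            violations.append(
                f"track {tid}: short track ({len(frames)} < shortest_track={params.shortest_track})"
            )
    return violations


def displacements(table: TrackTable, lag: int, include_interpolated: bool = False) -> pd.DataFrame:
    """Per-track displacements at a given frame lag.

    Returns a DataFrame with columns ``track_id, frame, dx, dy, r`` (pixels)
    and ``r_um``. A pair contributes only when both endpoints exist exactly
    ``lag`` frames apart; by default pairs touching an interpolated
    (gap-closed) localization are dropped, so no fabricated positions enter
    displacement statistics.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    df = table.df
    tid = df["track_id"].to_numpy()
    frame = df["frame"].to_numpy()
    x = df["x_px"].to_numpy(dtype=float)
    y = df["y_px"].to_numpy(dtype=float)
    interp = df["interpolated"].to_numpy(dtype=bool)

    out = {k: [] for k in ("track_id", "frame", "dx", "dy")}
    # rows are sorted by (track_id, frame): match i with j where same track
    # and frame difference == lag, via a per-track frame index
    start = 0
    n = len(df)
    while start < n:
        end = start
        while end < n and tid[end] == tid[start]:
            end += 1
        f = frame[start:end]
        idx_of = {fv: i for i, fv in enumerate(f)}
        for i, fv in enumerate(f):
            j = idx_of.get(fv + lag)
            if j is None:
                continue
            if not include_interpolated and (interp[start + i] or interp[start + j]):
                continue
            out["track_id"].append(tid[start])
            out["frame"].append(fv)
            out["dx"].append(x[start + j] - x[start + i])
            out["dy"].append(y[start + j] - y[start + i])
        start = end

    res = pd.DataFrame(out)
    if len(res) == 0:
        res = pd.DataFrame(columns=["track_id", "frame", "dx", "dy"])
    r = np.hypot(res["dx"].to_numpy(dtype=float), res["dy"].to_numpy(dtype=float))
    res["r"] = r
    res["r_um"] = table.acq.px_to_um(r)
    return res


def empty_track_df() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        TRACK_COLUMNS,
        [int, int, float, float, float, float, float, float, float, float, float, bool],
    )})
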