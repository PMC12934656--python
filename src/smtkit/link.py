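"""Nearest-neighbor track linking with gap closing.

Within each frame pair, all candidate (open track end, new detection)
pairs within the maximum jump are sorted by distance and accepted
greedily, shortest first — an order-independent variant of nearest
neighbor assignment (equal distances break on lower detection index, then
lower track id). A track end stays open for ``gaps_to_close`` extra
frames; by default the same max jump applies across a gap (set
``scale_mj_across_gap`` to scale it by sqrt(gap + 1) instead). Skipped
frames inside a track are filled by linear interpolation and flagged
``interpolated``; tracks with fewer real localizations than
``shortest_track`` are discarded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import AcquisitionParams, LinkingParams, TrackTable, empty_track_df


def link_tracks(
    detections: pd.DataFrame,
    params: LinkingParams,
    acq: AcquisitionParams | None = None,
) -> TrackTable:
    """Connect per-frame detections into tracks.

    ``detections`` needs columns ``frame, x_px, y_px``; all other columns
    are carried through. Returns a :class:`TrackTable` satisfying the
    linking invariants (no in-track jump above max_jump_px, gaps closed up
    to ``gaps_to_close``, minimum length enforced).
    """
    if acq is None:
        acq = AcquisitionParams()
    if len(detections) == 0:
        return TrackTable(empty_track_df(), acq)
    det = detections.reset_index(drop=True)
    frames_present = np.sort(det["frame"].unique())

    # open tracks: list of [row_indices], last_frame cached separately
    open_rows: list[list[int]] = []
    open_last: list[int] = []
    finished: list[list[int]] = []

    by_frame = {int(f): grp.index.to_numpy() for f, grp in det.groupby("frame")}
    x = det["x_px"].to_numpy(dtype=float)
    y = det["y_px"].to_numpy(dtype=float)
    fr = det["frame"].to_numpy()

    for f in range(int(frames_present[0]), int(frames_present[-1]) + 1):
        rows = by_frame.get(f, np.array([], dtype=int))
        # candidate links
        pairs = []
        for ti, (trk, last) in enumerate(zip(open_rows, open_last)):
            gap = f - last - 1
            if gap > params.gaps_to_close:
                continue
            mj = params.max_jump_px
            if params.scale_mj_across_gap:
                mj *= np.sqrt(gap + 1.0)
            lx, ly = x[trk[-1]], y[trk[-1]]
            for di, row in enumerate(rows):
                d = float(np.hypot(x[row] - lx, y[row] - ly))
                if d <= mj:
                    pairs.append((d, di, ti))
        pairs.sort()
        used_det: set[int] = set()
        used_trk: set[int] = set()
        for d, di, ti in pairs:
            if di in used_det or ti in used_trk:
                continue
            used_det.add(di)
            used_trk.add(ti)
            open_rows[ti].append(int(rows[di]))
            open_last[ti] = f
        for di, row in enumerate(rows):
            if di not in used_det:
                open_rows.append([int(row)])
                open_last.append(f)
        # retire tracks that can no longer be extended
        still_rows, still_last = [], []
        for trk, last in zip(open_rows, open_last):
            if f - last > params.gaps_to_close:
                finished.append(trk)
            else:
                still_rows.append(trk)
                still_last.append(last)
        open_rows, open_last = still_rows, still_last
    finished.extend(open_rows)

    out_parts = []
    tid = 0
    for trk in finished:
        if len(trk) < params.shortest_track:
            continue
        part = det.loc[trk].copy()
        part.insert(0, "track_id", tid)
        part["interpolated"] = False
        # fill closed gaps by linear interpolation
        fvals = fr[trk]
        gaps = np.flatnonzero(np.diff(fvals) > 1)
        fills = []
        for g in gaps:
            f0, f1 = int(fvals[g]), int(fvals[g + 1])
            r0, r1 = trk[g], trk[g + 1]
            for fm in range(f0 + 1, f1):
                w = (fm - f0) / (f1 - f0)
                fills.append(
                    {
                        "track_id": tid,
                        "frame": fm,
                        "x_px": x[r0] * (1 - w) + x[r1] * w,
                        "y_px": y[r0] * (1 - w) + y[r1] * w,
                        "interpolated": True,
                    }
                )
        out_parts.append(part)
        if fills:
            out_parts.append(pd.DataFrame(fills))
        tid += 1

    if not out_parts:
        return TrackTable(empty_track_df(), acq)
    df = pd.concat(out_parts, ignore_index=True)
    return TrackTable(df, acq)


def tracked_fraction(detections: pd.DataFrame, table: TrackTable) -> pd.DataFrame:
    """Per-frame (n_detected, n_tracked) series for the QC time plot.

    ``n_tracked`` counts real (non-interpolated) localizations that made
    it into a retained track; it can never exceed ``n_detected``.
    """
    det_counts = detections.groupby("frame").size()
    real = table.df[~table.df["interpolated"]]
    trk_counts = real.groupby("frame").size()
    frames = sorted(set(det_counts.index) | set(trk_counts.index))
    return pd.DataFrame(
        {
            "frame": frames,
            "n_detected": [int(det_counts.get(f, 0)) for f in frames],
            "n_tracked": [int(trk_counts.get(f, 0)) for f in frames],
        }
    )
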