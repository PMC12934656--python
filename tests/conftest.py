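import numpy as np
import pandas as pd
import pytest

from smtkit.core import AcquisitionParams, TrackTable
from smtkit.simulate import SimConfig, simulate_tracks


@pytest.fixture
def acq():
    return AcquisitionParams()


@pytest.fixture
def slow_acq():
    return AcquisitionParams(frame_interval_s=0.2, exposure_s=0.01)


def make_table(tracks: dict[int, list[tuple[int, float, float]]], acq=None) -> TrackTable:
    """Build a TrackTable from {track_id: [(frame, x_px, y_px), ...]}."""
    rows = [
        {"track_id": tid, "frame": f, "x_px": x, "y_px": y}
        for tid, pts in tracks.items()
        for f, x, y in pts
    ]
    return TrackTable(pd.DataFrame(rows), acq or AcquisitionParams())


@pytest.fixture
def brownian_table():
    """2000 free tracks, D=1 µm²/s, Δt=12 ms, no localization error."""
    cfg = SimConfig(
        diffusivities=(1.0,),
        labels=("free",),
        n_particles=2000,
        n_frames=10,
        dt_s=0.012,
        loc_sigma_um=0.0,
        fov_um=80.0,
        seed=11,
    )
    table, _ = simulate_tracks(cfg)
    return table
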