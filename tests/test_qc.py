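import numpy as np
import pandas as pd
import pytest

from smtkit.core import AcquisitionParams, Detection, LinkingParams
from smtkit.link import link_tracks
from smtkit.qc import (
    airy_radius,
    maxjump_sweep,
    photometry,
    second_nn_within_mj,
    snr,
    snr_fraction_below,
    threshold_sweep,
)


class TestAiryRadius:
    def test_printed_formula(self):
        acq = AcquisitionParams(wavelength_nm=580, pixel_size_nm=104, numerical_aperture=1.45)
        r, r_int = airy_radius(acq)
        assert r == pytest.approx(1.22 * 580 / (2 * 104 * 1.45), rel=1e-12)
        assert r == pytest.approx(2.35, abs=0.01)
        assert r_int == 3

    def test_doubling_pixel_size_halves_radius(self):
        a1 = AcquisitionParams(pixel_size_nm=104)
        a2 = AcquisitionParams(pixel_size_nm=208)
        assert airy_radius(a1)[0] == pytest.approx(2 * airy_radius(a2)[0])

    def test_cancellation(self):
        acq = AcquisitionParams(wavelength_nm=2 * 104 * 1.45, pixel_size_nm=104,
                                numerical_aperture=1.45)
        assert airy_radius(acq)[0] == pytest.approx(1.22)


class TestPhotometry:
    # lambda chosen so ceil(r_Airy) = 2: integer disk of 13 pixels
    ACQ = AcquisitionParams(wavelength_nm=340, pixel_size_nm=104, numerical_aperture=1.45)

    def test_flat_field(self):
        img = np.full((32, 32), 100.0)
        det = Detection(frame=0, x=16.0, y=16.0)
        p, b = photometry(img, det, self.ACQ)
        assert p == pytest.approx(100.0)
        assert b == pytest.approx(100.0)
        assert det.snr == pytest.approx(0.0)

    def test_delta_spot_disk_average(self):
        assert airy_radius(self.ACQ)[1] == 2
        img = np.full((32, 32), 100.0)
        img[16, 16] = 1000.0
        det = Detection(frame=0, x=16.0, y=16.0)
        p, b = photometry(img, det, self.ACQ)
        assert p == pytest.approx((1000 + 12 * 100) / 13)
        assert b == pytest.approx(100.0)

    def test_linear_ramp_background_matches_center(self):
        xx = np.tile(np.arange(64, dtype=float), (64, 1))
        img = 50.0 + 2.0 * xx
        det = Detection(frame=0, x=32.0, y=32.0)
        p, b = photometry(img, det, self.ACQ)
        assert b == pytest.approx(50.0 + 2.0 * 32.0, rel=0.01)

    def test_edge_clipped_donut_flagged(self):
        img = np.full((32, 32), 100.0)
        det = Detection(frame=0, x=2.0, y=16.0)
        p, b = photometry(img, det, self.ACQ)
        assert det.flagged and np.isnan(p)


class TestSNR:
    @pytest.mark.parametrize("ip,ibg,expected", [(100, 100, 0.0), (250, 100, 1.5)])
    def test_formula(self, ip, ibg, expected):
        assert snr(ip, ibg) == pytest.approx(expected)

    def test_cutoff_ratio(self):
        # I_p = 2.5 I_bg sits exactly at the 1.5 cutoff
        assert snr(2.5 * 80.0, 80.0) == pytest.approx(1.5)

    def test_nonpositive_background_rejected(self):
        with pytest.raises(ValueError):
            snr(10.0, 0.0)

    def test_fraction_below(self):
        frac, hist = snr_fraction_below(np.array([0.5, 2.0, 3.0, 4.0]))
        assert frac == 0.25
        assert hist["count"].sum() == 4
        frac2, _ = snr_fraction_below(np.array([2.0, 3.0]))
        assert frac2 == 0.0


class TestSecondNN:
    def _table(self, rows, acq=None):
        df = pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px"])
        from smtkit.core import TrackTable

        return TrackTable(df, acq or AcquisitionParams())

    def test_far_second_neighbor_not_within(self):
        det = pd.DataFrame({"frame": [0, 1, 1], "x_px": [0.0, 1.0, 10.0], "y_px": 0.0})
        table = self._table([(0, 0, 0.0, 0.0), (0, 1, 1.0, 0.0)])
        frac, _ = second_nn_within_mj(det, table, mj_px=4.0)
        assert frac == 0.0

    def test_close_second_neighbor_within(self):
        det = pd.DataFrame({"frame": [0, 1, 1, 1], "x_px": [0.0, 1.0, 10.0, 2.0], "y_px": 0.0})
        table = self._table([(0, 0, 0.0, 0.0), (0, 1, 1.0, 0.0)])
        frac, _ = second_nn_within_mj(det, table, mj_px=4.0)
        assert frac == 1.0

    def test_single_next_frame_detection_excluded(self):
        det = pd.DataFrame({"frame": [0, 1], "x_px": [0.0, 1.0], "y_px": 0.0})
        table = self._table([(0, 0, 0.0, 0.0), (0, 1, 1.0, 0.0)])
        with pytest.raises(ValueError):
            second_nn_within_mj(det, table, mj_px=4.0)

    def test_brute_force_oracle_on_random_field(self):
        rng = np.random.default_rng(16)
        n_per, mj = 30, 5.0
        rows = [(f, x, y) for f in range(6) for x, y in rng.uniform(0, 100, (n_per, 2))]
        det = pd.DataFrame(rows, columns=["frame", "x_px", "y_px"])
        table = link_tracks(det, LinkingParams(max_jump_px=mj))
        frac, hist = second_nn_within_mj(det, table, mj)
        # brute force: for every tracked localization compute all pairwise
        # distances to the next frame and take the 2nd smallest
        real = table.df[~table.df["interpolated"]]
        brute = []
        for _, row in real.iterrows():
            nxt = det[det["frame"] == row["frame"] + 1]
            if len(nxt) < 2:
                continue
            d = np.sort(np.hypot(nxt["x_px"] - row["x_px"], nxt["y_px"] - row["y_px"]))
            brute.append(d[1])
        assert frac == pytest.approx(np.mean(np.asarray(brute) <= mj))
        assert hist["count"].sum() == len(brute)


class TestSweeps:
    def test_maxjump_fraction_monotone_and_recommendation(self):
        rng = np.random.default_rng(17)
        rows = [(f, x, y) for f in range(8) for x, y in rng.uniform(0, 60, (40, 2))]
        det = pd.DataFrame(rows, columns=["frame", "x_px", "y_px"])
        mj_values = [1.0, 2.0, 4.0, 8.0, 12.0]
        out, rec = maxjump_sweep(det, mj_values, LinkingParams(max_jump_px=6), target=0.05)
        frac = out["fraction_2nn_within_mj"].to_numpy()
        assert (np.diff(frac) >= -1e-12).all()
        below = out[out["fraction_2nn_within_mj"] < 0.05]
        assert rec == (below["mj_px"].max() if len(below) else None)

    def test_threshold_sweep_on_bright_movie(self):
        from smtkit.simulate import SimConfig, render_movie, simulate_tracks

        acq = AcquisitionParams()
        cfg = SimConfig(diffusivities=(0.05,), labels=("s",), n_particles=15, n_frames=4,
                        fov_um=15.0, loc_sigma_um=0.0, seed=18)
        _, truth = simulate_tracks(cfg, acq=acq)
        movie = render_movie(truth, acq, photons_per_frame=5000, background_level=20, seed=2)
        out, rec = threshold_sweep(movie, [40.0, 80.0, 160.0], acq, target=0.01)
        # only bright simulated spots: fraction ~ 0 everywhere, smallest wins
        assert rec == 40.0
        frac = out["fraction_snr_below"].to_numpy()
        assert (np.diff(frac) <= 1e-12).all()  # non-increasing in threshold
        assert (out["n_detections"].to_numpy() >= 0).all()

    def test_single_threshold_one_row(self):
        from smtkit.simulate import SimConfig, render_movie, simulate_tracks

        acq = AcquisitionParams()
        cfg = SimConfig(diffusivities=(0.05,), labels=("s",), n_particles=5, n_frames=2,
                        fov_um=10.0, seed=19)
        _, truth = simulate_tracks(cfg, acq=acq)
        movie = render_movie(truth, acq, photons_per_frame=5000, background_level=20, seed=3)
        out, _ = threshold_sweep(movie, [60.0], acq)
        assert len(out) == 1
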