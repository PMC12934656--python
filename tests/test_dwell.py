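import numpy as np
import pandas as pd
import pytest

from smtkit import dwell
from smtkit.core import AcquisitionParams
from smtkit.simulate import SimConfig, simulate_tracks

from .conftest import make_table


@pytest.fixture(scope="module")
def reference_table():
    """Immobile emitters with 30 nm localization noise at slow-SMT timing."""
    acq = AcquisitionParams(frame_interval_s=0.2, exposure_s=0.01)
    cfg = SimConfig(diffusivities=(0.0,), labels=("bound",), n_particles=400, n_frames=40,
                    dt_s=0.2, loc_sigma_um=0.03, fov_um=40.0, seed=21)
    table, _ = simulate_tracks(cfg, acq=acq)
    return table


class TestCalibration:
    def test_rmin_matches_rayleigh_percentile(self, reference_table):
        # displacement of an immobile emitter with sigma_loc = 30 nm is
        # Rayleigh(sqrt(2)*30 nm); its 99th pct = sqrt(2*(2*0.03^2)*ln 100)
        r_min = dwell.calibrate_rmin(reference_table)
        expected = np.sqrt(2 * (2 * 0.03**2) * np.log(100))
        assert r_min == pytest.approx(expected, rel=0.05)

    def test_rmin_constant_displacements(self):
        pts = [(f, 0.5 * (f % 2), 0.0) for f in range(200)]  # constant 0.5 px jumps
        t = make_table({0: pts})
        assert dwell.calibrate_rmin(t) == pytest.approx(0.5 * t.acq.pixel_size_um)

    def test_rmin_needs_enough_data(self):
        t = make_table({0: [(0, 0.0, 0.0), (1, 1.0, 0.0)]})
        with pytest.raises(ValueError):
            dwell.calibrate_rmin(t)

    def test_rmax_noise_only_is_lag_independent(self, reference_table):
        # immobile emitters: displacement distribution identical at all lags
        r_min = dwell.calibrate_rmin(reference_table)
        r_max = dwell.calibrate_rmax(reference_table, 4)
        assert r_max == pytest.approx(r_min, rel=0.1)

    def test_rmax_grows_for_diffusing_reference(self):
        cfg = SimConfig(diffusivities=(0.002,), labels=("slow",), n_particles=300,
                        n_frames=30, dt_s=0.2, loc_sigma_um=0.01, fov_um=40.0, seed=22)
        table, _ = simulate_tracks(cfg)
        r1 = dwell.calibrate_rmin(table)
        r4 = dwell.calibrate_rmax(table, 4)
        assert r4 > r1


class TestNmin:
    def test_small_rmin_single_frame(self):
        # p1 = 1 - exp(-0.04/4) ~ 0.00995 < 0.01 already
        assert dwell.compute_nmin(0.2, 5.0, 0.2) == 1

    def test_printed_example_four_frames(self):
        # r_min = 1 um: p1 ~ 0.221; 0.221^3 > 1% > 0.221^4
        assert dwell.compute_nmin(1.0, 5.0, 0.2) == 4

    def test_pcut_one_always_single_frame(self):
        assert dwell.compute_nmin(1.0, 5.0, 0.2, p_cut=1.0) == 1

    @pytest.mark.parametrize("r_min", np.linspace(0.1, 1.5, 8))
    def test_guarantee_bracket(self, r_min):
        n = dwell.compute_nmin(r_min, 5.0, 0.2, p_cut=0.01)
        p1 = dwell.per_frame_bound_probability(r_min, 5.0, 0.2)
        assert p1**n < 0.01
        if n > 1:
            assert p1 ** (n - 1) >= 0.01

    def test_brute_force_agreement(self):
        for r_min in (0.3, 0.6, 0.9, 1.2):
            p1 = dwell.per_frame_bound_probability(r_min, 5.0, 0.2)
            brute = next(n for n in range(1, 100) if p1**n < 0.01)
            assert dwell.compute_nmin(r_min, 5.0, 0.2) == brute


class TestSegments:
    def test_immobile_track_one_full_segment(self, reference_table):
        params = dwell.calibrate_bound_call(reference_table)
        pts = [(f, 10.0, 10.0) for f in range(20)]
        t = make_table({0: pts}, acq=reference_table.acq)
        segs = dwell.call_bound_segments(t, params)
        assert len(segs) == 1
        assert segs["n_frames"].iloc[0] == 20
        assert segs["duration_s"].iloc[0] == pytest.approx(19 * 0.2)

    def test_free_track_produces_no_segments(self, reference_table):
        params = dwell.calibrate_bound_call(reference_table)
        acq = reference_table.acq
        cfg = SimConfig(diffusivities=(5.0,), labels=("free",), n_particles=100,
                        n_frames=20, dt_s=0.2, loc_sigma_um=0.03, fov_um=60.0, seed=23)
        free, _ = simulate_tracks(cfg, acq=acq)
        segs = dwell.call_bound_segments(free, params)
        # each displacement pair is a misclassification opportunity with
        # chance p1^n_min < 1%; segments should be correspondingly rare
        n_pairs = len(free.displacements(1))
        p1 = dwell.per_frame_bound_probability(params.r_min_um, 5.0, 0.2)
        assert len(segs) <= max(3 * p1**params.n_min * n_pairs, 5)

    def test_alternating_mobility_two_segments(self, reference_table):
        params = dwell.calibrate_bound_call(reference_table)
        rng = np.random.default_rng(3)
        px = reference_table.acq.pixel_size_um
        pts, x, y = [], 20.0, 20.0
        for f in range(30):
            if 10 <= f < 20:  # free interlude: big jumps
                x += 2.0
                y += 2.0
            else:
                x += rng.normal(0, 0.01 / px)
                y += rng.normal(0, 0.01 / px)
            pts.append((f, x, y))
        t = make_table({0: pts}, acq=reference_table.acq)
        segs = dwell.call_bound_segments(t, params)
        assert len(segs) == 2


class TestSurvival:
    def test_closed_at_t(self):
        s = dwell.survival(np.array([1.0, 2.0, 3.0]), n_boot=10, seed=0)
        assert np.allclose(s.t_s, [1, 2, 3])
        assert np.allclose(s.s, [1.0, 2 / 3, 1 / 3])

    def test_identical_durations_step(self):
        s = dwell.survival(np.full(50, 2.0), n_boot=10, seed=0)
        assert len(s.t_s) == 1 and s.s[0] == 1.0

    def test_raw_survival_nonincreasing(self):
        rng = np.random.default_rng(1)
        s = dwell.survival(rng.exponential(2.0, 500), n_boot=10, seed=0)
        assert (np.diff(s.s) <= 1e-12).all()

    def test_exponential_durations_fit_rate(self):
        rng = np.random.default_rng(4)
        k = 0.5
        s = dwell.survival(rng.exponential(1 / k, 4000), n_boot=10, seed=0)
        # log-linear fit of S(t)
        sel = s.s > 0.02
        slope = np.polyfit(s.t_s[sel], np.log(s.s[sel]), 1)[0]
        assert -slope == pytest.approx(k, rel=0.1)


class TestTripleExponential:
    def test_parameter_recovery(self):
        t = np.linspace(0.0, 40.0, 200)
        true = 0.5 * np.exp(-5 * t) + 0.3 * np.exp(-0.5 * t) + 0.2 * np.exp(-0.05 * t)
        curve = dwell.SurvivalCurve(t_s=t, s=true, ci_low=true, ci_high=true)
        fit = dwell.fit_triple_exponential(curve, seed=0)
        assert np.allclose(np.sort(fit.rates), [0.05, 0.5, 5.0], rtol=0.1)
        assert fit.k_pb == pytest.approx(0.05, rel=0.1)

    def test_single_exponential_input_recovers_rate(self):
        t = np.linspace(0.0, 20.0, 100)
        s = np.exp(-0.3 * t)
        fit = dwell.fit_triple_exponential(
            dwell.SurvivalCurve(t_s=t, s=s, ci_low=s, ci_high=s), seed=0
        )
        assert fit.k_pb == pytest.approx(0.3, rel=0.15)

    def test_constant_curve_degenerate(self):
        t = np.linspace(0, 10, 20)
        s = np.ones_like(t)
        with pytest.raises(ValueError):
            dwell.fit_triple_exponential(dwell.SurvivalCurve(t_s=t, s=s, ci_low=s, ci_high=s))


class TestCorrection:
    def _curve(self, t, s):
        return dwell.SurvivalCurve(t_s=t, s=s, ci_low=s, ci_high=s)

    def test_zero_rate_is_identity(self):
        t = np.linspace(0, 5, 10)
        s = np.exp(-t)
        out = dwell.photobleach_correct(self._curve(t, s), 0.0)
        assert np.allclose(out.s, s)

    def test_removes_bleaching_decay_exactly(self):
        t = np.linspace(0, 5, 50)
        k, k_pb = 0.4, 0.25
        s_raw = np.exp(-(k + k_pb) * t)
        out = dwell.photobleach_correct(self._curve(t, s_raw), k_pb, t0=0.0)
        assert np.allclose(out.s, np.exp(-k * t))

    def test_halving_example(self):
        t = np.array([0.0, 1.0])
        s = np.array([1.0, 0.5])
        out = dwell.photobleach_correct(self._curve(t, s), np.log(2), t0=0.0)
        assert out.s[1] == pytest.approx(1.0)

    def test_negative_rate_rejected(self):
        t = np.array([0.0, 1.0])
        with pytest.raises(ValueError):
            dwell.photobleach_correct(self._curve(t, t), -1.0)

    def test_normalization_sets_intercept(self):
        t = np.array([0.0, 1.0])
        s = np.array([1.0, 0.4])
        out = dwell.normalize_to_bound_fraction(self._curve(t, s), 0.5)
        assert np.allclose(out.s, [0.5, 0.2])
        with pytest.raises(ValueError):
            dwell.normalize_to_bound_fraction(self._curve(t, s), 1.4)


def test_end_to_end_rate_recovery():
    """Bleaching-censored binding durations: corrected survival decays at k_u."""
    rng = np.random.default_rng(30)
    k_u, k_pb = 0.25, 0.6
    n = 6000
    ref = dwell.survival(rng.exponential(1 / k_pb, n), n_boot=5, seed=0)
    k_pb_est = dwell.fit_triple_exponential(ref, seed=0).k_pb
    tf_raw = dwell.survival(
        np.minimum(rng.exponential(1 / k_u, n), rng.exponential(1 / k_pb, n)),
        n_boot=5, seed=0,
    )
    sel_raw = tf_raw.s > 0.02
    raw_rate = -np.polyfit(tf_raw.t_s[sel_raw], np.log(tf_raw.s[sel_raw]), 1)[0]
    assert raw_rate == pytest.approx(k_u + k_pb, rel=0.1)
    corr = dwell.photobleach_correct(tf_raw, k_pb_est)
    sel = (corr.s > 0.02) & (tf_raw.s > 0.02)
    corr_rate = -np.polyfit(corr.t_s[sel], np.log(corr.s[sel]), 1)[0]
    assert corr_rate == pytest.approx(k_u, rel=0.1)
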